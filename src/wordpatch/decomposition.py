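"""Nonparametric ICA of voxel x condition response matrices.

Voxels are modeled as weighted sums of a small number of canonical
condition-response profiles; the decomposition first restricts the data
to its best rank-k subspace (SVD) and then rotates within that subspace
to maximize the non-Gaussianity of the voxel-weight distributions,
measured as histogram-based negentropy (no parametric density model).
Distinct neural populations mixing within voxels produce heavy-tailed,
sparse weight distributions, which is what the rotation seeks.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment, minimize_scalar

__all__ = [
    "Decomposition",
    "nonparametric_ica",
    "project_weights",
    "exclusion_robustness",
    "match_profiles",
]

#: Differential entropy of a standard Gaussian.
_H_GAUSS = 0.5 * np.log(2 * np.pi * np.e)


@dataclass
class Decomposition:
    """Canonical response profiles and voxel weights.

    ``profiles`` is (components x conditions) with unit-norm rows;
    ``weights`` is (voxels x components); ``weights @ profiles``
    reconstructs the rank-k approximation of the input.
    """

    profiles: np.ndarray
    weights: np.ndarray
    explained_variance: np.ndarray
    negentropy: float
    converged: bool
    n_iterations: int
    restart_objectives: np.ndarray
    degenerate: bool = False

    def reconstruct(self) -> np.ndarray:
        return self.weights @ self.profiles


def _histogram_entropy(x: np.ndarray) -> float:
    """Differential entropy of standardized data via a Freedman-Diaconis histogram."""
    z = (x - x.mean()) / x.std()
    iqr = np.subtract(*np.percentile(z, [75, 25]))
    width = 2 * iqr / len(z) ** (1 / 3)
    if width <= 0:
        width = 3.5 / len(z) ** (1 / 3)  # Scott fallback for peaked data
    n_bins = max(int(np.ceil(np.ptp(z) / width)), 2)
    counts, edges = np.histogram(z, bins=n_bins)
    p = counts[counts > 0] / len(z)
    h = float(-(p * np.log(p)).sum() + np.log(edges[1] - edges[0]))
    return h


def _negentropy(weights: np.ndarray) -> float:
    """Summed negentropy of each weight column (>= 0 up to estimator error)."""
    total = 0.0
    for j in range(weights.shape[1]):
        col = weights[:, j]
        if col.std() == 0:
            continue
        total += _H_GAUSS - _histogram_entropy(col)
    return total


def _pair_rotation(theta: float, k: int, i: int, j: int) -> np.ndarray:
    r = np.eye(k)
    c, s = np.cos(theta), np.sin(theta)
    r[i, i] = c
    r[j, j] = c
    r[i, j] = -s
    r[j, i] = s
    return r


def _optimize_rotation(
    weights: np.ndarray,
    rng: np.random.Generator,
    max_sweeps: int = 50,
    tol: float = 1e-6,
) -> tuple[np.ndarray, float, bool, int]:
    """Jacobi-style sweeps of pairwise planar rotations.

    Each pair's angle is optimized by bounded scalar search over one period
    of the objective; sweeps repeat until the summed negentropy stops
    improving.
    """
    k = weights.shape[1]
    rotation = np.eye(k)
    current = _negentropy(weights)
    sweeps = 0
    converged = False
    for sweep in range(max_sweeps):
        sweeps = sweep + 1
        improved = 0.0
        for i in range(k - 1):
            for j in range(i + 1, k):
                w2 = weights @ rotation[:, [i, j]]

                def neg(theta: float) -> float:
                    c, s = np.cos(theta), np.sin(theta)
                    a = c * w2[:, 0] + s * w2[:, 1]
                    b = -s * w2[:, 0] + c * w2[:, 1]
                    return -(_negentropy(np.column_stack([a, b])))

                res = minimize_scalar(
                    neg, bounds=(-np.pi / 4, np.pi / 4), method="bounded",
                    options={"xatol": 1e-4},
                )
                theta = float(res.x)
                gain = -res.fun - _negentropy(w2)
                if gain > tol:
                    rotation = rotation @ _pair_rotation(theta, k, i, j)
                    improved += gain
        total = _negentropy(weights @ rotation)
        if improved < tol:
            converged = True
            break
        current = total
    return rotation, _negentropy(weights @ rotation), converged, sweeps


def nonparametric_ica(
    data: np.ndarray,
    n_components: int = 3,
    n_restarts: int = 10,
    seed: int = 0,
    max_sweeps: int = 50,
    degeneracy_tol: float = 0.02,
) -> Decomposition:
    """Rank-k SVD followed by negentropy-maximizing rotation.

    The best of ``n_restarts`` random initial rotations is kept; components
    are ordered by explained variance and sign-fixed so the largest-
    magnitude profile element is positive.  Rows of ``profiles`` have unit
    norm.  A near-flat spread of restart objectives is flagged as
    ``degenerate`` (e.g. Gaussian weights, for which every rotation is an
    optimum).
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be a voxels x conditions matrix")
    v, c = data.shape
    if not np.isfinite(data).all():
        raise ValueError("data must be finite")
    if n_components > min(v, c):
        raise ValueError(
            f"cannot extract {n_components} components from a {v} x {c} matrix"
        )
    if v <= c:
        raise ValueError("need more voxels than conditions")
    rank = np.linalg.matrix_rank(data, tol=1e-10 * np.abs(data).max() * max(v, c))
    if n_components > rank:
        raise ValueError(
            f"requested {n_components} components but the data have rank {rank}"
        )
    u, s, vt = np.linalg.svd(data, full_matrices=False)
    base_weights = u[:, :n_components] * s[:n_components]
    base_profiles = vt[:n_components]
    rng = np.random.default_rng(seed)
    best = None
    objectives = []
    initial_objectives = []
    any_converged = False
    iters = 0
    for restart in range(n_restarts):
        if restart == 0:
            init = np.eye(n_components)
        else:
            q, r = np.linalg.qr(rng.standard_normal((n_components, n_components)))
            init = q * np.sign(np.diag(r))
        initial_objectives.append(_negentropy(base_weights @ init))
        rot, obj, conv, sweeps = _optimize_rotation(
            base_weights @ init, rng, max_sweeps=max_sweeps
        )
        total_rot = init @ rot
        objectives.append(obj)
        any_converged = any_converged or conv
        if best is None or obj > best[1]:
            best = (total_rot, obj, conv, sweeps)
    rotation, objective, converged, iters = best
    objectives = np.asarray(objectives)
    # flat landscape: optimization gains nothing over random rotations
    gain = objective - float(np.mean(initial_objectives))
    degenerate = bool(gain < degeneracy_tol)
    if not any_converged:
        warnings.warn(
            "rotation optimization did not converge; returning the best solution",
            stacklevel=2,
        )
    weights = base_weights @ rotation
    profiles = rotation.T @ base_profiles
    # unit-norm profiles, variance ordering, positive max-magnitude element
    norms = np.linalg.norm(profiles, axis=1)
    profiles = profiles / norms[:, None]
    weights = weights * norms[None, :]
    var = weights.var(axis=0) + weights.mean(axis=0) ** 2
    order = np.argsort(var)[::-1]
    profiles = profiles[order]
    weights = weights[:, order]
    for jc in range(n_components):
        peak = np.argmax(np.abs(profiles[jc]))
        if profiles[jc, peak] < 0:
            profiles[jc] = -profiles[jc]
            weights[:, jc] = -weights[:, jc]
    total_var = (data**2).sum()
    comp_var = (weights**2).sum(axis=0) / total_var
    return Decomposition(
        profiles=profiles,
        weights=weights,
        explained_variance=comp_var,
        negentropy=float(objective),
        converged=bool(converged or degenerate),
        n_iterations=int(iters),
        restart_objectives=objectives,
        degenerate=degenerate,
    )


def project_weights(other_data: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Back-project voxel weights onto another condition set.

    Solves ``other_data ~= weights @ profiles`` for the profiles in the
    least-squares sense (the matrix 'division' of the localizer data by the
    main-run component weights).
    """
    other_data = np.asarray(other_data, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if other_data.shape[0] != weights.shape[0]:
        raise ValueError(
            f"voxel axes differ: data has {other_data.shape[0]}, "
            f"weights have {weights.shape[0]}"
        )
    if np.linalg.matrix_rank(weights) < weights.shape[1]:
        raise ValueError("weight matrix is rank deficient")
    profiles, *_ = np.linalg.lstsq(weights, other_data, rcond=None)
    return profiles


def match_profiles(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Hungarian matching of two profile sets on |Pearson correlation|.

    Returns (permutation of b's rows matched to a, matched |r| values).
    """
    ka, kb = a.shape[0], b.shape[0]
    corr = np.zeros((ka, kb))
    for i in range(ka):
        for j in range(kb):
            corr[i, j] = abs(np.corrcoef(a[i], b[j])[0, 1])
    rows, cols = linear_sum_assignment(-corr)
    return cols, corr[rows, cols]


def exclusion_robustness(
    data: np.ndarray,
    mask_to_remove: np.ndarray,
    n_components: int = 3,
    seed: int = 0,
    n_restarts: int = 10,
) -> dict:
    """Stability of the profiles under removal of a voxel subset.

    Reruns the decomposition without the masked voxels and reports the
    matched-profile |correlations| against the full-data solution.
    """
    data = np.asarray(data, dtype=float)
    mask = np.asarray(mask_to_remove, dtype=bool)
    if mask.shape[0] != data.shape[0]:
        raise ValueError("mask length must equal the number of voxels")
    frac = mask.mean()
    if frac >= 0.5:
        raise ValueError("mask removes half or more of the voxels")
    kept = data[~mask]
    if kept.shape[0] == 0:
        raise ValueError("mask removes every voxel")
    full = nonparametric_ica(data, n_components, n_restarts=n_restarts, seed=seed)
    reduced = nonparametric_ica(kept, n_components, n_restarts=n_restarts, seed=seed)
    perm, corrs = match_profiles(full.profiles, reduced.profiles)
    return {
        "removed_fraction": float(frac),
        "matched_correlations": corrs,
        "permutation": perm,
        "full": full,
        "reduced": reduced,
    }
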