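"""ROI-level statistics for word-specific cortical patches.

Implements the analysis battery applied to per-ROI beta estimates:
word-similarity regression slopes with Benjamini-Hochberg FDR control,
posterior-to-anterior spatial-gradient tests on Talairach Y coordinates,
a PCA-axis correlation for lateral frontal ROIs, word-selectivity and
language-dominance indices, region-level dominance correlations, a
contrast battery over the condition designs, an averaged-time-course GLM
with AR(2) prewhitening, cluster-based ROI definition on statistical
maps, and voxel-set overlap percentages.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from statsmodels.regression.linear_model import yule_walker
from statsmodels.stats.multitest import multipletests

from .hemo import design_matrix_from_schedule
from .schedule import Schedule

__all__ = [
    "Predictor",
    "SlopeResult",
    "GradientResult",
    "define_rois",
    "word_similarity_slope",
    "slope_table",
    "fdr_bh",
    "gradient_test",
    "paired_gradient_test",
    "frontal_axis_correlation",
    "selectivity_index",
    "dominance_score",
    "region_dominance_correlation",
    "roi_glm",
    "GLMResult",
    "contrast_battery",
    "contrast_weights",
    "voxel_overlap",
]


# ---------------------------------------------------------------------------
# Predictors

@dataclass(frozen=True)
class Predictor:
    """Named condition weights, normalized so the maximum equals 1."""

    name: str
    labels: tuple[str, ...]
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.weights):
            raise ValueError("labels and weights must have equal length")
        w = np.asarray(self.weights, dtype=float)
        if not np.isfinite(w).all():
            raise ValueError("weights must be finite")
        if abs(w.max() - 1.0) > 1e-9:
            raise ValueError("weights must be normalized so that max = 1")

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.weights, dtype=float)

    @classmethod
    def en_fr(cls) -> "Predictor":
        """Word-similarity weights over the 14 alphabetic conditions.

        Ranks run from infrequent letters in both languages (1) up to real
        words (10); the two language variants of each 2 x 2 cell share a
        rank, so the predictor assumes no difference between languages.
        """
        labels = ("L-", "LE", "LF", "L+", "B-", "BE", "BF", "B+",
                  "Q-", "QE", "QF", "Q+", "WE", "WF")
        ranks = (1, 2, 2, 3, 4, 5, 5, 6, 7, 8, 8, 9, 10, 10)
        return cls("word_similarity_enfr", labels, tuple(r / 10 for r in ranks))

    @classmethod
    def five_level(cls, labels: Sequence[str], name: str = "word_similarity_5") -> "Predictor":
        """Linear 1..5 weights over five increasingly word-like conditions."""
        if len(labels) != 5:
            raise ValueError("the five-level predictor needs exactly 5 labels")
        return cls(name, tuple(labels), tuple((r + 1) / 5 for r in range(5)))


@dataclass
class SlopeResult:
    """Word-similarity regression for one ROI."""

    slope: float
    intercept: float
    p: float
    r: float
    q: float | None = None


@dataclass
class GradientResult:
    """Group test of per-participant spatial-gradient coefficients."""

    coefficients: pd.Series  # indexed by participant
    mean: float
    t: float
    df: int
    p: float
    hemisphere: str | None = None
    excluded: tuple = ()


# ---------------------------------------------------------------------------
# ROI definition on statistical maps

@dataclass
class ROI:
    roi_id: int
    size: int
    centroid_mm: tuple[float, float, float]
    voxels: np.ndarray  # (size, 3) integer indices


def define_rois(
    stat_map: np.ndarray,
    affine: np.ndarray | None = None,
    threshold: float = 0.001,
    stat: str = "p",
    min_cluster: int = 4,
    connectivity: int = 6,
) -> list[ROI]:
    """Connected suprathreshold clusters of a 3-D statistical map.

    ``stat='p'`` keeps voxels with p < threshold; ``stat='t'`` keeps voxels
    with value > threshold.  Clusters must be strictly larger than
    ``min_cluster`` voxels (size > 4 keeps clusters of 5 or more).  Centroids
    are the voxel-index means mapped through ``affine`` (identity if None).
    """
    stat_map = np.asarray(stat_map)
    if stat_map.ndim != 3:
        raise ValueError("stat_map must be a 3-D voxel grid")
    if stat == "p":
        mask = stat_map < threshold
    elif stat == "t":
        mask = stat_map > threshold
    else:
        raise ValueError("stat must be 'p' or 't'")
    if connectivity == 6:
        structure = ndimage.generate_binary_structure(3, 1)
    elif connectivity == 26:
        structure = ndimage.generate_binary_structure(3, 3)
    else:
        raise ValueError("connectivity must be 6 or 26")
    labels, n = ndimage.label(mask, structure=structure)
    if affine is None:
        affine = np.eye(4)
    rois = []
    for lab in range(1, n + 1):
        vox = np.argwhere(labels == lab)
        if len(vox) <= min_cluster:
            continue
        center_vox = vox.mean(axis=0)
        center_mm = affine @ np.append(center_vox, 1.0)
        rois.append(
            ROI(
                roi_id=len(rois) + 1,
                size=len(vox),
                centroid_mm=tuple(float(v) for v in center_mm[:3]),
                voxels=vox,
            )
        )
    return rois


# ---------------------------------------------------------------------------
# Word-similarity slopes and FDR

def word_similarity_slope(
    betas: Sequence[float] | pd.Series, predictor: Predictor
) -> SlopeResult:
    """OLS fit of condition betas on the word-similarity weights.

    The slope is the word-similarity effect; p is the two-tailed test of a
    zero slope.
    """
    if isinstance(betas, pd.Series):
        betas = betas.reindex(list(predictor.labels)).to_numpy()
    betas = np.asarray(betas, dtype=float)
    w = predictor.array
    if len(betas) != len(w):
        raise ValueError("betas and predictor must cover the same conditions")
    if len(betas) < 3:
        raise ValueError("need at least three conditions for a slope test")
    if np.ptp(w) == 0:
        raise ValueError("predictor weights are constant")
    fit = stats.linregress(w, betas)
    return SlopeResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        p=float(fit.pvalue),
        r=float(fit.rvalue),
    )


def fdr_bh(pvalues: Sequence[float], q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (monotone q-values, rejection mask)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, qvals, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return qvals, reject


def slope_table(
    roi_betas: pd.DataFrame,
    predictor: Predictor,
    q: float = 0.05,
) -> pd.DataFrame:
    """Per-ROI slopes with BH-FDR across all rows.

    ``roi_betas`` is ROI x condition (columns must cover the predictor's
    labels); the index is carried through.
    """
    rows = {}
    for roi, row in roi_betas.iterrows():
        res = word_similarity_slope(row, predictor)
        rows[roi] = {"slope": res.slope, "intercept": res.intercept, "p": res.p}
    out = pd.DataFrame.from_dict(rows, orient="index")
    qvals, reject = fdr_bh(out["p"].to_numpy(), q=q)
    out["q"] = qvals
    out["significant"] = reject
    return out


# ---------------------------------------------------------------------------
# Spatial gradients

def _per_participant_coefficients(
    table: pd.DataFrame, min_rois: int
) -> tuple[pd.Series, list]:
    coeffs = {}
    excluded = []
    for pid, grp in table.groupby("participant"):
        if len(grp) < min_rois or grp["tal_y"].nunique() < 2:
            excluded.append(pid)
            continue
        fit = stats.linregress(grp["tal_y"].to_numpy(), grp["slope"].to_numpy())
        coeffs[pid] = float(fit.slope)
    if excluded:
        warnings.warn(
            f"participants skipped (too few ROIs or degenerate coordinates): {excluded}",
            stacklevel=3,
        )
    return pd.Series(coeffs, name="coefficient"), excluded


def gradient_test(
    table: pd.DataFrame,
    hemisphere: str | None = "L",
    min_rois: int = 2,
) -> GradientResult:
    """Posterior-to-anterior gradient of the word-similarity slope.

    ``table`` needs columns ``participant``, ``tal_y``, ``slope`` and, if
    ``hemisphere`` is given, ``hemisphere``.  Per participant, the ROI slopes
    are regressed on TAL Y; the coefficients are then tested against zero
    with a two-tailed one-sample t test.
    """
    if hemisphere is not None:
        table = table[table["hemisphere"] == hemisphere]
    coeffs, excluded = _per_participant_coefficients(table, min_rois)
    if len(coeffs) < 2:
        raise ValueError("fewer than two participants contribute coefficients")
    t, p = stats.ttest_1samp(coeffs.to_numpy(), 0.0)
    return GradientResult(
        coefficients=coeffs,
        mean=float(coeffs.mean()),
        t=float(t),
        df=len(coeffs) - 1,
        p=float(p),
        hemisphere=hemisphere,
        excluded=tuple(excluded),
    )


def paired_gradient_test(
    table: pd.DataFrame,
    min_rois_rh: int = 3,
    min_rois: int = 2,
) -> dict:
    """Paired L vs R comparison of gradient coefficients.

    Only participants with at least ``min_rois_rh`` right-hemisphere ROIs
    enter, mirroring the restriction used for right-hemisphere inference.
    """
    rh_counts = table[table["hemisphere"] == "R"].groupby("participant").size()
    keep = rh_counts[rh_counts >= min_rois_rh].index
    sub = table[table["participant"].isin(keep)]
    if sub.empty:
        raise ValueError("no participant meets the right-hemisphere ROI minimum")
    left, _ = _per_participant_coefficients(sub[sub["hemisphere"] == "L"], min_rois)
    right, _ = _per_participant_coefficients(sub[sub["hemisphere"] == "R"], min_rois)
    common = left.index.intersection(right.index)
    if len(common) < 2:
        raise ValueError("fewer than two participants have both-hemisphere data")
    t, p = stats.ttest_rel(left[common].to_numpy(), right[common].to_numpy())
    return {
        "n": len(common),
        "mean_left": float(left[common].mean()),
        "mean_right": float(right[common].mean()),
        "t": float(t),
        "df": len(common) - 1,
        "p": float(p),
    }


def frontal_axis_correlation(
    tal_y: Sequence[float],
    tal_z: Sequence[float],
    slopes: Sequence[float],
) -> dict:
    """Correlate slopes with position along the first PCA axis of (Y, Z).

    Used for lateral frontal ROIs, whose putative gradient axis is oblique;
    the first principal component of the centered (Y, Z) coordinates serves
    as the axis coordinate.
    """
    y = np.asarray(tal_y, float)
    z = np.asarray(tal_z, float)
    s = np.asarray(slopes, float)
    if not (len(y) == len(z) == len(s)):
        raise ValueError("coordinate and slope arrays must have equal length")
    if len(y) < 3:
        raise ValueError("at least three ROIs are required")
    coords = np.column_stack([y, z])
    centered = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    if axis[np.argmax(np.abs(axis))] < 0:  # sign convention: dominant loading > 0
        axis = -axis
    scores = centered @ axis
    if np.std(s) < 1e-15 or np.std(scores) < 1e-15:
        raise ValueError("correlation undefined: zero variance in slopes or axis scores")
    r, p = stats.pearsonr(scores, s)
    return {"scores": scores, "r": float(r), "p": float(p), "axis": axis}


# ---------------------------------------------------------------------------
# Selectivity and dominance

def selectivity_index(
    condition_betas: Mapping[str, float],
    word_labels: Sequence[str],
    other_labels: Sequence[str],
) -> float:
    """(word - other) / (word + other) on condition means, padded to >= 0.

    If any involved condition beta is negative, all involved betas are
    shifted up by the absolute value of the most negative one before the
    means are formed, bounding the index in [-1, 1].  A zero padded
    denominator yields 0 with a warning.
    """
    wl, ol = list(word_labels), list(other_labels)
    if not wl or not ol:
        raise ValueError("word and other label sets must be non-empty")
    if set(wl) & set(ol):
        raise ValueError("word and other label sets must be disjoint")
    vals = np.array([condition_betas[l] for l in wl + ol], dtype=float)
    if not np.isfinite(vals).all():
        raise ValueError("condition betas must be finite")
    if vals.min() < 0:
        vals = vals + abs(vals.min())
    word_mean = vals[: len(wl)].mean()
    other_mean = vals[len(wl):].mean()
    denom = word_mean + other_mean
    if denom == 0:
        warnings.warn("selectivity denominator is zero; returning 0", stacklevel=2)
        return 0.0
    return float((word_mean - other_mean) / denom)


def dominance_score(words_read_a: float, words_read_b: float) -> float:
    """(A - B) / (A + B) from a one-minute reading test; in [-1, 1]."""
    if words_read_a < 0 or words_read_b < 0:
        raise ValueError("reading counts must be non-negative")
    total = words_read_a + words_read_b
    if total == 0:
        raise ValueError("at least one reading count must be positive")
    return float((words_read_a - words_read_b) / total)


#: The five language-difference comparisons tested per region: four from the
#: main runs (words, letters, bigrams, quadrigrams) and the localizer words.
DEFAULT_DOMINANCE_PAIRS = (
    ("words_main", "main", "WE", "WF"),
    ("letters_main", "main", "LE", "LF"),
    ("bigrams_main", "main", "BE", "BF"),
    ("quadrigrams_main", "main", "QE", "QF"),
    ("words_localizer", "localizer", "word_E", "word_F"),
)


def region_dominance_correlation(
    cohort,
    regions: Sequence[str] | None = None,
    pairs: Sequence[tuple[str, str, str, str]] = DEFAULT_DOMINANCE_PAIRS,
    q: float = 0.05,
    min_participants: int = 3,
) -> pd.DataFrame:
    """Correlate regional language-difference activity with dominance scores.

    For each region, each participant's betas are averaged over that
    region's ROIs and voxels; the per-pair difference (e.g. WE - WF) is then
    correlated with the behavioral dominance scores across participants, and
    the family of pairs is BH-FDR corrected within the region.
    """
    region_set = set()
    for part in cohort.participants:
        region_set.update(r.region for r in part.rois)
    if regions is None:
        regions = sorted(region_set)
    rows = []
    for region in regions:
        if region not in region_set:
            raise ValueError(f"region {region!r} absent from every participant")
        diffs: dict[str, list[float]] = {name: [] for name, *_ in pairs}
        doms: list[float] = []
        for part in cohort.participants:
            rois = [r for r in part.rois if r.region == region]
            if not rois:
                continue
            doms.append(part.dominance)
            for name, source, cond_a, cond_b in pairs:
                mats = [
                    (r.betas_main if source == "main" else r.betas_localizer)
                    for r in rois
                ]
                a = float(np.mean([m[cond_a].mean() for m in mats]))
                b = float(np.mean([m[cond_b].mean() for m in mats]))
                diffs[name].append(a - b)
        if len(doms) < min_participants:
            raise ValueError(
                f"region {region!r}: only {len(doms)} participants with data"
            )
        doms_arr = np.asarray(doms)
        region_rows = []
        for name, *_ in pairs:
            d = np.asarray(diffs[name])
            if np.std(doms_arr) < 1e-15 or np.std(d) < 1e-15:
                warnings.warn(
                    f"region {region!r}, pair {name!r}: correlation undefined "
                    "(zero variance)",
                    stacklevel=2,
                )
                region_rows.append(
                    {"region": region, "pair": name, "n": len(doms), "r": np.nan, "p": np.nan}
                )
                continue
            r, p = stats.pearsonr(doms_arr, d)
            region_rows.append(
                {"region": region, "pair": name, "n": len(doms), "r": float(r), "p": float(p)}
            )
        ps = np.array([row["p"] for row in region_rows])
        valid = np.isfinite(ps)
        qvals = np.full(len(ps), np.nan)
        rej = np.zeros(len(ps), dtype=bool)
        if valid.any():
            qvals[valid], rej[valid] = fdr_bh(ps[valid], q=q)
        for row, qv, rj in zip(region_rows, qvals, rej):
            row["q"] = qv
            row["significant"] = bool(rj)
        rows.extend(region_rows)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ROI-GLM

@dataclass
class GLMResult:
    """Fitted condition betas plus the machinery for contrast tests."""

    betas: pd.Series
    cov: np.ndarray
    df: int
    sigma2: float
    ar_coefs: tuple[float, ...]
    design_columns: tuple[str, ...]

    def contrast(self, weights: Mapping[str, float] | Sequence[float]) -> dict:
        if isinstance(weights, Mapping):
            c = np.zeros(len(self.design_columns))
            unknown = set(weights) - set(self.betas.index)
            if unknown:
                raise ValueError(f"unknown conditions in contrast: {sorted(unknown)}")
            for i, name in enumerate(self.design_columns):
                c[i] = weights.get(name, 0.0)
        else:
            c = np.asarray(weights, dtype=float)
            if len(c) != len(self.design_columns):
                raise ValueError("contrast length does not match the design")
        if not np.any(c):
            raise ValueError("contrast vector is all zeros")
        full = pd.Series(0.0, index=list(self.design_columns))
        full[self.betas.index] = self.betas
        est = float(c @ full.to_numpy())
        var = float(c @ self.cov @ c)
        t = est / np.sqrt(var)
        p = 2 * stats.t.sf(abs(t), self.df)
        return {"estimate": est, "t": float(t), "p": float(p), "df": self.df}


def percent_transform(x: np.ndarray) -> np.ndarray:
    """Percent signal change around the time-series mean: 100 (x - m) / m."""
    x = np.asarray(x, dtype=float)
    m = x.mean()
    if m == 0:
        raise ValueError("cannot percent-transform a zero-mean series")
    return 100.0 * (x - m) / m


def roi_glm(
    timecourse: np.ndarray,
    schedule: Schedule,
    confounds: np.ndarray | None = None,
    ar_order: int = 2,
    apply_percent_transform: bool = True,
    hrf_params: dict | None = None,
) -> GLMResult:
    """GLM on an ROI-averaged time course with optional AR prewhitening.

    The design holds one HRF-convolved regressor per condition plus an
    intercept and optional confound columns.  With ``ar_order > 0`` the
    serial correlation of the OLS residuals is estimated by Yule-Walker and
    removed by Cochrane-Orcutt prewhitening before refitting (the first
    ``ar_order`` samples are dropped).
    """
    y = np.asarray(timecourse, dtype=float)
    X_cond = design_matrix_from_schedule(schedule, hrf_params=hrf_params)
    if len(y) != len(X_cond):
        raise ValueError(
            f"time course has {len(y)} samples, schedule implies {len(X_cond)}"
        )
    if apply_percent_transform:
        y = percent_transform(y)
    names = list(X_cond.columns)
    X = X_cond.to_numpy()
    if confounds is not None:
        confounds = np.asarray(confounds, dtype=float)
        if confounds.ndim == 1:
            confounds = confounds[:, None]
        # z-score confounds so their scale does not leak into conditioning
        std = confounds.std(axis=0)
        if np.any(std == 0):
            raise ValueError("constant confound column (the intercept is implicit)")
        confounds = (confounds - confounds.mean(axis=0)) / std
        X = np.column_stack([X, confounds])
        names += [f"confound_{i}" for i in range(confounds.shape[1])]
    X = np.column_stack([X, np.ones(len(y))])
    names.append("intercept")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        corr = np.corrcoef(X[:, :-1].T)
        bad = [
            f"{names[i]}~{names[j]}"
            for i in range(len(names) - 1)
            for j in range(i + 1, len(names) - 1)
            if abs(corr[i, j]) > 0.999
        ]
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} of {X.shape[1]}); "
            f"collinear columns: {bad or 'not pairwise identifiable'}"
        )
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    rho: tuple[float, ...] = ()
    if ar_order > 0:
        resid = y - X @ beta
        rho_arr, _ = yule_walker(resid, order=ar_order, method="mle")
        rho = tuple(float(r) for r in rho_arr)
        yw = y.copy()
        Xw = X.copy()
        for k, r in enumerate(rho, start=1):
            yw[ar_order:] -= r * y[ar_order - k : len(y) - k]
            Xw[ar_order:] -= r * X[ar_order - k : len(y) - k]
        yw = yw[ar_order:]
        Xw = Xw[ar_order:]
        beta = np.linalg.lstsq(Xw, yw, rcond=None)[0]
        resid_w = yw - Xw @ beta
        dof = len(yw) - X.shape[1]
        sigma2 = float(resid_w @ resid_w / dof)
        cov = sigma2 * np.linalg.inv(Xw.T @ Xw)
    else:
        resid = y - X @ beta
        dof = len(y) - X.shape[1]
        sigma2 = float(resid @ resid / dof)
        cov = sigma2 * np.linalg.inv(X.T @ X)
    cond_betas = pd.Series(beta[: len(X_cond.columns)], index=list(X_cond.columns))
    return GLMResult(
        betas=cond_betas,
        cov=cov,
        df=dof,
        sigma2=sigma2,
        ar_coefs=rho,
        design_columns=tuple(names),
    )


# ---------------------------------------------------------------------------
# Contrast battery

def _w(**kv: float) -> dict[str, float]:
    return dict(kv)


def contrast_weights(design: str = "enfr") -> dict[str, dict[str, float]]:
    """Named signed weight vectors over the conditions of a design.

    ``enfr``: lexicality, per-level frequency effects, differences between
    adjacent levels, language pairs, and per-level language main effects and
    interactions.  ``encn``: English frequency/lexicality steps plus the
    pairwise steps of the logographic hierarchy.
    """
    if design == "enfr":
        out = {
            "lexicality": {"WE": 1, "WF": 1, "QE": -1, "QF": -1},
            "letter_freq": {"L+": 1, "L-": -1},
            "bigram_freq": {"B+": 1, "B-": -1},
            "quadrigram_freq": {"Q+": 1, "Q-": -1},
            "bigram_vs_letter": {"B+": 1, "B-": -1, "L+": -1, "L-": 1},
            "quadrigram_vs_bigram": {"Q+": 1, "Q-": -1, "B+": -1, "B-": 1},
            "lexicality_vs_quadrigram": {
                "WE": 1, "WF": 1, "QE": -1, "QF": -1, "Q+": -2, "Q-": 2
            },
            "letter_lang": {"LF": 1, "LE": -1},
            "bigram_lang": {"BF": 1, "BE": -1},
            "quadrigram_lang": {"QF": 1, "QE": -1},
        }
        for lvl in "LBQ":
            name = {"L": "letter", "B": "bigram", "Q": "quadrigram"}[lvl]
            out[f"{name}_main_F"] = {f"{lvl}F": 1, f"{lvl}+": 1, f"{lvl}E": -1, f"{lvl}-": -1}
            out[f"{name}_main_E"] = {f"{lvl}E": 1, f"{lvl}+": 1, f"{lvl}F": -1, f"{lvl}-": -1}
            out[f"{name}_interaction"] = {
                f"{lvl}+": 1, f"{lvl}F": -1, f"{lvl}E": -1, f"{lvl}-": 1
            }
        return out
    if design == "encn":
        return {
            "letter_freq": {"L+": 1, "L-": -1},
            "bigram_freq": {"B+": 1, "B-": -1},
            "quadrigram_freq": {"Q+": 1, "Q-": -1},
            "lexicality_en": {"WE": 1, "Q+": -1},
            "stroke_grouping": {"SG": 1, "S": -1},
            "radicals_impossible": {"RI": 1, "SG": -1},
            "radicals_possible": {"RP": 1, "RI": -1},
            "characters": {"CP": 1, "RP": -1},
            "lexicality_cn": {"WL": 1, "CP": -1},
            "word_frequency_cn": {"WH": 1, "WL": -1},
        }
    raise ValueError(f"unknown design {design!r} (expected 'enfr' or 'encn')")


def contrast_battery(
    betas_or_glm: Mapping[str, float] | pd.Series | GLMResult,
    design: str = "enfr",
) -> pd.DataFrame:
    """Evaluate the design's named contrasts on betas or a fitted GLM.

    On a :class:`GLMResult` each row carries estimate, t, p; on raw betas
    only the weighted estimates are available.
    """
    weights = contrast_weights(design)
    rows = []
    if isinstance(betas_or_glm, GLMResult):
        for name, w in weights.items():
            res = betas_or_glm.contrast(w)
            rows.append({"contrast": name, **res})
    else:
        betas = dict(betas_or_glm)
        for name, w in weights.items():
            missing = set(w) - set(betas)
            if missing:
                raise ValueError(
                    f"contrast {name!r}: conditions missing from betas: {sorted(missing)}"
                )
            est = sum(c * betas[k] for k, c in w.items())
            rows.append({"contrast": name, "estimate": float(est)})
    return pd.DataFrame(rows)


def voxel_overlap(voxel_set_a: Iterable, voxel_set_b: Iterable) -> float:
    """Percentage of set A contained in set B: 100 |A ∩ B| / |A|."""
    a = {tuple(v) if isinstance(v, (list, np.ndarray)) else v for v in voxel_set_a}
    b = {tuple(v) if isinstance(v, (list, np.ndarray)) else v for v in voxel_set_b}
    if not a:
        raise ValueError("set A is empty")
    return 100.0 * len(a & b) / len(a)
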