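"""Hemodynamic forward model: two-gamma HRF and schedule design matrices.

Condition regressors are boxcars over each condition's stimulus blocks,
convolved with a canonical two-gamma hemodynamic response function (peak
at 6 s, undershoot at 16 s) on a fine 50-ms grid and sampled at the TR.
The HRF integrates to one, so a regressor plateaus at 1 during a
sustained block and condition betas read directly in the units of the
time course (percent signal change for percent-transformed data).
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist

from .schedule import GRID, Schedule

__all__ = ["two_gamma_hrf", "hrf_kernel", "design_matrix_from_schedule"]


def two_gamma_hrf(
    t: np.ndarray,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    peak_disp: float = 1.0,
    undershoot_disp: float = 1.0,
    undershoot_ratio: float = 1.0 / 6.0,
) -> np.ndarray:
    """Canonical two-gamma HRF evaluated at times ``t`` (seconds).

    Shape parameters are delay/dispersion, so the positive lobe peaks at
    ``peak_delay`` and the undershoot at ``undershoot_delay``.
    """
    t = np.asarray(t, dtype=float)
    peak = gamma_dist.pdf(t, peak_delay / peak_disp, scale=peak_disp)
    under = gamma_dist.pdf(t, undershoot_delay / undershoot_disp, scale=undershoot_disp)
    return peak - undershoot_ratio * under


def hrf_kernel(dt: float = GRID, length: float = 32.0, **hrf_params) -> np.ndarray:
    """HRF sampled every ``dt`` s and normalized to unit integral."""
    t = np.arange(0.0, length, dt)
    h = two_gamma_hrf(t, **hrf_params)
    return h / (h.sum() * dt)


def design_matrix_from_schedule(
    schedule: Schedule,
    dt: float = GRID,
    hrf_params: dict | None = None,
    sample_offset: float = 0.0,
) -> pd.DataFrame:
    """HRF-convolved condition regressors sampled at the schedule's TR.

    Returns a (volumes x conditions) frame; column order follows first
    appearance of each condition in the schedule.  ``sample_offset`` shifts
    the sampling instants within each TR (0 = volume onset).
    """
    tr = schedule.tr
    if abs(round(tr / dt) * dt - tr) > 1e-9:
        raise ValueError(f"TR {tr} s is not a multiple of the {dt} s grid")
    n_fine = round(schedule.total_duration / dt)
    conditions: list[str] = []
    boxcars: dict[str, np.ndarray] = {}
    for e in schedule.stimulus_blocks:
        if e.condition not in boxcars:
            conditions.append(e.condition)
            boxcars[e.condition] = np.zeros(n_fine)
        i0 = round(e.onset / dt)
        i1 = round(e.end / dt)
        boxcars[e.condition][i0:i1] = 1.0
    kernel = hrf_kernel(dt, **(hrf_params or {}))
    vol_times = np.arange(schedule.n_volumes) * tr + sample_offset
    idx = np.clip(np.round(vol_times / dt).astype(int), 0, n_fine - 1)
    cols = {}
    for c in conditions:
        conv = np.convolve(boxcars[c], kernel)[:n_fine] * dt
        cols[c] = conv[idx]
    return pd.DataFrame(cols, columns=conditions)
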