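"""First level of the two-level summary-statistic approach.

Per-subject voxel-wise least-squares slope (and quadratic-term) images over
all available time-points, plus per-subject clinical slopes and the
EDSS-step conversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Volume
from .phantoms import EDSS_GRID

__all__ = [
    "SummaryImage",
    "fit_voxelwise_slope",
    "fit_voxelwise_quadratic",
    "edss_to_steps",
    "clinical_slope",
]


@dataclass
class SummaryImage:
    """Per-subject first-level coefficient map in group space."""

    volume: Volume
    subject_id: str = ""
    kind: str = "slope"  # "slope" (units/yr) | "quadratic" (units/yr^2)
    n_visits: int = 0
    covariates: dict[str, float] = field(default_factory=dict)


def _check_times(times, minimum: int) -> np.ndarray:
    t = np.asarray(times, dtype=float)
    if len(np.unique(t)) < minimum:
        raise ValueError(f"need at least {minimum} distinct time-points, got {t}")
    return t


def fit_voxelwise_slope(
    pseudo_timepoints: list[Volume], times, subject_id: str = ""
) -> SummaryImage:
    """Ordinary least-squares slope against time, per voxel.

    Uses whatever visits exist for the subject (unbalanced designs are fine);
    requires >= 2 distinct times.
    """
    t = _check_times(times, 2)
    ref = pseudo_timepoints[0]
    y = np.stack([v.data for v in pseudo_timepoints], axis=0)
    tc = t - t.mean()
    denom = float((tc**2).sum())
    slope = np.tensordot(tc, y - y.mean(axis=0), axes=(0, 0)) / denom
    return SummaryImage(ref.like(slope), subject_id, "slope", len(t))


def fit_voxelwise_quadratic(
    pseudo_timepoints: list[Volume], times, subject_id: str = ""
) -> SummaryImage:
    """Coefficient of t^2 from a degree-2 polynomial LS fit, per voxel."""
    t = _check_times(times, 3)
    ref = pseudo_timepoints[0]
    y = np.stack([v.data for v in pseudo_timepoints], axis=0).reshape(len(t), -1)
    X = np.stack([np.ones_like(t), t, t**2], axis=1)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    quad = coef[2].reshape(ref.shape)
    return SummaryImage(ref.like(quad), subject_id, "quadratic", len(t))


def edss_to_steps(edss_values) -> np.ndarray:
    """Map EDSS values to their ordinal rank on the legal grid.

    The grid is {0, 1, 1.5, 2, ..., 10} (no 0.5), so 0 -> 0, 1 -> 1,
    1.5 -> 2, ..., 10 -> 19; differences of ranks are "EDSS steps".
    """
    x = np.atleast_1d(np.asarray(edss_values, dtype=float))
    out = np.empty(len(x), dtype=int)
    for i, v in enumerate(x):
        hit = np.nonzero(np.isclose(EDSS_GRID, v, atol=1e-9))[0]
        if len(hit) == 0:
            raise ValueError(f"EDSS value {v} is not on the legal grid")
        out[i] = hit[0]
    return out


def clinical_slope(scores, times) -> float:
    """OLS slope of a clinical score against time (per year)."""
    t = _check_times(times, 2)
    y = np.asarray(scores, dtype=float)
    tc = t - t.mean()
    return float((tc * (y - y.mean())).sum() / (tc**2).sum())
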