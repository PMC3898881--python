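"""Associations between regional atrophy rates and clinical outcomes.

ROI-mean slope extraction, Box-Cox normalisation with a shift, Pearson and
partial correlations, studentized-residual outlier flagging, and the
one-sample progression test on clinical slopes.
"""

from __future__ import annotations

import numpy as np
from scipy import special, stats

from .core import Volume

__all__ = [
    "roi_rate",
    "boxcox_shift",
    "pearson_corr",
    "partial_corr",
    "flag_outliers",
    "one_sample_progression_test",
]


def roi_rate(
    slope_image: Volume, atlas: Volume, label: int, mask: Volume | None = None
) -> float:
    """Mean slope over an atlas label (optionally within the explicit mask)."""
    slope_image.require_same_grid(atlas, "roi_rate")
    sel = np.asarray(atlas.data) == label
    if not sel.any():
        raise ValueError(f"label {label} absent from atlas")
    if mask is not None:
        sel &= np.asarray(mask.data, dtype=bool)
        if not sel.any():
            raise ValueError(f"label {label} does not intersect the mask")
    return float(np.asarray(slope_image.data, dtype=float)[sel].mean())


def boxcox_shift(values, shift: float = 10.0, lam="mle"):
    """Box-Cox transform of ``values + shift``.

    ``y = ((x+shift)^lam - 1)/lam`` for ``lam != 0``, ``log(x+shift)`` for
    ``lam = 0``.  With ``lam="mle"`` the exponent maximizing the profile
    log-likelihood is used and ``(y, lam)`` is returned.
    """
    x = np.asarray(values, dtype=float) + shift
    if np.any(x <= 0):
        raise ValueError("all values + shift must be positive")
    if isinstance(lam, str):
        if lam != "mle":
            raise ValueError("lam must be a number or 'mle'")
        y, lam_hat = stats.boxcox(x)
        return y, float(lam_hat)
    return special.boxcox(x, float(lam))


def pearson_corr(x, y) -> tuple[float, float]:
    """Sample Pearson r with a two-sided p from the t transform (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def partial_corr(x, y, z) -> tuple[float, float]:
    """Correlation of x and y after regressing each on [1, z]; p with n-3 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 observations")
    Z = np.stack([np.ones(n), z], axis=1)
    if np.linalg.matrix_rank(Z) < 2:
        raise ValueError("covariate is collinear with the intercept")
    rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
    ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
    if rx.std() <= 1e-12 * max(x.std(), 1e-30) or ry.std() <= 1e-12 * max(
        y.std(), 1e-30
    ):
        raise ValueError("zero residual variance after adjusting for covariate")
    r = float(np.dot(rx, ry) / np.sqrt(np.dot(rx, rx) * np.dot(ry, ry)))
    df = n - 3
    t = r * np.sqrt(df / max(1.0 - r**2, 1e-300))
    p = 2.0 * stats.t.sf(abs(t), df)
    return r, float(p)


def flag_outliers(x, y, threshold: float = 3.0) -> np.ndarray:
    """Indices with |externally studentized residual| > threshold from y ~ x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 5:
        raise ValueError("need at least 5 observations")
    import statsmodels.api as sm
    from statsmodels.stats.outliers_influence import OLSInfluence

    model = sm.OLS(y, sm.add_constant(x)).fit()
    resid = np.asarray(OLSInfluence(model).resid_studentized_external)
    return np.nonzero(np.abs(resid) > threshold)[0]


def one_sample_progression_test(slopes) -> tuple[float, float]:
    """One-sample t test of clinical slopes against zero (two-sided)."""
    s = np.asarray(slopes, dtype=float)
    if len(s) < 2:
        raise ValueError("need at least 2 slopes")
    if s.std(ddof=1) == 0:
        if np.allclose(s, 0):
            return 0.0, 1.0
        raise ValueError("zero-variance slopes with nonzero mean: t undefined")
    t, p = stats.ttest_1samp(s, 0.0)
    return float(t), float(p)
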