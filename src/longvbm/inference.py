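"""Second-level GLM, threshold-free cluster enhancement and permutation
family-wise-error inference.

The TFCE transform follows the discrete-sum definition
``TFCE(v) = sum_{h=dh,2dh,...<=stat(v)} e(h,v)^E * h^H * dh`` with
``e(h,v)`` the voxel count of the suprathreshold connected component at
height ``h`` containing ``v`` (26-connectivity by default).  Only the
positive tail is enhanced; negate the contrast for the other direction.

Permutation schemes: sign-flip for one-sample designs, group relabelling for
two-sample designs, Freedman-Lane residual permutation when nuisance
covariates are present.  FWE p-values use the max-statistic distribution with
the (b+1)/(B+1) convention; the observed labelling is always part of the
null sample.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .core import Volume

logger = logging.getLogger(__name__)

__all__ = [
    "DesignMatrix",
    "PermutationResult",
    "build_design",
    "glm_t_map",
    "glm_t",
    "tfce",
    "permutation_fwe",
    "paired_baseline_subtraction_test",
]


# --------------------------------------------------------------------------
# design matrices and GLM t statistics
# --------------------------------------------------------------------------


@dataclass
class DesignMatrix:
    """Second-level design: one row per subject."""

    X: np.ndarray
    columns: list[str]

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] != len(self.columns):
            raise ValueError("X must be (n_subjects, n_columns)")
        r = np.linalg.matrix_rank(self.X)
        if r < self.X.shape[1]:
            bad = [
                c
                for i, c in enumerate(self.columns)
                if np.linalg.matrix_rank(np.delete(self.X, i, axis=1)) == r
            ]
            raise ValueError(f"design is rank deficient; collinear columns: {bad}")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    def contrast(self, name: str) -> np.ndarray:
        c = np.zeros(len(self.columns))
        c[self.columns.index(name)] = 1.0
        return c


def build_design(
    covariates: pd.DataFrame,
    group_column: str | None = "group",
    nuisance: tuple[str, ...] = (),
) -> DesignMatrix:
    """Intercept + optional patient indicator + mean-centered nuisance columns.

    ``sex`` values are coded F=1 / M=0 before centering.  Centering the
    nuisance columns keeps group/intercept contrasts interpretable.
    """
    n = len(covariates)
    cols, names = [np.ones(n)], ["intercept"]
    if group_column is not None:
        g = (covariates[group_column].to_numpy() == "patient").astype(float)
        cols.append(g)
        names.append("group")
    for c in nuisance:
        v = covariates[c]
        if v.dtype == object:
            v = (v == "F").astype(float)
        v = np.asarray(v, dtype=float)
        if np.ptp(v) == 0:
            logger.info("dropping constant nuisance column %r", c)
            continue
        cols.append(v - v.mean())
        names.append(c)
    return DesignMatrix(np.stack(cols, axis=1), names)


def glm_t(Y: np.ndarray, X: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Voxel-wise OLS t statistic, t = c'b / sqrt(c'(X'X)^-1 c * s2).

    Y is (n_subjects, n_voxels); s2 uses n - rank(X) degrees of freedom.
    """
    X = np.asarray(X, dtype=float)
    c = np.asarray(c, dtype=float)
    n, p = X.shape
    pinv = np.linalg.pinv(X)
    beta = pinv @ Y
    resid = Y - X @ beta
    df = n - np.linalg.matrix_rank(X)
    if df <= 0:
        raise ValueError("no residual degrees of freedom")
    s2 = (resid**2).sum(axis=0) / df
    var_c = float(c @ np.linalg.pinv(X.T @ X) @ c)
    num = c @ beta
    scale = np.maximum((Y**2).mean(axis=0), 1e-30)
    degenerate = s2 <= 1e-20 * scale  # residuals numerically zero
    denom = np.sqrt(var_c * np.where(degenerate, 1.0, s2))
    t = num / denom
    # noiseless data: zero effect over zero variance is t = 0, a real
    # effect over zero variance saturates
    with np.errstate(invalid="ignore"):
        saturated = np.where(num**2 <= 1e-20 * scale, 0.0, np.sign(num) * np.inf)
    return np.where(degenerate, saturated, t)


def glm_t_map(
    summary_images: list[Volume],
    design: DesignMatrix,
    contrast: np.ndarray,
    mask: Volume | None = None,
) -> Volume:
    """t-statistic volume for a contrast on second-level summary images."""
    ref = summary_images[0]
    if len(summary_images) != design.n:
        raise ValueError("one summary image per design row required")
    m = (
        np.ones(ref.shape, dtype=bool)
        if mask is None
        else np.asarray(mask.data, dtype=bool)
    )
    Y = np.stack([np.asarray(v.data, dtype=float)[m] for v in summary_images])
    t = glm_t(Y, design.X, contrast)
    out = np.zeros(ref.shape)
    out[m] = t
    return ref.like(out)


# --------------------------------------------------------------------------
# TFCE
# --------------------------------------------------------------------------


@njit(cache=True)
def _uf_find(parent, offs, i):
    r = i
    acc = 0.0
    while parent[r] != r:
        acc += offs[r]
        r = parent[r]
    j = i
    rem = acc
    while parent[j] != r:
        nxt = parent[j]
        o = offs[j]
        parent[j] = r
        offs[j] = rem
        rem -= o
        j = nxt
    return r


@njit(cache=True)
def _tfce_engine(stat, E, H, dh, use26):
    nx, ny, nz = stat.shape
    n = nx * ny * nz
    flat = stat.copy().reshape(n)
    order = np.argsort(flat)[::-1]
    smax = flat[order[0]]
    out = np.zeros(n)
    if smax <= 0.0:
        return out.reshape(nx, ny, nz)
    K = int(math.floor(smax / dh + 1e-12))
    parent = np.full(n, -1, np.int64)
    offs = np.zeros(n)
    delta = np.zeros(n)
    size = np.zeros(n, np.int64)
    stamp = np.full(n, -1, np.int64)
    active = np.empty(n, np.int64)
    n_active = 0
    ptr = 0
    for k in range(K, 0, -1):
        h = k * dh
        while ptr < n and flat[order[ptr]] >= h:
            v = order[ptr]
            ptr += 1
            parent[v] = v
            offs[v] = 0.0
            delta[v] = 0.0
            size[v] = 1
            active[n_active] = v
            n_active += 1
            x = v // (ny * nz)
            rem = v % (ny * nz)
            y = rem // nz
            z = rem % nz
            for dx in range(-1, 2):
                xx = x + dx
                if xx < 0 or xx >= nx:
                    continue
                for dy in range(-1, 2):
                    yy = y + dy
                    if yy < 0 or yy >= ny:
                        continue
                    for dz in range(-1, 2):
                        zz = z + dz
                        if zz < 0 or zz >= nz:
                            continue
                        if dx == 0 and dy == 0 and dz == 0:
                            continue
                        if not use26 and abs(dx) + abs(dy) + abs(dz) != 1:
                            continue
                        w = (xx * ny + yy) * nz + zz
                        if parent[w] == -1:
                            continue
                        ra = _uf_find(parent, offs, v)
                        rb = _uf_find(parent, offs, w)
                        if ra == rb:
                            continue
                        if size[ra] < size[rb]:
                            ra, rb = rb, ra
                        parent[rb] = ra
                        offs[rb] = delta[rb] - delta[ra]
                        size[ra] += size[rb]
        c_h = (h**H) * dh
        for idx in range(n_active):
            r = _uf_find(parent, offs, active[idx])
            if stamp[r] != k:
                delta[r] += size[r] ** E * c_h
                stamp[r] = k
    for idx in range(n_active):
        v = active[idx]
        r = _uf_find(parent, offs, v)
        if v == r:
            out[v] = delta[r]
        else:
            out[v] = offs[v] + delta[r]
    return out.reshape(nx, ny, nz)


def tfce(
    stat,
    E: float = 0.5,
    H: float = 2.0,
    dh: float | None = None,
    connectivity: int = 26,
):
    """Threshold-free cluster enhancement of the positive tail.

    ``dh`` defaults to max(stat)/100.  Accepts and returns either a
    :class:`Volume` or a bare 3-D array.
    """
    is_vol = isinstance(stat, Volume)
    data = np.asarray(stat.data if is_vol else stat, dtype=np.float64)
    if connectivity not in (6, 26):
        raise ValueError("connectivity must be 6 or 26")
    smax = float(data.max(initial=0.0))
    if dh is None:
        dh = smax / 100.0 if smax > 0 else 1.0
    if dh <= 0:
        raise ValueError("dh must be positive")
    out = _tfce_engine(data, float(E), float(H), float(dh), connectivity == 26)
    return stat.like(out) if is_vol else out


# --------------------------------------------------------------------------
# permutation FWE
# --------------------------------------------------------------------------


@dataclass
class PermutationResult:
    """Observed map, max-statistic null and FWE-corrected p map."""

    observed: Volume  # t map (or TFCE-enhanced t map)
    raw_t: Volume
    null_max: np.ndarray
    p: Volume
    significant: Volume
    n_perm: int
    alpha: float
    seed: int
    scheme: str
    exhaustive: bool = False
    extra: dict = field(default_factory=dict)

    @property
    def n_significant(self) -> int:
        return int(np.asarray(self.significant.data).sum())


def _enhance(tmap: np.ndarray, mask: np.ndarray, enhance: str, dh: float | None):
    if enhance == "none":
        return tmap
    full = np.zeros(mask.shape)
    full[mask] = tmap
    return tfce(full, dh=dh)[mask]


def _iter_sign_flips(n: int, n_perm: int, rng: np.random.Generator):
    if 2**n <= n_perm:
        signs = np.array(list(itertools.product([1.0, -1.0], repeat=n)))
        return signs, True
    signs = np.where(rng.uniform(size=(n_perm, n)) < 0.5, -1.0, 1.0)
    signs[0] = 1.0  # observed labelling is part of the null sample
    return signs, False


def _iter_relabelings(g: np.ndarray, n_perm: int, rng: np.random.Generator):
    n = len(g)
    n1 = int(g.sum())
    total = math.comb(n, n1)
    if total <= n_perm:
        labels = np.zeros((total, n))
        for i, idx in enumerate(itertools.combinations(range(n), n1)):
            labels[i, list(idx)] = 1.0
        return labels, True
    labels = np.empty((n_perm, n))
    labels[0] = g
    for i in range(1, n_perm):
        labels[i] = g[rng.permutation(n)]
    return labels, False


def _auto_scheme(design: DesignMatrix, contrast: np.ndarray) -> str:
    nz = [design.columns[i] for i in np.nonzero(contrast)[0]]
    p = design.X.shape[1]
    if p == 1:
        return "sign_flip"
    if p == 2 and nz == ["group"]:
        return "relabel"
    return "freedman_lane"


def permutation_fwe(
    summary_images: list[Volume],
    design: DesignMatrix,
    contrast: np.ndarray,
    mask: Volume | None = None,
    n_perm: int = 5000,
    enhance: str = "tfce",
    alpha: float = 0.05,
    seed: int = 0,
    scheme: str | None = None,
    dh: float | None = None,
) -> PermutationResult:
    """Max-statistic permutation FWE inference on second-level images.

    The statistic is the (optionally TFCE-enhanced) one-tailed t map of the
    contrast; the null maximum is taken over masked voxels.  When the number
    of distinct permutations is below ``n_perm`` the full set is enumerated
    (logged) and p-values are exact.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if enhance not in ("tfce", "none"):
        raise ValueError("enhance must be 'tfce' or 'none'")
    contrast = np.asarray(contrast, dtype=float)
    ref = summary_images[0].volume if hasattr(summary_images[0], "volume") else summary_images[0]
    vols = [v.volume if hasattr(v, "volume") else v for v in summary_images]
    m = (
        np.ones(ref.shape, dtype=bool)
        if mask is None
        else np.asarray(mask.data, dtype=bool)
    )
    Y = np.stack([np.asarray(v.data, dtype=float)[m] for v in vols])
    n = Y.shape[0]
    if n != design.n:
        raise ValueError("one image per design row required")
    rng = np.random.default_rng(seed)
    scheme = scheme or _auto_scheme(design, contrast)

    X = design.X
    t_obs = glm_t(Y, X, contrast)
    enh_obs = _enhance(t_obs, m, enhance, dh)

    if scheme == "sign_flip":
        # one-sample on the contrast column; other columns must be absent
        signs, exhaustive = _iter_sign_flips(n, n_perm, rng)
        stats = np.empty(len(signs))
        for i, s in enumerate(signs):
            t = glm_t(s[:, None] * Y, X, contrast)
            stats[i] = _enhance(t, m, enhance, dh).max(initial=0.0)
    elif scheme == "relabel":
        gi = design.columns.index("group")
        g = X[:, gi]
        labels, exhaustive = _iter_relabelings(g, n_perm, rng)
        stats = np.empty(len(labels))
        Xp = X.copy()
        for i, lab in enumerate(labels):
            Xp[:, gi] = lab
            t = glm_t(Y, Xp, contrast)
            stats[i] = _enhance(t, m, enhance, dh).max(initial=0.0)
    elif scheme == "freedman_lane":
        keep = np.nonzero(contrast == 0)[0]
        Z = X[:, keep] if len(keep) else np.ones((n, 1))
        pz = np.linalg.pinv(Z)
        gamma = pz @ Y
        fit_red = Z @ gamma
        resid = Y - fit_red
        # one-sample effects (contrast on the intercept) exchange residual
        # signs; group/covariate effects exchange residual rows
        one_sample = (
            "intercept" in design.columns
            and contrast[design.columns.index("intercept")] != 0
        )
        if one_sample:
            signs, exhaustive = _iter_sign_flips(n, n_perm, rng)
            variants = (s[:, None] * resid for s in signs)
            n_variants = len(signs)
        else:
            exhaustive = False
            perms = [np.arange(n)] + [rng.permutation(n) for _ in range(n_perm - 1)]
            variants = (resid[pr] for pr in perms)
            n_variants = len(perms)
        stats = np.empty(n_variants)
        for i, rv in enumerate(variants):
            Ystar = fit_red + rv
            t = glm_t(Ystar, X, contrast)
            stats[i] = _enhance(t, m, enhance, dh).max(initial=0.0)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    if exhaustive:
        logger.info("enumerating all %d distinct permutations (exhaustive)", len(stats))
        pvals = (stats[None, :] >= enh_obs[:, None]).sum(axis=1) / len(stats)
    else:
        # stats[0] corresponds to the observed labelling: (b+1)/(B+1)
        pvals = (1 + (stats[1:][None, :] >= enh_obs[:, None]).sum(axis=1)) / len(stats)

    def vol_of(x):
        full = np.zeros(ref.shape)
        full[m] = x
        return ref.like(full)

    p_full = np.ones(ref.shape)
    p_full[m] = pvals
    p_vol = ref.like(p_full)
    sig = ref.like(((p_full <= alpha) & m).astype(np.uint8))
    return PermutationResult(
        observed=vol_of(enh_obs),
        raw_t=vol_of(t_obs),
        null_max=stats,
        p=p_vol,
        significant=sig,
        n_perm=len(stats),
        alpha=alpha,
        seed=seed,
        scheme=scheme,
        exhaustive=exhaustive,
    )


def paired_baseline_subtraction_test(
    series_pseudo: dict[str, dict[float, Volume]],
    target_year: float,
    all_times: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0, 5.0),
    baseline_year: float = 0.0,
    mask: Volume | None = None,
    n_perm: int = 5000,
    alpha: float = 0.05,
    seed: int = 0,
) -> PermutationResult:
    """Year-by-year volume loss in complete-data subjects.

    Baseline-minus-year difference images (positive = loss) from subjects who
    attended every visit are tested against zero with sign-flip permutations
    and voxel-wise max-statistic FWE, without TFCE.  Subjects missing any
    scheduled visit are excluded (logged).
    """
    diffs = []
    for sid, visits in sorted(series_pseudo.items()):
        if not all(t in visits for t in all_times):
            logger.info("subject %s excluded from post-hoc (incomplete visits)", sid)
            continue
        b, y = visits[baseline_year], visits[target_year]
        diffs.append(b.like(np.asarray(b.data) - np.asarray(y.data)))
    if len(diffs) < 2:
        raise ValueError("fewer than 2 complete-data subjects")
    design = DesignMatrix(np.ones((len(diffs), 1)), ["intercept"])
    res = permutation_fwe(
        diffs,
        design,
        np.array([1.0]),
        mask=mask,
        n_perm=n_perm,
        enhance="none",
        alpha=alpha,
        seed=seed,
        scheme="sign_flip",
    )
    res.extra["n_subjects"] = len(diffs)
    res.extra["target_year"] = target_year
    return res
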