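"""Preprocessing: rigid coregistration, lesion filling, non-uniformity
correction and brain extraction.

Conventions: world coordinates in mm, voxel indices 0-based.  A
:class:`RigidTransform` acts on world coordinates and is stored as the
*pull-back* map used for resampling: it sends fixed-image world points to the
corresponding moving-image world points.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize
from scipy.spatial.transform import Rotation
from skimage.filters import threshold_multiotsu, threshold_otsu

from .core import Volume

logger = logging.getLogger(__name__)

__all__ = [
    "RigidTransform",
    "rigid_coregister",
    "resample_rigid",
    "fill_lesions",
    "correct_nonuniformity",
    "extract_brain",
    "mutual_information",
]


@dataclass(frozen=True)
class RigidTransform:
    """6-dof rigid transform: xyz Euler rotations (radians) + translation (mm).

    ``matrix`` maps fixed-image world coordinates to moving-image world
    coordinates (the pull-back used when resampling the moving image onto the
    fixed grid).
    """

    rotation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)

    @property
    def matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = Rotation.from_euler("xyz", self.rotation).as_matrix()
        m[:3, 3] = self.translation
        return m

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "RigidTransform":
        rot = Rotation.from_matrix(m[:3, :3]).as_euler("xyz")
        return cls(tuple(rot), tuple(m[:3, 3]))

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other (apply ``other`` first)."""
        return RigidTransform.from_matrix(self.matrix @ other.matrix)

    def inverse(self) -> "RigidTransform":
        return RigidTransform.from_matrix(np.linalg.inv(self.matrix))

    def apply_to_points(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        return pts @ self.matrix[:3, :3].T + self.matrix[:3, 3]

    @property
    def params(self) -> np.ndarray:
        return np.concatenate([self.rotation, self.translation])

    def max_param_change(self, other: "RigidTransform") -> float:
        """Max abs difference, rotations compared in degrees vs mm as-is."""
        d = np.abs(self.params - other.params)
        d[:3] = np.degrees(d[:3])
        return float(d.max())


def resample_rigid(
    moving: Volume, fixed: Volume, transform: RigidTransform, order: int = 1
) -> Volume:
    """Resample ``moving`` onto the grid of ``fixed`` through ``transform``.

    Trilinear by default; zero-padding outside the field of view.
    """
    # voxel(fixed) -> world -> (pull-back) world(moving) -> voxel(moving)
    m = np.linalg.inv(moving.affine) @ transform.matrix @ fixed.affine
    out = ndimage.affine_transform(
        np.asarray(moving.data, dtype=float),
        m[:3, :3],
        offset=m[:3, 3],
        output_shape=fixed.shape,
        order=order,
        mode="constant",
        cval=0.0,
    )
    return fixed.like(out)


def mutual_information(a: np.ndarray, b: np.ndarray, bins: int = 32) -> float:
    """Mutual information of the joint intensity histogram (nats)."""
    h, _, _ = np.histogram2d(a.ravel(), b.ravel(), bins=bins)
    p = h / max(h.sum(), 1.0)
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float((p[nz] * np.log(p[nz] / (px @ py)[nz])).sum())


def _metric_value(
    moving: Volume, fixed: Volume, t: RigidTransform, metric: str, mask: np.ndarray | None
) -> float:
    res = resample_rigid(moving, fixed, t).data
    f = fixed.data if mask is None else fixed.data[mask]
    r = res if mask is None else res[mask]
    if metric == "ssd":
        return -float(np.mean((r - f) ** 2))
    if metric == "mutual_information":
        return mutual_information(r, f)
    raise ValueError(f"unknown metric {metric!r}")


def _strided(vol: Volume, s: int) -> Volume:
    if s == 1:
        return vol
    aff = vol.affine.copy()
    aff[:3, :3] *= s
    return Volume(np.ascontiguousarray(vol.data[::s, ::s, ::s]), aff)


def _com_world(vol: Volume) -> np.ndarray:
    w = np.clip(np.asarray(vol.data, dtype=float), 0, None)
    tot = w.sum()
    if tot <= 0:
        return vol.voxel_to_world(np.asarray(vol.shape) / 2.0)
    idx = np.asarray(ndimage.center_of_mass(w))
    return vol.voxel_to_world(idx)


def rigid_coregister(
    moving: Volume,
    fixed: Volume,
    metric: str = "ssd",
    mask: np.ndarray | None = None,
    init: RigidTransform | None = None,
    maxiter: int = 25,
) -> RigidTransform:
    """Estimate the rigid transform aligning ``moving`` to ``fixed``.

    Powell optimization of SSD (phantom default) or a 32-bin
    mutual-information metric, initialised at the intensity
    center-of-mass offset and run coarse-to-fine.  Returns the pull-back
    transform; resampling with it brings ``moving`` onto the ``fixed`` grid.
    """
    if float(np.ptp(fixed.data)) == 0.0 or float(np.ptp(moving.data)) == 0.0:
        raise ValueError("flat-intensity image: registration is ill-posed")

    # rotations scaled so one optimizer unit ~ 1 mm at the brain radius
    rot_scale = 0.02

    def unpack(p):
        return RigidTransform(tuple(p[:3] * rot_scale), tuple(p[3:]))

    x0 = np.zeros(6)
    if init is not None:
        x0[:3] = np.asarray(init.rotation) / rot_scale
        x0[3:] = init.translation
    else:
        x0[3:] = _com_world(moving) - _com_world(fixed)

    stride = 2 if min(fixed.shape) >= 24 else 1
    stages = [(stride, maxiter, 1e-2)] if stride == 1 else [
        (stride, maxiter, 1e-2),
        (1, 3, 2e-3),
    ]
    x = x0
    for s, it, xtol in stages:
        fx = _strided(fixed, s)
        mk = None if mask is None else np.asarray(mask, dtype=bool)[::s, ::s, ::s]

        def cost(p, fx=fx, mk=mk):
            return -_metric_value(moving, fx, unpack(p), metric, mk)

        res = optimize.minimize(
            cost, x, method="Powell", options=dict(maxiter=it, xtol=xtol, ftol=1e-8)
        )
        # optimality guard: never accept something worse than the start point
        x = res.x if cost(res.x) <= cost(x) else x
    best = unpack(x)
    overlap = _overlap_fraction(moving, fixed, best)
    if overlap < 0.05:
        raise ValueError(
            f"registration failed: grids barely overlap (fraction {overlap:.3f})"
        )
    return best


def _overlap_fraction(moving: Volume, fixed: Volume, t: RigidTransform) -> float:
    ones = moving.like(np.ones(moving.shape))
    res = resample_rigid(ones, fixed, t).data
    return float(res.mean())


# --------------------------------------------------------------------------
# lesion filling
# --------------------------------------------------------------------------

# SD shrink factor of 3-D white noise after a sigma=1 voxel Gaussian filter
_GAUSS1_SD_SHRINK = 0.1547


def fill_lesions(t1: Volume, lesion_mask: Volume, wm_mask: Volume, seed: int = 0) -> Volume:
    """Replace lesion voxels by draws from the normal-WM intensity model.

    Fill = normal-WM mean + Gaussian noise matched to the normal-WM SD, with a
    1-voxel Gaussian smoothing applied to the filled patch to blend its
    boundary.  Voxels outside the lesion mask are exactly unchanged.
    """
    t1.require_same_grid(lesion_mask, "fill_lesions")
    t1.require_same_grid(wm_mask, "fill_lesions")
    les = np.asarray(lesion_mask.data, dtype=bool)
    wm = np.asarray(wm_mask.data, dtype=bool) & ~les
    if not wm.any():
        raise ValueError("no normal WM voxels to sample fill intensities from")
    if les.sum() > 0.5 * (wm.sum() + les.sum()):
        warnings.warn("lesion mask covers > 50% of WM; filling anyway", stacklevel=2)
    out = np.array(t1.data, dtype=float, copy=True)
    if not les.any():
        return t1.like(out)
    mu, sd = float(out[wm].mean()), float(out[wm].std())
    rng = np.random.default_rng(seed)
    # smooth the synthetic fill texture, not the surrounding image, so the
    # fill stays on the normal-WM intensity model
    texture = rng.normal(0.0, sd, size=t1.shape)
    fill = mu + ndimage.gaussian_filter(texture, sigma=1.0) / max(
        _GAUSS1_SD_SHRINK, 1e-6
    )
    out[les] = fill[les]
    return t1.like(out)


# --------------------------------------------------------------------------
# non-uniformity correction
# --------------------------------------------------------------------------


def _poly_basis(shape: tuple[int, int, int], order: int) -> np.ndarray:
    ax = [np.linspace(-1.0, 1.0, n) for n in shape]
    x, y, z = np.meshgrid(*ax, indexing="ij")
    cols = []
    for i in range(order + 1):
        for j in range(order + 1 - i):
            for k in range(order + 1 - i - j):
                cols.append((x**i) * (y**j) * (z**k))
    return np.stack([c.ravel() for c in cols], axis=1)


def correct_nonuniformity(image: Volume, order: int = 2, brain_mask: Volume | None = None) -> Volume:
    """Divide out a low-order polynomial multiplicative bias field.

    The log-domain field is estimated by least squares on the brightest
    tissue class only (3-class Gaussian mixture inside the brain), where the
    true intensity is approximately constant, so anatomy does not leak into
    the bias estimate.  The mean brain intensity is preserved.  Nonpositive
    intensities trigger a shifted-log fallback (logged).
    """
    if not 1 <= order <= 4:
        raise ValueError("order must be in 1..4")
    data = np.asarray(image.data, dtype=float)
    brain = extract_brain(image) if brain_mask is None else brain_mask
    m = np.asarray(brain.data, dtype=bool)
    vals = data[m]
    shift = 0.0
    if vals.min() <= 0:
        shift = -vals.min() + 1e-3 * max(float(np.ptp(vals)), 1.0)
        logger.info("nonpositive intensities in brain; shifted-log fallback (+%g)", shift)
    logdata = np.log(np.where(m, data + shift, 1.0))

    # reference class = brightest mixture component inside the brain
    from sklearn.mixture import GaussianMixture

    x = logdata[m].reshape(-1, 1)
    gmm = GaussianMixture(
        n_components=3,
        covariance_type="diag",
        reg_covar=1e-4 * max(float(x.var()), 1e-6),
        random_state=0,
    ).fit(x)
    bright = int(np.argmax(gmm.means_.ravel()))
    ref = np.zeros(image.shape, dtype=bool)
    ref[m] = gmm.predict_proba(x)[:, bright] > 0.5
    if ref.sum() < 10 * _n_poly_terms(order):
        ref = m  # tiny reference class: fall back to whole brain

    basis = _poly_basis(image.shape, order)
    coef, *_ = np.linalg.lstsq(basis[ref.ravel()], logdata[ref], rcond=None)
    logfield = (basis @ coef).reshape(image.shape)
    logfield -= logfield[m].mean()  # unit-mean field inside brain (log domain)
    corrected = (data + shift) / np.exp(logfield) - shift
    # exact mean preservation inside the brain
    corrected[m] *= vals.mean() / corrected[m].mean()
    out = data.copy()
    out[m] = corrected[m]
    return image.like(out)


def _n_poly_terms(order: int) -> int:
    return sum(
        1
        for i in range(order + 1)
        for j in range(order + 1 - i)
        for _ in range(order + 1 - i - j)
    )


# --------------------------------------------------------------------------
# brain extraction
# --------------------------------------------------------------------------


def extract_brain(image: Volume) -> Volume:
    """Binary brain mask: Otsu threshold, largest component, closing.

    A multi-level Otsu is used so the lowest threshold separates background
    from the darkest tissue class (plain Otsu lands between CSF and GM on
    T1-like contrast and truncates the mask).
    """
    data = np.asarray(image.data, dtype=float)
    if float(np.ptp(data)) == 0.0:
        raise ValueError("constant image: cannot extract brain")
    try:
        thr = float(threshold_multiotsu(data, classes=4)[0])
    except ValueError:  # too few distinct values for 4 classes
        thr = float(threshold_otsu(data))
    fg = data > thr
    # Otsu on bimodal background/foreground; fall back if empty
    if not fg.any():
        raise ValueError("empty brain mask")
    lab, n = ndimage.label(fg)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
        fg = lab == (1 + int(np.argmax(sizes)))
    fg = ndimage.binary_closing(fg, structure=np.ones((3, 3, 3)), iterations=1)
    fg = ndimage.binary_fill_holes(fg)
    return image.like(fg.astype(np.uint8))
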