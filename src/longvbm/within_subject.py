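"""Within-subject longitudinal processing.

Builds an unbiased voxel-wise median template from all of a subject's visits,
estimates a small-deformation (demons-like) non-rigid field mapping each
visit onto the template, derives Jacobian-determinant maps, segments the
template into CSF/GM/WM, and forms "pseudo-time-point" images (template GM
probability x visit Jacobian).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from sklearn.mixture import GaussianMixture

from .core import GridMismatchError, Volume
from .preprocess import RigidTransform, resample_rigid, rigid_coregister

logger = logging.getLogger(__name__)

__all__ = [
    "WithinSubjectTemplate",
    "DeformationField",
    "build_median_template",
    "hdw_register",
    "jacobian_determinant",
    "segment_template",
    "pseudo_timepoint",
    "warp_volume",
    "membrane_energy",
]


@dataclass
class WithinSubjectTemplate:
    """Voxel-wise median template plus per-visit rigid transforms."""

    volume: Volume
    transforms: list[RigidTransform]
    n_iterations: int
    history: list[float] = field(default_factory=list)  # max param change per iter
    converged: bool = True

    def resampled_visits(self, visits: list[Volume]) -> list[Volume]:
        return [
            resample_rigid(v, self.volume, t) for v, t in zip(visits, self.transforms)
        ]


def build_median_template(
    visits: list[Volume],
    max_iter: int = 5,
    tol: float = 0.01,
) -> WithinSubjectTemplate:
    """Iterative unbiased voxel-wise intensity median template.

    All visits are registered and resampled to the current median, then the
    median is recomputed, until the largest rigid-parameter change drops below
    ``tol`` (mm / degrees) or ``max_iter`` is reached.  No visit serves as the
    fixed reference, so the construction is symmetric in the visits; it is
    also invariant to visit order (the median is permutation-invariant and
    registrations are independent).
    """
    if len(visits) == 0:
        raise ValueError("at least one visit required")
    grid = visits[0]
    for v in visits[1:]:
        grid.require_same_grid(v, "median template")
    if len(visits) == 1:
        return WithinSubjectTemplate(visits[0].copy(), [RigidTransform.identity()], 1)

    transforms = [RigidTransform.identity() for _ in visits]
    template = grid.like(np.median(np.stack([v.data for v in visits]), axis=0))
    history: list[float] = []
    converged = False
    n_done = 0
    for it in range(max_iter):
        new_transforms = [
            rigid_coregister(v, template, metric="ssd", init=t)
            for v, t in zip(visits, transforms)
        ]
        change = max(
            t.max_param_change(nt) for t, nt in zip(transforms, new_transforms)
        )
        transforms = new_transforms
        resampled = [resample_rigid(v, template, t) for v, t in zip(visits, transforms)]
        template = grid.like(np.median(np.stack([r.data for r in resampled]), axis=0))
        history.append(change)
        n_done = it + 1
        if change < tol:
            converged = True
            break
    if not converged:
        logger.warning("median template did not converge in %d iterations", max_iter)
    return WithinSubjectTemplate(template, transforms, n_done, history, converged)


@dataclass
class DeformationField:
    """Per-voxel displacement (mm) on the template grid.

    ``displacement`` has shape (3, nx, ny, nz).  Sampling a visit at
    ``x + u(x)`` (world mm) pulls it back onto the template grid, so the
    Jacobian ``det(I + grad u)`` is the visit-relative volume ratio at each
    template voxel (<1 where the visit has contracted).
    """

    displacement: np.ndarray
    grid: Volume
    reg_param: float
    n_iter: int

    def __post_init__(self):
        self.displacement = np.asarray(self.displacement, dtype=float)
        if self.displacement.shape != (3, *self.grid.shape):
            raise ValueError("displacement must have shape (3, nx, ny, nz)")
        if not np.all(np.isfinite(self.displacement)):
            raise ValueError("displacement field contains non-finite values")

    @property
    def max_displacement_mm(self) -> float:
        return float(np.sqrt((self.displacement**2).sum(axis=0)).max())


def warp_volume(volume: Volume, fld: DeformationField, order: int = 1) -> Volume:
    """Resample ``volume`` at x + u(x) for each template grid point."""
    grid = fld.grid
    pts = grid.grid_world_coords() + np.moveaxis(fld.displacement, 0, -1)
    vox = volume.world_to_voxel(pts)
    out = ndimage.map_coordinates(
        np.asarray(volume.data, dtype=float),
        [vox[..., 0], vox[..., 1], vox[..., 2]],
        order=order,
        mode="constant",
        cval=0.0,
    )
    return grid.like(out)


def membrane_energy(fld: DeformationField) -> float:
    """Sum of squared first spatial derivatives of the displacement (mm^2/mm^2)."""
    e = 0.0
    sp = fld.grid.voxel_size
    for c in range(3):
        for ax in range(3):
            g = np.gradient(fld.displacement[c], sp[ax], axis=ax)
            e += float((g**2).sum())
    return e


def _downsample(vol: Volume, f: int) -> Volume:
    if f == 1:
        return vol
    data = ndimage.zoom(np.asarray(vol.data, dtype=float), 1.0 / f, order=1)
    aff = vol.affine.copy()
    aff[:3, :3] *= f
    return Volume(data, aff)


def hdw_register(
    visit: Volume,
    template: Volume,
    reg_param: float = 4.0,
    n_iter: int = 8,
    levels: tuple[int, ...] = (2, 1),
    step: float = 2.0,
    inner_iter: int = 5,
    presmooth_vox: float = 0.8,
) -> DeformationField:
    """High-dimensional (small-deformation) registration of a visit to the
    within-subject template.

    Multi-resolution demons-style descent on SSD with membrane-energy
    regularisation applied as Gaussian smoothing of the displacement field;
    ``reg_param`` sets the smoothing scale (a calibration of the penalty
    weight, sigma = 0.6*sqrt(reg_param) voxels; default 4) and ``n_iter`` the
    outer iterations per level (default 8; each outer iteration performs
    ``inner_iter`` demons updates).  Inputs are pre-smoothed by
    ``presmooth_vox`` voxels for gradient stability.  Divergence
    (negative-Jacobian fraction > 0.1%) halves the step and retries; if the
    step underflows the registration fails.
    """
    visit.require_same_grid(template, "hdw_register")
    sigma_vox = 0.6 * float(np.sqrt(max(reg_param, 1e-6)))

    # global intensity matching: an SSD metric reads a scanner-wide
    # brightness change (e.g. an upgrade shift) as spurious deformation
    tdata0 = np.asarray(template.data, dtype=float)
    vdata0 = np.asarray(visit.data, dtype=float)
    joint = (tdata0 > 0) & (vdata0 > 0)
    if joint.any() and vdata0[joint].mean() > 0:
        scale = float(tdata0[joint].mean() / vdata0[joint].mean())
        if abs(scale - 1.0) > 1e-6:
            visit = visit.like(vdata0 * scale)

    u = None  # (3, ...) mm, on current level grid
    for f in sorted(set(levels), reverse=True):
        tpl_l = _downsample(template, f)
        vis_l = _downsample(visit, f)
        if presmooth_vox > 0:
            tpl_l = tpl_l.like(ndimage.gaussian_filter(tpl_l.data, presmooth_vox))
            vis_l = vis_l.like(ndimage.gaussian_filter(vis_l.data, presmooth_vox))
        sp = tpl_l.voxel_size
        if u is None:
            u = np.zeros((3, *tpl_l.shape))
        else:
            u = np.stack(
                [
                    ndimage.zoom(u[c], np.array(tpl_l.shape) / np.array(u.shape[1:]), order=1)
                    for c in range(3)
                ]
            )
        fld = DeformationField(u, tpl_l, reg_param, n_iter)
        tdata = np.asarray(tpl_l.data, dtype=float)
        scale2 = float(np.mean(sp) ** 2)
        cur_step = step
        it = 0
        while it < n_iter * inner_iter:
            warped = warp_volume(vis_l, fld).data
            diff = tdata - warped
            grads = np.stack(
                [np.gradient(warped, sp[ax], axis=ax) for ax in range(3)]
            )
            gnorm2 = (grads**2).sum(axis=0)
            denom = gnorm2 + diff**2 / scale2
            with np.errstate(invalid="ignore", divide="ignore"):
                force = np.where(denom > 1e-12, diff / denom, 0.0)[None] * grads
            cand = np.stack(
                [
                    ndimage.gaussian_filter(u[c] + cur_step * force[c], sigma_vox)
                    for c in range(3)
                ]
            )
            cand_fld = DeformationField(cand, tpl_l, reg_param, n_iter)
            neg = float(np.mean(jacobian_determinant(cand_fld).data <= 0))
            if neg > 0.001:
                cur_step *= 0.5
                if cur_step < 1e-3 * step:
                    raise RuntimeError(
                        "hdw_register diverged: negative Jacobians persist"
                    )
                logger.info("negative Jacobians (%.3f%%): halving step", 100 * neg)
                continue
            u = cand
            fld = cand_fld
            it += 1
    return DeformationField(u, template, reg_param, n_iter)


def jacobian_determinant(fld: DeformationField) -> Volume:
    """det(I + grad u) by central finite differences (one-sided at borders).

    Displacement gradients are taken with respect to world mm via the voxel
    size, so the determinant is a unitless volume ratio.
    """
    sp = fld.grid.voxel_size
    g = np.empty((3, 3, *fld.grid.shape))
    for c in range(3):
        for ax in range(3):
            g[c, ax] = np.gradient(fld.displacement[c], sp[ax], axis=ax)
    j = np.moveaxis(g, (0, 1), (-2, -1))  # (..., 3, 3)
    j = j + np.eye(3)
    return fld.grid.like(np.linalg.det(j))


def segment_template(
    template: Volume,
    brain_mask: Volume,
    K: int = 3,
    seed: int = 0,
) -> dict[str, Volume]:
    """K-class Gaussian-mixture EM segmentation within the brain mask.

    Posteriors sum to 1 at every masked voxel; classes map to tissue names by
    ascending mean intensity (T1-like convention: CSF < GM < WM).
    """
    m = np.asarray(brain_mask.data, dtype=bool)
    if not m.any():
        raise ValueError("empty brain mask")
    x = np.asarray(template.data, dtype=float)[m].reshape(-1, 1)
    for attempt in range(2):
        gm = GaussianMixture(
            n_components=K,
            covariance_type="diag",
            reg_covar=1e-4 * max(float(x.var()), 1e-6),
            random_state=seed + attempt,
            n_init=1,
            max_iter=200,
        )
        gm.fit(x)
        if np.all(gm.covariances_ > 0) and np.all(np.isfinite(gm.means_)):
            break
    else:  # pragma: no cover - defensive
        raise RuntimeError("EM segmentation degenerate after re-initialization")
    post = gm.predict_proba(x)
    order = np.argsort(gm.means_.ravel())
    names = ["csf", "gm", "wm"] if K == 3 else [f"class{i}" for i in range(K)]
    out: dict[str, Volume] = {}
    for rank, comp in enumerate(order):
        vol = np.zeros(template.shape)
        vol[m] = post[:, comp]
        out[names[rank]] = template.like(vol)
    return out


def pseudo_timepoint(gm_prob: Volume, jac: Volume) -> Volume:
    """Probabilistic GM volume at a visit: GM probability x Jacobian map."""
    if not gm_prob.same_grid(jac):
        raise GridMismatchError("pseudo_timepoint: GM map and Jacobian grids differ")
    out = np.asarray(gm_prob.data, dtype=float) * np.asarray(jac.data, dtype=float)
    return gm_prob.like(np.maximum(out, 0.0))
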