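"""Group-space construction: balanced average template, normalisation of
pseudo-time-points WITHOUT modulation, Gaussian smoothing, explicit GM mask.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .core import GridMismatchError, Volume
from .preprocess import rigid_coregister, resample_rigid
from .within_subject import DeformationField, hdw_register, warp_volume

logger = logging.getLogger(__name__)

__all__ = [
    "GroupTemplate",
    "build_group_template",
    "normalize_to_group",
    "gaussian_smooth",
    "make_explicit_mask",
    "FWHM_TO_SIGMA",
]

# sigma = FWHM / (2 sqrt(2 ln 2))
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class GroupTemplate:
    """Average GM template plus per-subject warps into group space.

    ``warps`` maps subject id -> total displacement field (rigid composed
    with non-rigid) on the template grid; sampling a subject image at
    ``x + warp(x)`` normalizes it to group space.
    """

    volume: Volume
    warps: dict[str, DeformationField]
    balanced_ids: list[str]
    seed: int


def _total_warp(
    subject_map: Volume, template: Volume, reg_param: float, n_iter: int
) -> DeformationField:
    """Rigid + demons registration composed into one displacement field."""
    rig = rigid_coregister(subject_map, template, metric="ssd")
    res = resample_rigid(subject_map, template, rig)
    fld = hdw_register(res, template, reg_param=reg_param, n_iter=n_iter)
    # total sampling point: R(x + u(x)); store as displacement from x
    pts = template.grid_world_coords() + np.moveaxis(fld.displacement, 0, -1)
    total = rig.apply_to_points(pts) - template.grid_world_coords()
    return DeformationField(np.moveaxis(total, -1, 0), template, reg_param, n_iter)


def build_group_template(
    subject_gm_maps: dict[str, Volume],
    groups: dict[str, str],
    seed: int = 0,
    n_average_iter: int = 2,
    reg_param: float = 4.0,
    n_iter: int = 4,
) -> GroupTemplate:
    """Balanced study-specific average GM template.

    The construction set contains all controls plus an equal-sized random
    patient subset (seeded); if there are fewer patients than controls, all
    patients are used and the imbalance is logged.  The template is an
    iterative register-and-average; warps to the final template are then
    estimated for every subject, including those outside the balanced set.
    """
    ids = sorted(subject_gm_maps)
    controls = [s for s in ids if groups[s] == "control"]
    patients = [s for s in ids if groups[s] == "patient"]
    if len(controls) < 2 or len(patients) < 2:
        raise ValueError("need at least 2 subjects per group")
    rng = np.random.default_rng(seed)
    if len(patients) <= len(controls):
        chosen = list(patients)
        if len(patients) < len(controls):
            logger.warning(
                "patient group (%d) smaller than control group (%d): using all patients",
                len(patients), len(controls),
            )
    else:
        chosen = sorted(rng.choice(patients, size=len(controls), replace=False))
    balanced = controls + list(chosen)

    ref = subject_gm_maps[balanced[0]]
    template = ref.like(
        np.mean(np.stack([subject_gm_maps[s].data for s in balanced]), axis=0)
    )
    for _ in range(n_average_iter):
        warped = []
        for s in balanced:
            fld = _total_warp(subject_gm_maps[s], template, reg_param, n_iter)
            warped.append(warp_volume(subject_gm_maps[s], fld).data)
        template = ref.like(np.mean(np.stack(warped), axis=0))

    warps = {
        s: _total_warp(subject_gm_maps[s], template, reg_param, n_iter) for s in ids
    }
    return GroupTemplate(template, warps, balanced, seed)


def normalize_to_group(image: Volume, warp: DeformationField, order: int = 1) -> Volume:
    """Resample into group space through the warp; NO Jacobian modulation."""
    if image.shape != warp.grid.shape and not image.same_grid(warp.grid):
        # images live on the subject grid; warp samples arbitrary world points
        pass
    return warp_volume(image, warp, order=order)


def gaussian_smooth(image: Volume, fwhm_mm: float = 8.0) -> Volume:
    """Separable Gaussian smoothing, sigma = fwhm/(2*sqrt(2 ln 2)) per axis in
    mm converted to voxels; reflecting boundaries."""
    if fwhm_mm < 0:
        raise ValueError("fwhm must be nonnegative")
    if fwhm_mm == 0:
        return image.copy()
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / image.voxel_size
    out = ndimage.gaussian_filter(
        np.asarray(image.data, dtype=float), sigma=sigma_vox, mode="reflect"
    )
    return image.like(out)


def make_explicit_mask(smoothed_gm_maps: list[Volume]) -> Volume:
    """Explicit GM analysis mask from averaged smoothed GM probability maps.

    Threshold on the average map by Otsu's bimodal-gap rule; the largest
    connected component is retained.
    """
    if len(smoothed_gm_maps) == 0:
        raise ValueError("at least one GM map required")
    ref = smoothed_gm_maps[0]
    for v in smoothed_gm_maps[1:]:
        ref.require_same_grid(v, "make_explicit_mask")
    avg = np.mean(np.stack([v.data for v in smoothed_gm_maps]), axis=0)
    if float(np.ptp(avg)) == 0.0 or avg.max() <= 0:
        raise ValueError("degenerate GM maps: cannot build explicit mask")
    thr = threshold_otsu(avg)
    mask = avg > thr
    if not mask.any():
        raise ValueError("empty explicit mask")
    lab, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
        mask = lab == (1 + int(np.argmax(sizes)))
    return ref.like(mask.astype(np.uint8))
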