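"""Shared spatial data structures.

A :class:`Volume` is a 3-D scalar grid together with a grid-to-world affine
(world coordinates in mm, voxel indices 0-based).  All pipeline stages pass
volumes around; NIfTI-1 is the on-disk format (via nibabel).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import nibabel as nib
import numpy as np

__all__ = ["Volume", "SubjectSeries", "GridMismatchError"]


class GridMismatchError(ValueError):
    """Raised when an operation requires two volumes on the same grid."""


class Volume:
    """3-D scalar grid with a voxel-to-world affine.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Voxel values.
    affine : ndarray, shape (4, 4), optional
        Voxel-index -> world (mm) map.  Defaults to identity spacing.
    """

    __slots__ = ("data", "affine")

    def __init__(self, data: np.ndarray, affine: np.ndarray | None = None):
        data = np.asarray(data)
        if data.ndim != 3:
            raise ValueError(f"Volume requires 3-D data, got shape {data.shape}")
        if affine is None:
            affine = np.eye(4)
        affine = np.asarray(affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        self.data = data
        self.affine = affine

    # ------------------------------------------------------------------ basic
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge lengths in mm (per axis)."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def like(self, data: np.ndarray) -> "Volume":
        """New Volume on this grid holding ``data``."""
        return Volume(np.asarray(data), self.affine.copy())

    def copy(self) -> "Volume":
        return Volume(self.data.copy(), self.affine.copy())

    def same_grid(self, other: "Volume", atol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )

    def require_same_grid(self, other: "Volume", what: str = "operation") -> None:
        if not self.same_grid(other):
            raise GridMismatchError(
                f"{what}: grids differ (shape {self.shape} vs {other.shape})"
            )

    # ------------------------------------------------------------ coordinates
    def voxel_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map voxel indices (..., 3) to world mm coordinates."""
        idx = np.asarray(idx, dtype=float)
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        inv = np.linalg.inv(self.affine)
        return pts @ inv[:3, :3].T + inv[:3, 3]

    def grid_world_coords(self) -> np.ndarray:
        """World coordinates of every voxel, shape (nx, ny, nz, 3)."""
        idx = np.stack(
            np.meshgrid(*[np.arange(n) for n in self.shape], indexing="ij"), axis=-1
        )
        return self.voxel_to_world(idx)

    # --------------------------------------------------------------------- io
    def save(self, path) -> None:
        img = nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), self.affine)
        nib.save(img, str(path))

    @classmethod
    def load(cls, path) -> "Volume":
        img = nib.load(str(path))
        return cls(np.asarray(img.get_fdata(), dtype=np.float64), img.affine)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Volume(shape={self.shape}, voxel={tuple(np.round(self.voxel_size, 3))})"


@dataclass
class SubjectSeries:
    """One subject's ordered longitudinal visits.

    ``times`` are acquisition times in years from study entry; lists are
    index-aligned.  ``clinical`` maps a score name (e.g. ``"msfc"``) to a
    per-visit list of values (may be absent for controls).
    """

    subject_id: str
    group: str  # "patient" | "control"
    times: list[float]
    volumes: list[Volume]
    lesion_masks: list[Volume] = field(default_factory=list)
    upgrade_flags: list[bool] = field(default_factory=list)
    clinical: dict[str, list[float]] = field(default_factory=dict)
    age: float | None = None
    sex: str | None = None

    def __post_init__(self):
        if list(self.times) != sorted(self.times):
            raise ValueError("visit times must be sorted ascending")
        if len(self.volumes) != len(self.times):
            raise ValueError("one volume per visit required")

    @property
    def n_visits(self) -> int:
        return len(self.times)

    @property
    def upgrade_proportion(self) -> float:
        """Fraction of this subject's images acquired after the scanner upgrade."""
        if not self.upgrade_flags:
            return 0.0
        return float(np.mean(self.upgrade_flags))


def as_array_list(volumes: Sequence[Volume]) -> np.ndarray:
    """Stack a list of same-grid volumes into (n, nx, ny, nz)."""
    ref = volumes[0]
    for v in volumes[1:]:
        ref.require_same_grid(v, "stacking")
    return np.stack([v.data for v in volumes], axis=0)
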