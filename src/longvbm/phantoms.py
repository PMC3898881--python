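"""Synthetic longitudinal brain phantoms with known regional atrophy.

A phantom is a nested-sphere "brain" (CSF shell, GM shell, WM core) plus
designated spherical GM regions embedded in the core.  Atrophy is applied as
an analytically synthesized radial contraction field per designated region,
so every visit has an exact truth deformation and an exact truth Jacobian:
inside a region contracting with cumulative volume factor ``k`` the Jacobian
determinant is ``k`` everywhere, and the displacement decays smoothly to zero
in a surrounding blend shell.

Labels: 0 background, 1 CSF, 2 WM, 3 GM shell ("gm_cortex"), 4.. designated
GM regions (defaults: 4 "cingulate_analog", 5 "precentral_analog").
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .core import SubjectSeries, Volume

logger = logging.getLogger(__name__)

__all__ = [
    "PhantomSpec",
    "PhantomGeometry",
    "SphereRegion",
    "AtrophyModel",
    "ClinicalCoupling",
    "Cohort",
    "CohortTruth",
    "SubjectTruth",
    "make_phantom",
    "simulate_subject_series",
    "simulate_cohort",
    "write_cohort",
    "EDSS_GRID",
]

# Legal EDSS values: 0, 1, then half steps up to 10 (no 0.5).
EDSS_GRID = np.array([0.0, 1.0] + [1.5 + 0.5 * i for i in range(18)])

LABEL_BACKGROUND, LABEL_CSF, LABEL_WM, LABEL_GM_SHELL = 0, 1, 2, 3
_TISSUE_OF_LABEL = {LABEL_CSF: "csf", LABEL_WM: "wm"}  # labels >= 3 are GM


def tissue_of_label(label: int) -> str:
    if label == LABEL_BACKGROUND:
        return "background"
    return _TISSUE_OF_LABEL.get(label, "gm")


# --------------------------------------------------------------------------
# geometry
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SphereRegion:
    """A designated spherical GM region with an analytic contraction support.

    ``radius_mm`` is the region proper; displacement decays to zero between
    ``radius_mm`` and ``radius_mm + blend_mm``.
    """

    label: int
    name: str
    center_mm: tuple[float, float, float]
    radius_mm: float
    blend_mm: float

    @property
    def outer_mm(self) -> float:
        return self.radius_mm + self.blend_mm


@dataclass(frozen=True)
class PhantomGeometry:
    """Continuous-space label model of the phantom brain."""

    center_mm: tuple[float, float, float]
    r_brain_mm: float
    r_csf_inner_mm: float
    r_gm_inner_mm: float
    spheres: tuple[SphereRegion, ...]

    def __post_init__(self):
        # contraction supports must not overlap each other or leave the brain
        for i, a in enumerate(self.spheres):
            ca = np.asarray(a.center_mm)
            if np.linalg.norm(ca - np.asarray(self.center_mm)) + a.outer_mm > self.r_brain_mm:
                raise ValueError(f"region {a.name}: contraction support exits the brain")
            for b in self.spheres[i + 1 :]:
                d = np.linalg.norm(ca - np.asarray(b.center_mm))
                if d < a.outer_mm + b.outer_mm:
                    raise ValueError(
                        f"regions {a.name} and {b.name}: contraction supports overlap"
                    )

    def label_at(self, pts: np.ndarray) -> np.ndarray:
        """Vectorized label lookup at world points (..., 3)."""
        pts = np.asarray(pts, dtype=float)
        r = np.linalg.norm(pts - np.asarray(self.center_mm), axis=-1)
        lab = np.zeros(r.shape, dtype=np.int32)
        lab[r < self.r_brain_mm] = LABEL_CSF
        lab[r < self.r_csf_inner_mm] = LABEL_GM_SHELL
        lab[r < self.r_gm_inner_mm] = LABEL_WM
        for s in self.spheres:
            rs = np.linalg.norm(pts - np.asarray(s.center_mm), axis=-1)
            lab[rs < s.radius_mm] = s.label
        return lab

    @property
    def gm_labels(self) -> list[int]:
        return [LABEL_GM_SHELL] + [s.label for s in self.spheres]

    def sphere(self, label: int) -> SphereRegion:
        for s in self.spheres:
            if s.label == label:
                return s
        raise KeyError(f"no designated sphere region with label {label}")


def default_geometry(
    grid_shape: tuple[int, int, int], voxel_size_mm: tuple[float, float, float]
) -> PhantomGeometry:
    """Scale the default nested-sphere geometry to a grid.

    Brain radius is 40% of the smallest box extent; the two designated GM
    balls sit on the x axis inside the WM core.
    """
    extent = np.asarray(grid_shape) * np.asarray(voxel_size_mm)
    center = tuple(extent / 2.0)
    rb = 0.40 * float(extent.min())
    r_ball = 0.25 * rb
    blend = 0.15 * rb
    offset = 0.45 * rb
    spheres = (
        SphereRegion(4, "cingulate_analog",
                     (center[0] + offset, center[1], center[2]), r_ball, blend),
        SphereRegion(5, "precentral_analog",
                     (center[0] - offset, center[1], center[2]), r_ball, blend),
    )
    return PhantomGeometry(
        center_mm=center,
        r_brain_mm=rb,
        r_csf_inner_mm=0.88 * rb,
        r_gm_inner_mm=0.64 * rb,
        spheres=spheres,
    )


# --------------------------------------------------------------------------
# phantom spec / baseline image
# --------------------------------------------------------------------------


@dataclass
class PhantomSpec:
    """Parameters of the baseline phantom image."""

    grid_shape: tuple[int, int, int] = (32, 32, 32)
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    tissue_means: dict[str, float] = field(
        default_factory=lambda: {"csf": 30.0, "gm": 80.0, "wm": 120.0}
    )
    noise_sd: float = 4.0
    bias_amplitude: float = 0.0
    seed: int = 0
    geometry: PhantomGeometry | None = None

    def __post_init__(self):
        if min(self.grid_shape) < 16:
            raise ValueError("grid_shape must be >= 16 per axis")
        if min(self.voxel_size_mm) <= 0:
            raise ValueError("voxel sizes must be positive")
        if self.noise_sd < 0 or self.bias_amplitude < 0:
            raise ValueError("noise_sd and bias_amplitude must be nonnegative")
        for t in ("csf", "gm", "wm"):
            if t not in self.tissue_means:
                raise ValueError(f"tissue_means missing {t!r}")
        if self.geometry is None:
            self.geometry = default_geometry(self.grid_shape, self.voxel_size_mm)

    @property
    def affine(self) -> np.ndarray:
        a = np.eye(4)
        a[0, 0], a[1, 1], a[2, 2] = self.voxel_size_mm
        return a

    def mean_of_label(self, label: int) -> float:
        t = tissue_of_label(label)
        return 0.0 if t == "background" else self.tissue_means[t]


def _bias_field(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative bias 1 + amplitude * f, max |f| = 1."""
    if spec.bias_amplitude == 0:
        return np.ones(spec.grid_shape)
    ax = [np.linspace(-1, 1, n) for n in spec.grid_shape]
    x, y, z = np.meshgrid(*ax, indexing="ij")
    basis = [x, y, z, x * y, x * z, y * z, x * x - 1 / 3, y * y - 1 / 3, z * z - 1 / 3]
    coef = rng.standard_normal(len(basis))
    f = sum(c * b for c, b in zip(coef, basis))
    f = f / max(np.abs(f).max(), 1e-12)
    return 1.0 + spec.bias_amplitude * f


def _render(
    spec: PhantomSpec,
    labels: np.ndarray,
    bias: np.ndarray,
    rng: np.random.Generator,
    lesion_mask: np.ndarray | None = None,
    intensity_scale: float = 1.0,
) -> np.ndarray:
    means = np.zeros(max(labels.max() + 1, 6))
    for lab in range(len(means)):
        means[lab] = spec.mean_of_label(lab)
    img = means[labels]
    if lesion_mask is not None:
        # T2 lesions are hypointense on T1-like contrast
        img[lesion_mask] = 0.72 * spec.tissue_means["wm"]
    img = img * bias * intensity_scale
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    return img


def make_phantom(spec: PhantomSpec) -> tuple[Volume, Volume]:
    """Baseline phantom image and its label atlas.

    Returns ``(volume, atlas)``; deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    affine = spec.affine
    grid = Volume(np.zeros(spec.grid_shape), affine)
    pts = grid.grid_world_coords()
    labels = spec.geometry.label_at(pts)
    bias = _bias_field(spec, rng)
    img = _render(spec, labels, bias, rng)
    return Volume(img, affine), Volume(labels.astype(np.int16), affine)


# --------------------------------------------------------------------------
# atrophy model and analytic contraction fields
# --------------------------------------------------------------------------


@dataclass
class AtrophyModel:
    """Per-region annual fractional volume-change rates.

    Rates apply to designated sphere regions only (keyed by label).  The
    cumulative volume factor at time ``t`` is ``1 + rate * max(0, t - onset)``
    (linear model; a nonzero onset gives the delayed-onset variant used to
    exercise quadratic-term analyses).
    """

    patient_rates: dict[int, float] = field(default_factory=dict)
    control_rates: dict[int, float] = field(default_factory=dict)
    onset_years: dict[int, float] = field(default_factory=dict)
    rate_jitter_sd: float = 0.0

    def __post_init__(self):
        for rates in (self.patient_rates, self.control_rates):
            for lab, r in rates.items():
                if not -0.5 < r < 0.5:
                    raise ValueError(f"rate {r} for label {lab} outside (-0.5, 0.5)")
        for lab, r in self.patient_rates.items():
            c = self.control_rates.get(lab, 0.0)
            if abs(c) > abs(r):
                raise ValueError(
                    f"control rate magnitude exceeds patient rate for label {lab}"
                )

    def rates_for(self, group: str) -> dict[int, float]:
        return dict(self.patient_rates if group == "patient" else self.control_rates)

    def cumulative_factor(self, rate: float, t: float, label: int) -> float:
        onset = self.onset_years.get(label, 0.0)
        return 1.0 + rate * max(0.0, t - onset)


def _blend_q(xi: np.ndarray) -> np.ndarray:
    """Smoothstep complement: q(0)=1, q(1)=0, q'(0)=q'(1)=0."""
    xi = np.clip(xi, 0.0, 1.0)
    return (1.0 - xi) ** 2 * (1.0 + 2.0 * xi)


def _radial_g(r: np.ndarray, sphere: SphereRegion, factor: float) -> np.ndarray:
    """Forward radial map g(r): baseline radius -> deformed radius.

    g(r) = s*r inside the region (s = factor**(1/3)), blends back to the
    identity across the blend shell.
    """
    s = factor ** (1.0 / 3.0)
    R, W = sphere.radius_mm, sphere.blend_mm
    g = np.array(r, dtype=float, copy=True)
    inside = r <= R
    g[inside] = s * r[inside]
    shell = (r > R) & (r < R + W)
    xi = (r[shell] - R) / W
    g[shell] = r[shell] + (s - 1.0) * R * _blend_q(xi)
    return g


def _radial_g_prime(r: np.ndarray, sphere: SphereRegion, factor: float) -> np.ndarray:
    s = factor ** (1.0 / 3.0)
    R, W = sphere.radius_mm, sphere.blend_mm
    gp = np.ones_like(np.asarray(r, dtype=float))
    gp[r <= R] = s
    shell = (r > R) & (r < R + W)
    xi = (r[shell] - R) / W
    gp[shell] = 1.0 + (s - 1.0) * R * (-6.0 * xi * (1.0 - xi)) / W
    return gp


def truth_displacement(
    geometry: PhantomGeometry, factors: dict[int, float], grid: Volume
) -> np.ndarray:
    """Forward displacement u(x) = phi(x) - x on the grid, in mm, shape (3, ...).

    phi maps baseline coordinates to visit coordinates; the visit image is the
    baseline pulled back through phi^{-1}.
    """
    pts = grid.grid_world_coords()
    u = np.zeros(pts.shape[:-1] + (3,))
    for s in geometry.spheres:
        k = factors.get(s.label, 1.0)
        if k == 1.0:
            continue
        d = pts - np.asarray(s.center_mm)
        r = np.linalg.norm(d, axis=-1)
        sup = (r < s.outer_mm) & (r > 1e-9)
        g = _radial_g(r[sup], s, k)
        u[sup] += (g / r[sup] - 1.0)[:, None] * d[sup]
    return np.moveaxis(u, -1, 0)


def truth_jacobian(
    geometry: PhantomGeometry, factors: dict[int, float], grid: Volume
) -> np.ndarray:
    """Analytic Jacobian determinant of the truth map: g'(r) * (g(r)/r)^2."""
    pts = grid.grid_world_coords()
    jac = np.ones(pts.shape[:-1])
    for s in geometry.spheres:
        k = factors.get(s.label, 1.0)
        if k == 1.0:
            continue
        r = np.linalg.norm(pts - np.asarray(s.center_mm), axis=-1)
        sup = r < s.outer_mm
        rs = np.maximum(r[sup], 1e-9)
        g = _radial_g(rs, s, k)
        gp = _radial_g_prime(rs, s, k)
        jac[sup] = gp * (g / rs) ** 2
    return jac


def _inverse_radius(rprime: np.ndarray, sphere: SphereRegion, factor: float) -> np.ndarray:
    """Invert g by dense monotone tabulation (g is strictly increasing)."""
    table_r = np.linspace(0.0, sphere.outer_mm, 2048)
    table_g = _radial_g(table_r, sphere, factor)
    return np.interp(rprime, table_g, table_r)


def _deformed_labels(
    geometry: PhantomGeometry, factors: dict[int, float], grid: Volume
) -> np.ndarray:
    """Visit labels: evaluate the baseline label model at phi^{-1}(grid)."""
    pts = grid.grid_world_coords()
    src = pts.copy()
    for s in geometry.spheres:
        k = factors.get(s.label, 1.0)
        if k == 1.0:
            continue
        d = pts - np.asarray(s.center_mm)
        rp = np.linalg.norm(d, axis=-1)
        sup = (rp < _radial_g(np.array([s.outer_mm]), s, k)[0]) & (rp > 1e-9)
        r = _inverse_radius(rp[sup], s, k)
        src[sup] = np.asarray(s.center_mm) + (r / rp[sup])[:, None] * d[sup]
    return geometry.label_at(src)


# --------------------------------------------------------------------------
# subject / cohort simulation
# --------------------------------------------------------------------------


@dataclass
class SubjectTruth:
    """Ground truth for one simulated subject."""

    rates: dict[int, float]
    factors: dict[float, dict[int, float]]  # time -> label -> cumulative factor
    region_volumes_mm3: dict[float, dict[int, float]]  # time -> label -> true volume
    gm_volume_mm3: dict[float, float]
    clinical_slopes: dict[str, float] = field(default_factory=dict)


@dataclass
class CohortTruth:
    spec: PhantomSpec
    subjects: dict[str, SubjectTruth] = field(default_factory=dict)

    def displacement(self, subject_id: str, time: float, grid: Volume) -> np.ndarray:
        """Truth displacement field for a visit, computed on demand."""
        return truth_displacement(
            self.spec.geometry, self.subjects[subject_id].factors[time], grid
        )

    def jacobian(self, subject_id: str, time: float, grid: Volume) -> np.ndarray:
        return truth_jacobian(
            self.spec.geometry, self.subjects[subject_id].factors[time], grid
        )


def _place_lesions(
    spec: PhantomSpec, labels0: np.ndarray, rng: np.random.Generator, n_lesions: int
) -> np.ndarray:
    """Small static lesion balls inside WM, clear of the contraction supports."""
    geom = spec.geometry
    grid = Volume(np.zeros(spec.grid_shape), spec.affine)
    pts = grid.grid_world_coords()
    mask = np.zeros(spec.grid_shape, dtype=bool)
    ok = labels0 == LABEL_WM
    for s in geom.spheres:
        r = np.linalg.norm(pts - np.asarray(s.center_mm), axis=-1)
        ok &= r > s.outer_mm + 2.0
    cand = np.argwhere(ok)
    if len(cand) == 0 or n_lesions == 0:
        return mask
    radius = 1.4 * float(np.mean(spec.voxel_size_mm))
    for _ in range(n_lesions):
        c = cand[rng.integers(len(cand))]
        cw = grid.voxel_to_world(c)
        r = np.linalg.norm(pts - cw, axis=-1)
        mask |= (r < radius) & ok
    return mask


def simulate_subject_series(
    spec: PhantomSpec,
    model: AtrophyModel,
    visit_times: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0, 5.0),
    missing: tuple[float, ...] = (),
    seed: int = 0,
    group: str = "patient",
    subject_id: str = "sub-01",
    n_lesions: int = 3,
) -> tuple[SubjectSeries, SubjectTruth]:
    """Simulate one subject's serial volumes with analytic atrophy truth.

    Each visit's image is the baseline tissue model pulled back through a
    synthesized diffeomorphic contraction whose regional Jacobian integral
    equals the model's cumulative volume factor (exactly, up to voxelization).
    """
    times = sorted(t for t in visit_times if t not in set(missing))
    if len(times) < 2:
        raise ValueError("at least 2 retained visits required")
    rng = np.random.default_rng(seed)
    geom = spec.geometry

    rates = model.rates_for(group)
    for lab in rates:
        geom.sphere(lab)  # raises for non-sphere labels
    if model.rate_jitter_sd > 0:
        rates = {
            lab: r + rng.normal(0.0, model.rate_jitter_sd) for lab, r in rates.items()
        }

    grid = Volume(np.zeros(spec.grid_shape), spec.affine)
    labels0 = geom.label_at(grid.grid_world_coords())
    bias = _bias_field(spec, rng)
    lesions = _place_lesions(spec, labels0, rng, n_lesions if group == "patient" else 0)
    vox_vol = grid.voxel_volume

    base_counts = {lab: int((labels0 == lab).sum()) for lab in geom.gm_labels}

    volumes, lesion_masks, factors, region_vols, gm_vols = [], [], {}, {}, {}
    for t in times:
        f = {lab: model.cumulative_factor(r, t, lab) for lab, r in rates.items()}
        for lab, k in f.items():
            if k <= 0:
                raise ValueError(
                    f"cumulative volume factor {k:.3f} <= 0 for label {lab} at t={t}"
                )
        labels_t = labels0 if all(k == 1.0 for k in f.values()) else _deformed_labels(
            geom, f, grid
        )
        img = _render(spec, labels_t, bias, rng, lesion_mask=lesions)
        volumes.append(Volume(img, spec.affine))
        lesion_masks.append(Volume(lesions.astype(np.uint8), spec.affine))
        factors[t] = f
        region_vols[t] = {
            lab: base_counts[lab] * vox_vol * f.get(lab, 1.0) for lab in geom.gm_labels
        }
        gm_vols[t] = float(sum(region_vols[t].values()))

    series = SubjectSeries(
        subject_id=subject_id,
        group=group,
        times=list(times),
        volumes=volumes,
        lesion_masks=lesion_masks,
        upgrade_flags=[False] * len(times),
    )
    truth = SubjectTruth(
        rates=rates, factors=factors, region_volumes_mm3=region_vols, gm_volume_mm3=gm_vols
    )
    return series, truth


@dataclass
class ClinicalCoupling:
    """Linear coupling of clinical slopes to the designated region's true rate.

    ``msfc slope = intercept + gain * rate + Normal(0, noise_sd)``; the
    designated region defaults to the first sphere (the fast-atrophy analog).
    """

    intercept: float = 0.0
    gain: float = 0.0
    noise_sd: float = 0.05
    region_label: int = 4


def snap_to_edss_grid(x: np.ndarray) -> np.ndarray:
    """Round arbitrary values to the nearest legal EDSS value, clipped to [0, 10]."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    idx = np.abs(x[:, None] - EDSS_GRID[None, :]).argmin(axis=1)
    return EDSS_GRID[idx]


@dataclass
class Cohort:
    subjects: list[SubjectSeries]
    truth: CohortTruth
    spec: PhantomSpec
    model: AtrophyModel
    seed: int

    @property
    def patients(self) -> list[SubjectSeries]:
        return [s for s in self.subjects if s.group == "patient"]

    @property
    def controls(self) -> list[SubjectSeries]:
        return [s for s in self.subjects if s.group == "control"]


def _simulate_clinical(
    series: SubjectSeries,
    truth: SubjectTruth,
    coupling: ClinicalCoupling,
    rng: np.random.Generator,
) -> None:
    """Attach per-visit clinical scores; slopes coupled to the true rate."""
    t = np.asarray(series.times)
    rate = truth.rates.get(coupling.region_label, 0.0)
    if series.group == "patient":
        msfc_slope = coupling.intercept + coupling.gain * rate + rng.normal(
            0.0, coupling.noise_sd
        )
        msfc0 = rng.normal(-1.2, 0.4)  # baseline MSFC regime of the cohort
        edss0 = float(snap_to_edss_grid(rng.uniform(1.5, 6.0))[0])
        edss_step_slope = max(0.0, rng.normal(0.5, 0.4))  # ordinal steps / yr
        t2ll0 = max(0.5, rng.normal(12.0, 6.0))
        t2ll_slope = rng.normal(2.6, 1.5)
    else:
        msfc_slope = rng.normal(0.0, 0.02)
        msfc0 = rng.normal(0.0, 0.3)
        edss0, edss_step_slope = 0.0, 0.0
        t2ll0, t2ll_slope = 0.0, 0.0
    msfc = msfc0 + msfc_slope * t + rng.normal(0.0, 0.02, size=len(t))
    step0 = int(np.argmin(np.abs(EDSS_GRID - edss0)))
    steps = np.clip(np.round(step0 + edss_step_slope * t).astype(int), 0, len(EDSS_GRID) - 1)
    edss = EDSS_GRID[steps]
    t2ll = np.maximum(0.0, t2ll0 + t2ll_slope * t + rng.normal(0.0, 0.3, size=len(t)))
    series.clinical = {
        "msfc": msfc.tolist(),
        "edss": edss.tolist(),
        "t2_lesion_load_ml": t2ll.tolist(),
    }
    truth.clinical_slopes = {
        "msfc": float(msfc_slope),
        "edss_steps": float(edss_step_slope),
        "t2_lesion_load_ml": float(t2ll_slope),
    }


def simulate_cohort(
    n_patients: int,
    n_controls: int,
    model: AtrophyModel,
    missingness_rate: float = 0.15,
    upgrade_year: float | None = None,
    clinical_coupling: ClinicalCoupling | None = None,
    seed: int = 0,
    spec: PhantomSpec | None = None,
    visit_times: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0, 5.0),
    upgrade_gain: float = 1.05,
) -> Cohort:
    """Simulate a two-group longitudinal cohort.

    Visits after ``upgrade_year`` get a global multiplicative intensity shift
    and an upgrade flag; clinical slopes are linear in the designated region's
    true rate (see :class:`ClinicalCoupling`).  Missingness never removes the
    baseline visit; draws leaving a subject with fewer than 2 visits are
    redrawn (logged).
    """
    if n_patients < 2 or n_controls < 2:
        raise ValueError("need at least 2 subjects per group")
    spec = spec if spec is not None else PhantomSpec()
    coupling = clinical_coupling if clinical_coupling is not None else ClinicalCoupling()
    rng = np.random.default_rng(seed)
    truth = CohortTruth(spec=spec)
    subjects: list[SubjectSeries] = []

    groups = ["patient"] * n_patients + ["control"] * n_controls
    for i, group in enumerate(groups):
        sid = f"{'pat' if group == 'patient' else 'con'}-{i:03d}"
        followups = [t for t in visit_times if t > min(visit_times)]
        for attempt in range(20):
            missing = tuple(t for t in followups if rng.uniform() < missingness_rate)
            if len(visit_times) - len(missing) >= 2:
                break
            logger.info("subject %s: redrawing missingness (too few visits)", sid)
        series, struth = simulate_subject_series(
            spec,
            model,
            visit_times=visit_times,
            missing=missing,
            seed=int(rng.integers(2**31)),
            group=group,
            subject_id=sid,
        )
        series.age = float(
            rng.normal(42.8 if group == "patient" else 37.6, 5.0)
        )
        series.sex = "F" if rng.uniform() < (0.33 if group == "patient" else 0.47) else "M"
        if upgrade_year is not None:
            flags = [t >= upgrade_year for t in series.times]
            series.upgrade_flags = flags
            for v, f in zip(series.volumes, flags):
                if f:
                    v.data = v.data * upgrade_gain
        _simulate_clinical(series, struth, coupling, rng)
        subjects.append(series)
        truth.subjects[sid] = struth

    return Cohort(subjects=subjects, truth=truth, spec=spec, model=model, seed=seed)


# --------------------------------------------------------------------------
# on-disk representation
# --------------------------------------------------------------------------


def write_cohort(cohort: Cohort, outdir) -> Path:
    """Write NIfTI volumes, a manifest CSV, clinical CSV and a truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows, crows = [], []
    for s in cohort.subjects:
        sdir = outdir / s.subject_id
        sdir.mkdir(exist_ok=True)
        for j, t in enumerate(s.times):
            p = sdir / f"visit-{j}_t{t:g}.nii"
            s.volumes[j].save(p)
            lp = sdir / f"visit-{j}_t{t:g}_lesions.nii"
            if s.lesion_masks:
                s.lesion_masks[j].save(lp)
            rows.append(
                dict(
                    subject=s.subject_id,
                    group=s.group,
                    visit=j,
                    time_years=t,
                    path=str(p.relative_to(outdir)),
                    lesion_path=str(lp.relative_to(outdir)) if s.lesion_masks else "",
                    upgrade_flag=bool(s.upgrade_flags[j]) if s.upgrade_flags else False,
                    age=s.age,
                    sex=s.sex,
                )
            )
            crow = dict(subject=s.subject_id, visit=j, time_years=t)
            for k, vals in s.clinical.items():
                crow[k] = vals[j]
            crows.append(crow)
    pd.DataFrame(rows).to_csv(outdir / "manifest.csv", index=False)
    pd.DataFrame(crows).to_csv(outdir / "clinical.csv", index=False)
    tr = {
        sid: dict(
            rates={str(k): v for k, v in st.rates.items()},
            gm_volume_mm3={str(k): v for k, v in st.gm_volume_mm3.items()},
            clinical_slopes=st.clinical_slopes,
        )
        for sid, st in cohort.truth.subjects.items()
    }
    (outdir / "truth.json").write_text(json.dumps(tr, indent=1))
    return outdir
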