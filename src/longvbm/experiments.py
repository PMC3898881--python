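"""Validation experiments on synthetic cohorts.

These drivers back the acceptance checks: type-I error of the permutation
machinery on null cohorts, recovery of known regional atrophy through the
full pipeline, and power/false-positive behaviour of the clinical
association analysis.  They are ordinary package code (deterministic given
seeds) so validations can be re-run from the CLI or scripts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .clinical_assoc import pearson_corr, roi_rate
from .core import Volume
from .group_space import gaussian_smooth
from .inference import build_design, permutation_fwe
from .phantoms import (
    AtrophyModel,
    ClinicalCoupling,
    PhantomSpec,
    make_phantom,
    simulate_cohort,
    simulate_subject_series,
    truth_jacobian,
)
from .pipeline import RunConfig, run_pipeline
from .summary_stats import fit_voxelwise_slope
from .within_subject import pseudo_timepoint

logger = logging.getLogger(__name__)

__all__ = [
    "null_cohort_rejection_rate",
    "clinical_association_simulation",
    "AtrophyRecoveryResult",
    "atrophy_recovery_experiment",
]


def _null_slope_images(
    spec: PhantomSpec, n_subjects: int, fwhm_mm: float, rng: np.random.Generator
) -> list[Volume]:
    """Per-subject slope images for a zero-atrophy cohort.

    With no atrophy the truth deformations are identity, so registration is a
    no-op on expectation and is skipped for speed; slope images are fitted to
    the smoothed serial images directly (the inference stage under test sees
    exchangeable noise either way).
    """
    slopes = []
    for _ in range(n_subjects):
        series, _ = simulate_subject_series(
            spec, AtrophyModel(), seed=int(rng.integers(2**31)), n_lesions=0
        )
        vols = [gaussian_smooth(v, fwhm_mm) for v in series.volumes]
        slopes.append(fit_voxelwise_slope(vols, series.times).volume)
    return slopes


def null_cohort_rejection_rate(
    n_cohorts: int = 200,
    grid: int = 24,
    n_per_group: int = 4,
    n_perm: int = 200,
    alpha: float = 0.05,
    noise_sd: float = 4.0,
    fwhm_mm: float = 4.0,
    seed: int = 0,
) -> float:
    """Family-wise rejection rate of the two-sample TFCE FWE test under the
    null (no group difference), across independent simulated cohorts."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    spec = PhantomSpec(grid_shape=(grid,) * 3, noise_sd=noise_sd, seed=seed)
    _, atlas = make_phantom(spec)
    mask = atlas.like((atlas.data > 0).astype(np.uint8))
    design = build_design(
        pd.DataFrame(dict(group=["patient"] * n_per_group + ["control"] * n_per_group))
    )
    contrast = design.contrast("group")
    rejections = 0
    for i in range(n_cohorts):
        slopes = _null_slope_images(spec, 2 * n_per_group, fwhm_mm, rng)
        res = permutation_fwe(
            slopes,
            design,
            contrast,
            mask=mask,
            n_perm=n_perm,
            enhance="tfce",
            alpha=alpha,
            seed=int(rng.integers(2**31)),
            scheme="relabel",
        )
        rejections += int(res.n_significant > 0)
    return rejections / n_cohorts


# --------------------------------------------------------------------------
# clinical association power / type-I
# --------------------------------------------------------------------------


def _gm_probability(spec: PhantomSpec) -> tuple[Volume, Volume]:
    _, atlas = make_phantom(spec)
    gm = atlas.like((atlas.data >= 3).astype(float))
    return gm, atlas


def clinical_association_simulation(
    n_sims: int = 100,
    n_patients: int = 36,
    gain: float = 12.0,
    noise_sd: float = 0.104,
    rate_sd: float = 0.005,
    base_rate: float = -0.02,
    grid: int = 24,
    image_noise_sd: float = 0.02,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Simulate the ROI-rate vs year-5 outcome association.

    Per simulation: patient rates are drawn around ``base_rate``; each
    subject's ROI rate is *estimated* by fitting voxel-wise slopes to noisy
    truth-Jacobian pseudo-time-points and averaging over the designated
    region; the year-5 outcome follows the linear coupling model.  Returns
    the fraction of simulations with a significant Pearson correlation and
    the mean observed r.
    """
    rng = np.random.default_rng(seed)
    spec = PhantomSpec(grid_shape=(grid,) * 3, noise_sd=0.0, seed=seed)
    gm, atlas = _gm_probability(spec)
    times = (0.0, 1.0, 2.0, 3.0, 5.0)
    label = 4
    hits, rs = 0, []
    for _ in range(n_sims):
        roi_rates = np.empty(n_patients)
        outcomes = np.empty(n_patients)
        for i in range(n_patients):
            rate = base_rate + rng.normal(0.0, rate_sd)
            pseudos = []
            for t in times:
                jac = gm.like(
                    truth_jacobian(spec.geometry, {label: 1.0 + rate * t}, gm)
                )
                p = pseudo_timepoint(gm, jac)
                noisy = p.like(p.data + rng.normal(0, image_noise_sd, p.shape))
                pseudos.append(noisy)
            slope = fit_voxelwise_slope(pseudos, times).volume
            roi_rates[i] = roi_rate(slope, atlas, label)
            msfc_slope = gain * rate + rng.normal(0.0, noise_sd)
            outcomes[i] = rng.normal(-1.2, 0.0) + 5.0 * msfc_slope
        r, p = pearson_corr(roi_rates, outcomes)
        rs.append(r)
        hits += int(p < alpha)
    return dict(power=hits / n_sims, mean_r=float(np.mean(rs)), n_sims=n_sims)


# --------------------------------------------------------------------------
# full-pipeline atrophy recovery
# --------------------------------------------------------------------------


@dataclass
class AtrophyRecoveryResult:
    dice_high_rate: float
    recovered_rate: float
    true_rate: float
    detection: dict[int, dict[str, bool]] = field(default_factory=dict)
    ordering_holds: bool = False
    n_significant: int = 0


def _detected(result, region_mask: np.ndarray) -> bool:
    return bool((result.significant.data.astype(bool) & region_mask).any())


def atrophy_recovery_experiment(
    n_per_group: int = 12,
    grid: int = 32,
    noise_sd: float = 4.0,
    rate_fast: float = -0.02,
    rate_slow: float = -0.005,
    fwhm_mm: float = 4.0,
    n_perm: int = 500,
    subset_sizes: tuple[int, ...] = (4, 8, 12),
    seed: int = 0,
    out_dir: str = "scratch/recovery",
) -> AtrophyRecoveryResult:
    """Run the full pipeline on a cohort with known patient-only atrophy and
    measure recovery of the fast-atrophy region.

    Returns the Dice overlap of the FWE-significant set with the truth
    region, the recovered fractional annual rate (ROI slope over ROI baseline
    pseudo-GM), and per-sample-size detection flags for the fast and slow
    regions (the rate-heterogeneity ordering).
    """
    import pandas as pd

    spec = PhantomSpec(grid_shape=(grid,) * 3, noise_sd=noise_sd, seed=seed)
    model = AtrophyModel(
        patient_rates={4: rate_fast, 5: rate_slow}, rate_jitter_sd=0.002
    )
    cohort = simulate_cohort(
        n_per_group,
        n_per_group,
        model,
        missingness_rate=0.1,
        upgrade_year=2.5,
        clinical_coupling=ClinicalCoupling(gain=10.0, noise_sd=0.05),
        seed=seed,
        spec=spec,
    )
    cfg = RunConfig(
        out_dir=out_dir,
        fwhm_mm=fwhm_mm,
        n_perm=n_perm,
        run_quadratic=False,
        run_posthoc=False,
        run_clinical=False,
        write_intermediates=False,
        permutation_seed=seed,
        balanced_seed=seed,
    )
    res = run_pipeline(cohort, cfg, stop_after="second_level")

    _, atlas = make_phantom(spec)
    high = atlas.data == 4
    low = atlas.data == 5
    sig = res.second_level["group_slope"].significant.data.astype(bool)
    dice = 2.0 * (sig & high).sum() / max(sig.sum() + high.sum(), 1)

    # fractional rate: ROI mean slope over ROI mean baseline pseudo-GM
    patients = [s.subject_id for s in cohort.patients]
    mask = res.explicit_mask
    slopes, bases = [], []
    for sid in patients:
        f = res.first_level[sid]
        baseline = f.pseudo_group[min(f.pseudo_group)]
        slopes.append(roi_rate(f.slope, atlas, 4, mask=mask))
        bases.append(roi_rate(baseline, atlas, 4, mask=mask))
    recovered = float(np.mean(slopes) / np.mean(bases))
    true_rate = float(np.mean(
        [cohort.truth.subjects[sid].rates[4] for sid in patients]
    ))

    # sample-size sweep reusing first-level images
    order = [s.subject_id for s in cohort.subjects]
    loss = {
        sid: res.first_level[sid].slope.like(-np.asarray(res.first_level[sid].slope.data))
        for sid in order
    }
    cov = res.covariates
    detection: dict[int, dict[str, bool]] = {}
    for n_sub in subset_sizes:
        ids = [s.subject_id for s in cohort.patients[:n_sub]] + [
            s.subject_id for s in cohort.controls[:n_sub]
        ]
        from .pipeline import _fit_nuisance

        d = build_design(
            cov.loc[ids], group_column="group",
            nuisance=_fit_nuisance(len(ids), 2),
        )
        pr = permutation_fwe(
            [loss[sid] for sid in ids],
            d,
            d.contrast("group"),
            mask=mask,
            n_perm=n_perm,
            enhance="tfce",
            seed=seed + n_sub,
        )
        detection[n_sub] = dict(high=_detected(pr, high), low=_detected(pr, low))
    ordering = any(v["high"] and not v["low"] for v in detection.values())
    return AtrophyRecoveryResult(
        dice_high_rate=float(dice),
        recovered_rate=recovered,
        true_rate=true_rate,
        detection=detection,
        ordering_holds=ordering,
        n_significant=int(sig.sum()),
    )
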