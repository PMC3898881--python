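"""End-to-end orchestration of the longitudinal morphometry run.

Stages (in order): preprocessing, within-subject template + deformation
fields + Jacobians + pseudo-time-points, group-space normalisation and
smoothing, first-level slope/quadratic images, second-level permutation
inference, post-hoc year-by-year subtraction, clinical associations.  Every
numeric setting and seed is recorded in a provenance JSON so a run is
re-executable bit-identically.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import SubjectSeries, Volume
from .clinical_assoc import (
    boxcox_shift,
    flag_outliers,
    one_sample_progression_test,
    partial_corr,
    pearson_corr,
    roi_rate,
)
from .group_space import (
    build_group_template,
    gaussian_smooth,
    make_explicit_mask,
    normalize_to_group,
)
from .inference import (
    build_design,
    paired_baseline_subtraction_test,
    permutation_fwe,
)
from .phantoms import Cohort, make_phantom
from .preprocess import correct_nonuniformity, extract_brain, fill_lesions
from .summary_stats import (
    clinical_slope,
    edss_to_steps,
    fit_voxelwise_quadratic,
    fit_voxelwise_slope,
)
from .within_subject import (
    build_median_template,
    hdw_register,
    jacobian_determinant,
    pseudo_timepoint,
    segment_template,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "load_cohort_dir"]


@dataclass
class RunConfig:
    """All pipeline settings.

    Defaults: registration regularisation 4 with 8 iterations, 8 mm FWHM
    smoothing, 5000 permutations, alpha 0.05.  Every seed is recorded so
    runs are reproducible bit-for-bit.
    """

    out_dir: str = "longvbm_out"
    reg_param: float = 4.0
    n_iter: int = 8
    fwhm_mm: float = 8.0
    n_perm: int = 5000
    alpha: float = 0.05
    nonuniformity_order: int = 2
    correct_bias: bool = True
    template_max_iter: int = 2
    group_reg_iter: int = 4
    group_average_iter: int = 1
    balanced_seed: int = 0
    permutation_seed: int = 0
    run_quadratic: bool = True
    run_posthoc: bool = True
    run_clinical: bool = True
    write_intermediates: bool = True
    visit_schedule: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0, 5.0)
    roi_label: int = 4

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        if "visit_schedule" in raw:
            raw["visit_schedule"] = tuple(raw["visit_schedule"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["visit_schedule"] = list(self.visit_schedule)
        return d


@dataclass
class SubjectFirstLevel:
    """Per-subject intermediates and first-level maps."""

    subject_id: str
    template: Volume
    gm_prob: Volume
    jacobians: dict[float, Volume]
    pseudo: dict[float, Volume]  # within-subject space
    pseudo_group: dict[float, Volume] = field(default_factory=dict)  # smoothed, group space
    slope: Volume | None = None
    quadratic: Volume | None = None
    baseline_gm_volume: float = 0.0


@dataclass
class PipelineResult:
    config: RunConfig
    first_level: dict[str, SubjectFirstLevel]
    explicit_mask: Volume
    group_template: object
    covariates: pd.DataFrame
    second_level: dict[str, object] = field(default_factory=dict)
    clinical: dict[str, object] = field(default_factory=dict)
    timings: dict[str, float] = field(default_factory=dict)


# ------------------------------------------------------------------ stages


def preprocess_series(series: SubjectSeries, cfg: RunConfig) -> list[Volume]:
    """Lesion filling, optional non-uniformity correction, brain extraction."""
    out = []
    for j, vol in enumerate(series.volumes):
        v = vol
        brain = extract_brain(v)
        if series.lesion_masks:
            seg = segment_template(v, brain)
            wm = v.like((np.asarray(seg["wm"].data) > 0.5).astype(np.uint8))
            v = fill_lesions(v, series.lesion_masks[j], wm, seed=j)
        if cfg.correct_bias:
            v = correct_nonuniformity(v, cfg.nonuniformity_order, brain_mask=brain)
        masked = np.asarray(v.data, dtype=float) * np.asarray(brain.data, dtype=bool)
        out.append(v.like(masked))
    return out


def within_subject_stage(
    series: SubjectSeries, preprocessed: list[Volume], cfg: RunConfig
) -> SubjectFirstLevel:
    """Median template, HDW fields, Jacobians, segmentation, pseudo-time-points."""
    tpl = build_median_template(preprocessed, max_iter=cfg.template_max_iter)
    resampled = tpl.resampled_visits(preprocessed)
    brain = extract_brain(tpl.volume)
    seg = segment_template(tpl.volume, brain)
    gm = seg["gm"]
    jac, pseudo = {}, {}
    for t, vis in zip(series.times, resampled):
        fld = hdw_register(vis, tpl.volume, reg_param=cfg.reg_param, n_iter=cfg.n_iter)
        jmap = jacobian_determinant(fld)
        jac[t] = jmap
        pseudo[t] = pseudo_timepoint(gm, jmap)
    baseline_gm = float(
        np.asarray(pseudo[min(series.times)].data).sum()
        * pseudo[min(series.times)].voxel_volume
    )
    return SubjectFirstLevel(
        subject_id=series.subject_id,
        template=tpl.volume,
        gm_prob=gm,
        jacobians=jac,
        pseudo=pseudo,
        baseline_gm_volume=baseline_gm,
    )


def group_stage(
    firsts: dict[str, SubjectFirstLevel],
    groups: dict[str, str],
    cfg: RunConfig,
):
    """Balanced group template, normalisation (no modulation), smoothing, mask."""
    gm_maps = {sid: f.gm_prob for sid, f in firsts.items()}
    gt = build_group_template(
        gm_maps,
        groups,
        seed=cfg.balanced_seed,
        n_average_iter=cfg.group_average_iter,
        n_iter=cfg.group_reg_iter,
        reg_param=cfg.reg_param,
    )
    smoothed_gm = []
    for sid, f in firsts.items():
        w = gt.warps[sid]
        for t, p in f.pseudo.items():
            f.pseudo_group[t] = gaussian_smooth(normalize_to_group(p, w), cfg.fwhm_mm)
        smoothed_gm.append(gaussian_smooth(normalize_to_group(f.gm_prob, w), cfg.fwhm_mm))
    mask = make_explicit_mask(smoothed_gm)
    return gt, mask


def first_level_stage(firsts: dict[str, SubjectFirstLevel], cfg: RunConfig) -> None:
    for f in firsts.values():
        times = sorted(f.pseudo_group)
        vols = [f.pseudo_group[t] for t in times]
        f.slope = fit_voxelwise_slope(vols, times, f.subject_id).volume
        if cfg.run_quadratic and len(set(times)) >= 3:
            f.quadratic = fit_voxelwise_quadratic(vols, times, f.subject_id).volume
        elif cfg.run_quadratic:
            logger.info(
                "subject %s excluded from quadratic analysis (<3 visits)", f.subject_id
            )


def build_covariates(
    cohort: Cohort, firsts: dict[str, SubjectFirstLevel]
) -> pd.DataFrame:
    rows = []
    for s in cohort.subjects:
        rows.append(
            dict(
                subject=s.subject_id,
                group=s.group,
                age=s.age if s.age is not None else 0.0,
                sex=s.sex if s.sex is not None else "M",
                baseline_gm=firsts[s.subject_id].baseline_gm_volume,
                upgrade_proportion=s.upgrade_proportion,
            )
        )
    return pd.DataFrame(rows).set_index("subject", drop=False)


NUISANCE = ("age", "sex", "baseline_gm", "upgrade_proportion")


def _fit_nuisance(n: int, base_columns: int, min_df: int = 3) -> tuple[str, ...]:
    """Trim the nuisance list so the design keeps >= min_df residual df.

    Desk-scale cohorts can be smaller than the full covariate set; covariates
    are dropped from the tail of ``NUISANCE`` (least important last).
    """
    room = max(n - base_columns - min_df, 0)
    kept = NUISANCE[: min(room, len(NUISANCE))]
    if len(kept) < len(NUISANCE):
        logger.info("small design (n=%d): nuisance reduced to %s", n, kept)
    return kept


def second_level_stage(
    cohort: Cohort,
    firsts: dict[str, SubjectFirstLevel],
    mask: Volume,
    cov: pd.DataFrame,
    cfg: RunConfig,
) -> dict[str, object]:
    """Group comparison of atrophy rates (TFCE FWE) plus one-sample and
    quadratic analogues.  Slope images are negated ("loss rate") so that the
    positive tail tests greater atrophy."""
    out: dict[str, object] = {}
    order = [s.subject_id for s in cohort.subjects]
    loss = [firsts[sid].slope.like(-np.asarray(firsts[sid].slope.data)) for sid in order]
    design = build_design(
        cov.loc[order], group_column="group", nuisance=_fit_nuisance(len(order), 2)
    )
    out["group_slope"] = permutation_fwe(
        loss,
        design,
        design.contrast("group"),
        mask=mask,
        n_perm=cfg.n_perm,
        enhance="tfce",
        alpha=cfg.alpha,
        seed=cfg.permutation_seed,
    )
    # within-group loss (one-sample with nuisance -> Freedman-Lane sign flips)
    for grp in ("patient", "control"):
        ids = [s.subject_id for s in cohort.subjects if s.group == grp]
        if len(ids) < 2:
            continue
        d = build_design(
            cov.loc[ids], group_column=None, nuisance=_fit_nuisance(len(ids), 1)
        )
        out[f"{grp}_slope"] = permutation_fwe(
            [firsts[sid].slope.like(-np.asarray(firsts[sid].slope.data)) for sid in ids],
            d,
            d.contrast("intercept"),
            mask=mask,
            n_perm=cfg.n_perm,
            enhance="tfce",
            alpha=cfg.alpha,
            seed=cfg.permutation_seed + 1,
        )
    if cfg.run_quadratic:
        qids = [sid for sid in order if firsts[sid].quadratic is not None]
        if len(qids) >= 4:
            dq = build_design(
                cov.loc[qids], group_column="group", nuisance=_fit_nuisance(len(qids), 2)
            )
            out["group_quadratic"] = permutation_fwe(
                [firsts[sid].quadratic for sid in qids],
                dq,
                dq.contrast("group"),
                mask=mask,
                n_perm=cfg.n_perm,
                enhance="tfce",
                alpha=cfg.alpha,
                seed=cfg.permutation_seed + 2,
            )
    if cfg.run_posthoc:
        patients = {
            s.subject_id: firsts[s.subject_id].pseudo_group
            for s in cohort.subjects
            if s.group == "patient"
        }
        complete = {
            sid: v
            for sid, v in patients.items()
            if all(t in v for t in cfg.visit_schedule)
        }
        if len(complete) >= 2:
            posthoc = {}
            for yr in cfg.visit_schedule[1:]:
                posthoc[f"year_{yr:g}"] = paired_baseline_subtraction_test(
                    complete,
                    yr,
                    all_times=cfg.visit_schedule,
                    mask=mask,
                    n_perm=cfg.n_perm,
                    alpha=cfg.alpha,
                    seed=cfg.permutation_seed + 3,
                )
            out["posthoc"] = posthoc
    return out


def clinical_stage(
    cohort: Cohort,
    firsts: dict[str, SubjectFirstLevel],
    mask: Volume,
    cfg: RunConfig,
    atlas: Volume | None = None,
) -> dict[str, object]:
    """Clinical slopes, progression tests and ROI-rate associations."""
    out: dict[str, object] = {}
    if atlas is None:
        _, atlas = make_phantom(cohort.spec)
    rows = []
    for s in cohort.patients:
        t = np.asarray(s.times)
        rec = dict(subject=s.subject_id)
        if "msfc" in s.clinical:
            rec["msfc_slope"] = clinical_slope(s.clinical["msfc"], t)
            if 5.0 in s.times:
                rec["msfc_year5"] = s.clinical["msfc"][s.times.index(5.0)]
        if "edss" in s.clinical:
            steps = edss_to_steps(s.clinical["edss"])
            rec["edss_step_slope"] = clinical_slope(steps, t)
        if "t2_lesion_load_ml" in s.clinical:
            rec["t2ll_slope"] = clinical_slope(s.clinical["t2_lesion_load_ml"], t)
        rec["roi_rate"] = roi_rate(
            firsts[s.subject_id].slope, atlas, cfg.roi_label, mask=mask
        )
        rec["baseline_gm"] = firsts[s.subject_id].baseline_gm_volume
        rows.append(rec)
    table = pd.DataFrame(rows)
    out["patient_table"] = table
    for col in ("msfc_slope", "edss_step_slope", "t2ll_slope"):
        if col in table and table[col].notna().sum() >= 2:
            out[f"progression_{col}"] = one_sample_progression_test(
                table[col].dropna().to_numpy()
            )
    sub = table.dropna(subset=["msfc_year5"]) if "msfc_year5" in table else table.iloc[:0]
    if len(sub) >= 5:
        x = sub["roi_rate"].to_numpy()
        # outcome normalised by a shift-10 Box-Cox transform before correlation
        y, lam = boxcox_shift(sub["msfc_year5"].to_numpy(), shift=10.0, lam="mle")
        out["boxcox_lambda"] = lam
        out["assoc_all"] = pearson_corr(x, y)
        bad = flag_outliers(x, y)
        keep = np.setdiff1d(np.arange(len(x)), bad)
        if len(keep) >= 3:
            out["assoc_no_outliers"] = pearson_corr(x[keep], y[keep])
        out["outlier_indices"] = bad.tolist()
        out["assoc_partial_baseline_gm"] = partial_corr(
            x, y, sub["baseline_gm"].to_numpy()
        )
    return out


# --------------------------------------------------------------- top level


_STAGES = ("within_subject", "group", "first_level", "second_level", "clinical")


def run_pipeline(
    cohort: Cohort, cfg: RunConfig, stop_after: str = "clinical"
) -> PipelineResult:
    """Execute the full first-level -> second-level analysis on a cohort.

    Writes all declared outputs plus a provenance JSON under
    ``cfg.out_dir``; given identical config and seeds the final maps are
    bit-identical across runs.  ``stop_after`` truncates the run after the
    named stage (one of ``within_subject``, ``group``, ``first_level``,
    ``second_level``, ``clinical``).
    """
    if stop_after not in _STAGES:
        raise ValueError(f"stop_after must be one of {_STAGES}")
    stage_idx = _STAGES.index(stop_after)
    outdir = Path(cfg.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    groups = {s.subject_id: s.group for s in cohort.subjects}

    firsts: dict[str, SubjectFirstLevel] = {}
    t0 = time.perf_counter()
    for s in cohort.subjects:
        try:
            pre = preprocess_series(s, cfg)
            firsts[s.subject_id] = within_subject_stage(s, pre, cfg)
        except Exception as exc:
            raise RuntimeError(
                f"stage within_subject failed for subject {s.subject_id}: {exc}"
            ) from exc
    timings["within_subject"] = time.perf_counter() - t0

    gt, mask, second = None, None, {}
    cov = pd.DataFrame()
    if stage_idx >= 1:
        t0 = time.perf_counter()
        gt, mask = group_stage(firsts, groups, cfg)
        timings["group_space"] = time.perf_counter() - t0

    if stage_idx >= 2:
        t0 = time.perf_counter()
        first_level_stage(firsts, cfg)
        timings["first_level"] = time.perf_counter() - t0
        cov = build_covariates(cohort, firsts)

    if stage_idx >= 3:
        t0 = time.perf_counter()
        second = second_level_stage(cohort, firsts, mask, cov, cfg)
        timings["second_level"] = time.perf_counter() - t0

    clin: dict[str, object] = {}
    if cfg.run_clinical and stage_idx >= 4:
        t0 = time.perf_counter()
        clin = clinical_stage(cohort, firsts, mask, cfg)
        timings["clinical"] = time.perf_counter() - t0

    result = PipelineResult(
        config=cfg,
        first_level=firsts,
        explicit_mask=mask,
        group_template=gt,
        covariates=cov,
        second_level=second,
        clinical=clin,
        timings=timings,
    )
    _write_outputs(result, cohort, outdir)
    return result


def _write_outputs(result: PipelineResult, cohort: Cohort, outdir: Path) -> None:
    cfg = result.config
    if result.explicit_mask is not None:
        result.explicit_mask.save(outdir / "explicit_mask.nii")
    if result.group_template is not None:
        result.group_template.volume.save(outdir / "group_template.nii")
    if len(result.covariates):
        result.covariates.to_csv(outdir / "covariates.csv", index=False)
    if cfg.write_intermediates:
        for sid, f in result.first_level.items():
            sdir = outdir / "first_level" / sid
            sdir.mkdir(parents=True, exist_ok=True)
            f.template.save(sdir / "template.nii")
            f.gm_prob.save(sdir / "gm_prob.nii")
            for t, j in f.jacobians.items():
                j.save(sdir / f"jacobian_t{t:g}.nii")
            for t, p in f.pseudo_group.items():
                p.save(sdir / f"pseudo_group_t{t:g}.nii")
            if f.slope is not None:
                f.slope.save(sdir / "slope.nii")
            if f.quadratic is not None:
                f.quadratic.save(sdir / "quadratic.nii")
    stats_dir = outdir / "second_level"
    stats_dir.mkdir(parents=True, exist_ok=True)
    summary = {}
    for name, res in result.second_level.items():
        if name == "posthoc":
            for yr, r in res.items():
                r.raw_t.save(stats_dir / f"posthoc_{yr}_t.nii")
                r.p.save(stats_dir / f"posthoc_{yr}_pfwe.nii")
                r.significant.save(stats_dir / f"posthoc_{yr}_sig.nii")
                summary[f"posthoc_{yr}"] = _res_summary(r)
            continue
        res.raw_t.save(stats_dir / f"{name}_t.nii")
        res.observed.save(stats_dir / f"{name}_enhanced.nii")
        res.p.save(stats_dir / f"{name}_pfwe.nii")
        res.significant.save(stats_dir / f"{name}_sig.nii")
        summary[name] = _res_summary(res)
    if result.clinical:
        table = result.clinical.get("patient_table")
        if table is not None:
            table.to_csv(outdir / "clinical_associations.csv", index=False)
        for k, v in result.clinical.items():
            if isinstance(v, tuple):
                summary[f"clinical_{k}"] = list(v)
    provenance = dict(
        package_version=__version__,
        config=cfg.to_dict(),
        cohort_seed=cohort.seed,
        n_patients=len(cohort.patients),
        n_controls=len(cohort.controls),
        balanced_set=(
            result.group_template.balanced_ids
            if result.group_template is not None
            else []
        ),
        timings=result.timings,
        results=summary,
    )
    (outdir / "provenance.json").write_text(json.dumps(provenance, indent=1))


def _res_summary(r) -> dict:
    return dict(
        n_significant=r.n_significant,
        min_p=float(np.asarray(r.p.data).min()),
        scheme=r.scheme,
        n_perm=r.n_perm,
        exhaustive=r.exhaustive,
        seed=r.seed,
    )


def load_cohort_dir(path) -> Cohort:
    """Rehydrate a cohort written by :func:`longvbm.phantoms.write_cohort`.

    Truth fields are not reloaded (the truth JSON carries rates and volumes
    only); sufficient for running the analysis pipeline.
    """
    from .phantoms import CohortTruth, PhantomSpec, SubjectTruth, AtrophyModel

    path = Path(path)
    manifest = pd.read_csv(path / "manifest.csv")
    clinical = pd.read_csv(path / "clinical.csv")
    truth_raw = json.loads((path / "truth.json").read_text())
    subjects = []
    truth = CohortTruth(spec=PhantomSpec())
    for sid, g in manifest.groupby("subject", sort=True):
        g = g.sort_values("visit")
        vols = [Volume.load(path / p) for p in g["path"]]
        lesions = [
            Volume.load(path / p) if isinstance(p, str) and p else None
            for p in g["lesion_path"]
        ]
        clin = clinical[clinical["subject"] == sid].sort_values("visit")
        series = SubjectSeries(
            subject_id=sid,
            group=g["group"].iloc[0],
            times=[float(t) for t in g["time_years"]],
            volumes=vols,
            lesion_masks=[l for l in lesions if l is not None],
            upgrade_flags=[bool(u) for u in g["upgrade_flag"]],
            clinical={
                c: clin[c].tolist()
                for c in clin.columns
                if c not in ("subject", "visit", "time_years")
            },
            age=float(g["age"].iloc[0]),
            sex=str(g["sex"].iloc[0]),
        )
        subjects.append(series)
        tr = truth_raw.get(sid, {})
        truth.subjects[sid] = SubjectTruth(
            rates={int(k): v for k, v in tr.get("rates", {}).items()},
            factors={},
            region_volumes_mm3={},
            gm_volume_mm3={float(k): v for k, v in tr.get("gm_volume_mm3", {}).items()},
            clinical_slopes=tr.get("clinical_slopes", {}),
        )
    return Cohort(
        subjects=subjects,
        truth=truth,
        spec=truth.spec,
        model=AtrophyModel(),
        seed=-1,
    )
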