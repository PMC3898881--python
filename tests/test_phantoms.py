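import numpy as np
import pytest

from longvbm.core import Volume
from longvbm.phantoms import (
    EDSS_GRID,
    AtrophyModel,
    ClinicalCoupling,
    PhantomSpec,
    make_phantom,
    simulate_cohort,
    simulate_subject_series,
    snap_to_edss_grid,
    truth_displacement,
    truth_jacobian,
    write_cohort,
)
from longvbm.within_subject import DeformationField, jacobian_determinant


class TestMakePhantom:
    def test_noiseless_intensities_equal_class_means(self, spec24_clean):
        vol, atlas = make_phantom(spec24_clean)
        means = {0: 0.0, 1: 30.0, 2: 120.0}
        for lab, mu in means.items():
            sel = atlas.data == lab
            assert sel.any()
            np.testing.assert_array_equal(vol.data[sel], mu)
        # all GM labels share the GM mean
        for lab in (3, 4, 5):
            np.testing.assert_array_equal(vol.data[atlas.data == lab], 80.0)

    def test_determinism_same_seed(self):
        spec = PhantomSpec(noise_sd=5.0, bias_amplitude=0.1, seed=42)
        v1, a1 = make_phantom(spec)
        v2, a2 = make_phantom(PhantomSpec(noise_sd=5.0, bias_amplitude=0.1, seed=42))
        np.testing.assert_array_equal(v1.data, v2.data)
        np.testing.assert_array_equal(a1.data, a2.data)

    def test_noise_sd_recovered_per_class(self):
        # oracle: sample SD of (intensity - class mean) inside each label
        spec = PhantomSpec(grid_shape=(32, 32, 32), noise_sd=5.0, seed=3)
        vol, atlas = make_phantom(spec)
        for lab, mu in ((1, 30.0), (2, 120.0), (3, 80.0)):
            resid = vol.data[atlas.data == lab] - mu
            assert abs(resid.std() - 5.0) < 0.5

    def test_degenerate_grid_rejected(self):
        with pytest.raises(ValueError, match="16"):
            PhantomSpec(grid_shape=(8, 32, 32))

    def test_every_label_has_tissue_mean(self, phantom24):
        vol, atlas, spec = phantom24
        for lab in np.unique(atlas.data):
            assert spec.mean_of_label(int(lab)) >= 0.0

    def test_labels_contiguous_from_zero(self, phantom24):
        _, atlas, _ = phantom24
        labs = np.unique(atlas.data)
        np.testing.assert_array_equal(labs, np.arange(labs.max() + 1))


class TestSubjectSeries:
    def test_zero_rates_visits_equal_baseline(self, spec24_clean):
        model = AtrophyModel()
        series, truth = simulate_subject_series(spec24_clean, model, seed=4)
        base = series.volumes[0].data
        for v in series.volumes[1:]:
            np.testing.assert_array_equal(v.data, base)
        grid = series.volumes[0]
        for t in series.times:
            u = truth_displacement(spec24_clean.geometry, truth.factors[t], grid)
            assert np.abs(u).max() == 0.0

    def test_truth_jacobian_integral_matches_volume_factor(
        self, series32_clean, spec32_clean
    ):
        # numeric oracle: finite-difference Jacobian of the synthesized
        # displacement on a fine (0.5 mm) subgrid covering the region
        series, truth = series32_clean
        geom = spec32_clean.geometry
        sph = geom.sphere(4)
        step = 0.5
        half = sph.outer_mm + 2.0
        n = int(2 * half / step)
        aff = np.diag([step, step, step, 1.0])
        aff[:3, 3] = np.asarray(sph.center_mm) - half
        fine = Volume(np.zeros((n, n, n)), aff)
        u = truth_displacement(geom, truth.factors[5.0], fine)
        fld = DeformationField(u, fine, 0.0, 0)
        jac_numeric = jacobian_determinant(fld)
        pts = fine.grid_world_coords()
        region = np.linalg.norm(pts - np.asarray(sph.center_mm), axis=-1) < sph.radius_mm
        assert abs(jac_numeric.data[region].mean() - 0.90) < 0.01
        # analytic map agrees exactly on the coarse grid region
        grid = series.volumes[0]
        _, atlas = make_phantom(spec32_clean)
        jac_analytic = truth_jacobian(geom, truth.factors[5.0], grid)
        assert abs(jac_analytic[atlas.data == 4].mean() - 0.90) < 1e-9

    def test_all_regions_all_visits_within_one_percent(
        self, series32_clean, spec32_clean
    ):
        series, truth = series32_clean
        grid = series.volumes[0]
        _, atlas = make_phantom(spec32_clean)
        for t in series.times:
            jac = truth_jacobian(spec32_clean.geometry, truth.factors[t], grid)
            for lab in (4, 5):
                region = atlas.data == lab
                expected = truth.factors[t].get(lab, 1.0)
                assert abs(jac[region].mean() - expected) < 0.01 * expected

    def test_missing_year_four_schedule(self, spec24_clean):
        series, _ = simulate_subject_series(
            spec24_clean,
            AtrophyModel(),
            visit_times=(0.0, 1.0, 2.0, 3.0, 4.0, 5.0),
            missing=(4.0,),
            seed=1,
        )
        assert series.times == [0.0, 1.0, 2.0, 3.0, 5.0]

    def test_nonpositive_volume_factor_rejected(self, spec24_clean):
        model = AtrophyModel(patient_rates={4: -0.25})
        with pytest.raises(ValueError, match="factor"):
            simulate_subject_series(
                spec24_clean, model, visit_times=(0.0, 5.0), seed=1
            )

    def test_fewer_than_two_visits_rejected(self, spec24_clean):
        with pytest.raises(ValueError, match="2 retained"):
            simulate_subject_series(
                spec24_clean,
                AtrophyModel(),
                visit_times=(0.0, 1.0),
                missing=(1.0,),
                seed=1,
            )

    def test_lesions_only_in_wm(self, spec24):
        series, _ = simulate_subject_series(
            spec24, AtrophyModel(), seed=9, n_lesions=4
        )
        _, atlas = make_phantom(spec24)
        lesions = series.lesion_masks[0].data.astype(bool)
        assert lesions.any()
        assert np.all(atlas.data[lesions] == 2)

    def test_determinism_and_seed_variation(self, spec24, atrophy_model):
        s1, t1 = simulate_subject_series(spec24, atrophy_model, seed=5)
        s2, t2 = simulate_subject_series(spec24, atrophy_model, seed=5)
        s3, t3 = simulate_subject_series(spec24, atrophy_model, seed=6)
        for a, b in zip(s1.volumes, s2.volumes):
            np.testing.assert_array_equal(a.data, b.data)
        assert any(
            not np.array_equal(a.data, b.data)
            for a, b in zip(s1.volumes, s3.volumes)
        )
        # identical truth structure when rates carry no jitter
        assert t1.rates == t3.rates
        assert t1.factors == t3.factors


class TestAtrophyModel:
    def test_rate_bounds(self):
        with pytest.raises(ValueError):
            AtrophyModel(patient_rates={4: 0.6})

    def test_control_rate_must_not_exceed_patient(self):
        with pytest.raises(ValueError):
            AtrophyModel(patient_rates={4: -0.01}, control_rates={4: -0.02})

    def test_delayed_onset(self):
        m = AtrophyModel(patient_rates={4: -0.02}, onset_years={4: 2.0})
        assert m.cumulative_factor(-0.02, 1.0, 4) == 1.0
        assert m.cumulative_factor(-0.02, 5.0, 4) == pytest.approx(1 - 0.02 * 3)


@pytest.fixture(scope="module")
def cohort():
    spec = PhantomSpec(grid_shape=(24, 24, 24), noise_sd=3.0, seed=2)
    model = AtrophyModel(patient_rates={4: -0.02}, rate_jitter_sd=0.004)
    return simulate_cohort(
        3,
        3,
        model,
        missingness_rate=0.2,
        upgrade_year=2.5,
        clinical_coupling=ClinicalCoupling(gain=10.0, noise_sd=0.05),
        seed=8,
        spec=spec,
    )


class TestCohort:

    def test_group_sizes(self, cohort):
        assert len(cohort.patients) == 3 and len(cohort.controls) == 3

    def test_every_subject_at_least_two_visits(self, cohort):
        assert all(s.n_visits >= 2 for s in cohort.subjects)

    def test_upgrade_flags_and_proportion(self, cohort):
        for s in cohort.subjects:
            expected = [t >= 2.5 for t in s.times]
            assert s.upgrade_flags == expected
            assert s.upgrade_proportion == pytest.approx(np.mean(expected))

    def test_upgrade_proportion_full_schedule(self, spec24_clean):
        # schedule {0,1,2,3,5}, upgrade between years 2 and 3 -> 2/5 of images
        cohort = simulate_cohort(
            2, 2, AtrophyModel(), missingness_rate=0.0, upgrade_year=2.5,
            seed=1, spec=spec24_clean,
        )
        for s in cohort.subjects:
            assert s.upgrade_proportion == pytest.approx(2 / 5)

    def test_upgrade_beyond_study_end(self, spec24_clean):
        cohort = simulate_cohort(
            2, 2, AtrophyModel(), missingness_rate=0.0, upgrade_year=99.0,
            seed=1, spec=spec24_clean,
        )
        assert all(not any(s.upgrade_flags) for s in cohort.subjects)

    def test_upgrade_shift_applied_to_images(self, spec24_clean):
        c0 = simulate_cohort(2, 2, AtrophyModel(), missingness_rate=0.0,
                             upgrade_year=99.0, seed=1, spec=spec24_clean)
        c1 = simulate_cohort(2, 2, AtrophyModel(), missingness_rate=0.0,
                             upgrade_year=2.5, seed=1, spec=spec24_clean,
                             upgrade_gain=1.05)
        s0, s1 = c0.subjects[0], c1.subjects[0]
        j = s1.upgrade_flags.index(True)
        ratio = s1.volumes[j].data / np.where(s0.volumes[j].data == 0, 1, s0.volumes[j].data)
        assert ratio[s0.volumes[j].data > 0].mean() == pytest.approx(1.05, rel=1e-6)

    def test_zero_coupling_gives_rate_independent_slopes(self, spec24_clean):
        cohort = simulate_cohort(
            12, 2, AtrophyModel(patient_rates={4: -0.02}, rate_jitter_sd=0.005),
            missingness_rate=0.0, clinical_coupling=ClinicalCoupling(gain=0.0, noise_sd=0.05),
            seed=3, spec=spec24_clean,
        )
        rates = [cohort.truth.subjects[s.subject_id].rates[4] for s in cohort.patients]
        slopes = [
            cohort.truth.subjects[s.subject_id].clinical_slopes["msfc"]
            for s in cohort.patients
        ]
        r = np.corrcoef(rates, slopes)[0, 1]
        assert abs(r) < 0.6  # no systematic coupling (small-n null draw)

    def test_edss_on_legal_grid(self, cohort):
        for s in cohort.subjects:
            for v in s.clinical["edss"]:
                assert np.isclose(EDSS_GRID, v).any()

    def test_lesion_load_nonnegative(self, cohort):
        for s in cohort.subjects:
            assert all(v >= 0 for v in s.clinical["t2_lesion_load_ml"])

    def test_cohort_determinism(self, spec24_clean):
        kw = dict(missingness_rate=0.2, upgrade_year=2.5, seed=4, spec=spec24_clean)
        c1 = simulate_cohort(2, 2, AtrophyModel(patient_rates={4: -0.01}), **kw)
        c2 = simulate_cohort(2, 2, AtrophyModel(patient_rates={4: -0.01}), **kw)
        for a, b in zip(c1.subjects, c2.subjects):
            assert a.times == b.times
            for va, vb in zip(a.volumes, b.volumes):
                np.testing.assert_array_equal(va.data, vb.data)


class TestEdssGrid:
    def test_grid_is_twenty_values(self):
        assert len(EDSS_GRID) == 20
        assert EDSS_GRID[0] == 0.0 and EDSS_GRID[1] == 1.0 and EDSS_GRID[-1] == 10.0

    def test_snap(self):
        np.testing.assert_array_equal(
            snap_to_edss_grid([0.2, 1.6, 9.9]), [0.0, 1.5, 10.0]
        )


def test_write_cohort_roundtrip(tmp_path, tiny_cohort):
    from longvbm.pipeline import load_cohort_dir

    out = write_cohort(tiny_cohort, tmp_path / "cohort")
    assert (out / "manifest.csv").exists()
    assert (out / "clinical.csv").exists()
    assert (out / "truth.json").exists()
    re = load_cohort_dir(out)
    assert len(re.subjects) == len(tiny_cohort.subjects)
    orig = {s.subject_id: s for s in tiny_cohort.subjects}
    for s in re.subjects:
        o = orig[s.subject_id]
        assert s.times == o.times
        assert s.group == o.group
        np.testing.assert_allclose(s.volumes[0].data, o.volumes[0].data, atol=1e-4)
        assert re.truth.subjects[s.subject_id].rates == pytest.approx(
            tiny_cohort.truth.subjects[s.subject_id].rates
        )
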