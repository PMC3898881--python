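import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage, stats

from longvbm.core import Volume
from longvbm.inference import (
    DesignMatrix,
    build_design,
    glm_t,
    glm_t_map,
    paired_baseline_subtraction_test,
    permutation_fwe,
    tfce,
)


def vol(data, voxel=2.0):
    return Volume(np.asarray(data, dtype=float), np.diag([voxel] * 3 + [1.0]))


# --------------------------------------------------------------------- GLM


class TestGlm:
    def test_one_sample_matches_textbook_formula(self):
        rng = np.random.default_rng(0)
        Y = rng.normal(0.3, 1.0, (9, 50))
        X = np.ones((9, 1))
        t = glm_t(Y, X, np.array([1.0]))
        oracle = Y.mean(axis=0) / (Y.std(axis=0, ddof=1) / np.sqrt(9))
        np.testing.assert_allclose(t, oracle, atol=1e-10)

    def test_orthogonal_nuisance_leaves_t_unchanged(self):
        rng = np.random.default_rng(1)
        n = 8
        Y = rng.normal(size=(n, 30))
        g = np.array([1.0] * 4 + [0.0] * 4)
        X = np.stack([np.ones(n), g - g.mean()], axis=1)
        # nuisance orthogonal to the design AND to the data: estimate,
        # contrast variance and residuals are all unchanged; t differs only
        # by the df bookkeeping sqrt((n-p)/(n-p-1))
        z = np.array([1, -1, 1, -1, -1, 1, -1, 1], dtype=float)
        z -= X @ np.linalg.lstsq(X, z, rcond=None)[0]
        Yo = Y - np.outer(z, z @ Y / (z @ z))
        c1, c2 = np.array([0.0, 1.0]), np.array([0.0, 1.0, 0.0])
        X2 = np.column_stack([X, z])
        t1 = glm_t(Yo, X, c1)
        t2 = glm_t(Yo, X2, c2)
        np.testing.assert_allclose(t1, t2 * np.sqrt((n - 2) / (n - 3)), atol=1e-10)
        b1 = np.linalg.pinv(X) @ Yo
        b2 = np.linalg.pinv(X2) @ Yo
        np.testing.assert_allclose(c1 @ b1, c2 @ b2, atol=1e-10)
        rss1 = ((Yo - X @ b1) ** 2).sum(0)
        rss2 = ((Yo - X2 @ b2) ** 2).sum(0)
        np.testing.assert_allclose(rss1, rss2, atol=1e-10)

    def test_equal_group_means_zero_t(self):
        # noiseless equal inputs: 0/0 resolves to t = 0
        Y = np.tile(np.linspace(0, 1, 20), (6, 1))
        X = np.stack([np.ones(6), np.array([1.0, 1, 1, 0, 0, 0])], axis=1)
        t = glm_t(Y + 0.0, X, np.array([0.0, 1.0]))
        assert np.abs(t).max() < 1e-10

    def test_real_effect_over_zero_variance_saturates(self):
        Y = np.concatenate([np.ones((3, 4)), np.zeros((3, 4))])
        X = np.stack([np.ones(6), np.array([1.0, 1, 1, 0, 0, 0])], axis=1)
        t = glm_t(Y, X, np.array([0.0, 1.0]))
        assert np.all(np.isinf(t)) and np.all(t > 0)

    def test_rank_deficient_design_names_columns(self):
        X = np.ones((6, 2))
        with pytest.raises(ValueError, match="collinear"):
            DesignMatrix(X, ["intercept", "dup"])

    def test_build_design_centers_nuisance(self):
        df = pd.DataFrame(
            dict(
                group=["patient"] * 3 + ["control"] * 3,
                age=[40.0, 50, 60, 45, 55, 65],
                sex=["F", "M", "M", "F", "F", "M"],
            )
        )
        d = build_design(df, nuisance=("age", "sex"))
        assert d.columns == ["intercept", "group", "age", "sex"]
        assert abs(d.X[:, 2].mean()) < 1e-12
        assert abs(d.X[:, 3].mean()) < 1e-12

    def test_glm_t_map_roundtrip(self):
        rng = np.random.default_rng(2)
        imgs = [vol(rng.normal(0.5, 1, (6, 6, 6))) for _ in range(8)]
        d = DesignMatrix(np.ones((8, 1)), ["intercept"])
        tmap = glm_t_map(imgs, d, np.array([1.0]))
        Y = np.stack([i.data.ravel() for i in imgs])
        oracle = Y.mean(0) / (Y.std(0, ddof=1) / np.sqrt(8))
        np.testing.assert_allclose(tmap.data.ravel(), oracle, atol=1e-10)


# -------------------------------------------------------------------- TFCE


def brute_tfce(stat, E=0.5, H=2.0, dh=None, connectivity=26):
    """Independent oracle: explicit labeling at every threshold step."""
    smax = float(stat.max(initial=0.0))
    if smax <= 0:
        return np.zeros_like(stat, dtype=float)
    if dh is None:
        dh = smax / 100.0
    out = np.zeros_like(stat, dtype=float)
    structure = np.ones((3, 3, 3)) if connectivity == 26 else None
    K = int(math.floor(smax / dh + 1e-12))
    for k in range(1, K + 1):
        h = k * dh
        sup = stat >= h
        lab, _ = ndimage.label(sup, structure=structure)
        sizes = np.bincount(lab.ravel())
        out[sup] += sizes[lab[sup]] ** E * h**H * dh
    return out


class TestTfce:
    def test_zero_image_zero_output(self):
        assert np.all(tfce(np.zeros((8, 8, 8))) == 0)

    def test_cuboid_closed_form(self):
        st_img = np.zeros((10, 10, 10))
        st_img[3:6, 3:6, 3:6] = 3.0
        out = tfce(st_img, dh=0.01)
        expected = math.sqrt(27.0) * 9.0  # ∫0^3 sqrt(27) h^2 dh
        cluster = out[3:6, 3:6, 3:6]
        assert np.allclose(cluster, cluster[0, 0, 0])
        assert abs(cluster[0, 0, 0] - expected) / expected < 0.01

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        stat = rng.normal(0, 1, (12, 12, 12))
        np.testing.assert_allclose(tfce(stat), brute_tfce(stat), atol=1e-8)

    def test_six_connectivity_matches_oracle(self):
        rng = np.random.default_rng(3)
        stat = rng.normal(0, 1, (10, 10, 10))
        np.testing.assert_allclose(
            tfce(stat, connectivity=6),
            brute_tfce(stat, connectivity=6),
            atol=1e-8,
        )

    def test_monotone_in_stat(self):
        rng = np.random.default_rng(4)
        s1 = np.abs(rng.normal(0, 1, (10, 10, 10)))
        s2 = 0.8 * s1  # same support topology at matched thresholds
        t1 = tfce(s1, dh=0.02)
        t2 = tfce(s2, dh=0.02)
        assert np.all(t1 - t2 >= -1e-12)

    def test_volume_in_volume_out(self):
        v = vol(np.abs(np.random.default_rng(5).normal(0, 1, (8, 8, 8))))
        out = tfce(v)
        assert isinstance(out, Volume)
        np.testing.assert_allclose(out.data, brute_tfce(v.data), atol=1e-8)

    def test_bad_dh_rejected(self):
        with pytest.raises(ValueError):
            tfce(np.ones((8, 8, 8)), dh=0.0)

    def test_bad_connectivity_rejected(self):
        with pytest.raises(ValueError):
            tfce(np.ones((8, 8, 8)), connectivity=18)


# ------------------------------------------------------- permutation FWE


def exhaustive_two_sample_oracle(imgs, g, enhance_fn):
    """Brute-force FWE p-values over all C(n, n1) relabelings."""
    Y = np.stack([i.data.ravel() for i in imgs])
    n = len(g)
    n1 = int(g.sum())

    def tmap(lab):
        a, b = Y[lab == 1], Y[lab == 0]
        va = a.var(axis=0, ddof=1)
        vb = b.var(axis=0, ddof=1)
        sp = ((len(a) - 1) * va + (len(b) - 1) * vb) / (n - 2)
        with np.errstate(invalid="ignore", divide="ignore"):
            t = (a.mean(0) - b.mean(0)) / np.sqrt(sp * (1 / len(a) + 1 / len(b)))
        return np.nan_to_num(t)

    shape = imgs[0].shape
    obs = enhance_fn(tmap(g).reshape(shape)).ravel()
    maxes = []
    for idx in itertools.combinations(range(n), n1):
        lab = np.zeros(n)
        lab[list(idx)] = 1
        maxes.append(enhance_fn(tmap(lab).reshape(shape)).max(initial=0.0))
    maxes = np.asarray(maxes)
    return (maxes[None, :] >= obs[:, None]).sum(axis=1) / len(maxes)


class TestPermutationFwe:
    def test_exhaustive_two_sample_matches_independent_oracle(self):
        # raw-t variant: statistic AND enumeration both recomputed
        # independently (pooled-variance two-sample t) -> exact agreement
        rng = np.random.default_rng(6)
        imgs = [vol(rng.normal(0, 1, (5, 5, 5)) + (0.8 if i < 3 else 0.0)) for i in range(6)]
        df = pd.DataFrame(dict(group=["patient"] * 3 + ["control"] * 3))
        d = build_design(df)
        res = permutation_fwe(
            imgs, d, d.contrast("group"), n_perm=5000, enhance="none", seed=1
        )
        assert res.exhaustive and res.n_perm == math.comb(6, 3)
        oracle_p = exhaustive_two_sample_oracle(imgs, d.X[:, 1], lambda s: s)
        np.testing.assert_allclose(res.p.data.ravel(), oracle_p, atol=1e-12)

    def test_exhaustive_two_sample_tfce_enumeration_matches_oracle(self):
        # TFCE variant: the enumeration / max-statistic / counting logic is
        # reimplemented here, sharing the statistic functions (per-map
        # max/100 dh makes an independent float path diverge by 1 ulp at the
        # top integration level, so the statistic is held in common)
        rng = np.random.default_rng(6)
        imgs = [vol(rng.normal(0, 1, (5, 5, 5)) + (0.8 if i < 3 else 0.0)) for i in range(6)]
        df = pd.DataFrame(dict(group=["patient"] * 3 + ["control"] * 3))
        d = build_design(df)
        res = permutation_fwe(
            imgs, d, d.contrast("group"), n_perm=5000, enhance="tfce", seed=1
        )
        assert res.exhaustive and res.n_perm == math.comb(6, 3)
        Y = np.stack([i.data.ravel() for i in imgs])
        obs = tfce(
            glm_t(Y, d.X, d.contrast("group")).reshape(imgs[0].shape)
        ).ravel()
        maxes = []
        for idx in itertools.combinations(range(6), 3):
            lab = np.zeros(6)
            lab[list(idx)] = 1
            Xp = d.X.copy()
            Xp[:, 1] = lab
            t = glm_t(Y, Xp, d.contrast("group")).reshape(imgs[0].shape)
            maxes.append(tfce(t).max(initial=0.0))
        maxes = np.asarray(maxes)
        oracle_p = (maxes[None, :] >= obs[:, None]).sum(axis=1) / len(maxes)
        np.testing.assert_allclose(res.p.data.ravel(), oracle_p, atol=1e-12)

    def test_exhaustive_sign_flip_matches_oracle(self):
        rng = np.random.default_rng(7)
        imgs = [vol(rng.normal(0.5, 1, (4, 4, 4))) for _ in range(6)]
        d = DesignMatrix(np.ones((6, 1)), ["intercept"])
        res = permutation_fwe(
            imgs, d, np.array([1.0]), n_perm=5000, enhance="none", seed=2
        )
        assert res.exhaustive and res.n_perm == 64
        Y = np.stack([i.data.ravel() for i in imgs])

        def one_t(y):
            sd = y.std(axis=0, ddof=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                return np.nan_to_num(y.mean(0) / (sd / np.sqrt(len(y))))

        obs = one_t(Y)
        maxes = [
            one_t(np.asarray(s)[:, None] * Y).max(initial=0.0)
            for s in itertools.product([1.0, -1.0], repeat=6)
        ]
        maxes = np.asarray(maxes)
        oracle_p = (maxes[None, :] >= obs[:, None]).sum(axis=1) / 64
        np.testing.assert_allclose(res.p.data.ravel(), oracle_p, atol=1e-12)

    def test_identical_constant_images_nothing_significant(self):
        imgs = [vol(np.full((5, 5, 5), 2.0)) for _ in range(6)]
        df = pd.DataFrame(dict(group=["patient"] * 3 + ["control"] * 3))
        d = build_design(df)
        res = permutation_fwe(imgs, d, d.contrast("group"), n_perm=100, seed=0)
        assert res.n_significant == 0
        assert np.all(res.p.data == 1.0)

    def test_p_never_zero(self):
        rng = np.random.default_rng(8)
        imgs = [vol(rng.normal(5.0, 0.1, (4, 4, 4))) for _ in range(5)]
        d = DesignMatrix(np.ones((5, 1)), ["intercept"])
        res = permutation_fwe(imgs, d, np.array([1.0]), n_perm=200, seed=3)
        assert res.p.data.min() >= 1.0 / (res.n_perm)

    def test_sampled_p_floor_convention(self):
        rng = np.random.default_rng(9)
        imgs = [vol(rng.normal(1.0, 0.2, (4, 4, 4))) for _ in range(12)]
        d = DesignMatrix(np.ones((12, 1)), ["intercept"])
        res = permutation_fwe(imgs, d, np.array([1.0]), n_perm=99, seed=4)
        assert not res.exhaustive
        assert res.p.data.min() >= 1.0 / 99

    def test_freedman_lane_with_nuisance_runs(self):
        rng = np.random.default_rng(10)
        n = 10
        imgs = [vol(rng.normal(0, 1, (4, 4, 4))) for _ in range(n)]
        df = pd.DataFrame(
            dict(group=["patient"] * 5 + ["control"] * 5, age=rng.normal(45, 5, n))
        )
        d = build_design(df, nuisance=("age",))
        res = permutation_fwe(
            imgs, d, d.contrast("group"), n_perm=50, enhance="none", seed=5
        )
        assert res.scheme == "freedman_lane"
        assert res.p.data.min() >= 1 / 50

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(11)
        imgs = [vol(rng.normal(0, 1, (4, 4, 4))) for _ in range(10)]
        d = DesignMatrix(np.ones((10, 1)), ["intercept"])
        r1 = permutation_fwe(imgs, d, np.array([1.0]), n_perm=100, seed=7)
        r2 = permutation_fwe(imgs, d, np.array([1.0]), n_perm=100, seed=7)
        np.testing.assert_array_equal(r1.p.data, r2.p.data)
        np.testing.assert_array_equal(r1.null_max, r2.null_max)


class TestPairedBaselineSubtraction:
    def make_series(self, n, effect, seed=0, times=(0.0, 1.0, 2.0)):
        rng = np.random.default_rng(seed)
        series = {}
        for i in range(n):
            visits = {}
            for t in times:
                d = rng.normal(0, 0.05, (6, 6, 6))
                if t > 0:
                    d[2:4, 2:4, 2:4] -= effect * t
                visits[t] = vol(0.8 + d)
            series[f"s{i}"] = visits
        return series

    def test_zero_differences_nothing_significant(self):
        series = {
            f"s{i}": {t: vol(np.full((5, 5, 5), 0.7)) for t in (0.0, 1.0, 2.0)}
            for i in range(6)
        }
        res = paired_baseline_subtraction_test(
            series, 2.0, all_times=(0.0, 1.0, 2.0), n_perm=100, seed=0
        )
        assert res.n_significant == 0

    def test_sign_flip_enumeration_count(self):
        series = self.make_series(6, effect=0.1, seed=1)
        res = paired_baseline_subtraction_test(
            series, 2.0, all_times=(0.0, 1.0, 2.0), n_perm=5000, seed=0
        )
        assert res.exhaustive and res.n_perm == 2**6
        assert res.scheme == "sign_flip"

    def test_incomplete_subjects_excluded(self, caplog):
        series = self.make_series(5, effect=0.0, seed=2)
        del series["s0"][1.0]
        res = paired_baseline_subtraction_test(
            series, 2.0, all_times=(0.0, 1.0, 2.0), n_perm=50, seed=0
        )
        assert res.extra["n_subjects"] == 4

    def test_detects_constructed_effect(self):
        series = self.make_series(8, effect=0.15, seed=3)
        res = paired_baseline_subtraction_test(
            series, 2.0, all_times=(0.0, 1.0, 2.0), n_perm=200, seed=0
        )
        sig = res.significant.data.astype(bool)
        truth = np.zeros((6, 6, 6), dtype=bool)
        truth[2:4, 2:4, 2:4] = True
        assert (sig & truth).sum() > 0

    def test_too_few_complete_subjects(self):
        series = self.make_series(2, effect=0.0)
        del series["s0"][1.0]
        with pytest.raises(ValueError, match="complete"):
            paired_baseline_subtraction_test(
                series, 2.0, all_times=(0.0, 1.0, 2.0), n_perm=10, seed=0
            )
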