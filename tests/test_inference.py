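"""Group-level inference: cluster permutation, t tests, ANOVA, Bayes
factors, circular statistics; cross-checks against pingouin."""

import numpy as np
import pingouin as pg
import pytest
from scipy import stats

from gazemem import inference


class TestClusterPermutation:
    def test_constant_effect_floor_p(self, rng):
        data = 1.0 + 0.01 * rng.normal(size=(12, 60))
        res = inference.cluster_permutation(data, n_perm=200, seed=0)
        assert len(res.clusters) == 1
        c = res.clusters[0]
        assert c.p_cluster == pytest.approx(1 / 201)
        assert c.start_ms == 0 and c.end_ms == 59

    def test_sign_flip_symmetry(self, rng):
        data = rng.normal(size=(10, 80)) + 0.4
        r1 = inference.cluster_permutation(data, n_perm=300, seed=5)
        r2 = inference.cluster_permutation(-data, n_perm=300, seed=5)
        s1 = sorted(round(c.sum_t, 9) for c in r1.clusters)
        s2 = sorted(round(-c.sum_t, 9) for c in r2.clusters)
        assert s1 == s2
        assert np.allclose(r1.null_max, r2.null_max)

    def test_seed_reproducible(self, rng):
        data = rng.normal(size=(8, 50))
        a = inference.cluster_permutation(data, n_perm=200, seed=3)
        b = inference.cluster_permutation(data, n_perm=200, seed=3)
        assert np.array_equal(a.null_max, b.null_max)

    def test_participant_order_invariant(self, rng):
        data = rng.normal(size=(9, 40)) + 0.3
        a = inference.cluster_permutation(data, n_perm=150, seed=1)
        b = inference.cluster_permutation(data[::-1], n_perm=150, seed=1)
        assert [round(c.sum_t, 9) for c in a.clusters] \
            == [round(c.sum_t, 9) for c in b.clusters]

    def test_type_i_error_quick(self, rng):
        """Cheap null calibration: family-wise false-positive rate near 5%."""
        hits = 0
        n_rep = 150
        for _ in range(n_rep):
            data = rng.normal(size=(15, 80))
            res = inference.cluster_permutation(data, n_perm=300, seed=int(rng.integers(2**31)))
            hits += res.min_p < 0.05
        rate = hits / n_rep
        assert 0.0 <= rate <= 0.12  # 3-sigma band around 0.05 at n=150

    def test_clusters_are_maximal_runs(self, rng):
        data = rng.normal(0, 0.1, size=(10, 30))
        data[:, 10:15] += 2.0
        res = inference.cluster_permutation(data, n_perm=100, seed=0)
        big = max(res.clusters, key=lambda c: abs(c.sum_t))
        assert big.start_ms == 10 and big.end_ms == 14


class TestOneSample:
    def test_zero_values(self):
        res = inference.one_sample_test([0.0, 0.0, 1e-14, -1e-14])
        assert res.t == pytest.approx(0.0, abs=1e-6)
        assert res.p > 0.99

    def test_against_scipy_and_pingouin(self, rng):
        x = rng.normal(0.3, 1.0, 25)
        mine = inference.one_sample_test(x)
        ref = pg.ttest(x, 0.0)
        assert mine.t == pytest.approx(float(ref["T"].iloc[0]))
        assert mine.p == pytest.approx(float(ref["p_val"].iloc[0]))
        assert mine.cohens_d == pytest.approx(float(ref["cohen_d"].iloc[0]), abs=1e-9)
        lo, hi = ref["CI95"].iloc[0]
        assert mine.ci95[0] == pytest.approx(lo, abs=5e-3)
        assert mine.ci95[1] == pytest.approx(hi, abs=5e-3)

    def test_one_tailed(self, rng):
        x = rng.normal(0.5, 1.0, 20)
        two = inference.one_sample_test(x)
        one = inference.one_sample_test(x, tail="greater")
        assert one.p == pytest.approx(two.p / 2 if two.t > 0 else 1 - two.p / 2)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            inference.one_sample_test([1.0, 1.0, 1.0])


class TestRmAnova:
    def test_identical_cells_zero_f(self):
        cells = np.ones((8, 2, 2))
        out = inference.rm_anova_2x2(cells)
        assert all(v["F"] == 0 for v in out.values())

    def test_f_equals_squared_paired_t(self, rng):
        cells = rng.normal(size=(15, 2, 2))
        out = inference.rm_anova_2x2(cells)
        contrast = cells[:, 0, :].mean(axis=1) - cells[:, 1, :].mean(axis=1)
        t = stats.ttest_1samp(contrast, 0.0)
        assert out["A"]["F"] == pytest.approx(t.statistic ** 2)
        assert out["A"]["p"] == pytest.approx(t.pvalue)

    def test_against_pingouin(self, rng):
        import pandas as pd
        n = 12
        cells = rng.normal(size=(n, 2, 2)) + np.array([[0.5, 0], [0, 0]])
        out = inference.rm_anova_2x2(cells)
        long = pd.DataFrame([
            {"subj": i, "A": a, "B": b, "y": cells[i, a, b]}
            for i in range(n) for a in (0, 1) for b in (0, 1)])
        ref = pg.rm_anova(data=long, dv="y", within=["A", "B"], subject="subj")
        for name, row in (("A", 0), ("B", 1), ("AxB", 2)):
            assert out[name]["F"] == pytest.approx(float(ref["F"].iloc[row]), rel=1e-6)
            assert out[name]["p"] == pytest.approx(float(ref["p_unc"].iloc[row]), rel=1e-6)

    def test_pure_row_effect(self, rng):
        cells = rng.normal(0, 0.1, size=(20, 2, 2))
        cells[:, 0, :] += 1.0
        out = inference.rm_anova_2x2(cells)
        assert out["A"]["p"] < 1e-6
        assert out["B"]["p"] > 0.01 or out["B"]["F"] < out["A"]["F"] / 10


class TestBayesFactor:
    def test_two_sided_matches_pingouin(self):
        for t, n in ((2.5, 20), (0.3, 15), (4.0, 30)):
            mine = 1.0 / inference.jzs_bf01(t, n, tail="two_sided")
            ref = float(pg.bayesfactor_ttest(t, n))
            assert mine == pytest.approx(ref, rel=1e-3)

    def test_strong_effect_gives_small_bf01(self):
        assert np.log10(inference.jzs_bf01(6.0, 25, tail="greater")) < -1.1

    def test_null_large_n_supports_h0(self):
        assert np.log10(inference.jzs_bf01(0.0, 300, tail="greater")) > 0.5

    def test_timecourse_smoothing_zero_is_identity(self, rng):
        data = rng.normal(0.8, 0.5, size=(10, 6))
        bf0 = inference.bf01_timecourse(data, smoothing_ms=0.0, dt_ms=1.0)
        direct = []
        for j in range(6):
            col = data[:, j]
            tval = col.mean() / (col.std(ddof=1) / np.sqrt(10))
            direct.append(np.log10(inference.jzs_bf01(tval, 10)))
        assert np.allclose(bf0, direct)


class TestCircularStats:
    def test_rayleigh_identical_angles(self):
        z, p = inference.rayleigh_test(np.full(100, 37.0))
        assert z == pytest.approx(100.0)
        assert p < 1e-10

    def test_rayleigh_balanced_pairs_cancel(self):
        angles = np.concatenate([np.zeros(50), np.full(50, 180.0)])
        z, _ = inference.rayleigh_test(angles)
        assert z == pytest.approx(0.0, abs=1e-20)

    def test_rayleigh_matches_pingouin(self, rng):
        a = rng.uniform(0, 360, 200)
        z, p = inference.rayleigh_test(a)
        z_ref, p_ref = pg.circ_rayleigh(np.deg2rad(a))
        assert z == pytest.approx(z_ref)
        assert p == pytest.approx(p_ref, rel=1e-6)

    def test_circcorr_identity_and_rotation(self, rng):
        a = rng.uniform(0, 360, 50)
        r, _ = inference.circular_correlation(a, a)
        assert r == pytest.approx(1.0)
        r2, _ = inference.circular_correlation(a, (a + 73.0) % 360)
        assert r2 == pytest.approx(1.0)

    def test_circcorr_matches_pingouin(self, rng):
        a = rng.uniform(0, 360, 80)
        b = (a + rng.normal(0, 40, 80)) % 360
        r, _ = inference.circular_correlation(a, b)
        r_ref = pg.circ_corrcc(np.deg2rad(a), np.deg2rad(b))
        assert r == pytest.approx(float(np.atleast_1d(r_ref)[0]), abs=1e-9)

    def test_circcorr_independent_near_zero(self, rng):
        rs = [inference.circular_correlation(rng.uniform(0, 360, 100),
                                             rng.uniform(0, 360, 100))[0]
              for _ in range(30)]
        assert abs(np.mean(rs)) < 3 * np.std(rs, ddof=1) / np.sqrt(30)

    def test_circcorr_permutation_p(self, rng):
        a = rng.uniform(0, 360, 60)
        b = (a + rng.normal(0, 20, 60)) % 360
        r, p = inference.circular_correlation(a, b, n_perm=200, seed=0)
        assert r > 0.5 and p < 0.05


class TestGaussianSmooth:
    def test_zero_kernel_identity(self, rng):
        x = rng.normal(size=(3, 50))
        assert np.array_equal(inference.gaussian_smooth(x, 0.0, 2.0), x)

    def test_constant_preserved(self):
        x = np.full((2, 40), 3.7)
        out = inference.gaussian_smooth(x, 20.0, 2.0)
        assert np.allclose(out, 3.7)

    def test_white_noise_variance_reduction(self, rng):
        """Variance of smoothed white noise shrinks by ~1/(2 sigma sqrt(pi))."""
        sigma_samples = 5.0
        x = rng.normal(size=(200, 2000))
        out = inference.gaussian_smooth(x, sigma_samples, 1.0)
        factor = out[:, 100:-100].var() / x.var()
        expected = 1.0 / (2 * sigma_samples * np.sqrt(np.pi))
        assert factor == pytest.approx(expected, rel=0.1)

    def test_nan_handling_renormalizes(self):
        x = np.ones((1, 30))
        x[0, 10] = np.nan
        out = inference.gaussian_smooth(x, 3.0, 1.0)
        assert np.allclose(out[0, ~np.isnan(out[0])], 1.0)
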