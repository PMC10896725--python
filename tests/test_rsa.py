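"""Single-trial RSA: leave-one-out averages, encoding, within/between,
binning, bias contrasts; equivalence to a from-scratch reference."""

import numpy as np
import pytest
from scipy.stats import pearsonr

from gazemem import geometry, rsa
from conftest import make_epoch


def naive_single_trial_rsa(xy, valid, ori_idx, model_rdm, n_orient=16,
                           min_entries=rsa.MIN_RDV_ENTRIES):
    """Independent reference: rebuild hold-out averages from scratch per
    trial and correlate with scipy."""
    n, T, _ = xy.shape
    out = np.full((n, T), np.nan)
    for i in range(n):
        avgs = rsa.loo_orientation_averages(xy, valid, ori_idx, i, n_orient)
        for t in range(T):
            if not valid[i, t]:
                continue
            d = np.linalg.norm(xy[i, t] - avgs[:, t, :], axis=-1)
            ok = ~np.isnan(d)
            if ok.sum() < min_entries:
                continue
            mv = model_rdm[ori_idx[i]][ok]
            if np.ptp(d[ok]) == 0 or np.ptp(mv) == 0:
                continue
            out[i, t] = pearsonr(d[ok], mv)[0]
    return out


@pytest.fixture(scope="module")
def fixture_epoch(tmp_path_factory):
    """Small fixture: 6 orientations of interest over 24 trials, 5 time
    points, with a couple of invalid samples."""
    rng = np.random.default_rng(99)
    n, T = 24, 5
    ori_idx = np.tile(np.arange(16), 2)[:n]
    rng.shuffle(ori_idx)
    xy = rng.normal(size=(n, T, 2))
    valid = np.ones((n, T), bool)
    valid[0, 2] = False
    valid[5, :] = False
    return make_epoch(xy, valid=valid), ori_idx


class TestLooAverages:
    def test_two_trials_holding_one_out(self, rng):
        xy = rng.normal(size=(2, 3, 2))
        ori = np.array([4, 4])
        avgs = rsa.loo_orientation_averages(xy, np.ones((2, 3), bool), ori, 0)
        assert np.allclose(avgs[4], xy[1])

    def test_held_out_trial_does_not_influence(self, rng):
        xy = rng.normal(size=(6, 4, 2))
        ori = np.array([0, 0, 1, 1, 2, 2])
        v = np.ones((6, 4), bool)
        a1 = rsa.loo_orientation_averages(xy, v, ori, 0)
        xy2 = xy.copy()
        xy2[0] += 100.0
        a2 = rsa.loo_orientation_averages(xy2, v, ori, 0)
        assert np.allclose(a1[~np.isnan(a1)], a2[~np.isnan(a2)])

    def test_empty_cell_is_nan(self, rng):
        xy = rng.normal(size=(2, 3, 2))
        avgs = rsa.loo_orientation_averages(xy, np.ones((2, 3), bool),
                                            np.array([0, 1]), 0)
        assert np.isnan(avgs[0]).all()      # only trial 0 had orientation 0
        assert not np.isnan(avgs[1]).any()


class TestOracleEquivalence:
    def test_matches_naive_reference(self, fixture_epoch):
        ep, ori_idx = fixture_epoch
        model = geometry.blend_geometry(0.0)
        fast = rsa.single_trial_encoding(ep, ori_idx, model)
        slow = naive_single_trial_rsa(ep.xy, ep.valid, ori_idx, model.rdm)
        assert np.isnan(fast).sum() == np.isnan(slow).sum()
        ok = ~np.isnan(fast)
        assert np.abs(fast[ok] - slow[ok]).max() < 1e-10

    def test_trial_mean_equals_conventional_timecourse(self, fixture_epoch):
        ep, ori_idx = fixture_epoch
        tc = rsa.encoding_timecourse(ep, ori_idx)
        per_trial = rsa.single_trial_encoding(ep, ori_idx)
        assert np.allclose(tc, rsa.nanmean(per_trial, axis=0), equal_nan=True)


class TestSingleTrialEncoding:
    def test_perfect_circle_gives_r_one(self):
        """Gaze exactly on the generative circle with averages on the circle
        yields r = 1 (RDV proportional to the model RDV)."""
        oset = geometry.build_orientation_set()
        ang = np.deg2rad(oset.angles)
        circle = np.column_stack([np.cos(ang), np.sin(ang)])
        xy = np.repeat(circle[None, :, :], 3, axis=0).reshape(48, 1, 2)
        ori_idx = np.tile(np.arange(16), 3)
        r = rsa.single_trial_encoding(make_epoch(xy), ori_idx)
        assert np.allclose(r, 1.0, atol=1e-9)

    def test_label_shuffle_destroys_encoding(self, medium_dataset, rng):
        ep = medium_dataset.epochs[1]
        idx = rng.permutation(medium_dataset.trials["ori_idx_1"].to_numpy())
        r = rsa.single_trial_encoding(ep, idx)
        grand = rsa.nanmean(r)
        sem = np.nanstd(rsa.nanmean(r, axis=1), ddof=1) / np.sqrt(r.shape[0])
        assert abs(grand) < 3 * sem

    def test_rotation_consistency(self, rng):
        """Rotating all gaze positions and the model geometry together by a
        multiple of the grid step leaves encoding unchanged."""
        n, T = 32, 3
        ori_idx = rng.integers(0, 16, n)
        xy = rng.normal(size=(n, T, 2))
        r1 = rsa.single_trial_encoding(make_epoch(xy), ori_idx)
        # rotate data by 90° and relabel orientations by +4 steps
        rot = np.array([[0.0, -1.0], [1.0, 0.0]])
        r2 = rsa.single_trial_encoding(make_epoch(xy @ rot.T), (ori_idx + 4) % 16)
        assert np.allclose(r1, r2, atol=1e-10, equal_nan=True)


class TestWithinBetween:
    def test_exchangeable_objects_no_difference(self, rng):
        """Object-agnostic gaze: within - between differs from 0 only by
        sampling noise."""
        n, T = 240, 4
        ori_idx = rng.integers(0, 16, n)
        objects = rng.integers(0, 3, n)
        ang = np.deg2rad(11.25 + 22.5 * ori_idx)
        xy = np.stack([np.cos(ang), np.sin(ang)], axis=-1)[:, None, :] \
            + rng.normal(0, 0.5, (n, T, 2))
        w, b = rsa.within_between_encoding(make_epoch(xy), ori_idx, objects)
        diff = rsa.nanmean(w, axis=1) - rsa.nanmean(b, axis=1)
        sem = np.nanstd(diff, ddof=1) / np.sqrt(len(diff))
        assert abs(np.nanmean(diff)) < 3 * sem

    def test_object_phases_make_within_exceed_between(self, rng):
        n, T = 240, 2
        ori_idx = rng.integers(0, 16, n)
        objects = rng.integers(0, 3, n)
        phases = np.array([0.0, 120.0, 240.0])[objects]
        ang = np.deg2rad(11.25 + 22.5 * ori_idx + phases)
        xy = np.stack([np.cos(ang), np.sin(ang)], axis=-1)[:, None, :] \
            + rng.normal(0, 0.3, (n, T, 2))
        w, b = rsa.within_between_encoding(make_epoch(xy), ori_idx, objects)
        assert rsa.nanmean(w) > rsa.nanmean(b) + 0.2


class TestBinning:
    def test_equal_count_partition(self, rng):
        enc = rng.normal(size=(103, 20))
        prof = rsa.bin_by_encoding_strength(enc, enc, np.arange(20.0) * 50,
                                            window=(0, 950), n_bins=8)
        sizes = prof["n_trials"].to_numpy()
        assert sizes.sum() == 103 and sizes.max() - sizes.min() <= 1

    def test_sorting_is_monotone_in_sort_variable(self, rng):
        enc = rng.normal(size=(80, 10))
        prof = rsa.bin_by_encoding_strength(enc, enc, np.arange(10.0) * 100,
                                            window=(0, 900), n_bins=4)
        assert prof["mean_sort_encoding"].is_monotonic_increasing

    def test_independent_encodings_flat_slope(self, rng):
        slopes = []
        for _ in range(40):
            a = rng.normal(size=(64, 8))
            b = rng.normal(size=(64, 8))
            prof = rsa.bin_by_encoding_strength(a, b, np.arange(8.0) * 100,
                                                window=(0, 700), n_bins=4)
            slopes.append(rsa.bin_profile_slope(prof))
        m, s = np.mean(slopes), np.std(slopes, ddof=1) / np.sqrt(len(slopes))
        assert abs(m) < 3 * s

    def test_fewer_trials_than_bins_raises(self, rng):
        with pytest.raises(ValueError):
            rsa.bin_by_encoding_strength(rng.normal(size=(3, 5)),
                                         rng.normal(size=(3, 5)),
                                         np.arange(5.0), window=(0, 4), n_bins=8)


class TestBiasContrast:
    def _epoch_on_geometry(self, B, rng, n=96, noise=0.05):
        oset = geometry.build_orientation_set()
        g = geometry.blend_geometry(B)
        ori_idx = rng.integers(0, 16, n)
        xy = g.points[ori_idx][:, None, :] + rng.normal(0, noise, (n, 2, 2))
        return make_epoch(xy), ori_idx

    def test_unbiased_data_no_contrast(self, rng):
        ep, idx = self._epoch_on_geometry(0.0, rng, noise=0.3)
        out = rsa.bias_model_contrast(ep, idx)
        c = rsa.nanmean(out["contrast"], axis=1)
        sem = np.nanstd(c, ddof=1) / np.sqrt(len(c))
        assert abs(np.nanmean(c)) < 3.5 * sem

    def test_repulsion_geometry_prefers_repulsion_model(self, rng):
        ep, idx = self._epoch_on_geometry(1.0, rng, noise=0.02)
        out = rsa.bias_model_contrast(ep, idx)
        assert rsa.nanmean(out["repulsion"]) > 0.97
        assert rsa.nanmean(out["repulsion"]) > rsa.nanmean(out["circle"])
        assert rsa.nanmean(out["contrast"]) > 0.1

    def test_window_mean_present(self, rng):
        ep, idx = self._epoch_on_geometry(0.5, rng)
        out = rsa.bias_model_contrast(ep, idx, last_ms=(0.0, 10.0))
        assert out["contrast_mean"].shape == (96,)


class TestSummaries:
    def test_condition_partition_identity(self, rng):
        enc = rng.normal(size=(40, 6))
        mask = rng.random(40) < 0.5
        full = rsa.condition_timecourse(enc, np.ones(40, bool))
        parts = (rsa.condition_timecourse(enc, mask) * mask.sum()
                 + rsa.condition_timecourse(enc, ~mask) * (~mask).sum()) / 40
        assert np.allclose(full, parts)

    def test_empty_condition_raises(self, rng):
        with pytest.raises(ValueError):
            rsa.condition_timecourse(rng.normal(size=(4, 3)), np.zeros(4, bool))

    def test_mnemonic_slope_exact_linear(self):
        assert rsa.mnemonic_distance_summary(np.array([4.0, 3.0, 2.0, 1.0]))[0] \
            == pytest.approx(-1.0)
        assert rsa.mnemonic_distance_summary(np.array([2.0, 2.0, 2.0, 2.0]))[0] \
            == pytest.approx(0.0)
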