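"""Morlet band power, cluster permutation statistics, and source-map ops."""

import numpy as np
import pytest

from pursuitmon.timefreq import (
    EpochSet,
    SourceGrid,
    baseline_correct,
    channel_adjacency,
    cluster_permutation_test,
    dbscan_voxel_clusters,
    morlet_power,
    normalized_contrast,
    segment_conditions,
    TFR,
)


def _epochs(data, montage, fs=250.0, t0=0.0):
    times = t0 + np.arange(data.shape[-1]) / fs
    return EpochSet(data=data, times_s=times, ch_pos=montage[: data.shape[1]],
                    sampling_rate=fs)


class TestMorletPower:
    def test_sinusoid_peak_frequency_and_amplitude_square_law(self, montage16):
        fs = 250.0
        t = np.arange(int(3 * fs)) / fs
        for amp, store in ((1.0, {}), (2.0, {})):
            sig = amp * np.sin(2 * np.pi * 10 * t)
            data = np.tile(sig, (2, 3, 1))
            tfr = morlet_power(_epochs(data, montage16), "alpha")
            store["peak"] = tfr.freqs[np.argmax(tfr.power.mean((0, 1, 3)))]
            store["power"] = tfr.power.mean()
            if amp == 1.0:
                p1 = store["power"]
                assert store["peak"] == 10.0
            else:
                assert store["power"] / p1 == pytest.approx(4.0, rel=0.01)

    def test_zero_signal_zero_power(self, montage16):
        data = np.zeros((1, 2, 500))
        tfr = morlet_power(_epochs(data, montage16), "theta")
        assert np.allclose(tfr.power, 0.0)

    def test_white_noise_roughly_flat_band(self, montage16, rng):
        data = rng.standard_normal((20, 4, 1000))
        tfr = morlet_power(_epochs(data, montage16), "alpha")
        per_freq = tfr.power.mean(axis=(0, 1, 3))
        assert np.ptp(per_freq) / per_freq.mean() < 0.5

    def test_epoch_too_short_rejected(self, montage16):
        data = np.zeros((1, 2, 100))  # < 5 cycles at 4 Hz (313 samples)
        with pytest.raises(ValueError):
            morlet_power(_epochs(data, montage16), "theta")


class TestBaselineCorrect:
    def _tfr(self, power, fs=250.0, t0=-1.0):
        times = t0 + np.arange(power.shape[-1]) / fs
        return TFR(power=power, freqs=np.arange(8, 13.0), times_s=times,
                   band="alpha")

    def test_stationary_signal_is_zero_db(self):
        power = np.full((2, 3, 5, 500), 7.0)
        out = baseline_correct(self._tfr(power))
        np.testing.assert_allclose(out.power, 0.0, atol=1e-12)

    def test_power_doubling_is_3db(self):
        power = np.ones((1, 1, 5, 500))
        power[..., 250:] = 2.0  # doubling after t=0
        out = baseline_correct(self._tfr(power))
        np.testing.assert_allclose(out.power[..., 250:], 10 * np.log10(2),
                                   atol=1e-12)

    def test_zero_baseline_rejected(self):
        power = np.zeros((1, 1, 5, 500))
        power[..., 250:] = 1.0
        with pytest.raises(ValueError):
            baseline_correct(self._tfr(power))

    def test_window_outside_epoch_rejected(self):
        power = np.ones((1, 1, 5, 100))
        with pytest.raises(ValueError):
            baseline_correct(self._tfr(power, t0=0.0), window_s=(-0.75, -0.5))


class TestSegmentConditions:
    def test_task1_first_interval_windows_500ms(self):
        times = np.arange(0, 12, 1 / 250)
        win = segment_conditions(times, 1,
                                 {"random1": 0.5, "constant": 4.5},
                                 interval="first")
        for a, b in win.values():
            assert b - a == pytest.approx(0.5)

    def test_task1_second_interval_windows_2500ms(self):
        times = np.arange(0, 12, 1 / 250)
        win = segment_conditions(times, 1,
                                 {"random1": 0.5, "constant": 4.5},
                                 interval="second")
        assert win["random"] == pytest.approx((1.0, 3.5))
        assert win["constant"] == pytest.approx((4.5, 7.0))
        for a, b in win.values():
            assert b - a == pytest.approx(2.5)

    def test_task2_alternating_2s_starting_visible(self):
        times = np.arange(0, 12, 1 / 250)
        win = segment_conditions(times, 2, trial_duration_s=12.0)
        assert win["visible"][0] == (0.0, 2.0)
        assert win["occluded"][0] == (2.0, 4.0)
        assert all(b - a == pytest.approx(2.0) for a, b in win["visible"])

    def test_trial_too_short_rejected(self):
        times = np.arange(0, 1.0, 1 / 250)
        with pytest.raises(ValueError):
            segment_conditions(times, 1, {"random1": 0.0, "constant": 0.6},
                               interval="second")


class TestClusterPermutation:
    def test_identical_conditions_empty(self, adjacency16, rng):
        a = rng.standard_normal((8, 16, 40))
        assert cluster_permutation_test(a, a.copy(), adjacency16,
                                        n_permutations=50) == []

    def test_t_sum_matches_bruteforce_recomputation(self, adjacency16, rng):
        from scipy.stats import ttest_rel

        a = rng.standard_normal((10, 16, 40))
        b = rng.standard_normal((10, 16, 40))
        b[:, :5, 5:20] += 1.2
        clusters = cluster_permutation_test(a, b, adjacency16,
                                            n_permutations=100, seed=0)
        assert clusters
        t_map = ttest_rel(a, b, axis=0).statistic
        for c in clusters:
            brute = sum(t_map[ch, tt] for ch, tt in c.members)
            assert c.t_sum == pytest.approx(brute, rel=1e-9)

    def test_invariance_to_channel_relabeling(self, adjacency16, rng):
        a = rng.standard_normal((9, 16, 30))
        b = rng.standard_normal((9, 16, 30))
        b[:, 2:7, 10:20] += 1.0
        res1 = cluster_permutation_test(a, b, adjacency16,
                                        n_permutations=200, seed=3)
        perm = np.random.default_rng(0).permutation(16)
        adj2 = adjacency16[np.ix_(perm, perm)]
        res2 = cluster_permutation_test(a[:, perm], b[:, perm], adj2,
                                        n_permutations=200, seed=3)
        assert sorted(round(c.t_sum, 6) for c in res1) == \
            sorted(round(c.t_sum, 6) for c in res2)
        assert sorted(c.p for c in res1) == sorted(c.p for c in res2)

    def test_injected_effect_detected(self, adjacency16, rng):
        a = rng.standard_normal((12, 16, 50))
        b = rng.standard_normal((12, 16, 50))
        b[:, :6, 10:35] += 1.5
        clusters = cluster_permutation_test(a, b, adjacency16,
                                            n_permutations=500, seed=1)
        sig = [c for c in clusters if c.p <= 0.05]
        assert sig
        top = max(sig, key=lambda c: abs(c.t_sum))
        assert top.polarity == "negative"
        assert set(top.channels) & set(range(6))

    def test_matches_mne_observed_clusters(self, adjacency16, rng):
        """Independent cross-check of cluster formation against MNE."""
        from mne.stats import permutation_cluster_1samp_test
        from scipy import sparse
        from scipy.stats import t as t_dist

        a = rng.standard_normal((10, 16, 30))
        b = rng.standard_normal((10, 16, 30))
        b[:, 3:9, 8:22] += 1.0
        ours = cluster_permutation_test(a, b, adjacency16,
                                        n_permutations=100, seed=0)
        thr = t_dist.ppf(1 - 0.001 / 2, df=9)
        X = np.transpose(a - b, (0, 2, 1))  # mne wants (obs, times, channels)
        _, clusters, _, _ = permutation_cluster_1samp_test(
            X, threshold=thr, n_permutations=50, tail=0,
            adjacency=sparse.coo_matrix(adjacency16), out_type="indices",
            seed=0, verbose="error")
        mne_sets = set()
        for tt, cc in clusters:
            mne_sets.add(frozenset(zip(np.atleast_1d(cc), np.atleast_1d(tt))))
        our_sets = {frozenset(map(tuple, c.members)) for c in ours}
        assert our_sets == mne_sets

    def test_fewer_than_two_subjects_rejected(self, adjacency16):
        with pytest.raises(ValueError):
            cluster_permutation_test(np.zeros((1, 16, 10)),
                                     np.zeros((1, 16, 10)), adjacency16)


class TestNormalizedContrast:
    def _grid(self, values):
        n = len(values)
        coords = np.column_stack([np.arange(n), np.zeros(n), np.zeros(n)]) * 5.0
        return SourceGrid(coords_mm=coords, values=np.asarray(values, float),
                          edge_length_mm=5.0)

    def test_equal_power_gives_zero(self):
        r = normalized_contrast(self._grid([1, 2, 3]), self._grid([1, 2, 3]))
        np.testing.assert_allclose(r.values, 0.0)

    def test_simple_arithmetic(self):
        r = normalized_contrast(self._grid([2.0]), self._grid([1.0]))
        assert r.values[0] == pytest.approx(1 / 3)

    def test_boundary_attained(self):
        r = normalized_contrast(self._grid([5.0, 0.0]), self._grid([0.0, 0.0]))
        assert r.values[0] == 1.0
        assert r.values[1] == 0.0  # zero-sum voxel maps to 0

    def test_antisymmetry(self, rng):
        a = self._grid(rng.uniform(0, 10, 20))
        b = self._grid(rng.uniform(0, 10, 20))
        np.testing.assert_allclose(normalized_contrast(a, b).values,
                                   -normalized_contrast(b, a).values)


class TestDbscanVoxelClusters:
    def _random_grid(self, rng, n=4000, edge=5.0):
        side = int(round(n ** (1 / 3)))
        g = np.stack(np.meshgrid(*[np.arange(side)] * 3,
                                 indexing="ij")).reshape(3, -1).T * edge
        vals = rng.normal(0, 0.01, g.shape[0])
        return g, vals

    def test_single_blob_forms_one_cluster(self, rng):
        coords, vals = self._random_grid(rng)
        # a compact 1% blob of extreme voxels
        center = coords.mean(axis=0)
        d = np.linalg.norm(coords - center, axis=1)
        n_sel = int(np.ceil(0.01 * len(vals)))
        blob = np.argsort(d)[:n_sel]
        vals[blob] = 1.0
        grid = SourceGrid(coords_mm=coords, values=vals, edge_length_mm=5.0)
        clusters = dbscan_voxel_clusters(grid, direction="positive")
        assert len(clusters) == 1
        assert set(clusters[0].voxel_indices) == set(blob)

    def test_two_separated_blobs_form_two_clusters(self, rng):
        coords, vals = self._random_grid(rng)
        lo = np.argsort(np.linalg.norm(coords - coords[0], axis=1))[:20]
        hi = np.argsort(np.linalg.norm(coords - coords[-1], axis=1))[:20]
        vals[lo] = 1.0
        vals[hi] = 1.0
        grid = SourceGrid(coords_mm=coords, values=vals, edge_length_mm=5.0)
        clusters = dbscan_voxel_clusters(grid, direction="positive")
        assert len(clusters) == 2

    def test_scattered_extremes_are_noise(self, rng):
        coords, vals = self._random_grid(rng)
        # extreme voxels spread far apart (stride larger than eps)
        idx = np.arange(0, len(vals), 97)[:40]
        vals[idx] = 1.0
        grid = SourceGrid(coords_mm=coords, values=vals, edge_length_mm=5.0)
        sel_vals = np.sort(vals)[::-1]
        clusters = dbscan_voxel_clusters(grid, tail_fraction=40 / len(vals),
                                         direction="positive")
        assert clusters == []
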