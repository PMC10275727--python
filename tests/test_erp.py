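"""ERP epoching, CSD, weighting, cluster selection, and the vincentile matrix."""

import numpy as np
import pytest

from pursuitmon.erp import (
    epoch_around_peaks,
    csd_transform,
    erp_cluster_test,
    erp_vincentile_matrix,
    peak_latency_contrast,
    select_clusters,
    weight_by_trial_count,
)
from pursuitmon.timefreq import ClusterResult, EpochSet


class TestEpochAroundPeaks:
    def test_epoch_sample_count_is_313(self, rng):
        eeg = rng.standard_normal((4, 5000))
        eps, times, _ = epoch_around_peaks(eeg, [5.0, 10.0])
        assert eps.shape == (2, 4, 313)
        assert times.size == 313
        assert times[0] == pytest.approx(-0.5)

    def test_constant_channel_zero_after_baseline(self):
        eeg = np.full((2, 3000), 4.7)
        eps, _, _ = epoch_around_peaks(eeg, [6.0])
        np.testing.assert_allclose(eps, 0.0, atol=1e-12)

    def test_template_recovered_by_averaging(self, rng):
        t = np.arange(313) / 250.0 - 0.5
        template = 3.0 * np.exp(-((t - 0.25) ** 2) / (2 * 0.04**2))
        peaks = np.arange(2.0, 118.0, 1.0)
        eeg = rng.standard_normal((1, int(120 * 250))) * 0.5
        for pt in peaks:
            c = int(pt * 250)
            eeg[0, c - 125: c + 188] += template
        eps, _, _ = epoch_around_peaks(eeg, peaks.tolist())
        avg = eps.mean(axis=0)[0]
        assert np.corrcoef(avg, template)[0, 1] > 0.98

    def test_edge_peaks_skipped_and_logged(self, rng):
        eeg = rng.standard_normal((2, 1000))
        eps, _, skipped = epoch_around_peaks(eeg, [0.1, 2.0, 3.9])
        assert eps.shape[0] == 1
        assert skipped == [0, 2]


class TestCsdTransform:
    def test_uniform_potential_maps_to_zero(self, montage60):
        ep = EpochSet(data=np.ones((2, 60, 20)),
                      times_s=np.arange(20) / 250.0, ch_pos=montage60)
        out = csd_transform(ep)
        assert np.abs(out.data).max() < 1e-6

    def test_linearity(self, montage60, rng):
        x = rng.standard_normal((1, 60, 10))
        y = rng.standard_normal((1, 60, 10))
        times = np.arange(10) / 250.0

        def csd(d):
            return csd_transform(EpochSet(data=d, times_s=times,
                                          ch_pos=montage60)).data

        np.testing.assert_allclose(csd(2.0 * x + 3.0 * y),
                                   2.0 * csd(x) + 3.0 * csd(y),
                                   rtol=1e-6, atol=1e-10)

    def test_focal_source_has_center_surround_pattern(self, montage60):
        # dipolar topography concentrated under one electrode
        center = montage60[10]
        d = np.linalg.norm(montage60 - center, axis=1)
        topo = np.exp(-(d / 0.03) ** 2)
        ep = EpochSet(data=np.tile(topo[None, :, None], (1, 1, 5)),
                      times_s=np.arange(5) / 250.0, ch_pos=montage60)
        out = csd_transform(ep)
        csd_topo = out.data[0, :, 0]
        # CSD peaks at the source and reverses sign in the surround
        assert np.argmax(csd_topo) == 10
        ring = (d > 0.03) & (d < 0.08)
        assert csd_topo[ring].min() < 0

    def test_too_few_channels_rejected(self, montage16):
        ep = EpochSet(data=np.ones((1, 8, 5)), times_s=np.arange(5) / 250.0,
                      ch_pos=montage16[:8])
        with pytest.raises(ValueError):
            csd_transform(ep)


class TestWeights:
    def test_equal_counts_give_unit_weights(self):
        np.testing.assert_allclose(weight_by_trial_count([100, 100, 100]), 1.0)

    def test_median_over_count(self):
        np.testing.assert_allclose(weight_by_trial_count([50, 100, 150]),
                                   [2.0, 1.0, 2 / 3])

    def test_zero_count_rejected(self):
        with pytest.raises(ValueError):
            weight_by_trial_count([10, 0, 5])

    def test_grand_mean_unchanged_for_equal_counts(self, rng):
        erps = rng.standard_normal((5, 20))
        w = weight_by_trial_count([30] * 5)
        np.testing.assert_allclose((erps * w[:, None]).mean(0), erps.mean(0))


class TestErpClusterTest:
    def _times(self, n=188):
        return np.arange(-0.5 * 250, n).astype(int) / 250.0

    def test_identical_conditions_empty(self, adjacency16, rng):
        times = np.arange(-125, 188) / 250.0
        a = rng.standard_normal((8, 16, times.size))
        assert erp_cluster_test(a, a.copy(), adjacency16, times,
                                n_permutations=50) == []

    def test_injected_difference_detected_in_window(self, adjacency16, rng):
        times = np.arange(-125, 188) / 250.0
        a = rng.standard_normal((12, 16, times.size))
        b = rng.standard_normal((12, 16, times.size))
        win = (times >= 0.1) & (times <= 0.2)
        a[:, :6, win] += 1.8
        clusters = erp_cluster_test(a, b, adjacency16, times,
                                    n_permutations=300, seed=0)
        sig = [c for c in clusters if c.p <= 0.05 and c.polarity == "positive"]
        assert sig
        top = max(sig, key=lambda c: abs(c.t_sum))
        t0, t1 = top.time_extent()
        assert times[t0] >= 0.05 and times[t1] <= 0.30
        assert set(top.channels) & set(range(6))

    def test_two_channel_cluster_discarded(self, adjacency16, rng):
        times = np.arange(-125, 188) / 250.0
        a = rng.standard_normal((12, 16, times.size)) * 0.05
        b = rng.standard_normal((12, 16, times.size)) * 0.05
        win = (times >= 0.1) & (times <= 0.2)
        a[:, :2, win] += 2.0  # strong but spatially tiny
        clusters = erp_cluster_test(a, b, adjacency16, times,
                                    n_permutations=100, min_neighbors=4, seed=0)
        for c in clusters:
            chs = {ch for ch, _ in c.members}
            assert not chs <= {0, 1}


def _mk_cluster(t0, t1, tsum, pol, n_ch=5):
    members = np.array([(ch, t) for ch in range(n_ch)
                        for t in range(t0, t1 + 1)])
    return ClusterResult(members=members, t_sum=tsum, p=0.01, polarity=pol)


class TestSelectClusters:
    times = np.arange(0, 188) / 250.0

    def test_at_most_three_per_polarity_by_magnitude(self):
        clusters = [_mk_cluster(10, 30, 100 - i, "positive") for i in range(8)]
        kept = select_clusters(clusters, self.times)
        assert len(kept) == 3
        assert [c.t_sum for c in kept] == [100, 99, 98]

    def test_short_cluster_dropped(self):
        c = _mk_cluster(10, 13, 50, "positive")  # 4 samples < 5
        assert select_clusters([c], self.times) == []

    def test_late_onset_dropped(self):
        onset_idx = int(0.320 * 250)  # 320 ms
        c = _mk_cluster(onset_idx, onset_idx + 20, 50, "negative")
        assert select_clusters([c], self.times) == []

    def test_output_is_subset_sorted_by_magnitude(self):
        cl = [_mk_cluster(10, 40, 30, "positive"),
              _mk_cluster(20, 60, -80, "negative"),
              _mk_cluster(5, 25, 55, "positive")]
        kept = select_clusters(cl, self.times)
        assert [c.t_sum for c in kept] == [-80, 55, 30]
        assert all(any(c is orig for orig in cl) for c in kept)


class TestPeakLatencyContrast:
    def test_known_shift_recovered(self, rng):
        times = np.arange(-125, 188) / 250.0
        base = np.exp(-((times - 0.30) ** 2) / (2 * 0.05**2))
        n_sub = 10
        a = np.zeros((n_sub, times.size))
        b = np.zeros((n_sub, times.size))
        for s in range(n_sub):
            jit = rng.normal(0, 0.004)
            a[s] = np.exp(-((times - (0.30 + jit)) ** 2) / (2 * 0.05**2))
            b[s] = np.exp(-((times - (0.355 + jit)) ** 2) / (2 * 0.05**2))
        res = peak_latency_contrast(a, b, times)
        diff = res["mean_latency_a_s"] - res["mean_latency_b_s"]
        assert diff == pytest.approx(-0.055, abs=1 / 250.0)
        assert res["t"] < 0

    def test_injected_290_vs_345_ms_latencies(self, rng):
        times = np.arange(-125, 188) / 250.0
        n_sub = 12
        a = np.stack([np.exp(-((times - 0.290) ** 2) / (2 * 0.04**2))
                      + 0.01 * rng.standard_normal(times.size)
                      for _ in range(n_sub)])
        b = np.stack([np.exp(-((times - 0.345) ** 2) / (2 * 0.04**2))
                      + 0.01 * rng.standard_normal(times.size)
                      for _ in range(n_sub)])
        res = peak_latency_contrast(a, b, times)
        assert res["mean_latency_a_s"] == pytest.approx(0.290, abs=1 / 250.0)
        assert res["mean_latency_b_s"] == pytest.approx(0.345, abs=1 / 250.0)

    def test_flat_erp_subject_excluded(self, rng):
        times = np.arange(-125, 188) / 250.0
        a = np.stack([np.exp(-((times - 0.3 - 0.004 * s) ** 2) / 0.005)
                      for s in range(4)])
        b = np.stack([np.exp(-((times - 0.32 + 0.004 * s) ** 2) / 0.005)
                      for s in range(4)])
        a[2] = np.linspace(0, 1, times.size)  # max on window edge
        res = peak_latency_contrast(a, b, times)
        assert 2 in res["excluded_subjects"]


class TestVincentileMatrix:
    def _epoch_data(self, rng, n_sub=5, n_epochs=40):
        times = np.arange(-125, 188) / 250.0
        by_a, by_b = {}, {}
        for s in range(n_sub):
            amp_a = rng.standard_normal((n_epochs, times.size))
            amp_b = rng.standard_normal((n_epochs, times.size)) + 0.5
            meas = rng.uniform(0.08, 0.3, n_epochs)
            by_a[s] = (amp_a, meas)
            by_b[s] = (amp_b, rng.uniform(0.08, 0.3, n_epochs))
        return by_a, by_b, times

    def test_matrix_has_100_cells_and_12_13_samples_per_bin(self, rng):
        by_a, by_b, times = self._epoch_data(rng)
        res = erp_vincentile_matrix(by_a, by_b, times, n_boot=100, seed=0)
        assert res.t.shape == (10, 10)
        assert res.t.size == 100
        assert set(res.samples_per_bin.tolist()) <= {12, 13}

    def test_uniform_difference_yields_flat_d_profile(self, rng):
        by_a, by_b, times = self._epoch_data(rng, n_sub=8, n_epochs=60)
        res = erp_vincentile_matrix(by_a, by_b, times, n_boot=200, seed=1)
        # difference injected equally across vincentiles: no monotone trend
        from scipy.stats import spearmanr

        mean_d_per_vinc = np.nanmean(res.d, axis=1)
        rho = spearmanr(np.arange(10), mean_d_per_vinc).statistic
        assert abs(rho) < 0.85

    def test_matrix_grand_mean_matches_included_epoch_mean(self, rng):
        by_a, by_b, times = self._epoch_data(rng, n_sub=3, n_epochs=50)
        res = erp_vincentile_matrix(by_a, by_b, times, n_boot=50, seed=2)
        tsel = (times >= 0.05) & (times < 0.55)
        for s in range(3):
            amp, _ = by_a[s]
            # partition identity: cell means with equal populations average
            # to the epoch-mean amplitude over 50-550 ms
            assert np.nanmean(res.per_subject_a[s]) == pytest.approx(
                amp[:, tsel].mean(), abs=0.02)
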