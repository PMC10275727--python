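"""Direction-change-locked ERP analysis: epoching, CSD, cluster test, and
peak-latency contrast on synthetic EEG with injected templates.

Condition A's event-locked positive deflection peaks at 290 ms, condition
B's at 345 ms — the peak-latency contrast should recover this ~55 ms shift.
"""

import numpy as np

from pursuitmon import EpochSet, channel_adjacency, csd_transform, epoch_around_peaks, make_montage, peak_latency_contrast
from pursuitmon.erp import erp_cluster_test

montage = make_montage(60)
adjacency = channel_adjacency(montage)
rate = 250.0
times = np.arange(-125, 188) / rate
rng = np.random.default_rng(8)

# spatially compact affected region: the 8 electrodes nearest channel 10
d = np.linalg.norm(montage - montage[10], axis=1)
affected = np.argsort(d)[:8]

# per-subject ERPs with condition-specific peak latencies
erps = {"A": [], "B": []}
erps_csd = {"A": [], "B": []}
for _subject in range(15):
    for cond, mu in (("A", 0.290), ("B", 0.345)):
        template = 4.0 * np.exp(-((times - rng.normal(mu, 0.01)) ** 2)
                                / (2 * 0.05**2))
        topo = np.exp(-(d[affected] / 0.05) ** 2)  # smooth focal topography
        eeg = rng.standard_normal((60, int(60 * rate)))
        peaks = np.arange(2.0, 58.0, 1.5)
        for pt in peaks:
            c = int(pt * rate)
            eeg[np.ix_(affected, np.arange(c - 125, c + 188))] += \
                topo[:, None] * template[None, :]
        epochs, t, _ = epoch_around_peaks(eeg, peaks.tolist(), rate_hz=rate)
        es = EpochSet(data=epochs, times_s=t, ch_pos=montage,
                      sampling_rate=rate)
        csd = csd_transform(es)  # sharpen topographies for the cluster test
        erps[cond].append(epochs.mean(axis=0))
        erps_csd[cond].append(csd.data.mean(axis=0))

A, B = np.stack(erps["A"]), np.stack(erps["B"])
clusters = erp_cluster_test(np.stack(erps_csd["A"]), np.stack(erps_csd["B"]),
                            adjacency, times, n_permutations=300, seed=0)
print(f"{len(clusters)} clusters surviving the 4-neighboring-electrode rule")

# peak latency from the raw-potential average over the affected region
avg_a = A[:, affected].mean(axis=1)
avg_b = B[:, affected].mean(axis=1)
res = peak_latency_contrast(avg_a, avg_b, times)
print(f"peak latency A: {1000 * res['mean_latency_a_s']:.0f} ms, "
      f"B: {1000 * res['mean_latency_b_s']:.0f} ms")
print(f"paired t = {res['t']:.2f}, d = {res['d']:.2f}")
print("-> the injected 290 vs 345 ms latencies are recovered from the "
      "epoch averages over the affected region")
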