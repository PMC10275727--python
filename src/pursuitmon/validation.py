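"""End-to-end validation experiments on synthetic data with known truth.

These routines drive the full analysis chain — generator in, statistic out —
and measure its operating characteristics: recovery of an injected pursuit
lag, type-I error of the bootstrap paired test, family-wise error of the
cluster permutation test, empirical false discovery rate under BH, and
detection power for an injected alpha-band condition difference.  They are
used by the test suite and by the reproduction script.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm

from . import behavior as bh
from .synth import CursorModelParams, EEGEffectSpec, make_montage, simulate_cursor, simulate_eeg
from .task_design import build_trajectory
from .timefreq import EpochSet, channel_adjacency, cluster_permutation_test, morlet_power
from .vincentile import bootstrap_paired_test, fdr_correct

__all__ = [
    "lag_recovery",
    "bootstrap_type1_rate",
    "cluster_fwer",
    "fdr_empirical",
    "tfr_detection_power",
]


def lag_recovery(n_trials: int = 100, lag_s: float = 0.150, seed: int = 0,
                 noise_sd_px: float = 0.0) -> dict:
    """Median pursuit latency recovered from simulated trials with a known
    cursor lag (noise-free by default)."""
    rng = np.random.default_rng(seed)
    params = CursorModelParams(dead_time_s=0.0, lag_s=lag_s,
                               smoothing_tau_s=0.0,
                               motor_noise_sd_px=noise_sd_px)
    latencies = []
    for _ in range(n_trials):
        traj = build_trajectory(
            rng.choice(["left", "right"]), int(rng.integers(1, 4)),
            seed=int(rng.integers(0, 2**31 - 1)))
        cur = simulate_cursor(traj, params, seed=rng)
        tgt = bh.upsample_coordinates(traj.y)
        crs = bh.upsample_coordinates(cur)
        tp = bh.detect_peaks(tgt, 0.01, traj.screen.height_px)
        pp = bh.detect_peaks(crs, 0.05, traj.screen.height_px)
        for m in bh.match_pursuit_peaks(tp, pp):
            if m.valid:
                latencies.append(m.latency_s)
    latencies = np.asarray(latencies)
    return {"median_latency_s": float(np.median(latencies)),
            "injected_lag_s": lag_s, "n_latencies": int(latencies.size),
            "n_trials": n_trials}


def bootstrap_type1_rate(n_reps: int = 1000, n: int = 30, alpha: float = 0.05,
                         n_boot: int = 1000, seed: int = 0) -> dict:
    """Rejection rate of the bootstrap paired test under the null."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_reps):
        diff = rng.standard_normal(n)
        b = rng.standard_normal(n)
        _, p, _ = bootstrap_paired_test(b + diff, b, n_boot=n_boot, seed=rng)
        rejections += p <= alpha
    return {"rate": rejections / n_reps, "n_reps": n_reps, "alpha": alpha,
            "n": n}


def cluster_fwer(n_reps: int = 500, n_sub: int = 10, n_ch: int = 16,
                 n_times: int = 100, n_permutations: int = 500,
                 alpha: float = 0.05, seed: int = 0) -> dict:
    """Family-wise false-positive rate of the cluster permutation test on
    null Gaussian EEG-like data."""
    montage = make_montage(n_ch)
    adjacency = channel_adjacency(montage)
    rng = np.random.default_rng(seed)
    fp = 0
    for _ in range(n_reps):
        a = rng.standard_normal((n_sub, n_ch, n_times))
        b = rng.standard_normal((n_sub, n_ch, n_times))
        clusters = cluster_permutation_test(
            a, b, adjacency, n_permutations=n_permutations,
            seed=int(rng.integers(0, 2**31 - 1)))
        fp += any(c.p <= alpha for c in clusters)
    return {"rate": fp / n_reps, "n_reps": n_reps, "alpha": alpha,
            "n_channels": n_ch, "n_times": n_times}


def fdr_empirical(n_reps: int = 1000, n_tests: int = 100,
                  frac_null: float = 0.5, effect_z: float = 3.0,
                  q: float = 0.05, seed: int = 0) -> dict:
    """Empirical FDR of BH over replicated mixed null/alternative batteries.

    True nulls yield z ~ N(0,1); alternatives z ~ N(effect_z, 1); two-sided
    p-values; FDR = mean of V / max(R, 1).
    """
    rng = np.random.default_rng(seed)
    n_null = int(round(frac_null * n_tests))
    fdp = np.empty(n_reps)
    for i in range(n_reps):
        z = np.concatenate([rng.standard_normal(n_null),
                            rng.normal(effect_z, 1.0, n_tests - n_null)])
        p = 2 * norm.sf(np.abs(z))
        mask = fdr_correct(p, q=q)
        R = int(mask.sum())
        V = int(mask[:n_null].sum())
        fdp[i] = V / max(R, 1)
    return {"fdr": float(fdp.mean()), "n_reps": n_reps, "q": q,
            "frac_null": frac_null}


def tfr_detection_power(n_reps: int = 50, n_subjects: int = 30,
                        amp_a_uv: float = 3.0, amp_b_uv: float = 2.0,
                        n_channels: int = 16, n_affected: int = 6,
                        n_windows_per_condition: int = 6,
                        n_permutations: int = 250, alpha: float = 0.05,
                        seed: int = 0) -> dict:
    """Detection rate of an injected alpha-band condition power difference.

    Per subject, continuous EEG alternates 2-s condition windows (A then B);
    condition A carries a larger alpha oscillation amplitude on a subset of
    channels over 1/f background noise (10 uV scale — a moderate
    signal-to-noise ratio).  Window-wise Morlet alpha power, averaged within
    condition, feeds the paired cluster permutation test across subjects; a
    replicate counts as detected when a significant cluster overlaps the
    affected channels.
    """
    montage = make_montage(n_channels)
    adjacency = channel_adjacency(montage)
    affected = set(range(n_affected))
    windows = []
    for i in range(n_windows_per_condition):
        windows.append((i * 4.0, i * 4.0 + 2.0, "A"))
        windows.append((i * 4.0 + 2.0, i * 4.0 + 4.0, "B"))
    duration = 4.0 * n_windows_per_condition
    spec = EEGEffectSpec(
        band_effects={"alpha": {"A": amp_a_uv, "B": amp_b_uv}},
        noise_scale_uv=10.0, channels_affected=np.arange(n_affected))

    root = np.random.default_rng(seed)
    detected = 0
    for _ in range(n_reps):
        rng = np.random.default_rng(int(root.integers(0, 2**31 - 1)))
        maps_a, maps_b = [], []
        for _s in range(n_subjects):
            data, _ = simulate_eeg([], montage, spec, duration_s=duration,
                                   condition_windows=windows, seed=rng)
            eps = {"A": [], "B": []}
            for a, b, cond in windows:
                eps[cond].append(data[:, int(a * 250): int(b * 250)])
            for cond, out in (("A", maps_a), ("B", maps_b)):
                arr = np.stack(eps[cond])
                es = EpochSet(data=arr,
                              times_s=np.arange(arr.shape[-1]) / 250.0,
                              ch_pos=montage)
                tfr = morlet_power(es, "alpha")
                # average epochs and band frequencies; decimate time
                out.append(tfr.power.mean(axis=(0, 2))[:, ::10])
        clusters = cluster_permutation_test(
            np.stack(maps_a), np.stack(maps_b), adjacency,
            n_permutations=n_permutations,
            seed=int(root.integers(0, 2**31 - 1)))
        detected += any(c.p <= alpha and set(c.channels) & affected
                        for c in clusters)
    return {"power": detected / n_reps, "n_reps": n_reps,
            "amp_a_uv": amp_a_uv, "amp_b_uv": amp_b_uv,
            "n_subjects": n_subjects}
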