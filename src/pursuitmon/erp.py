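"""Direction-change-locked ERP analysis.

EEG is epoched from -500 to +750 ms around target direction changes
(trajectory peaks), baseline-corrected over the pre-peak 500 ms, and sharpened
with a spherical-spline current-source-density (CSD) transform.  Subjects'
averages are weighted by median-trials / subject-trials so that subjects with
many epochs do not dominate the grand average.  Condition differences are
assessed with the cluster-based permutation test over channels x time
(0-750 ms, 3000 Monte-Carlo iterations, cluster alpha 0.001); clusters
touching fewer than four neighboring electrodes are ignored, at most the three
largest clusters per polarity are analyzed further, and clusters shorter than
five samples or starting later than 300 ms after the direction change (when
the next direction change is already underway) are rejected.

The association between the ERP time course and tracking performance is a
10 x 10 matrix per subject and condition: behavioral vincentiles (rows) by
50-ms time bins from 50 to 550 ms after the direction change (columns), each
cell holding the mean ERP amplitude over the cluster's electrodes, tested
cell-wise with the bootstrap paired t-test and BH-FDR over the 100 cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .timefreq import ClusterResult, EpochSet, cluster_permutation_test
from .vincentile import bootstrap_paired_test, fdr_correct

__all__ = [
    "ERP_WINDOW_S",
    "epoch_around_peaks",
    "csd_transform",
    "weight_by_trial_count",
    "erp_cluster_test",
    "select_clusters",
    "peak_latency_contrast",
    "erp_vincentile_matrix",
    "VincentileBinMatrix",
]

ERP_WINDOW_S = (-0.5, 0.75)


def epoch_around_peaks(eeg: np.ndarray, peak_times_s, rate_hz: float = 250.0,
                       window_s: tuple[float, float] = ERP_WINDOW_S,
                       baseline_s: tuple[float, float] = (-0.5, 0.0),
                       ) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Cut epochs around trajectory peaks and baseline-correct them.

    ``eeg`` is continuous (channels, samples).  The window -500..750 ms at
    250 Hz yields 313 samples per epoch.  The per-channel mean over the
    baseline window is subtracted.  Peaks too close to the recording edge are
    skipped; their indices are returned for logging.

    Returns ``(epochs, epoch_times_s, skipped_peak_indices)``.
    """
    eeg = np.asarray(eeg, dtype=float)
    n_samples = eeg.shape[1]
    lo = int(round(window_s[0] * rate_hz))
    hi = int(np.floor(window_s[1] * rate_hz))
    times = np.arange(lo, hi + 1) / rate_hz
    base_sel = (times >= baseline_s[0]) & (times <= baseline_s[1])

    epochs, skipped = [], []
    for k, t in enumerate(peak_times_s):
        center = int(round(t * rate_hz))
        if center + lo < 0 or center + hi >= n_samples:
            skipped.append(k)
            continue
        ep = eeg[:, center + lo: center + hi + 1].copy()
        ep -= ep[:, base_sel].mean(axis=1, keepdims=True)
        epochs.append(ep)
    data = np.stack(epochs) if epochs else np.empty((0, eeg.shape[0], times.size))
    return data, times, skipped


def csd_transform(epochs: EpochSet, stiffness: int = 4,
                  lambda2: float = 1e-5) -> EpochSet:
    """Spherical-spline surface Laplacian (current source density).

    Uses the standard spherical-spline algorithm with spline order
    ``stiffness`` (m = 4) and regularization ``lambda2`` (1e-5); channel
    positions are normalized to a common head radius.  The transform is
    linear and maps a spatially uniform potential to (approximately) zero.
    """
    import mne

    pos = np.asarray(epochs.ch_pos, dtype=float)
    n_ch = pos.shape[0]
    if n_ch < 16:
        raise ValueError("CSD needs at least 16 channels")
    if np.linalg.matrix_rank(pos - pos.mean(axis=0)) < 3:
        raise ValueError("degenerate montage: positions are coplanar/collinear")

    names = [f"E{i:03d}" for i in range(n_ch)]
    info = mne.create_info(names, sfreq=epochs.sampling_rate, ch_types="eeg")
    montage = mne.channels.make_dig_montage(
        ch_pos={n: p for n, p in zip(names, pos)}, coord_frame="head")
    ep = mne.EpochsArray(epochs.data, info, tmin=float(epochs.times_s[0]),
                         verbose="error")
    ep.set_montage(montage, verbose="error")
    csd = mne.preprocessing.compute_current_source_density(
        ep, stiffness=stiffness, lambda2=lambda2, verbose="error")
    return EpochSet(data=csd.get_data(), times_s=epochs.times_s,
                    ch_pos=epochs.ch_pos, sampling_rate=epochs.sampling_rate,
                    condition=epochs.condition, subject_id=epochs.subject_id)


def weight_by_trial_count(subject_epoch_counts) -> np.ndarray:
    """Per-subject weights: median trial count divided by the subject's count.

    Multiplied into each subject's average before grand averaging; equal
    counts give unit weights everywhere.
    """
    counts = np.asarray(subject_epoch_counts, dtype=float)
    if np.any(counts <= 0):
        raise ValueError("every subject needs at least one epoch")
    return np.median(counts) / counts


def _cluster_spatial_extent(cluster: ClusterResult, adjacency: np.ndarray) -> int:
    """Largest number of channels the cluster occupies at any single time
    point (channels within a cluster are adjacency-connected by
    construction)."""
    tcol = cluster.members[:, -1]
    best = 0
    for t in np.unique(tcol):
        best = max(best, int(np.count_nonzero(tcol == t)))
    return best


def erp_cluster_test(cond_a: np.ndarray, cond_b: np.ndarray,
                     adjacency: np.ndarray, times_s: np.ndarray,
                     n_permutations: int = 3000, cluster_alpha: float = 0.001,
                     min_neighbors: int = 4,
                     seed: int | np.random.Generator = 0,
                     ) -> list[ClusterResult]:
    """Cluster-based permutation test over channels x time, restricted to the
    post-event interval 0-750 ms, dropping clusters that never span at least
    ``min_neighbors`` neighboring electrodes at one time point."""
    sel = times_s >= 0
    clusters = cluster_permutation_test(
        cond_a[..., sel], cond_b[..., sel], adjacency,
        n_permutations=n_permutations, cluster_alpha=cluster_alpha, seed=seed)
    # member time indices refer to the post-zero grid; shift back
    offset = int(np.count_nonzero(~sel))
    kept = []
    for c in clusters:
        if _cluster_spatial_extent(c, adjacency) < min_neighbors:
            continue
        members = c.members.copy()
        members[:, -1] += offset
        kept.append(ClusterResult(members=members, t_sum=c.t_sum, p=c.p,
                                  polarity=c.polarity))
    return kept


def select_clusters(clusters: list[ClusterResult], times_s: np.ndarray,
                    rate_hz: float = 250.0, max_per_polarity: int = 3,
                    min_duration_samples: int = 5,
                    max_onset_s: float = 0.300) -> list[ClusterResult]:
    """Multi-step cluster selection.

    Keep at most the ``max_per_polarity`` largest clusters by |t_sum| per
    polarity, then drop clusters shorter than ``min_duration_samples`` and
    those whose onset falls later than ``max_onset_s`` after the direction
    change (activity there is already dominated by the next direction
    change).
    """
    out: list[ClusterResult] = []
    for pol in ("positive", "negative"):
        cands = sorted([c for c in clusters if c.polarity == pol],
                       key=lambda c: -abs(c.t_sum))[:max_per_polarity]
        for c in cands:
            t0, t1 = c.time_extent()
            duration = t1 - t0 + 1
            onset = times_s[t0]
            if duration < min_duration_samples or onset > max_onset_s:
                continue
            out.append(c)
    out.sort(key=lambda c: -abs(c.t_sum))
    return out


def peak_latency_contrast(erp_a: np.ndarray, erp_b: np.ndarray,
                          times_s: np.ndarray,
                          search_window_s: tuple[float, float] = (0.2, 0.45),
                          ) -> dict:
    """Paired contrast of positive-peak latencies between two conditions.

    ``erp_a``/``erp_b``: (n_subjects, n_times) cluster-electrode-averaged
    ERPs.  The latency of the maximum within the search window is found per
    subject; subjects whose maximum sits on a window edge (no interior peak)
    are excluded and logged.  Returns t, p, Cohen's d and mean latencies.
    """
    from scipy.stats import ttest_rel

    sel = (times_s >= search_window_s[0]) & (times_s <= search_window_s[1])
    t_win = times_s[sel]
    lat_a, lat_b, excluded = [], [], []
    for s in range(erp_a.shape[0]):
        ia = int(np.argmax(erp_a[s, sel]))
        ib = int(np.argmax(erp_b[s, sel]))
        if ia in (0, t_win.size - 1) or ib in (0, t_win.size - 1):
            excluded.append(s)
            continue
        lat_a.append(t_win[ia])
        lat_b.append(t_win[ib])
    if len(lat_a) < 2:
        raise ValueError("fewer than 2 subjects with an interior peak")
    la, lb = np.asarray(lat_a), np.asarray(lat_b)
    diff = la - lb
    sd = diff.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance latency differences")
    res = ttest_rel(la, lb)
    return {
        "t": float(res.statistic), "p": float(res.pvalue),
        "d": float(diff.mean() / sd),
        "mean_latency_a_s": float(la.mean()),
        "mean_latency_b_s": float(lb.mean()),
        "excluded_subjects": excluded,
    }


@dataclass
class VincentileBinMatrix:
    """10 x 10 (vincentile x time-bin) ERP amplitude matrices and the
    cell-wise condition contrast."""

    per_subject_a: np.ndarray  # (n_subjects, k, n_bins)
    per_subject_b: np.ndarray
    t: np.ndarray
    p: np.ndarray
    d: np.ndarray
    fdr_mask: np.ndarray
    bin_edges_s: np.ndarray
    samples_per_bin: np.ndarray
    missing_cells: int


def _subject_matrix(epoch_amp: np.ndarray, measure: np.ndarray,
                    times_s: np.ndarray, k: int,
                    bin_edges_s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One subject's vincentile x time-bin matrix from epoch-level data.

    ``epoch_amp``: (n_epochs, n_times) cluster-electrode-averaged amplitude;
    ``measure``: per-epoch behavioral value used for vincentile ranking.
    """
    n_bins = bin_edges_s.size - 1
    n = measure.size
    order = np.argsort(measure, kind="stable")
    base, rem = divmod(n, k)
    sizes = np.full(k, base)
    sizes[:rem] += 1
    edges = np.concatenate([[0], np.cumsum(sizes)])
    mat = np.full((k, n_bins), np.nan)
    counts = np.zeros(n_bins, dtype=int)
    for bi in range(n_bins):
        tsel = (times_s >= bin_edges_s[bi]) & (times_s < bin_edges_s[bi + 1])
        counts[bi] = int(np.count_nonzero(tsel))
        for vi in range(k):
            idx = order[edges[vi]:edges[vi + 1]]
            if idx.size:
                mat[vi, bi] = epoch_amp[np.ix_(idx, np.flatnonzero(tsel))].mean()
    return mat, counts


def erp_vincentile_matrix(
    epochs_by_subject_a: dict[int, tuple[np.ndarray, np.ndarray]],
    epochs_by_subject_b: dict[int, tuple[np.ndarray, np.ndarray]],
    times_s: np.ndarray,
    k: int = 10,
    bin_start_s: float = 0.05,
    bin_stop_s: float = 0.55,
    n_bins: int = 10,
    n_boot: int = 5000,
    alpha: float = 0.001,
    q: float = 0.05,
    seed: int = 0,
) -> VincentileBinMatrix:
    """ERP-amplitude-by-performance matrix with cell-wise bootstrap contrast.

    Each subject contributes, per condition, ``(epoch_amp, measure)``: the
    cluster-electrode-averaged epoch amplitudes (n_epochs, n_times) and the
    per-epoch behavioral measure (only epochs with a valid pursuit latency
    should be passed in).  Rows are behavioral vincentiles, columns 50-ms time
    bins from 50 to 550 ms (12-13 samples each at 250 Hz).  The 100 cells are
    tested with the bootstrap paired t-test and BH-FDR-corrected; cells
    missing for any subject are skipped and counted.
    """
    subjects = sorted(set(epochs_by_subject_a) & set(epochs_by_subject_b))
    if len(subjects) < 2:
        raise ValueError("need at least 2 subjects present in both conditions")
    bin_edges = np.linspace(bin_start_s, bin_stop_s, n_bins + 1)

    mats_a, mats_b = [], []
    counts = None
    for s in subjects:
        amp_a, meas_a = epochs_by_subject_a[s]
        amp_b, meas_b = epochs_by_subject_b[s]
        ma, counts = _subject_matrix(np.asarray(amp_a, float),
                                     np.asarray(meas_a, float),
                                     times_s, k, bin_edges)
        mb, _ = _subject_matrix(np.asarray(amp_b, float),
                                np.asarray(meas_b, float),
                                times_s, k, bin_edges)
        mats_a.append(ma)
        mats_b.append(mb)
    A = np.stack(mats_a)  # (n_subjects, k, n_bins)
    B = np.stack(mats_b)

    rng = np.random.default_rng(seed)
    t = np.full((k, n_bins), np.nan)
    p = np.full((k, n_bins), np.nan)
    d = np.full((k, n_bins), np.nan)
    missing = 0
    for vi in range(k):
        for bi in range(n_bins):
            av, bv = A[:, vi, bi], B[:, vi, bi]
            if np.any(~np.isfinite(av)) or np.any(~np.isfinite(bv)):
                missing += 1
                continue
            t[vi, bi], p[vi, bi], d[vi, bi] = bootstrap_paired_test(
                av, bv, n_boot=n_boot, alpha=alpha, seed=rng)
    mask = np.zeros((k, n_bins), dtype=bool)
    tested = np.isfinite(p)
    if np.any(tested):
        mask[tested] = fdr_correct(p[tested], q=q)
    return VincentileBinMatrix(
        per_subject_a=A, per_subject_b=B, t=t, p=p, d=d, fdr_mask=mask,
        bin_edges_s=bin_edges, samples_per_bin=counts, missing_cells=missing)
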