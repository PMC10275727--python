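"""Time-frequency band power, cluster-based permutation tests, and
source-map contrast operations.

Band power is obtained with Morlet wavelets (width 5 Gaussians) in the theta
(4-7 Hz), alpha (8-12 Hz) and beta (13-30 Hz) bands, expressed as decibel
change relative to a pre-trial baseline (-750 ms to trial start by default).

Condition differences are assessed with cluster-based permutation tests:
pointwise paired t-tests are thresholded at a cluster-forming alpha,
supra-threshold points are grouped into spatio-temporal(-spectral) clusters
under the channel adjacency, each cluster is summarized by the sum of its
member t-values, and the observed cluster masses are compared against the
Monte-Carlo distribution of the maximum cluster mass under within-subject
sign flips of the paired differences (exact for a paired design).

Source-level condition contrasts of voxel power maps are expressed as the
normalized ratio r = (p1 - p2) / (p1 + p2), bounded in [-1, 1]; the extreme
tail of the ratio distribution is segmented into compact regions with DBSCAN
using a search radius of 1.5 voxel edge lengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.spatial import Delaunay
from scipy.stats import t as t_dist
from sklearn.cluster import DBSCAN

__all__ = [
    "BANDS",
    "EpochSet",
    "TFR",
    "ClusterResult",
    "SourceGrid",
    "channel_adjacency",
    "morlet_power",
    "baseline_correct",
    "segment_conditions",
    "cluster_permutation_test",
    "normalized_contrast",
    "dbscan_voxel_clusters",
]

BANDS = {"theta": (4.0, 7.0), "alpha": (8.0, 12.0), "beta": (13.0, 30.0)}


@dataclass
class EpochSet:
    """Epoched multichannel EEG: (epochs, channels, samples)."""

    data: np.ndarray
    times_s: np.ndarray
    ch_pos: np.ndarray
    sampling_rate: float = 250.0
    condition: str | None = None
    subject_id: int | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times_s = np.asarray(self.times_s, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (epochs, channels, samples)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite EEG data")
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.data.shape[1] != self.ch_pos.shape[0]:
            raise ValueError("channel count does not match montage")
        if self.data.shape[2] != self.times_s.size:
            raise ValueError("sample count does not match times")


@dataclass
class TFR:
    """Time-frequency power: (epochs, channels, frequencies, times)."""

    power: np.ndarray
    freqs: np.ndarray
    times_s: np.ndarray
    band: str
    baseline_window_s: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.power) < 0) and self.baseline_window_s is None:
            raise ValueError("raw power must be non-negative")


@dataclass
class ClusterResult:
    """One spatio-temporal(-spectral) cluster with its permutation p-value."""

    members: np.ndarray  # (n_points, ndim) integer indices: (channel, [freq,] time)
    t_sum: float
    p: float
    polarity: str  # "positive" | "negative"

    @property
    def channels(self) -> np.ndarray:
        return np.unique(self.members[:, 0])

    def time_extent(self) -> tuple[int, int]:
        tcol = self.members[:, -1]
        return int(tcol.min()), int(tcol.max())


@dataclass
class SourceGrid:
    """Voxel power map on a regular grid."""

    coords_mm: np.ndarray  # (n_voxels, 3)
    values: np.ndarray
    edge_length_mm: float
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.edge_length_mm <= 0:
            raise ValueError("voxel edge length must be positive")
        if self.coords_mm.shape[0] != np.asarray(self.values).shape[0]:
            raise ValueError("coords and values must align")


def channel_adjacency(ch_pos: np.ndarray) -> np.ndarray:
    """Neighbor matrix from Delaunay triangulation of the sensor layout.

    Positions are projected with an azimuthal-equidistant map about the
    vertex before triangulating, the standard flattening for EEG caps.
    """
    pos = np.asarray(ch_pos, dtype=float)
    n = pos.shape[0]
    r = np.linalg.norm(pos, axis=1)
    r[r == 0] = 1.0
    unit = pos / r[:, None]
    theta = np.arccos(np.clip(unit[:, 2], -1, 1))  # polar angle from vertex
    phi = np.arctan2(unit[:, 1], unit[:, 0])
    flat = np.column_stack([theta * np.cos(phi), theta * np.sin(phi)])
    tri = Delaunay(flat)
    adj = np.zeros((n, n), dtype=bool)
    for simplex in tri.simplices:
        for i in range(3):
            a, b = simplex[i], simplex[(i + 1) % 3]
            adj[a, b] = adj[b, a] = True
    return adj


def morlet_power(epochs: EpochSet, band: str, n_cycles: float = 5.0,
                 freq_step: float = 1.0) -> TFR:
    """Morlet-wavelet power in one frequency band (1 Hz steps).

    Wavelet width is ``n_cycles`` Gaussians.  Raises when the epoch is too
    short to support the wavelet at the band's lowest frequency.
    """
    from mne.time_frequency import tfr_array_morlet

    lo, hi = BANDS[band]
    freqs = np.arange(lo, hi + 1e-9, freq_step)
    min_len = int(np.ceil(n_cycles / lo * epochs.sampling_rate))
    if epochs.data.shape[-1] < min_len:
        raise ValueError(
            f"epoch of {epochs.data.shape[-1]} samples too short for "
            f"{lo} Hz x {n_cycles} cycles (needs >= {min_len})")
    power = tfr_array_morlet(epochs.data, sfreq=epochs.sampling_rate,
                             freqs=freqs, n_cycles=n_cycles, output="power",
                             zero_mean=True)
    return TFR(power=power, freqs=freqs, times_s=epochs.times_s, band=band)


def baseline_correct(tfr: TFR, window_s: tuple[float, float] = (-0.75, 0.0),
                     mode: str = "db") -> TFR:
    """Express power relative to the mean over a baseline window.

    ``db`` (default) returns 10*log10(power / baseline); ``ratio`` returns
    the plain quotient.  The baseline mean is taken per epoch, channel and
    frequency.  A zero baseline raises.
    """
    # upper edge exclusive: the window ends where the trial starts
    sel = (tfr.times_s >= window_s[0]) & (tfr.times_s < window_s[1])
    if not np.any(sel):
        raise ValueError("baseline window outside the epoch")
    base = tfr.power[..., sel].mean(axis=-1, keepdims=True)
    if np.any(base <= 0):
        raise ValueError("zero baseline power; cannot normalize")
    rel = tfr.power / base
    if mode == "db":
        rel = 10.0 * np.log10(rel)
    elif mode != "ratio":
        raise ValueError("mode must be 'db' or 'ratio'")
    return TFR(power=rel, freqs=tfr.freqs, times_s=tfr.times_s,
               band=tfr.band, baseline_window_s=window_s)


def segment_conditions(times_s: np.ndarray, task: int,
                       segment_onsets_s: dict[str, float] | None = None,
                       interval: str = "first",
                       trial_duration_s: float | None = None,
                       ) -> dict[str, tuple[float, float]]:
    """Condition windows (start_s, stop_s) for a trial's contrast.

    Task 1 compares the random and constant trajectory segments; because
    tracking behavior differs in the first 500 ms of a trial, the contrast is
    split: the *first* interval takes the opening 500 ms of each segment, the
    *second* takes 500-3000 ms of the random segment against 0-2500 ms of the
    constant one (windows of equal 2500 ms length).  Task 2 alternates 2-s
    visible and occluded windows, starting visible.
    """
    if task == 1:
        if segment_onsets_s is None:
            raise ValueError("task 1 needs segment onset times")
        r0 = segment_onsets_s["random1"]
        c0 = segment_onsets_s["constant"]
        if interval == "first":
            win = {"random": (r0, r0 + 0.5), "constant": (c0, c0 + 0.5)}
        elif interval == "second":
            win = {"random": (r0 + 0.5, r0 + 3.0), "constant": (c0, c0 + 2.5)}
        else:
            raise ValueError("interval must be 'first' or 'second'")
    elif task == 2:
        dur = trial_duration_s if trial_duration_s is not None else float(times_s[-1])
        vis, occ = [], []
        t = 0.0
        while t < dur:
            vis.append((t, min(t + 2.0, dur)))
            if t + 2.0 < dur:
                occ.append((t + 2.0, min(t + 4.0, dur)))
            t += 4.0
        return {"visible": vis, "occluded": occ}
    else:
        raise ValueError("task must be 1 or 2")
    for name, (a, b) in win.items():
        if a < times_s[0] - 1e-9 or b > times_s[-1] + 1e-9:
            raise ValueError(f"trial too short for the {name} window {a}-{b} s")
    return win


# ---------------------------------------------------------------------------
# cluster-based permutation test
# ---------------------------------------------------------------------------

def _label_clusters(mask: np.ndarray, adjacency: np.ndarray) -> np.ndarray:
    """Connected components of supra-threshold points.

    ``mask`` is boolean over (channels, *grid); two points are connected when
    they share a channel and are grid-adjacent (one step along any single
    grid axis), or share the full grid index and sit on neighboring channels.
    Returns an integer label map (-1 for sub-threshold points).
    """
    shape = mask.shape
    n_ch = shape[0]
    grid_shape = shape[1:]
    flat = mask.reshape(n_ch, -1)
    n_nodes = np.count_nonzero(flat)
    if n_nodes == 0:
        return -np.ones(shape, dtype=np.int64)
    node_id = -np.ones(flat.shape, dtype=np.int64)
    node_id[flat] = np.arange(n_nodes)
    if n_nodes == 1:
        return node_id.reshape(shape)

    rows, cols = [], []
    # grid-axis neighbors within a channel
    m = mask.reshape(shape)
    nid = node_id.reshape(shape)
    for ax in range(1, m.ndim):
        sl_a = [slice(None)] * m.ndim
        sl_b = [slice(None)] * m.ndim
        sl_a[ax] = slice(None, -1)
        sl_b[ax] = slice(1, None)
        both = m[tuple(sl_a)] & m[tuple(sl_b)]
        rows.append(nid[tuple(sl_a)][both])
        cols.append(nid[tuple(sl_b)][both])
    # channel neighbors at the same grid point
    ai, bi = np.nonzero(np.triu(adjacency, k=1))
    for a, b in zip(ai, bi):
        both = flat[a] & flat[b]
        rows.append(node_id[a][both])
        cols.append(node_id[b][both])
    if rows:
        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
    graph = sparse.coo_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n_nodes, n_nodes))
    n_comp, comp = sparse.csgraph.connected_components(graph, directed=False)
    labels = -np.ones(flat.shape, dtype=np.int64)
    labels[flat] = comp
    return labels.reshape(shape)


def _cluster_masses(t_map: np.ndarray, threshold: float,
                    adjacency: np.ndarray) -> tuple[list, list]:
    """Positive and negative cluster (member-index, t_sum) lists."""
    out = []
    for sign in (1.0, -1.0):
        mask = sign * t_map > threshold
        clusters = []
        if np.any(mask):
            labels = _label_clusters(mask, adjacency)
            for lab in range(labels.max() + 1):
                members = np.argwhere(labels == lab)
                tsum = float(t_map[tuple(members.T)].sum())
                clusters.append((members, tsum))
        out.append(clusters)
    return out[0], out[1]


def _max_masses(t_map: np.ndarray, threshold: float,
                adjacency: np.ndarray) -> tuple[float, float]:
    """Extreme cluster masses of one (permuted) t-map, with fast paths for
    the common sparse cases."""
    mx = mn = 0.0
    for sign in (1.0, -1.0):
        mask = sign * t_map > threshold
        n = np.count_nonzero(mask)
        if n == 0:
            extreme = 0.0
        elif n == 1:
            extreme = float(t_map[mask][0])
        else:
            labels = _label_clusters(mask, adjacency)
            vals = t_map[mask]
            labs = labels[mask]
            sums = np.bincount(labs, weights=vals)
            extreme = float(sums.max() if sign > 0 else sums.min())
        if sign > 0:
            mx = extreme
        else:
            mn = extreme
    return mx, mn


def cluster_permutation_test(cond_a: np.ndarray, cond_b: np.ndarray,
                             adjacency: np.ndarray,
                             n_permutations: int = 1000,
                             cluster_alpha: float = 0.001,
                             seed: int | np.random.Generator = 0,
                             ) -> list[ClusterResult]:
    """Cluster-based permutation test for a paired design.

    ``cond_a``/``cond_b``: subject-level maps shaped (n_subjects, n_channels,
    *grid) where grid is (times,) or (freqs, times).  Pointwise paired
    t-tests are thresholded two-sided at ``cluster_alpha``; supra-threshold
    points are clustered under ``adjacency`` plus grid contiguity; the null
    distribution of the maximum cluster t-sum per polarity is built from
    ``n_permutations`` random within-subject sign flips of the paired
    differences.
    """
    a = np.asarray(cond_a, dtype=float)
    b = np.asarray(cond_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("condition arrays must have identical shape")
    n_sub = a.shape[0]
    if n_sub < 2:
        raise ValueError("need at least 2 subjects")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    diff = (a - b).reshape(n_sub, -1)
    map_shape = a.shape[1:]
    threshold = float(t_dist.ppf(1 - cluster_alpha / 2, df=n_sub - 1))

    sumsq = (diff ** 2).sum(axis=0)  # invariant under sign flips

    def t_of(signs: np.ndarray) -> np.ndarray:
        """t-maps for a (n_flips, n_sub) block of sign assignments."""
        mean = signs @ diff / n_sub
        var = (sumsq[None, :] - n_sub * mean ** 2) / (n_sub - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(var > 0, mean / np.sqrt(var / n_sub), 0.0)
        return t

    t_obs = t_of(np.ones((1, n_sub)))[0].reshape(map_shape)
    pos, neg = _cluster_masses(t_obs, threshold, adjacency)
    if not pos and not neg:
        return []

    # two-sided null: distribution of the maximum |cluster mass| over both
    # polarities, so that comparing |t_sum| controls the family-wise error
    # across positive and negative clusters jointly
    max_abs = np.empty(n_permutations)
    chunk = 256
    done = 0
    while done < n_permutations:
        m = min(chunk, n_permutations - done)
        signs = rng.choice([-1.0, 1.0], size=(m, n_sub))
        t_block = t_of(signs)
        for i in range(m):
            mx, mn = _max_masses(t_block[i].reshape(map_shape), threshold,
                                 adjacency)
            max_abs[done + i] = max(mx, -mn)
        done += m

    results: list[ClusterResult] = []
    for members, tsum in pos:
        p = (1 + np.count_nonzero(max_abs >= tsum)) / (n_permutations + 1)
        results.append(ClusterResult(members=members, t_sum=tsum, p=float(p),
                                     polarity="positive"))
    for members, tsum in neg:
        p = (1 + np.count_nonzero(max_abs >= -tsum)) / (n_permutations + 1)
        results.append(ClusterResult(members=members, t_sum=tsum, p=float(p),
                                     polarity="negative"))
    results.sort(key=lambda c: -abs(c.t_sum))
    return results


def normalized_contrast(power_a: SourceGrid, power_b: SourceGrid) -> SourceGrid:
    """Bounded source contrast r = (p1 - p2) / (p1 + p2) in [-1, 1].

    Voxels where both conditions are zero map to 0.  Antisymmetric in its
    arguments.
    """
    if power_a.coords_mm.shape != power_b.coords_mm.shape or \
            not np.allclose(power_a.coords_mm, power_b.coords_mm):
        raise ValueError("source grids do not match")
    p1 = np.asarray(power_a.values, dtype=float)
    p2 = np.asarray(power_b.values, dtype=float)
    if np.any(p1 < 0) or np.any(p2 < 0):
        raise ValueError("power must be non-negative")
    s = p1 + p2
    ratio = np.zeros_like(s)
    nz = s > 0
    ratio[nz] = (p1[nz] - p2[nz]) / s[nz]
    return SourceGrid(coords_mm=power_a.coords_mm, values=ratio,
                      edge_length_mm=power_a.edge_length_mm,
                      labels=power_a.labels)


@dataclass
class VoxelCluster:
    voxel_indices: np.ndarray
    centroid_mm: np.ndarray
    mean_ratio: float


def dbscan_voxel_clusters(ratio_map: SourceGrid, tail_fraction: float = 0.01,
                          eps_factor: float = 1.5, direction: str = "positive",
                          min_samples: int = 5) -> list[VoxelCluster]:
    """Density-based clustering of the extreme tail of a contrast map.

    The most positive (or negative) ``tail_fraction`` of voxels is selected
    and clustered with DBSCAN using a neighborhood radius of ``eps_factor``
    voxel edge lengths.  Scattered extreme voxels below the density threshold
    are labeled noise and dropped.
    """
    vals = np.asarray(ratio_map.values, dtype=float)
    n_sel = max(1, int(np.ceil(tail_fraction * vals.size)))
    order = np.argsort(vals)
    sel = order[-n_sel:] if direction == "positive" else order[:n_sel]
    if sel.size == 0:
        raise ValueError("empty voxel selection")
    pts = ratio_map.coords_mm[sel]
    labels = DBSCAN(eps=eps_factor * ratio_map.edge_length_mm,
                    min_samples=min_samples).fit_predict(pts)
    clusters = []
    for lab in np.unique(labels):
        if lab == -1:
            continue
        idx = sel[labels == lab]
        clusters.append(VoxelCluster(
            voxel_indices=idx,
            centroid_mm=ratio_map.coords_mm[idx].mean(axis=0),
            mean_ratio=float(vals[idx].mean()),
        ))
    clusters.sort(key=lambda c: -abs(c.mean_ratio))
    return clusters
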