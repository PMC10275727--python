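"""Tracking-performance metrics and the sample-entropy interval analysis.

Two per-epoch error measures quantify pursuit tracking:

* **epoch error** — root-mean-squared vertical distance between target and
  cursor (pixels);
* **pursuit latency** — the time between a target direction change (a
  trajectory peak) and the following matching direction change of the cursor,
  valid when it falls between 80 and 300 ms and both extrema have the same
  direction.

Trajectory peaks are local extrema whose topographic prominence exceeds 1% of
the screen size; pursuit peaks, which carry more motor jitter, use a 5%
threshold.  Trials whose maximum tracking error exceeds the per-subject mean
by more than three standard deviations are flagged for exclusion.

Sample entropy, SampEn(m, r) = -ln(A/B), measures the predictability of the
tracking-error time series: B counts pairs of length-m templates within
Chebyshev distance r of each other (self-matches excluded), A the same for
length m+1.  Each trial interval is z-transformed before the computation, so
the similarity criterion r = 0.2 (in SD units) is identical across trials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import find_peaks
from scipy.stats import ranksums

__all__ = [
    "TrialRecord",
    "Peak",
    "PeakMatch",
    "EntropyResult",
    "upsample_coordinates",
    "epoch_error",
    "detect_peaks",
    "match_pursuit_peaks",
    "exclude_outlier_trials",
    "sample_entropy",
    "entropy_interval_test",
    "LATENCY_WINDOW_S",
]

#: Valid pursuit-latency window (seconds after a trajectory peak).
LATENCY_WINDOW_S = (0.080, 0.300)


@dataclass
class TrialRecord:
    """Target and cursor traces of one trial, plus condition tags."""

    target_y: np.ndarray
    cursor_y: np.ndarray
    frame_rate: float
    subject_id: int
    trial_id: int
    segment_labels: np.ndarray | None = None
    occluded: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.target_y = np.asarray(self.target_y, dtype=float)
        self.cursor_y = np.asarray(self.cursor_y, dtype=float)
        if self.target_y.shape != self.cursor_y.shape:
            raise ValueError("target and cursor traces must have equal length")

    @property
    def error(self) -> np.ndarray:
        """Signed per-frame tracking error (target minus cursor), pixels."""
        return self.target_y - self.cursor_y


@dataclass(frozen=True)
class Peak:
    time_s: float
    direction: str  # "max" | "min"
    prominence: float


@dataclass(frozen=True)
class PeakMatch:
    trajectory_peak_time_s: float
    pursuit_peak_time_s: float | None
    latency_s: float | None
    direction: str
    valid: bool


@dataclass
class EntropyResult:
    per_subject_first: np.ndarray
    per_subject_second: np.ndarray
    Z: float
    p: float
    effect_r: float
    n_skipped_trials: int = 0


def upsample_coordinates(trace, in_rate: float = 60.0, out_rate: float = 250.0,
                         times_s=None) -> np.ndarray:
    """Cubic-spline interpolation of a per-frame trace onto a finer grid.

    Original sample instants are reproduced exactly; output length is
    ``ceil(duration * out_rate)`` with duration = n_samples / in_rate.
    """
    y = np.asarray(trace, dtype=float)
    if y.size < 4:
        raise ValueError("need at least 4 samples for cubic interpolation")
    t = np.arange(y.size) / in_rate if times_s is None else np.asarray(times_s, float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("timestamps must be strictly increasing")
    n_out = int(np.ceil(y.size / in_rate * out_rate)) if times_s is None else \
        int(np.ceil((t[-1] - t[0] + np.median(np.diff(t))) * out_rate))
    t_out = t[0] + np.arange(n_out) / out_rate
    return CubicSpline(t, y)(t_out)


def epoch_error(target_y, cursor_y) -> float:
    """RMSE between target and cursor vertical positions (pixels)."""
    a = np.asarray(target_y, dtype=float)
    b = np.asarray(cursor_y, dtype=float)
    if a.shape != b.shape:
        raise ValueError("length mismatch between target and cursor")
    if a.size == 0:
        raise ValueError("empty traces")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def detect_peaks(series, prominence_fraction: float, screen_size_px: float,
                 rate_hz: float = 250.0) -> list[Peak]:
    """Local extrema whose prominence is at least a fraction of screen size.

    Minima are found by negating the series.  Returns peaks time-sorted.
    """
    if prominence_fraction <= 0:
        raise ValueError("prominence_fraction must be positive")
    y = np.asarray(series, dtype=float)
    thr = prominence_fraction * screen_size_px
    peaks: list[Peak] = []
    for sign, name in ((1.0, "max"), (-1.0, "min")):
        idx, props = find_peaks(sign * y, prominence=thr)
        for i, prom in zip(idx, props["prominences"]):
            peaks.append(Peak(time_s=i / rate_hz, direction=name,
                              prominence=float(prom)))
    return sorted(peaks, key=lambda p: p.time_s)


def match_pursuit_peaks(traj_peaks: list[Peak], pursuit_peaks: list[Peak],
                        window_s: tuple[float, float] = LATENCY_WINDOW_S,
                        ) -> list[PeakMatch]:
    """Pair each trajectory peak with the earliest unused same-direction
    pursuit peak that follows within the valid window.

    The assignment is one-to-one: a pursuit peak serves at most one trajectory
    peak.  Trajectory peaks without a valid partner yield an invalid match
    with null latency.
    """
    lo, hi = window_s
    used: set[int] = set()
    out: list[PeakMatch] = []
    for tp in traj_peaks:
        match_idx = None
        for j, pp in enumerate(pursuit_peaks):
            lat = pp.time_s - tp.time_s
            if lat > hi:
                break  # time-sorted: no later pursuit peak can be in-window
            if j in used or pp.direction != tp.direction or lat < lo:
                continue
            match_idx = j
            break
        if match_idx is None:
            out.append(PeakMatch(tp.time_s, None, None, tp.direction, False))
        else:
            used.add(match_idx)
            pp = pursuit_peaks[match_idx]
            out.append(PeakMatch(tp.time_s, pp.time_s, pp.time_s - tp.time_s,
                                 tp.direction, True))
    return out


def exclude_outlier_trials(max_errors_per_trial, n_sd: float = 3.0,
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Flag trials whose maximum |error| exceeds mean + n_sd * SD.

    Operates within subject.  Returns ``(kept_indices, flagged_indices)``.
    With zero spread across trials nothing is flagged.
    """
    mx = np.asarray(max_errors_per_trial, dtype=float)
    if mx.size < 2:
        raise ValueError("need at least 2 trials")
    sd = np.std(mx, ddof=1)
    if sd == 0:
        return np.arange(mx.size), np.array([], dtype=int)
    flagged = np.flatnonzero(mx > np.mean(mx) + n_sd * sd)
    kept = np.setdiff1d(np.arange(mx.size), flagged)
    return kept, flagged


def sample_entropy(series, m: int = 2, r: float | None = None) -> float:
    """SampEn(m, r): -ln(A/B) with Chebyshev distance, self-matches excluded.

    ``r`` defaults to 0.2 times the sample SD of the series.  Raises on
    zero-variance input (the similarity criterion would be degenerate).
    Returns ``inf`` when no template of length m+1 repeats (A = 0).
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if n <= m + 1:
        raise ValueError(f"series length {n} too short for m={m}")
    sd = np.std(x)
    if sd == 0:
        raise ValueError("zero-variance series: similarity criterion undefined")
    if r is None:
        r = 0.2 * sd

    def _count(mm: int) -> int:
        n_templates = n - m  # same template count for both lengths
        templ = np.lib.stride_tricks.sliding_window_view(x, mm)[:n_templates]
        # pairwise Chebyshev distances, upper triangle (i < j)
        d = np.abs(templ[:, None, :] - templ[None, :, :]).max(axis=-1)
        iu = np.triu_indices(n_templates, k=1)
        return int(np.count_nonzero(d[iu] <= r))

    B = _count(m)
    A = _count(m + 1)
    if B == 0:
        raise ValueError("no matching templates of length m; entropy undefined")
    if A == 0:
        return float("inf")
    return float(-np.log(A / B))


def entropy_interval_test(error_traces_by_subject: dict[int, list[np.ndarray]],
                          rate_hz: float = 250.0,
                          split_at_s: float = 0.5,
                          horizon_s: float = 2.0,
                          m: int = 2,
                          r: float = 0.2,
                          reducer: str = "median") -> EntropyResult:
    """Compare tracking-error sample entropy of the first 500 ms of each trial
    with the following 1500 ms.

    Each interval is z-transformed per trial before SampEn(m, r) is computed,
    so r is in SD units and identical across trials.  Per-subject values are
    aggregated with ``reducer`` (median by default) and compared across
    subjects with a Wilcoxon rank-sum test; the effect size is r = Z / sqrt(N).
    Trials with a degenerate (zero-variance) interval are skipped and counted.
    """
    red = {"median": np.median, "mean": np.mean}[reducer]
    split = int(round(split_at_s * rate_hz))
    stop = int(round(horizon_s * rate_hz))
    firsts, seconds = [], []
    n_skipped = 0
    for subj in sorted(error_traces_by_subject):
        se1, se2 = [], []
        for err in error_traces_by_subject[subj]:
            err = np.asarray(err, dtype=float)
            if err.size < stop:
                n_skipped += 1
                continue
            try:
                seg1 = err[:split]
                seg2 = err[split:stop]
                z1 = (seg1 - seg1.mean()) / seg1.std()
                z2 = (seg2 - seg2.mean()) / seg2.std()
                e1 = sample_entropy(z1, m=m, r=r)
                e2 = sample_entropy(z2, m=m, r=r)
            except (ValueError, FloatingPointError):
                n_skipped += 1
                continue
            if np.isfinite(e1) and np.isfinite(e2):
                se1.append(e1)
                se2.append(e2)
            else:
                n_skipped += 1
        if se1 and se2:
            firsts.append(red(se1))
            seconds.append(red(se2))
    firsts = np.asarray(firsts)
    seconds = np.asarray(seconds)
    if firsts.size < 2:
        raise ValueError("need at least 2 subjects with usable trials")
    stat = ranksums(firsts, seconds)
    z = float(stat.statistic)
    n = firsts.size
    return EntropyResult(
        per_subject_first=firsts, per_subject_second=seconds,
        Z=z, p=float(stat.pvalue), effect_r=z / np.sqrt(n),
        n_skipped_trials=n_skipped,
    )


def effect_size_r(z: float, n: int) -> float:
    """Rank-statistic effect size convention r = Z / sqrt(N)."""
    return z / np.sqrt(n)
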