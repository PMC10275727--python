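"""Pursuit-tracking task design: target trajectories and session plans.

The target moves horizontally at constant speed while its vertical position
follows a three-segment path.  Each segment is a truncated Fourier series

    f(x) = sum_{i=1..3} a_i * sin(i*x) + b_i * cos(i*x)

with coefficients in pixels.  The first and last segments use random
coefficients drawn uniformly from [-40, 40] px (resampled until the segment
stays on screen); the middle segment is the same on every trial, with fixed
coefficients a = (37, -3, 26), b = (23, -15, -9).  Segments are separated by a
30-px horizontal gap bridged with a cubic spline, and every trial opens with a
short straight start vector at screen-center height.

Two task variants exist: task 1 is plain pursuit tracking; task 2 additionally
occludes the cursor for 2 s out of every 4 s, starting with a visible cursor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

__all__ = [
    "CONSTANT_SEGMENT",
    "ScreenGeometry",
    "SegmentCoefficients",
    "Trajectory",
    "SessionPlan",
    "evaluate_segment",
    "sample_random_coefficients",
    "concatenate_segments",
    "build_trajectory",
    "build_session_plan",
    "occlusion_mask",
]

#: Vertical segment labels, in within-trial order (gaps interleaved).
SEGMENT_ORDER = ("random1", "constant", "random2")

#: Velocity level -> trial duration in seconds (mean over levels is 12 s).
TRIAL_DURATIONS_S = {1: 13.5, 2: 12.0, 3: 10.5}

BEHAVIOR_RATE_HZ = 60.0
GAP_PX = 30.0
START_VECTOR_S = 0.5


@dataclass(frozen=True)
class ScreenGeometry:
    """Virtual screen used for trajectory bounds and prominence thresholds."""

    width_px: int = 1920
    height_px: int = 1080
    target_size_px: int = 32

    @property
    def center_y(self) -> float:
        return self.height_px / 2.0

    @property
    def max_excursion_px(self) -> float:
        """Largest |f(x)| that keeps the whole target on screen."""
        return self.height_px / 2.0 - self.target_size_px / 2.0


@dataclass(frozen=True)
class SegmentCoefficients:
    """Sine/cosine amplitudes (pixels) of one trajectory segment."""

    a: tuple[float, float, float]
    b: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.a) != 3 or len(self.b) != 3:
            raise ValueError("SegmentCoefficients requires exactly 3 sine and "
                             "3 cosine amplitudes")
        object.__setattr__(self, "a", tuple(float(v) for v in self.a))
        object.__setattr__(self, "b", tuple(float(v) for v in self.b))


#: Fixed coefficients of the repeated middle segment.
CONSTANT_SEGMENT = SegmentCoefficients(a=(37.0, -3.0, 26.0), b=(23.0, -15.0, -9.0))


@dataclass
class Trajectory:
    """Per-frame target path of one trial.

    ``y`` is the vertical position in screen pixels (0 = top), ``x`` the
    horizontal position.  ``segment_labels`` tags every frame with one of
    ``start_vector, random1, constant, random2, gap``.
    """

    y: np.ndarray
    x: np.ndarray
    frame_rate: float
    segment_labels: np.ndarray
    direction: str  # "left" | "right"
    velocity_level: int
    screen: ScreenGeometry = field(default_factory=ScreenGeometry)

    @property
    def n_frames(self) -> int:
        return len(self.y)

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate

    def to_frame(self, occluded: np.ndarray | None = None) -> pd.DataFrame:
        occ = np.zeros(self.n_frames, dtype=bool) if occluded is None else occluded
        return pd.DataFrame(
            {
                "frame": np.arange(self.n_frames),
                "time_s": self.times_s,
                "x_px": self.x,
                "y_px": self.y,
                "segment_label": self.segment_labels,
                "occluded": occ,
            }
        )


@dataclass
class SessionPlan:
    """Counterbalanced trial order of one session."""

    task: int
    seed: int
    trials: list[dict]  # direction, velocity_level, trajectory_seed
    fixation_durations_s: list[float]
    break_positions: list[int]
    occlusion_intervals: list[list[tuple[float, float]]]

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def to_json(self) -> str:
        return json.dumps(
            {
                "task": self.task,
                "seed": self.seed,
                "trials": self.trials,
                "fixation_durations_s": self.fixation_durations_s,
                "break_positions": self.break_positions,
                "occlusion_intervals": [
                    [list(iv) for iv in ivs] for ivs in self.occlusion_intervals
                ],
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "SessionPlan":
        d = json.loads(text)
        return cls(
            task=d["task"],
            seed=d["seed"],
            trials=d["trials"],
            fixation_durations_s=d["fixation_durations_s"],
            break_positions=d["break_positions"],
            occlusion_intervals=[
                [tuple(iv) for iv in ivs] for ivs in d["occlusion_intervals"]
            ],
        )


def evaluate_segment(coeffs: SegmentCoefficients, x_values) -> np.ndarray:
    """Evaluate ``f(x) = sum_i a_i sin(i x) + b_i cos(i x)`` elementwise.

    Pure function; ``x_values`` may be scalar or array, result is in pixels
    relative to the segment's vertical center.
    """
    x = np.asarray(x_values, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("x_values must be finite")
    out = np.zeros_like(x)
    for i in (1, 2, 3):
        out += coeffs.a[i - 1] * np.sin(i * x) + coeffs.b[i - 1] * np.cos(i * x)
    return out


def _segment_within_bounds(coeffs: SegmentCoefficients,
                           screen: ScreenGeometry,
                           n_scan: int = 512) -> bool:
    x = np.linspace(0.0, 2.0 * np.pi, n_scan)
    return bool(np.max(np.abs(evaluate_segment(coeffs, x))) < screen.max_excursion_px)


def sample_random_coefficients(
    rng: np.random.Generator | int,
    screen: ScreenGeometry | None = None,
    coeff_bound_px: float = 40.0,
    max_attempts: int = 1000,
) -> SegmentCoefficients:
    """Draw uniform coefficients in [-bound, bound], resampling until the
    segment stays within the vertical screen bounds."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    screen = screen or ScreenGeometry()
    for _ in range(max_attempts):
        vals = rng.uniform(-coeff_bound_px, coeff_bound_px, size=6)
        coeffs = SegmentCoefficients(a=tuple(vals[:3]), b=tuple(vals[3:]))
        if _segment_within_bounds(coeffs, screen):
            return coeffs
    raise RuntimeError(f"no in-bounds segment found in {max_attempts} attempts")


def concatenate_segments(
    seg1: np.ndarray,
    seg2: np.ndarray,
    seg3: np.ndarray,
    gap_frames: int,
    labels: tuple[str, str, str] = SEGMENT_ORDER,
) -> tuple[np.ndarray, np.ndarray]:
    """Join three evaluated segments with spline-bridged gaps.

    Each gap spans ``gap_frames`` frames (the 30-px horizontal gap at the
    trial's horizontal speed).  The bridge is a cubic spline through the two
    flanking samples on either side, so every original segment sample is
    preserved unchanged.  Returns ``(y, labels_per_frame)``.
    """
    segs = [np.asarray(s, dtype=float) for s in (seg1, seg2, seg3)]
    for s in segs:
        if s.size == 0:
            raise ValueError("empty segment")
        if s.size < 2:
            raise ValueError("segments need at least 2 samples to anchor the bridge")

    y_parts: list[np.ndarray] = []
    lab_parts: list[np.ndarray] = []
    for k, (s, lab) in enumerate(zip(segs, labels)):
        if k > 0 and gap_frames > 0:
            prev = segs[k - 1]
            # anchors: last two samples of prev, first two of next, on the
            # frame grid; bridge evaluated strictly between them
            n_prev = sum(p.size for p in [segs[j] for j in range(k)]) + (k - 1) * gap_frames
            xs = np.array([n_prev - 2, n_prev - 1,
                           n_prev + gap_frames, n_prev + gap_frames + 1], dtype=float)
            ys = np.array([prev[-2], prev[-1], s[0], s[1]])
            spline = CubicSpline(xs, ys)
            bridge_x = np.arange(n_prev, n_prev + gap_frames, dtype=float)
            y_parts.append(spline(bridge_x))
            lab_parts.append(np.full(gap_frames, "gap", dtype=object))
        y_parts.append(s)
        lab_parts.append(np.full(s.size, lab, dtype=object))
    return np.concatenate(y_parts), np.concatenate(lab_parts).astype(str)


def build_trajectory(
    direction: str,
    velocity_level: int,
    seed: int,
    screen: ScreenGeometry | None = None,
    frame_rate: float = BEHAVIOR_RATE_HZ,
) -> Trajectory:
    """Assemble one trial's target path on the frame grid.

    The trajectory parameter x advances linearly with the target's horizontal
    position; each segment spans one full period (2*pi).  Horizontal speed is
    set by the velocity level so that trial durations are 13.5 / 12 / 10.5 s
    for levels 1-3 across the screen width.
    """
    if direction not in ("left", "right"):
        raise ValueError(f"direction must be 'left' or 'right', got {direction!r}")
    if velocity_level not in TRIAL_DURATIONS_S:
        raise ValueError(f"velocity_level must be in {sorted(TRIAL_DURATIONS_S)}")
    screen = screen or ScreenGeometry()
    rng = np.random.default_rng(seed)

    duration = TRIAL_DURATIONS_S[velocity_level]
    n_frames = int(round(duration * frame_rate))
    speed_px = screen.width_px / n_frames  # px per frame

    start_frames = int(round(START_VECTOR_S * frame_rate))
    gap_frames = max(1, int(round(GAP_PX / speed_px)))
    seg_frames = (n_frames - start_frames - 2 * gap_frames) // 3
    if seg_frames < 8:
        raise ValueError("trial too short for three segments")

    x_param = np.linspace(0.0, 2.0 * np.pi, seg_frames, endpoint=False)
    rand1 = sample_random_coefficients(rng, screen)
    rand2 = sample_random_coefficients(rng, screen)
    seg_ys = [evaluate_segment(c, x_param) for c in (rand1, CONSTANT_SEGMENT, rand2)]

    y_body, labels_body = concatenate_segments(*seg_ys, gap_frames=gap_frames)
    # pad so every frame is labeled even when division left a remainder
    n_body = n_frames - start_frames
    if y_body.size < n_body:
        pad = n_body - y_body.size
        y_body = np.concatenate([y_body, np.full(pad, y_body[-1])])
        labels_body = np.concatenate([labels_body, np.full(pad, "random2")])
    y = np.concatenate([np.zeros(start_frames), y_body[:n_body]]) + screen.center_y
    labels = np.concatenate(
        [np.full(start_frames, "start_vector"), labels_body[:n_body]]
    ).astype(str)

    x = np.arange(n_frames) * speed_px
    if direction == "left":
        x = screen.width_px - x  # mirror horizontal axis only; y identical

    return Trajectory(
        y=y, x=x, frame_rate=frame_rate, segment_labels=labels,
        direction=direction, velocity_level=velocity_level, screen=screen,
    )


def occlusion_mask(times_s: np.ndarray,
                   visible_s: float = 2.0,
                   occluded_s: float = 2.0) -> np.ndarray:
    """Cursor-occlusion mask: 2 s occluded out of every 4 s, trial starts
    visible.  True where the cursor is hidden."""
    cycle = visible_s + occluded_s
    return (np.asarray(times_s) % cycle) >= visible_s


def build_session_plan(task: int, seed: int,
                       n_repeats: int = 12,
                       break_every: int = 10,
                       fixation_range_s: tuple[float, float] = (1.0, 2.0),
                       ) -> SessionPlan:
    """Counterbalanced session: 2 directions x 3 velocities x 12 repeats =
    72 trials, seeded shuffle, a 30-s break after every 10 trials, and
    fixation durations uniform on [1, 2] s (mean 1.5 s).  Task-2 plans carry
    the 2-s-on/2-s-off occlusion intervals."""
    if task not in (1, 2):
        raise ValueError(f"task must be 1 or 2, got {task}")
    rng = np.random.default_rng(seed)
    cells = [(d, v) for d in ("left", "right") for v in (1, 2, 3)]
    trials = [
        {"direction": d, "velocity_level": v}
        for d, v in cells for _ in range(n_repeats)
    ]
    order = rng.permutation(len(trials))
    trials = [trials[i] for i in order]
    for i, tr in enumerate(trials):
        tr["trajectory_seed"] = int(rng.integers(0, 2**31 - 1))
        tr["trial_id"] = i

    fixations = rng.uniform(*fixation_range_s, size=len(trials)).tolist()
    breaks = list(range(break_every, len(trials), break_every))

    occl: list[list[tuple[float, float]]] = []
    for tr in trials:
        if task == 1:
            occl.append([])
        else:
            dur = TRIAL_DURATIONS_S[tr["velocity_level"]]
            ivs, t = [], 2.0
            while t < dur:
                ivs.append((t, min(t + 2.0, dur)))
                t += 4.0
            occl.append(ivs)

    return SessionPlan(
        task=task, seed=seed, trials=trials,
        fixation_durations_s=fixations, break_positions=breaks,
        occlusion_intervals=occl,
    )
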