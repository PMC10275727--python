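"""Synthetic cursor behavior and EEG with known ground truth.

Every downstream stage of the pipeline is testable without real recordings:
the generator produces cursor traces from a first-order tracking model and
multichannel EEG from 1/f noise plus injected band oscillations and
peak-locked potentials, and returns a manifest of every injected effect.

Cursor model
------------
The cursor sits at screen center during an initial dead time (participants
typically do not move the joystick during the first ~500 ms of a trial), then
follows a lag-shifted copy of the target through a first-order low-pass
(exponential smoothing with time constant tau), plus white Gaussian motor
noise per frame.  While the cursor is occluded the noise SD is multiplied by
``occlusion_noise_gain``, producing the larger occluded tracking error.

EEG model
---------
Each channel carries 1/f^exponent background noise (spectral shaping of white
noise), band-limited oscillations whose amplitude is scaled per experimental
condition, and an event-related template added at every target direction
change.  The montage is a deterministic set of 60 roughly equidistant
positions on the upper unit hemisphere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .task_design import (
    ScreenGeometry,
    SessionPlan,
    Trajectory,
    build_session_plan,
    build_trajectory,
    occlusion_mask,
)

__all__ = [
    "CursorModelParams",
    "EEGEffectSpec",
    "SyntheticStudy",
    "make_montage",
    "simulate_cursor",
    "one_over_f_noise",
    "simulate_eeg",
    "make_study",
]

EEG_RATE_HZ = 250.0

BANDS = {"theta": (4.0, 7.0), "alpha": (8.0, 12.0), "beta": (13.0, 30.0)}


@dataclass(frozen=True)
class CursorModelParams:
    """First-order tracking model parameters."""

    dead_time_s: float = 0.5
    lag_s: float = 0.15
    smoothing_tau_s: float = 0.05
    motor_noise_sd_px: float = 8.0
    occlusion_noise_gain: float = 2.0

    def __post_init__(self) -> None:
        if min(self.dead_time_s, self.lag_s, self.smoothing_tau_s,
               self.motor_noise_sd_px, self.occlusion_noise_gain) < 0:
            raise ValueError("cursor model parameters must be non-negative")
        if not 0 <= self.lag_s <= 0.5:
            raise ValueError("lag_s must lie in [0, 0.5] s")


@dataclass
class EEGEffectSpec:
    """Injected EEG effects: per-band condition amplitudes, an ERP template,
    the 1/f noise exponent, and which channels carry the effects.

    ``band_effects`` maps band name -> {condition: amplitude (uV)};
    ``erp_template`` maps condition -> 1-d array on the -500..750 ms grid.
    """

    band_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    erp_template: dict[str, np.ndarray] = field(default_factory=dict)
    noise_exponent: float = 1.0
    noise_scale_uv: float = 10.0
    channels_affected: np.ndarray | None = None

    def __post_init__(self) -> None:
        for band in self.band_effects:
            if band not in BANDS:
                raise ValueError(f"unknown band {band!r}; expected one of {sorted(BANDS)}")


def make_montage(n_channels: int = 60, radius_m: float = 0.095) -> np.ndarray:
    """Deterministic, roughly equidistant electrode positions on the upper
    hemisphere (Fibonacci lattice), in head coordinates (meters).

    Emulates an equidistant 60-channel cap layout.
    """
    i = np.arange(n_channels)
    golden = (1 + 5 ** 0.5) / 2
    # z from just above equator to vertex; azimuth by golden angle
    z = 0.05 + (1.0 - 0.1) * (i + 0.5) / n_channels
    phi = 2 * np.pi * i / golden
    r_xy = np.sqrt(np.clip(1 - z**2, 0, None))
    pts = np.column_stack([r_xy * np.cos(phi), r_xy * np.sin(phi), z])
    return pts * radius_m


def simulate_cursor(trajectory: Trajectory, params: CursorModelParams,
                    seed: int | np.random.Generator = 0,
                    occluded: np.ndarray | None = None) -> np.ndarray:
    """Simulate a cursor trace tracking the target.

    cursor = screen center during the dead time, then an exponentially
    smoothed, lag-shifted copy of the target plus per-frame Gaussian noise.
    With tau -> 0, zero lag, zero noise and zero dead time the cursor equals
    the target exactly.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fs = trajectory.frame_rate
    target = trajectory.y
    n = target.size
    center = trajectory.screen.center_y

    lag_frames = int(round(params.lag_s * fs))
    dead_frames = int(round(params.dead_time_s * fs))
    # lag-shifted target (held at its first value before the lag elapses)
    lagged = np.concatenate([np.full(lag_frames, target[0]), target])[:n]

    alpha = 1.0 if params.smoothing_tau_s <= 0 else \
        1.0 - np.exp(-1.0 / (fs * params.smoothing_tau_s))
    cursor = np.empty(n)
    state = center
    for t in range(n):
        if t < dead_frames:
            cursor[t] = center
            state = center
        else:
            state = state + alpha * (lagged[t] - state)
            cursor[t] = state

    noise_sd = np.full(n, params.motor_noise_sd_px)
    if occluded is not None:
        noise_sd[np.asarray(occluded, bool)] *= params.occlusion_noise_gain
    noise_sd[:dead_frames] = 0.0
    return cursor + rng.standard_normal(n) * noise_sd


def one_over_f_noise(n_samples: int, rate_hz: float, exponent: float,
                     rng: np.random.Generator, size: int = 1) -> np.ndarray:
    """Power-law noise via spectral shaping: white noise whose amplitude
    spectrum is multiplied by f^(-exponent/2), unit variance per row."""
    white = rng.standard_normal((size, n_samples))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / rate_hz)
    shaping = np.ones_like(freqs)
    shaping[1:] = freqs[1:] ** (-exponent / 2.0)
    shaping[0] = 0.0
    out = np.fft.irfft(spec * shaping, n=n_samples, axis=-1)
    sd = out.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return out / sd


def _band_oscillation(n_samples: int, rate_hz: float, band: tuple[float, float],
                      rng: np.random.Generator, size: int = 1) -> np.ndarray:
    """Unit-RMS band-limited Gaussian noise (hard spectral mask)."""
    white = rng.standard_normal((size, n_samples))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / rate_hz)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    spec[:, ~mask] = 0.0
    out = np.fft.irfft(spec, n=n_samples, axis=-1)
    sd = out.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return out / sd


def simulate_eeg(events: list[tuple[float, str]], montage: np.ndarray,
                 spec: EEGEffectSpec, duration_s: float,
                 condition_windows: list[tuple[float, float, str]] | None = None,
                 rate_hz: float = EEG_RATE_HZ,
                 seed: int | np.random.Generator = 0,
                 ) -> tuple[np.ndarray, list[dict]]:
    """Synthesize continuous multichannel EEG.

    Parameters
    ----------
    events : list of (time_s, condition) pairs; the condition's ERP template
        (if any) is added at each event on the affected channels.
    condition_windows : list of (start_s, stop_s, condition); band-limited
        oscillations are scaled by the condition's band amplitude inside each
        window (amplitude 0 outside all windows unless a "baseline" amplitude
        is given for the band).

    Returns ``(data, effect_log)`` with data shaped (n_channels, n_samples)
    in uV and a ground-truth log of every injected effect.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_ch = montage.shape[0]
    n = int(round(duration_s * rate_hz))
    for t, _ in events:
        if not 0 <= t <= duration_s:
            raise ValueError(f"event at {t} s outside recording span")

    data = spec.noise_scale_uv * one_over_f_noise(n, rate_hz, spec.noise_exponent,
                                                  rng, size=n_ch)
    affected = np.arange(n_ch) if spec.channels_affected is None \
        else np.asarray(spec.channels_affected, dtype=int)
    log: list[dict] = []

    times = np.arange(n) / rate_hz
    for band, cond_amps in spec.band_effects.items():
        osc = _band_oscillation(n, rate_hz, BANDS[band], rng, size=len(affected))
        gain = np.zeros(n)
        if condition_windows:
            for start, stop, cond in condition_windows:
                amp = cond_amps.get(cond, 0.0)
                gain[(times >= start) & (times < stop)] = amp
        base = cond_amps.get("baseline", 0.0)
        gain[gain == 0] = base
        data[affected] += osc * gain[None, :]
        log.append({"kind": "band", "band": band, "amplitudes": dict(cond_amps),
                    "channels": affected.tolist()})

    for t, cond in events:
        template = spec.erp_template.get(cond)
        if template is None:
            continue
        template = np.asarray(template, dtype=float)
        onset = int(round(t * rate_hz)) - int(round(0.5 * rate_hz))
        sl = slice(max(onset, 0), min(onset + template.size, n))
        tpl = template[sl.start - onset: sl.stop - onset]
        data[np.ix_(affected, np.arange(sl.start, sl.stop))] += tpl[None, :]
    if spec.erp_template:
        log.append({"kind": "erp", "conditions": sorted(spec.erp_template),
                    "channels": affected.tolist()})
    return data, log


@dataclass
class SyntheticStudy:
    """Full synthetic dataset: session plans, trajectories, cursor traces,
    per-trial EEG, montage, and a ground-truth manifest."""

    task: int
    seed: int
    plans: dict[int, SessionPlan]
    trajectories: dict[int, list[Trajectory]]
    cursor_traces: dict[int, list[np.ndarray]]
    occlusion: dict[int, list[np.ndarray]]
    cursor_params: dict[int, CursorModelParams]
    eeg: dict[int, list[np.ndarray]] | None
    eeg_events: dict[int, list[list[tuple[float, str]]]] | None
    montage: np.ndarray | None
    manifest: dict

    @property
    def subjects(self) -> list[int]:
        return sorted(self.plans)

    @property
    def n_trials(self) -> int:
        return sum(p.n_trials for p in self.plans.values())


def make_study(n_subjects: int = 30, task: int = 1,
               cursor_params_per_subject: list[CursorModelParams] | None = None,
               eeg_spec: EEGEffectSpec | None = None,
               seed: int = 0,
               n_trials: int | None = None,
               with_eeg: bool = False) -> SyntheticStudy:
    """Generate a full synthetic study (behavior and, optionally, EEG).

    Defaults mirror the study conditions: 30 subjects, 72 trials per subject
    per task, 60 Hz behavior and 250 Hz EEG.  ``n_trials`` can subsample the
    session for quick experiments.  The manifest records every injected
    parameter for downstream parameter-recovery tests.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    root = np.random.default_rng(seed)
    if cursor_params_per_subject is None:
        # mild between-subject variation around the default tracker
        cursor_params_per_subject = [
            CursorModelParams(
                dead_time_s=0.5,
                lag_s=float(np.clip(root.normal(0.15, 0.02), 0.05, 0.3)),
                smoothing_tau_s=0.05,
                motor_noise_sd_px=float(np.clip(root.normal(8.0, 1.5), 3.0, 15.0)),
            )
            for _ in range(n_subjects)
        ]
    montage = make_montage() if with_eeg else None

    plans, trajs, cursors, occls = {}, {}, {}, {}
    eeg_data: dict[int, list[np.ndarray]] = {}
    eeg_events: dict[int, list[list[tuple[float, str]]]] = {}
    params_by_subj: dict[int, CursorModelParams] = {}

    for s in range(n_subjects):
        subj_seed = int(root.integers(0, 2**31 - 1))
        plan = build_session_plan(task, seed=subj_seed)
        sel = plan.trials if n_trials is None else plan.trials[:n_trials]
        params = cursor_params_per_subject[s]
        params_by_subj[s] = params
        t_list, c_list, o_list, e_list, ev_list = [], [], [], [], []
        rng = np.random.default_rng(subj_seed + 1)
        for tr, occ_iv in zip(sel, plan.occlusion_intervals):
            traj = build_trajectory(tr["direction"], tr["velocity_level"],
                                    tr["trajectory_seed"])
            occ = occlusion_mask(traj.times_s) if task == 2 else \
                np.zeros(traj.n_frames, dtype=bool)
            cursor = simulate_cursor(traj, params, seed=rng, occluded=occ)
            t_list.append(traj)
            c_list.append(cursor)
            o_list.append(occ)
            if with_eeg and eeg_spec is not None:
                from .behavior import detect_peaks  # avoid cycle at import time
                peaks = detect_peaks(traj.y, 0.01, traj.screen.height_px,
                                     rate_hz=traj.frame_rate)
                events = []
                for p in peaks:
                    idx = int(p.time_s * traj.frame_rate)
                    if task == 2:
                        cond = "occluded" if occ[min(idx, occ.size - 1)] else "visible"
                    else:
                        cond = traj.segment_labels[min(idx, traj.n_frames - 1)]
                    events.append((p.time_s, cond))
                data, _ = simulate_eeg(events, montage, eeg_spec,
                                       duration_s=traj.duration_s, seed=rng)
                e_list.append(data)
                ev_list.append(events)
        plans[s] = plan
        trajs[s] = t_list
        cursors[s] = c_list
        occls[s] = o_list
        if with_eeg:
            eeg_data[s] = e_list
            eeg_events[s] = ev_list

    manifest = {
        "task": task, "seed": seed, "n_subjects": n_subjects,
        "cursor_params": [
            {"subject": s, "dead_time_s": p.dead_time_s, "lag_s": p.lag_s,
             "smoothing_tau_s": p.smoothing_tau_s,
             "motor_noise_sd_px": p.motor_noise_sd_px,
             "occlusion_noise_gain": p.occlusion_noise_gain}
            for s, p in params_by_subj.items()
        ],
        "eeg_effects": None if eeg_spec is None else {
            "band_effects": eeg_spec.band_effects,
            "noise_exponent": eeg_spec.noise_exponent,
            "erp_conditions": sorted(eeg_spec.erp_template),
        },
    }
    return SyntheticStudy(
        task=task, seed=seed, plans=plans, trajectories=trajs,
        cursor_traces=cursors, occlusion=occls, cursor_params=params_by_subj,
        eeg=eeg_data if with_eeg else None,
        eeg_events=eeg_events if with_eeg else None,
        montage=montage, manifest=manifest,
    )
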