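"""Configuration, file formats and round-trip readers/writers.

Behavioral data travel as CSV in a fixed dialect (one row per frame); EEG as
an HDF5 container with ``/data`` (channels x samples), ``/montage`` and
``/events`` groups, or as a BrainVision triad (vhdr/vmrk text plus IEEE
float32 binary) read through MNE.  ``StudyConfig`` collects every analysis
constant with the study's values as defaults and round-trips losslessly
through YAML/JSON.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .behavior import TrialRecord

__all__ = [
    "StudyConfig",
    "write_behavior",
    "read_behavior",
    "write_eeg_container",
    "read_eeg",
    "write_brainvision",
]

BEHAVIOR_COLUMNS = ["subject", "trial", "frame", "time_s", "x_px", "y_px",
                    "cursor_y_px", "segment_label", "occluded"]


@dataclass
class StudyConfig:
    """All analysis constants, with the study's values as defaults."""

    task: int = 1
    seed: int = 0
    screen_width_px: int = 1920
    screen_height_px: int = 1080
    behavior_rate_hz: float = 60.0
    eeg_rate_hz: float = 250.0
    traj_prominence_fraction: float = 0.01
    pursuit_prominence_fraction: float = 0.05
    latency_window_s: tuple[float, float] = (0.080, 0.300)
    entropy_m: int = 2
    entropy_r: float = 0.2
    entropy_split_s: float = 0.5
    entropy_horizon_s: float = 2.0
    vincentile_k: int = 10
    n_boot: int = 5000
    boot_alpha: float = 0.001
    fdr_q: float = 0.05
    tfr_n_cycles: float = 5.0
    tfr_n_permutations: int = 1000
    erp_n_permutations: int = 3000
    cluster_alpha: float = 0.001
    erp_min_neighbors: int = 4
    exclusion_n_sd: float = 3.0
    n_subjects: int = 30

    def __post_init__(self) -> None:
        if self.task not in (1, 2):
            raise ValueError(f"task must be 1 or 2, got {self.task}")
        self.latency_window_s = tuple(self.latency_window_s)

    def to_yaml(self) -> str:
        d = asdict(self)
        d["latency_window_s"] = list(self.latency_window_s)
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "StudyConfig":
        return cls(**yaml.safe_load(text))

    def hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def write_behavior(path, records: list[TrialRecord],
                   x_px: dict[tuple[int, int], np.ndarray] | None = None) -> None:
    """Write trial records to the behavioral CSV dialect."""
    rows = []
    for rec in records:
        n = rec.target_y.size
        occ = rec.occluded if rec.occluded is not None else np.zeros(n, bool)
        labels = rec.segment_labels if rec.segment_labels is not None \
            else np.full(n, "", dtype=object)
        xs = (x_px or {}).get((rec.subject_id, rec.trial_id),
                              np.full(n, np.nan))
        rows.append(pd.DataFrame({
            "subject": rec.subject_id, "trial": rec.trial_id,
            "frame": np.arange(n),
            "time_s": np.arange(n) / rec.frame_rate,
            "x_px": xs, "y_px": rec.target_y, "cursor_y_px": rec.cursor_y,
            "segment_label": labels, "occluded": np.asarray(occ, bool),
        }))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False,
                                              columns=BEHAVIOR_COLUMNS)


def read_behavior(path) -> list[TrialRecord]:
    """Read trial records; frame rate is inferred from the timestamps."""
    df = pd.read_csv(path)
    missing = set(BEHAVIOR_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"missing required columns: {sorted(missing)}")
    bad = df[~np.isfinite(pd.to_numeric(df["y_px"], errors="coerce"))]
    if len(bad):
        raise ValueError(f"non-numeric y_px at rows {bad.index.tolist()[:5]}")
    records = []
    for (subj, trial), g in df.groupby(["subject", "trial"], sort=True):
        dt = np.median(np.diff(g["time_s"].to_numpy()))
        records.append(TrialRecord(
            target_y=g["y_px"].to_numpy(float),
            cursor_y=g["cursor_y_px"].to_numpy(float),
            frame_rate=float(round(1.0 / dt)),
            subject_id=int(subj), trial_id=int(trial),
            segment_labels=g["segment_label"].to_numpy(str),
            occluded=g["occluded"].to_numpy(bool),
        ))
    return records


def write_eeg_container(path, data: np.ndarray, rate_hz: float,
                        montage: np.ndarray,
                        events: list[tuple[float, str]] | None = None) -> None:
    """Write the internal HDF5 EEG container (/data, /montage, /events)."""
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("data", data=np.asarray(data, dtype=np.float64))
        ds.attrs["rate_hz"] = float(rate_hz)
        f.create_dataset("montage", data=np.asarray(montage, dtype=np.float64))
        ev = events or []
        f.create_dataset("events/time_s",
                         data=np.array([t for t, _ in ev], dtype=np.float64))
        f.create_dataset("events/condition",
                         data=np.array([c for _, c in ev], dtype="S32"))


def read_eeg(path):
    """Read EEG from the HDF5 container or a BrainVision header.

    Returns ``(data, rate_hz, montage, events)``; montage/events are None
    when the format does not carry them.
    """
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            data = f["data"][()]
            rate = float(f["data"].attrs["rate_hz"])
            montage = f["montage"][()]
            events = list(zip(f["events/time_s"][()].tolist(),
                              [c.decode() for c in f["events/condition"][()]]))
        return data, rate, montage, events
    if path.suffix == ".vhdr":
        import mne
        raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
        return raw.get_data(), float(raw.info["sfreq"]), None, None
    raise ValueError(f"unknown EEG format: {path.suffix!r}")


def write_brainvision(basename, data: np.ndarray, rate_hz: float,
                      ch_names: list[str] | None = None) -> Path:
    """Write a minimal BrainVision triad (vhdr/vmrk + IEEE float32 .eeg,
    multiplexed) for interoperability.  Returns the vhdr path."""
    base = Path(basename)
    data = np.asarray(data, dtype=np.float32)
    n_ch = data.shape[0]
    names = ch_names or [f"E{i:03d}" for i in range(n_ch)]
    eeg_path = base.with_suffix(".eeg")
    vmrk_path = base.with_suffix(".vmrk")
    vhdr_path = base.with_suffix(".vhdr")

    data.T.ravel().tofile(eeg_path)  # multiplexed: sample-major
    vhdr = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "[Common Infos]",
        f"DataFile={eeg_path.name}",
        f"MarkerFile={vmrk_path.name}",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={n_ch}",
        f"SamplingInterval={1e6 / rate_hz:.6f}",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "[Channel Infos]",
    ]
    vhdr += [f"Ch{i + 1}={nm},,1,µV" for i, nm in enumerate(names)]
    vhdr_path.write_text("\n".join(vhdr) + "\n", encoding="utf-8")
    vmrk_path.write_text(
        "Brain Vision Data Exchange Marker File, Version 1.0\n"
        "[Common Infos]\n"
        f"DataFile={eeg_path.name}\n"
        "[Marker Infos]\n"
        "Mk1=New Segment,,1,1,0\n", encoding="utf-8")
    return vhdr_path
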