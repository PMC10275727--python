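"""Stage orchestration: design -> synthetic data -> behavior -> statistics.

Behavioral epochs are defined by target direction changes: each trajectory
peak opens an epoch that runs to the next peak (or the trial end).  Every
epoch carries an epoch error (RMSE over the epoch) and, when a matching
cursor direction change followed within 80-300 ms, a pursuit latency.
Condition tags come from the segment label (task 1: constant vs random) or
the occlusion state (task 2) at the peak.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as bh
from .io import StudyConfig
from .synth import SyntheticStudy, make_study
from .vincentile import contrast_vincentiles, vincentilize

__all__ = ["compute_trial_epochs", "compute_metrics", "vincentile_tables",
           "run_pipeline"]


def compute_trial_epochs(target_y: np.ndarray, cursor_y: np.ndarray,
                         config: StudyConfig,
                         in_rate_hz: float = 60.0,
                         segment_labels: np.ndarray | None = None,
                         occluded: np.ndarray | None = None,
                         task: int = 1) -> list[dict]:
    """Per-epoch metrics of one trial (upsampled to the EEG rate)."""
    out_rate = config.eeg_rate_hz
    tgt = bh.upsample_coordinates(target_y, in_rate_hz, out_rate)
    cur = bh.upsample_coordinates(cursor_y, in_rate_hz, out_rate)
    screen = config.screen_height_px
    traj_peaks = bh.detect_peaks(tgt, config.traj_prominence_fraction, screen,
                                 rate_hz=out_rate)
    purs_peaks = bh.detect_peaks(cur, config.pursuit_prominence_fraction,
                                 screen, rate_hz=out_rate)
    matches = bh.match_pursuit_peaks(traj_peaks, purs_peaks,
                                     window_s=config.latency_window_s)
    duration = tgt.size / out_rate
    epochs = []
    for i, (pk, mt) in enumerate(zip(traj_peaks, matches)):
        start = int(pk.time_s * out_rate)
        stop = int(traj_peaks[i + 1].time_s * out_rate) if i + 1 < len(traj_peaks) \
            else tgt.size
        if stop <= start:
            continue
        frame60 = min(int(pk.time_s * in_rate_hz), len(target_y) - 1)
        if task == 2 and occluded is not None:
            cond = "occluded" if occluded[frame60] else "visible"
        elif segment_labels is not None:
            lab = segment_labels[frame60]
            cond = "constant" if lab == "constant" else "random"
        else:
            cond = "all"
        epochs.append({
            "peak_time_s": pk.time_s,
            "condition": cond,
            "epoch_error_px": bh.epoch_error(tgt[start:stop], cur[start:stop]),
            "pursuit_latency_s": mt.latency_s if mt.valid else np.nan,
            "valid": bool(mt.valid),
            "duration_s": (stop - start) / out_rate,
            "n_epoch_total": None,
        })
    del duration
    return epochs


def compute_metrics(study: SyntheticStudy, config: StudyConfig | None = None,
                    ) -> pd.DataFrame:
    """Per-epoch metrics table for a whole study, with 3-SD trial exclusion.

    Columns: subject, trial, condition, peak_time_s, epoch_error_px,
    pursuit_latency_s, valid, excluded_trial.
    """
    config = config or StudyConfig(task=study.task)
    rows = []
    for subj in study.subjects:
        trial_max_err = []
        trial_rows: list[list[dict]] = []
        for ti, (traj, cursor, occ) in enumerate(zip(
                study.trajectories[subj], study.cursor_traces[subj],
                study.occlusion[subj])):
            eps = compute_trial_epochs(
                traj.y, cursor, config, in_rate_hz=traj.frame_rate,
                segment_labels=traj.segment_labels, occluded=occ,
                task=study.task)
            for e in eps:
                e.update(subject=subj, trial=ti)
            trial_max_err.append(float(np.max(np.abs(traj.y - cursor))))
            trial_rows.append(eps)
        _, flagged = bh.exclude_outlier_trials(trial_max_err,
                                               n_sd=config.exclusion_n_sd)
        flagged = set(flagged.tolist())
        for ti, eps in enumerate(trial_rows):
            for e in eps:
                e["excluded_trial"] = ti in flagged
                rows.append(e)
    df = pd.DataFrame(rows)
    return df.drop(columns=["n_epoch_total"])


def vincentile_tables(metrics: pd.DataFrame, measure: str,
                      conditions: tuple[str, str], k: int = 10,
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Subject x k vincentile tables for the two conditions of a contrast.

    ``measure`` is ``epoch_error_px`` or ``pursuit_latency_s`` (the latter
    restricted to valid epochs).  Excluded trials are dropped.
    """
    df = metrics[~metrics["excluded_trial"]]
    if measure == "pursuit_latency_s":
        df = df[df["valid"]]
    tables = []
    subjects = sorted(df["subject"].unique())
    for cond in conditions:
        rows = []
        for s in subjects:
            vals = df[(df["subject"] == s) & (df["condition"] == cond)][measure]
            rows.append(vincentilize(vals.to_numpy(float), k=k))
        tables.append(np.vstack(rows))
    return tables[0], tables[1]


def run_pipeline(config: StudyConfig, out_dir, n_trials: int | None = None,
                 stages: tuple[str, ...] = ("design", "synth", "behavior",
                                            "vincentiles")) -> dict:
    """Run the behavioral pipeline end to end on synthetic data.

    Writes a provenance log (config hash, seed) and stage outputs under
    ``out_dir``; returns the result bundle as a dict.  Stage failures raise
    with the stage name; partial outputs remain on disk.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"config_hash": config.hash(), "seed": config.seed,
                    "task": config.task}
    (out / "provenance.json").write_text(json.dumps(bundle, indent=1))

    study = None
    try:
        if "design" in stages or "synth" in stages:
            study = make_study(n_subjects=config.n_subjects, task=config.task,
                               seed=config.seed, n_trials=n_trials)
            bundle["n_trials_total"] = study.n_trials
        if "behavior" in stages:
            metrics = compute_metrics(study, config)
            metrics.to_csv(out / "metrics.csv", index=False)
            errors = {
                s: [np.asarray(t.y - c)
                    for t, c in zip(study.trajectories[s], study.cursor_traces[s])]
                for s in study.subjects
            }
            # entropy runs on the 250 Hz error traces
            errors250 = {
                s: [bh.upsample_coordinates(e, 60.0, config.eeg_rate_hz)
                    for e in errs]
                for s, errs in errors.items()
            }
            ent = bh.entropy_interval_test(
                errors250, rate_hz=config.eeg_rate_hz,
                split_at_s=config.entropy_split_s,
                horizon_s=config.entropy_horizon_s,
                m=config.entropy_m, r=config.entropy_r)
            bundle["entropy"] = {
                "median_first": float(np.median(ent.per_subject_first)),
                "median_second": float(np.median(ent.per_subject_second)),
                "Z": ent.Z, "p": ent.p, "effect_r": ent.effect_r,
            }
            bundle["n_epochs"] = int(len(metrics))
            bundle["n_valid_latency"] = int(metrics["valid"].sum())
        if "vincentiles" in stages:
            conds = ("constant", "random") if config.task == 1 else \
                ("occluded", "visible")
            contrasts = {}
            for measure in ("epoch_error_px", "pursuit_latency_s"):
                ta, tb = vincentile_tables(metrics, measure, conds,
                                           k=config.vincentile_k)
                res = contrast_vincentiles(ta, tb, n_boot=config.n_boot,
                                           alpha=config.boot_alpha,
                                           q=config.fdr_q, seed=config.seed)
                contrasts[measure] = {
                    "t": res.t_per_bin.tolist(), "p": res.p_per_bin.tolist(),
                    "d": res.d_per_bin.tolist(),
                    "significant": res.fdr_mask.tolist(),
                }
            bundle["vincentile_contrasts"] = contrasts
    except Exception as exc:  # annotate with the failing stage
        raise RuntimeError(f"pipeline failed: {exc}") from exc

    (out / "results.json").write_text(json.dumps(bundle, indent=1))
    return bundle
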