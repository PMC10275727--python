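"""Tracking metrics and the sample-entropy interval analysis on a small
synthetic study.

The cursor model tracks the target with a ~150 ms lag after a 500 ms dead
time; because the early tracking error is driven by the (smooth) target path
while later error is dominated by motor noise, sample entropy of the
z-scored error is lower in the first 500 ms than in the following 1500 ms.
"""

import numpy as np

from pursuitmon import StudyConfig, compute_metrics, entropy_interval_test, make_study, upsample_coordinates

study = make_study(n_subjects=6, task=1, seed=21, n_trials=12)
metrics = compute_metrics(study, StudyConfig(n_subjects=6))

print(f"epochs: {len(metrics)}, with valid pursuit latency: "
      f"{metrics['valid'].sum()} "
      f"({100 * metrics['valid'].mean():.1f}%)")
lat = metrics.loc[metrics["valid"], "pursuit_latency_s"]
print(f"median pursuit latency: {1000 * lat.median():.0f} ms "
      f"(simulated lag ~150 ms)")
print(f"median epoch error: {metrics['epoch_error_px'].median():.1f} px")

errors = {s: [upsample_coordinates(t.y - c, 60.0, 250.0)
              for t, c in zip(study.trajectories[s], study.cursor_traces[s])]
          for s in study.subjects}
ent = entropy_interval_test(errors)
print(f"sample entropy medians: first 500 ms = "
      f"{np.median(ent.per_subject_first):.3f}, following 1500 ms = "
      f"{np.median(ent.per_subject_second):.3f}")
print(f"rank-sum Z = {ent.Z:.2f}, p = {ent.p:.2g}, r = {ent.effect_r:.2f}")
print("-> the early error trace is more predictable (lower entropy), "
      "matching the dead-time tracking behavior")
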