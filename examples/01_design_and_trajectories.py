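"""Build a counterbalanced pursuit-tracking session and one target trajectory.

The target's vertical path is a three-segment truncated Fourier series
f(x) = sum a_i sin(ix) + b_i cos(ix); the middle segment repeats across
trials with fixed coefficients while the outer segments are random.
"""

import numpy as np

from pursuitmon import CONSTANT_SEGMENT, build_session_plan, build_trajectory, evaluate_segment

plan = build_session_plan(task=1, seed=7)
print(f"session: {plan.n_trials} trials, breaks after trials "
      f"{plan.break_positions}")
print(f"mean fixation duration: "
      f"{np.mean(plan.fixation_durations_s):.2f} s (target 1.5 s)")

# the repeated middle segment evaluated at two probe points
print(f"constant segment f(0)     = {evaluate_segment(CONSTANT_SEGMENT, 0.0):+.1f} px")
print(f"constant segment f(pi/2)  = {evaluate_segment(CONSTANT_SEGMENT, np.pi / 2):+.1f} px")

tr = plan.trials[0]
traj = build_trajectory(tr["direction"], tr["velocity_level"],
                        tr["trajectory_seed"])
labels = {lab: int((traj.segment_labels == lab).sum())
          for lab in np.unique(traj.segment_labels)}
print(f"first trial: {traj.direction}-moving, velocity level "
      f"{traj.velocity_level}, {traj.duration_s:.1f} s, frames per segment "
      f"label: {labels}")
# every frame is labeled and the trajectory stays on screen
assert traj.y.min() > 0 and traj.y.max() < traj.screen.height_px
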