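# Methods notes

This note documents the models, parameter choices and numerical decisions
behind `pursuitmon`, and what validation on synthetic data does and does not
establish about real recordings.

## Task model

A trial's vertical target path is three segments of
`f(x) = Σᵢ₌₁³ aᵢ sin(ix) + bᵢ cos(ix)` (pixels). The outer segments draw
coefficients uniformly from [−40, 40] px and are resampled (bounded loop,
default 1000 attempts) until the segment's full-period excursion keeps the
32-px target on screen; the middle segment is fixed
(a = 37, −3, 26; b = 23, −15, −9) and repeats unannounced on every trial.
The trajectory parameter x advances linearly with the target's horizontal
position and each segment spans one full period (2π), so the random segments
explore their whole waveform. Segments are separated by a 30-px horizontal
gap bridged by a cubic spline through the two flanking samples on each side;
original segment samples pass through unchanged.

Choices the task description leaves open, fixed here once:

- **Screen geometry**: virtual 1920 × 1080 px display; prominence
  thresholds use the vertical extent (1080 px). Configurable.
- **Velocity levels**: three horizontal speeds spanning the screen in
  13.5 / 12 / 10.5 s (levels 1–3), giving a 12-s mean trial at 60 Hz.
  Absolute px/s values are not documented for the original setup.
- **Start vector**: 500 ms straight segment at screen-center height.
- **Fixation**: uniform on [1.0, 2.0] s (mean 1.5 s).
- **Left-moving trials** mirror the horizontal axis only.
- **Occlusion** (task 2): 2 s hidden out of every 4 s, starting visible.
  (Figure captions elsewhere describe the same alternation as "2 s every
  2 s"; the 2-on/2-off reading satisfies both.)

## Synthetic behavior

The cursor is a first-order tracker: screen-center during an initial dead
time (default 0.5 s — participants typically leave the joystick idle at
trial start), then exponential smoothing (τ = 50 ms) of the lag-shifted
target (default lag 150 ms) plus i.i.d. Gaussian motor noise (default SD
8 px, doubled while occluded). The model was chosen for minimal parameters
and an analytic cross-correlation structure: with τ → 0 and zero noise, the
cursor is exactly the delayed target, so peak matching must recover the lag
to within one frame. Between-subject variation draws lag ~ N(150, 20) ms and
noise SD ~ N(8, 1.5) px, clipped to sane ranges.

This generator reproduces the qualitative structure the analyses rely on —
dead-time-dominated early error, lag-limited pursuit latency, noisier
occluded tracking — but not learning across trials, eye movements,
anticipatory tracking of the repeated segment, or x-axis error. Absolute
entropy or error magnitudes on synthetic data therefore do not predict the
magnitudes in real recordings; passing tests establish correctness of the
computations and calibration of the statistics, not empirical effect sizes.

## Synthetic EEG

Channels carry unit-variance 1/f^α background noise (spectral shaping,
α = 1 by default, scaled to 10 µV), band-limited oscillations (hard
spectral mask, unit RMS) whose amplitude is a per-condition scalar applied
inside condition time windows, and an ERP template added at each event on
the affected channels. The montage is a deterministic Fibonacci lattice of
60 (or fewer) positions on the upper hemisphere of a 9.5-cm sphere,
emulating an equidistant cap. "Moderate SNR" in the validation experiments
means a 3 vs 2 µV alpha amplitude difference on 6 of 16 channels over the
10-µV 1/f background — a ~2.25× band-power ratio before averaging.

## Behavioral metrics

Traces are up-sampled 60 → 250 Hz by cubic splines; the output grid has
`ceil(duration·250)` points, the last few of which may extrapolate up to one
input frame beyond the final sample. Epoch error is the RMSE of the vertical
target–cursor difference. Peaks use topographic prominence thresholds (1%
of screen size for the target, 5% for the noisier cursor), minima via
negation. Matching walks trajectory peaks in time order and takes the
*earliest* unused same-direction cursor peak within 80–300 ms — the latency
is the time to the following matching change — making the assignment
one-to-one by construction. Outlier trials are flagged when the maximum
|error| exceeds the within-subject mean by 3 SD; with zero spread nothing is
flagged, and flagged trials are excluded by default (an automated stand-in
for visual inspection, so exclusion sets on real data may differ).

Sample entropy follows the standard template-counting estimator: both
template lengths use the same N−m starting points, Chebyshev distance,
self-matches excluded; −ln(A/B), with an explicit error when B = 0 or the
series has zero variance, and +∞ when A = 0. Each trial interval
(0–500 ms and 501–2000 ms at 250 Hz) is z-scored separately so r = 0.2 is in
SD units for every trial. Per-subject aggregation uses the **median** over
trials (robust; mean available), and the across-subject comparison is the
Wilcoxon rank-sum test exactly as specified for the original analysis, even
though the design is paired; a signed-rank variant would be more powerful
but is deliberately not the default. Effect size r = Z/√N with N = number
of subjects (consistent with r = −3.65/√30 = −0.67).

## Vincentile statistics

Equal-populated bins after an ascending stable sort; when k does not divide
n, the remainder goes to the *lowest* bins (deterministic). The bootstrap
paired test computes the observed paired t, then resamples subjects'
*centered* differences with replacement and uses the smoothed two-tailed
proportion `(1 + #{|t*| ≥ |t_obs|}) / (B + 1)`; centering makes the
resampling valid under H0 whatever the true effect, and the statistic is
invariant to common affine transforms of both conditions. Cohen's d (paired)
is mean(diff)/SD(diff). BH-FDR is the standard step-up procedure
(statsmodels). Cross-sorting bins epochs by latency rank (stable sort, ties
by epoch order) and averages the error per bin.

## Cluster-based permutation tests

Pointwise paired t-tests are thresholded two-sided at the cluster-forming α
(0.001); supra-threshold points are clustered by connected components where
neighbors share a channel and one grid step (time, or time/frequency), or
share the grid point and sit on adjacent channels. Channel adjacency comes
from Delaunay triangulation of the azimuthal-equidistant projection of the
montage. The cluster statistic is the sum of member t-values. The null is
within-subject sign flipping of the paired differences (exact for a paired
design); the permutation distribution records the **maximum |cluster mass|
over both polarities**, so a cluster's p-value controls the family-wise
error two-sided at the nominal level rather than per tail. Sign-flipped
t-maps are computed vectorized using the flip-invariance of Σd². An
independent cross-check against MNE-Python's cluster formation is part of
the test suite; the implementation itself is self-contained so that cluster
membership, t-sums and the electrode-count rules are fully specified.

ERP-specific rules: test window 0–750 ms; clusters that never span ≥ 4
channels at a single time point are ignored; at most the 3 largest clusters
per polarity by |t-sum| are analyzed (the scree-plot elbow criterion
operationalized as top-3); clusters shorter than 5 samples or with onset
after 300 ms (when the next direction change is already underway on
average) are rejected. The peak-latency contrast searches 200–450 ms by
default (bracketing both expected peaks), excludes subjects whose window
maximum falls on an edge, and uses an ordinary paired t-test. (The original
report quotes t(35.99) for this paired n = 30 contrast, which is
inconsistent with df = 29; the paired test is implemented as described.)

## Time-frequency details

Morlet wavelets with 5 cycles, 1-Hz steps within each band, power = |W|²;
epochs must hold at least 5 cycles of the band's lowest frequency. Baseline
correction divides by the per-epoch mean over −750–0 ms (upper edge
exclusive — the window ends where the trial starts) and converts to dB;
ratio mode is available. Task-1 segmentation takes the opening 500 ms of the
random and constant segments (first interval) and 500–3000 ms of the random
vs 0–2500 ms of the constant segment (second interval; both windows
2500 ms). Task 2 alternates 2-s visible/occluded windows starting visible.

Source maps: the normalized contrast r = (p₁−p₂)/(p₁+p₂) maps zero-sum
voxels to 0; DBSCAN runs on the most extreme 1% of voxels with
ε = 1.5 voxel edges and min_samples = 5 (the density minimum is not
documented for the original analysis; 5 is the common DBSCAN default).
Beamforming itself is out of scope — the module consumes precomputed or
synthetic voxel power maps.

## ERP-by-performance matrix

Rows are vincentiles of the behavioral measure (valid-latency epochs only),
columns ten 50-ms bins from 50 to 550 ms; at 250 Hz the bins alternate
between 12 and 13 samples (125 samples total). Cells are bootstrap
paired-tested (5,000 resamples, α = 0.001) with BH-FDR across the 100 cells
per contrast; cells missing for any subject are skipped and counted. FDR is
applied per condition contrast.

## Validation experiments and problem sizes

The `validation` module measures operating characteristics at sizes chosen
to give tight Monte-Carlo intervals while keeping the default suite quick:
lag recovery on 100 noise-free trials; bootstrap type-I error over 1,000
null replicates (n = 30, 1,000 resamples); cluster family-wise error over
500 null replicates at 16 channels × 100 samples with 500 permutations;
BH-FDR over 1,000 batteries of 100 tests with 50% true nulls; and detection
power for the alpha-band difference over 50 replicates of 30 subjects with
250 permutations. The reproduction script (`scripts/acceptance.py`) runs
the same experiments plus the full 30 × 72-trial behavioral study.

## Known limitations

- The EEG preprocessing chain (filtering, artifact rejection, ICA) is out
  of scope; the pipeline assumes clean, epoch-ready data.
- The synthetic cursor has no anticipation, so the repeated middle segment
  confers no learning advantage in generated data; condition differences in
  synthetic vincentile contrasts reflect trajectory statistics only.
- Sample-entropy magnitudes depend on the error process; synthetic values
  are not comparable to values from human tracking.
- The "epochs" unit for behavioral statistics is the inter-peak interval;
  datasets with different peak densities yield different epoch counts.
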