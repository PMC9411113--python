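# Methods

## Trajectory representation and units

A recording is a per-frame table `frame,x,y,orientation` — the shape of
Ctrax-style tracker output. Frames are 0-based and must be gapless;
loading fails loudly on the first missing or duplicated frame and on any
non-numeric cell, and never repairs data silently. Positions are stored
internally in millimetres (tracker pixels divided by `pixels_per_mm` at
load; a `position_unit` field records provenance) and orientations are
wrapped once, at load, to the half-open interval [−180, 180). One wrap
convention everywhere avoids the classic ±180 double-counting bugs in
angular differencing. The temporal calibration defaults to 30.06
frames/s, so a 5-minute recording is 9018 frames and one frame spans
0.033 s.

Orientation is treated as a directed heading. Trackers that only resolve
the body axis up to 180° must disambiguate upstream; this package does
not attempt it.

## Kinematics

For frames i and i+1 the displacement is the Euclidean distance between
centroids (mm), the instantaneous speed is displacement × frame rate
(mm/s, so values are frame-rate independent), and the yaw is the signed
wrapped heading difference (deg). All three per-step series have length
n_frames − 1.

The three locomotor parameters:

* **mean speed** — mean of instantaneous speed, mm/s;
* **yawing** — mean absolute yaw, deg/frame. The aggregation over a
  recording is genuinely open (per-frame mean, total, or rate are all
  defensible); the per-frame mean is the default because it is
  length-independent, and `sum` and `rate` modes are exposed for
  sensitivity analysis;
* **freezing fraction** — share of steps with displacement ≤ ε. The
  literal definition of freezing is d = 0, but tracked centroids never
  repeat exactly, so ε (default 0.05 mm, configurable) absorbs sub-pixel
  jitter; ε = 0 recovers the literal definition on noiseless data.

All three are invariant under rigid translation and rotation of the
arena frame (property-tested). Mean speed scales linearly under uniform
spatial scaling; freezing with ε = 0 is scale-invariant.

## AIM scoring

The abnormal-involuntary-movement score counts frames whose speed
deviates from the animal's own local mean. The window mean v_s at frame
i averages the s speeds centred on i; the two-sided sum covers exactly s
frames only when s is odd, so an odd window is enforced (default 21
frames ≈ 0.7 s). A frame scores 1 when |log₁₀(vᵢ/vₛ)| > c, default
c = 0.4 (speed off by > ~2.5× either way); the raw score H is the sum.

Numerical and edge conventions:

* The absolute-value form is the default, so abrupt decelerations score
  as well as accelerations; a `signed` mode (accelerations only) is
  provided for sensitivity analysis.
* Edge frames without a full window are unscored — no shrinking windows —
  so H is comparable across equal-length recordings.
* Frames where vᵢ or vₛ falls at/below a guard `epsilon_speed` (default
  10⁻⁹ mm/s) are *skipped*, not clamped: the log is undefined there and
  stationary behaviour is already captured by the freezing fraction. A
  recording with no scorable frame returns H = 0 with an `all_skipped`
  flag and a warning. Skipped frames are counted separately from scored
  frames in the result diagnostics.
* Raw H is scale-invariant (vᵢ/vₛ is unitless), non-increasing in c, and
  exactly reproducible.

Scores are reported as raw − mean(control raw) within the same
experiment, so the control cohort averages exactly 0; no global baseline
constant exists. How the canonical threshold 0.4 was originally
calibrated from wild-type movement is not documented anywhere we could
rely on, so the package does not guess: `threshold_from_controls`
implements one explicit convention (a percentile, default 99.5, of
pooled control |log-ratios|) and documents itself as such.

One behaviour worth knowing: near freezing bouts the window mean is
dragged toward zero by the frozen frames, so the first walking steps at
a bout boundary often qualify. This inflates raw scores in any animal
that freezes — which is precisely why scores are normalized against
controls. The same effect makes `peak_deviation` (max of (vᵢ−vₛ)/vₛ, in
percent) large even for control recordings that contain freezing; peak
deviation is therefore a descriptive per-recording statistic, most
interpretable on continuous-movement segments.

## Synthetic trajectory generator

The generator is a correlated random walk with hidden per-frame states:

| state  | displacement                  | heading                        |
|--------|-------------------------------|--------------------------------|
| WALK   | (v/f) × lognormal (unit mean) | + Normal(0, turn_sd)           |
| FREEZE | 0                             | unchanged                      |
| BURST  | WALK step × gain (one frame)  | + Normal(0, turn_sd) ± kick    |

Freeze entry/exit are per-frame Bernoulli events, so dwell times are
geometric and the stationary frozen occupancy is enter/(enter+exit) in
closed form — the ground truth for parameter-recovery tests. Bursts are
single-frame multiplicative speed spikes co-occurring with a large
heading kick (default ±90°), arriving homogeneously in time; they encode
the empirical signature that abrupt accelerations accompany direction
changes, and they are the intended AIM-qualifying events, giving the
score a ground-truth detection target (~99% of hidden bursts qualify
under the defaults). Real dyskinetic behaviour may cluster bursts in
time; no temporal statistics were available to emulate, so homogeneous
arrivals are a known simplification.

Control defaults (9018 frames, 30.06 fps, 27.5 mm arena — a 60 mm dish
with a silicone insert): walk speed 8 mm/s, speed noise CV 0.25, freeze
enter/exit 0.008/0.10 per frame (≈ 7.4% frozen), heading diffusion
5 deg/frame, bursts 0.5/min. A scalar **dose** ∈ [0, 1] stands in for
L-DOPA concentration or diet duration and maps linearly onto the
parameters: walk speed × (1 − 0.487·dose), freeze entry + 0.025·dose,
turn SD × (1 + 3.1·dose), burst rate + 12·dose per minute. The slopes
were calibrated analytically — from the occupancy closed form and
E|N(0, σ)| = σ√(2/π) — so the dose = 1 cohort shows approximately the
effect sizes characteristic of dyskinetic fly locomotion: ~58% lower
mean speed and ~235%/~250% higher freezing/yawing than control (measured
values on simulated cohorts land within a few points of these, the gap
coming from burst contributions and wall interactions that the closed
forms ignore).

The arena boundary is reflective: a proposed position outside the wall
is folded back radially and the heading realigned with the realised
displacement. At the default step-to-arena ratio this distorts total
path length by ≪ 1%, which is why occupancy-weighted speed recovery
holds to within 2%.

Determinism: one master seed; per-fly streams are derived by
counter-based `SeedSequence` splitting over (dose index, fly index), so
any subset of a cohort reproduces identically regardless of what else is
simulated. Identical seed + config gives bit-identical trajectories.

What the generator does **not** emulate: tracking noise and identity
errors, body-axis flips, thigmotaxis and wall-following, burst
clustering, multi-fly interaction, 3-D motion. Passing tests therefore
demonstrate correctness of the quantification pipeline on data with the
assumed statistical structure, not robustness to every artefact of real
video tracking.

## Cohort analysis

`summarize_fly` composes the kinematic and AIM operations into one tidy
row per fly; `summarize_group` reports per-group mean, SEM (sd/√n) and
percent change (treated − control)/control × 100 against a designated
control group, whose own percent change is identically 0. A single-fly
group reports SEM = 0 with an explicit `degenerate_n` flag instead of
erroring, so toy fixtures run end-to-end.

Dose/duration trends use Spearman rank correlation with a seeded
permutation p-value (≥ 999 permutations, values shuffled over flies),
requiring ≥ 3 distinct dose levels. A rank test with a permutation null
was chosen because the metric–dose relation is monotone but not
plausibly linear, and the permutation null is exact under exchangeability
at small n. Between-group inference (ANOVA + post-hoc) is routine and
delegated to scipy/statsmodels by the caller rather than re-implemented.

## Problem sizes and defaults in the test suite

Unit and property tests run on short series (tens to hundreds of steps)
against brute-force oracles; simulation-backed checks use the full
recording length of 9018 frames with 20 seeds for parameter recovery and
5 dose levels × 10 flies for dose monotonicity — the cohort sizes the
assay design itself uses (6–12 flies per group). The whole suite runs in
well under a minute on one core.

## Known limitations

* Whether the original analyses scored zero-speed frames as 0 or
  excluded them is undocumented; this package excludes them (with
  diagnostics), and the choice matters only for heavily frozen
  recordings.
* The yawing aggregation convention (mean per frame) is a documented
  choice among defensible alternatives, not an established standard.
* `peak_deviation` is unstable near freezing bouts (see above).
* The dose mapping is a linear phenomenological stand-in, not a
  pharmacokinetic model; it exists to give monotone, calibrated effect
  sizes, not to fit real dose–response curves.
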