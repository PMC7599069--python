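# Methods

This note documents the generative model behind the synthetic data, the
detection/cleaning rules and their constants, the statistical machinery,
and the design choices made where more than one reasonable option
existed. Units are visual degrees (deg), deg/s, milliseconds, and
arbitrary pupil units (a.u.); all sample streams are 1000 Hz.

## Task structure emulated by the generator

A session is 4 blocks × 48 trials (12 per condition per block, randomly
ordered within block). Each trial: 500 ms fixation, auditory condition
cue (`Performance`, `Random`, `10p`, `0p`), a delay of 1400/1500/1600 ms
(equiprobable), then a target 9.3° left or right (50/50), followed by a
1000 ms response/feedback epoch. Two blocks use auditory speed feedback
with visual reward feedback and two the reverse, in randomised order.
Performance rewards follow the adaptive rule: 10 p iff the response time
beats the median of the previous (up to) 20 Performance response times.
With i.i.d. continuous response times this pays ~50% of trials. Cold
start: the first Performance trial is rewarded, and the median is taken
over however many previous trials exist — the steady-state rule does not
define the first trial, so the generous option was chosen once.

## Saccade model

Saccades follow a main sequence `v_peak(A) = vmax·(1 − e^(−A/a0))` with
defaults `vmax = 550 deg/s`, `a0 = 5°` (a conventional oculomotor
parameterisation), plus an additive per-condition *vigour offset* in
deg/s — the quantity the analysis is designed to recover. The velocity
profile is minimum-jerk, `v(τ) = 16·v_peak·τ²(1−τ)²`, whose unit-peak
area is 8/15; fixing amplitude and peak therefore fixes the duration
`D = 15A/(8·v_peak)` (≈ 37.5 ms at 9.3°). We derive `D` from amplitude
and peak rather than imposing an independent duration law, because a
profile cannot satisfy amplitude, peak *and* an arbitrary duration at
once; the derived durations sit within a few ms of standard
duration–amplitude regularities at task-relevant amplitudes.

Motor noise is signal-dependent: each 1 ms velocity command receives
zero-mean Gaussian noise with SD `noise_scale·|v|` (default 0.10),
integrated to position. With `feedback_gain g > 0` each step is
corrected by `−g·(x − x_nominal)`, an AR(1) recursion implemented as a
linear filter. Consequences used as test oracles: endpoint scatter is
monotonically non-increasing in `g`, and late-saccade time×time position
autocorrelation is lower under feedback (accumulated noise is being
removed in flight).

Trial amplitudes are `max(1.5°, N(0.95·9.3°, 0.6°))` — a slight average
undershoot with scatter, which also makes the main-sequence slope
identifiable. Latencies are shifted-lognormal (shift 80 ms, median
160 ms above the shift, σ = 0.20) plus per-condition latency offsets;
the distribution family is a generator choice, not an inference target.
Between-participant heterogeneity: each participant deviates from the
configured vigour offsets by N(0, 8 deg/s) per condition and session
(`vigour_effect_sd`), so cohort-level inference faces realistic random
effects rather than only trial noise.

## Fixation, blinks and pupil

Fixational drift is a weakly mean-reverting 2-D random walk whose step
scale is set so the median sample-to-sample speed equals `drift_speed`
(default 0.5 deg/s); tremor is a sinusoid (80 Hz, 0.005° default);
microsaccades are Poisson events (1/s default) of 0.1–0.8°, directed
back toward fixation when the eye has wandered. Blinks are Poisson
(0.1/s), 80–450 ms, encoded as invalid samples with NaN positions and a
pupil dip ramp on both edges; blinks are suppressed within −100/+700 ms
of target onset, since observers do not blink mid-response — without
this the "primary saccade" of an occasionally blink-obscured trial would
silently be the return saccade. The pupil channel is a baseline plus a
cue-locked unit-peak gamma-family kernel (peak 930 ms) scaled by the
per-condition `pupil_effect`, plus AR(1) noise (φ = 0.99).

What the generator does **not** emulate: head movement, calibration
drift, vertical saccade components, pupil foreshortening, glissades/
post-saccadic oscillations, and any dependence of noise on fatigue or
time-on-task. Passing recovery tests therefore shows the pipeline is
correct under the stated model, not that real recordings meet the
model's assumptions.

## Detection and exclusion rules

Velocity is the Euclidean displacement across a centred 4 ms window
divided by 4 ms; windows touching invalid samples, and segments faster
than 3000 deg/s, are treated as missing. Candidate saccades are runs of
speed > 30 deg/s lasting ≥ 10 ms; boundaries are then refined by walking
each crossing back/forward (≤ 20 ms) while speed stays above a 5 deg/s
floor and keeps falling, so onset/offset track the movement rather than
the 30 deg/s crossing — on noiseless data this recovers ground-truth
onsets within 1 sample. The primary saccade of a trial is the first
candidate after target onset with amplitude (straight-line start→end)
> 1°. Peak velocity is the maximum windowed speed within the boundaries.
Left-target trajectories are mirrored (x → −x) after detection so all
analyses use rightward-positive coordinates.

Exclusions: peak velocity outside [80, 2500] deg/s (inclusive bounds),
or target reached before 180 ms or after 580 ms. "Reached the target"
defaults to saccade offset time; a spatial-arrival alternative (first
sample within a 2° radius of the target) is available via
`DetectionThresholds.response_time_mode`, since the original criterion's
spatial component is not fully specified. Participants with fewer than
10 valid trials in any condition of any session are dropped entirely.

A measurement note: the 4 ms window underestimates the true peak by
≈ 1% (window averaging across the velocity peak) with a sub-1% ripple
that depends on where samples fall relative to the peak; residuals of
noiseless sessions are therefore ~±2 deg/s around zero rather than
exactly zero, which the tests bound explicitly.

## Vigour measures

Per participant-session, OLS of peak velocity on amplitude pooled over
all four conditions; the residual is the vigour measure. An
amplitude-as-covariate alternative is provided
(`session_residual_table(..., covariate_mode=True)`) and agrees in sign
with residualisation on synthetic data. Additional scalar measures:
amplitude, saccadic RT (onset latency), raw peak velocity, and endpoint
variability — by default the RMS Euclidean distance of a cell's
endpoints from their centroid (bivariate, in degrees); a horizontal-SD
variant is a flag, since the original measure's formula is unstated.

## Time-normalized traces

Each saccade trajectory is linearly interpolated to 50 points spanning
onset→offset. Velocity differentiates the normalized positions (rescaled
by true duration to deg/s) and smooths with a 3-point centred moving
average (window truncation at the edges); acceleration differentiates
the velocity trace and smooths over 5 points. The alternative order —
differentiate the raw 1 ms trace, then interpolate — is behind a flag
and agrees within 1% of peak on noiseless saccades.

Autocorrelation matrices correlate, across trials, the horizontal
position at normalized time *i* with time *j*; entries are Fisher
z = atanh(r). The unit diagonal is capped at atanh(0.9999) for display
only; inference excludes the diagonal (the cap is arbitrary and must not
enter statistics). Covariance matrices are the same construction without
normalisation, satisfying cov = r·sd·sd′ exactly.

## Pupil preprocessing

Steps larger than 2.5 a.u./ms mark the later sample missing; then
missing runs shorter than 500 ms are linearly bridged from flanking
valid samples (longer runs, and runs touching the record ends, stay
missing). The operation is idempotent on realistic traces. Trial traces
subtract the mean of the 20 ms bin centred on cue onset (a single-sample
baseline would be noise-dominated) and average into 20 ms bins over
0–1400 ms (70 bins); the window-of-interest statistic is the mean of the
bins fully inside 1000–1400 ms.

## Fixation-period analysis

The 1400 ms cue→earliest-target window is dropped wholesale if it
contains a blink or a saccade ≥ 1°; surviving samples are masked when
deviating > 1.8° from fixation or moving > 30 deg/s (the two masks are
independent, hence order-stable). Microsaccades are detected on the
deviation-masked (not speed-masked — that would excise the events
themselves) signal by a median-based velocity threshold: per-axis
thresholds at 6× a median-based SD, elliptic criterion, ≥ 6 ms, then an
amplitude < 1° filter. Drift speed is the median (mean behind a flag)
sample-to-sample speed after excising microsaccades ± 10 ms, requiring
≥ 100 ms of data. Tremor spectra are one-sided DFT amplitudes of the
linearly detrended, Hann-tapered horizontal position in the early
(200–700 ms) and late (700–1200 ms) windows — 2 Hz resolution, scaled so
an on-bin sinusoid of amplitude *a* peaks at ≈ *a*.

## Statistics

**Repeated-measures ANOVA.** Input is a balanced participant × cell
means table. The model is a linear mixed model with participant random
intercept; in a balanced design with sum-coded within-subject effects
the fixed estimates are OLS and are tested against the pooled
within-subject residual variance (REML closed form: residual SS after
projecting out subject means and all fixed effects). Wald F per effect;
denominator df follow the residual convention *rows − fixed parameters*
(26 × 2×2×2 → 208 − 8 = 200; 29 × 2×2 → 116 − 4 = 112). No sphericity
correction is applied — the pooled-error model assumes compound
symmetry, which the cell-means-plus-random-intercept formulation
implies. The implementation is cross-checked in the tests against
statsmodels MixedLM Wald statistics and against the squared paired-t
identity in the 2-level case, and its null rejection rate is calibrated
by simulation.

**Cluster-wise permutation tests.** Pointwise one-sample t across
participants on per-participant difference traces (1-D) or matrices
(2-D); cluster-forming threshold = two-tailed t critical value at
α = 0.05 (a field default, configurable); clusters are contiguous
supra-threshold runs (1-D) or 4-connected regions (2-D), separated by
sign; mass = summed t. The null distribution of the maximum |mass| comes
from whole-participant sign flips — 5000 random flips by default,
exhaustive enumeration when 2ⁿ ≤ n_perm — and cluster
p = (1 + #{null ≥ observed}) / (1 + n_perm). NaN cells (the excluded
matrix diagonal) never enter clusters. Family-wise error calibration is
verified by simulation in the acceptance suite.

**Within-subject SEM.** Cousineau participant-mean centring with the
Morey √(k/(k−1)) correction.

**Spearman correlation.** Average ranks for ties; exact two-tailed p by
full enumeration of rank permutations for n ≤ 9, t approximation above
(the study's ns are 26–29).

**Sensitivity analysis.** The minimal detectable Cohen's d_z inverts the
noncentral-t power function for a one-tailed paired t test (df = n − 1)
by root finding; one-tailed is the default because the study-size values
it reproduces (0.46 at n = 30, 0.50 at n = 26) are one-tailed
quantities. A two-tailed flag is provided.

## Problem sizes in the validation suite

Simulation studies are sized to give stable verdicts at interactive
runtimes: the family-wise error calibration uses 500 null datasets of 20
participants × 50 points with 1000 permutations each; vigour recovery
uses 4 participants × 2 sessions × 200 trials/condition through the full
sample-stream pipeline, and the three-way-interaction power check uses
100 cohorts of 26 participants on the generator's trial-level fast path
(the fixation and pupil channels do not enter the vigour measure, so
synthesising them for power studies would add cost without information).
The feedback-autocorrelation comparison uses 50 simulated participants ×
60 saccades per feedback level.

## Known limitations

* The ANOVA handles balanced full factorials only (by design — the input
  is a cell-means table); unbalanced data must be handled upstream by
  dropping participants, as the pipeline does.
* Trial-level mixed models (slopes per trial) are out of scope; the
  cell-means route is the primary analysis it implements.
* The saccade detector assumes clean 1000 Hz data between blinks; no
  glissade separation or binocular validation is attempted.
* Mixed between/within (patients vs controls) designs are not
  implemented; the machinery extends naturally but is untested for that
  case.
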