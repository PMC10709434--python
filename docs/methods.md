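# Methods

This note records the models implemented by `conceptnav`, the conventions
and parameters that matter, what the synthetic-data generator does and
does not emulate, and the numerical choices made where the design was
genuinely open. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Feature-space geometry and conventions

The feature space of each context is the unit square; axis 1 (x) is the
upper-bond length and axis 2 (y) the lower-bond length, in arbitrary
units. Quadrants are delimited by the axis midlines with Q1 = low x/low y,
Q2 = high x/low y, Q3 = low x/high y, Q4 = high x/high y. This orientation
puts the blue goal (long upper, short lower bond) in Q2 and the green goal
in Q3, and makes Q1/Q4 equidistant from both goals, which the
distance-matched rotation control requires. The goal coordinates are not
dictated by the task narrative; we place them at the quadrant centers,
blue (0.75, 0.25) and green (0.25, 0.75), which makes them exact
180°-rotation images of each other about the space center.

Angles are degrees counter-clockwise from the positive x axis, in
[0, 360). The signed egocentric offset of a trial is
`wrap(bearing(start → goal) − heading)` in (−180, 180]; positive means the
goal lies counter-clockwise ("left") of the movement direction. The sign
assignment is arbitrary by construction of the task; only its consistency
matters. Allocentric directions are binned to the nearest of twelve 30°
centers {0, 30, …, 330}; exact ties (15° from two centers) break toward
the lower bin.

## Trial, run, and session generation

A run fixes its context and holds 48 trials: 12 on-target (offset 0°) and
6 for each of ±45°, ±90°, ±135°, with 12 trials starting in each quadrant.
Half the trials receive the target question (6 expected-yes — exactly the
on-target trials among them — and 18 expected-no); the other half receive
a filler question whose probe lies on the trajectory (8 trials per run) or
±60° off it (8 each). The 34/33/33% filler split is implemented per run as
8/8/8 of 24, the integer rounding of those proportions.

Start points are sampled uniformly within the trial's quadrant shrunk by a
0.05 margin; the heading is `bearing(start, goal) − offset`; the visible
morph segment (0.15 space units over ~1 s) must stay strictly inside the
quadrant, enforced by resampling the start. Trial timing is 0.5 s static
image, 1 s morph, 4 s imagination, 2 s question window, with inter-trial
intervals jittered uniformly on 2–6 s and a 6 s lead-in; none of these are
forced onto the TR grid. A session is 8 runs (4 per context, order
shuffled), and the entire session is regenerated until the pooled Pearson
correlation between signed egocentric offset and start-to-goal distance
satisfies |r| ≤ 0.03 (capped at 10,000 resamples; the acceptance rate is
roughly 40%, so the cap is never approached). This decorrelation is what
licenses interpreting egocentric-condition effects as angular rather than
distance coding.

## Planted neural codes

The generator writes a trial × voxel amplitude matrix as a sum of

* a **baseline** (100 arbitrary units);
* an **egocentric code**: voxel v prefers one of the 7 offsets (uniformly
  assigned) and responds
  `A·exp(κ(cos(offset − pref_v) − 1))·(1 + k·log Δt)`, where Δt is the
  time since the last trial of the same condition within the run (factor 1
  for first presentations). The multiplicative log-recency release matches
  the analysis model's modulator exactly. Preferred offsets are shared
  across contexts by default; a context-specific option exists to test the
  cross-context decoding dissociation.
* a **quadrant code**: per-quadrant Gaussian voxel patterns; the green
  context reuses the blue patterns under the rotation map Q1↔Q4, Q2↔Q3
  (or under identity, for the negative control), plus an independent
  context-specific component at 0.3 of the shared amplitude;
* a **grid-like code** with per-quadrant goal-proximity gains (close /
  medium / far): an RSA-tuning term `gain·cos(n(θ − ψ_v))` with per-voxel
  phases ψ_v shared across contexts (n = 6 by default), and/or a
  repetition-suppression term `gain·δ₆₀(θ_t, θ_{t−1})/30` uniform across
  voxels. Both terms can be planted together, which lets a single cohort
  serve both the grid-RSA and the goal-modulation analyses.

Amplitudes scale boxcars over each imagination period, convolved with the
canonical double-gamma HRF and sampled at TR = 1.5 s — the same forward
model, same code path, as the analysis GLM, which is what makes the
noiseless round trip exact. Noise is AR(1)-filtered white noise
(innovation SD 1, coefficient 0.3) plus slow cosine drifts (periods 300
and 180 s, amplitude SD 0.5) and a per-subject multiplicative gain drawn
from N(1, 0.1) applied to all effect amplitudes.

### Calibration of the planted gains

The default gains (ego amplitude 0.006, adaptation k 0.12, quadrant gain
0.0015, grid gains 0.0042/0.003/0.0018) were calibrated once, against the
default noise, so that each subject-level statistic has a modest effect
size (Cohen's d roughly 1.3–6 at 200 voxels) — strong enough that a
40-subject group test recovers every effect in ≥90% of replicate cohorts,
weak enough that individual subjects remain noisy. Because the simulated
noise regime is far more benign than real fMRI (no physiological noise,
no motion, no spatial structure, exact forward model), the *magnitudes*
of pattern statistics here are larger than empirical fMRI values even at
these small gains; the recoverable-but-noisy regime, not any empirical
magnitude, is the calibration target. The univariate modulator betas
(adaptation, goal modulation) are estimated with much higher precision
than pattern correlations in this regime, so their effect sizes run
larger.

## First-level GLM

The canonical HRF is the double-gamma difference (peak delay 6 s,
undershoot delay 16 s, unit dispersions, peak:undershoot 6, 32 s support),
normalized to unit peak. Regressors are built on a grid oversampled 10×
relative to the TR; since all events are boxcars, the convolution is
evaluated in closed form as a difference of cumulative HRFs at the volume
times (identical to FFT convolution to ~1e−14). Parametric modulators
scale the boxcar by trial values mean-centered within run *before*
convolution; multiple modulators on one regressor are entered jointly with
no serial orthogonalization, so "controlling for" a covariate is literal
joint OLS. Trials excluded from modulation (first presentations) move to
an unmodulated companion regressor so their BOLD response stays modeled.
Each design carries a response-onset impulse regressor, optional nuisance
columns, a discrete-cosine drift basis (128 s cutoff) and an intercept;
rank deficiency is an error. Estimation is OLS without prewhitening: with
AR(1) noise the subject-level estimates remain unbiased and all inference
is carried at the group level.

## Analysis models

**Adaptation.** One task regressor over imagination periods with a
log-recency modulator over repeats of the same egocentric condition
(natural log; the base only rescales betas). Lags never cross run
boundaries. Variants re-filter trials (off-target only; left-vs-right uses
the sign of the offset as the condition key) or add jointly-entered
covariates: trial-wise start-goal distance, log-recency of the same
starting quadrant, log-recency of the same allocentric bin. Start points
are continuous and never repeat exactly, so the starting *quadrant* is the
repeatable granularity used for the starting-point control. The
subject-level statistic is the ROI-mean (all simulated voxels) modulator
beta averaged over runs; positive = release from adaptation.

**Cross-context decoding.** Run-level condition betas (4 exemplars per
class per context) feed a 1-nearest-neighbor classifier with correlation
distance (ties to the first training index; Euclidean available). Training
uses all runs of one context, testing proceeds per run of the other, both
directions averaged, chance (100/7 % or 100/6 %) subtracted. The
searchlight applies any pattern statistic in radius-3 spheres (123 voxels
interior) on a cubic lattice, flagging spheres with fewer than 10 voxels.
MDS is classical (Torgerson) on correlation distances, with axis signs
fixed against the condition labels.

**Rotation RSA.** Quadrant betas are run-averaged within context, then the
four blue patterns (Q1..Q4) are correlated with the four green patterns in
reversed order (Q4..Q1), placing rotation-matched pairs on the diagonal.
Score = mean Fisher-z(diagonal) − mean Fisher-z(off-diagonal), with |r|
clipped at 1 − 1e−6. The goal-exclusion control drops the blue-goal row
(Q2) and green-goal column (Q3) — one row and one column, which removes
every correlation involving a goal quadrant on its own context's side; the
distance control scores only the {Q1,Q4}×{Q4,Q1} submatrix. Note the score
is not magnitude-symmetric between rotation- and identity-correspondent
codes: the identity scheme concentrates its 4 high cells among the 12
off-diagonal ones, giving −1/3 the magnitude in expectation. The test
suite asserts this exact ratio.

**Grid-RSA.** The 12×12 cross-context direction-bin correlation matrix is
symmetrized by triangle averaging, the diagonal dropped, and the lower
triangle correlated (Pearson, then Fisher-z) with an aligned/misaligned
indicator: aligned iff the bin separation is a multiple of 360/n within
1e−6°. On 30° bins the 5-fold (72°) and 7-fold (51.4°) control periods
never hit an exact bin separation, so those models are constant and carry
no testable prediction; the scorer flags them as degenerate and reports
NaN rather than a score. A related structural fact: the 6-fold and 4-fold
indicators are negatively correlated (r ≈ −0.15) on this bin grid, so a
planted 4-fold code pushes the 6-fold score slightly *negative*; the
specificity check therefore requires the 6-fold score never to be
detected as positive under 4-fold planting. Directions missing from a
run (geometry makes some bins rare in runs far from the goal) are modeled
only where present and averaged over the runs that contain them.

**Goal modulation.** Four quadrant regressors per run, each with a
mean-centered δ₆₀-to-previous-trial modulator (previous = immediately
preceding trial in the run, any quadrant; the run's first trial is
excluded; a quadrant whose δ₆₀ values are constant in a run is skipped and
flagged). Raw δ₆₀ is the modulator (larger distance from the previous
direction → larger predicted signal, i.e. release from 60°-rotational
suppression); the sign convention is configurable. Betas map to classes
close (goal quadrant), far (opposite), medium (Q1/Q4 averaged within
context, as they are equidistant from both goals), are averaged across
contexts after the subject-level GLM, and the contrast is close − far with
a linear trend over (far, medium, close) also reported.

**Gaze.** Per-volume gaze estimates are taken as given (the package
models the *output* of an MR-based gaze decoder, not eyeball decoding).
The trial displacement subtracts the volume nearest the morph onset from
the first volume at or after the imagination onset; pure nearest-volume
sampling at both ends would collapse ~1/3 of trials onto a single volume
at TR = 1.5 s with a 1 s morph, so the post-movement sample is required
not to precede the movement's end. Choice validation correlates the
chosen option's screen side (±1) with the horizontal gaze change from the
last volume at or before the question onset to the first volume at or
after question onset + 1.5 s. The gaze generator is calibrated (slope
3.2e−4 screen units/degree, choice shift 0.04, noise SD 1) so the mean
trial-wise horizontal correlation is ≈0.02 and the choice correlation
≈0.03 — weak per subject and detectable only at the group level, which is
the regime the analysis is designed for.

**Group inference.** One-sample tests against zero. ROI-style summaries
pass a Shapiro–Wilk gate (α 0.05) that switches the t-test to a Wilcoxon
signed-rank test; the cohort pipeline's map-style statistics use the t
branch directly. One-sided (positive) tests for adaptation, decoding,
rotation, and goal modulation; two-sided for grid-RSA and gaze,
mirroring how each analysis frames its hypothesis.

## What the generator does and does not emulate

Emulated: the full printed trial structure and timing; HRF dynamics and
TR sampling; temporally autocorrelated noise with slow drift; between-
subject effect-size variability; cross-context sharing (or not) of each
code; behavioral hit/false-alarm rates by context and question type;
gaze traces at volume resolution with an egocentric and a choice
component.

Not emulated: spatial structure of BOLD (no smoothness, anatomy, or ROI
geometry — voxels are exchangeable), motion and physiological noise,
trial-by-trial coupling between behavior and neural amplitude, and
question-period neural responses beyond a single impulse regressor.
Passing tests therefore demonstrate that the analyses recover what they
claim from data whose generative structure matches their assumptions —
not that real fMRI of this task would yield these effect sizes.

## Problem sizes and runtime choices

The validation suite uses 200 voxels per simulated ROI, 40 subjects per
cohort, and 20 replicate cohorts per condition (planted, null, and
structurally-alternative codes); these sizes give binomially tight
recovery/rejection counts while keeping the full suite around ten
minutes. The per-run basis of convolved single-trial regressors is
computed once and shared by every GLM of that run.

## Known limitations

* OLS without prewhitening mildly misstates first-level standard errors
  under AR(1) noise; group-level inference, which is the package's
  decision surface, is unaffected in calibration (verified by the null
  cohort tests).
* The 5- and 7-fold control symmetries cannot be scored on 30° bins (see
  above); scoring them would require finer direction binning.
* The rejection-sampled |r| ≤ 0.03 constraint is enforced at the session
  level, not per run, matching the pooled statistic it licenses.
* Whole-brain cluster inference is out of scope; the searchlight operates
  on abstract lattices and the group tests are simple one-sample tests.
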