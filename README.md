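# conceptnav

Analysis pipeline for studying how goal locations in abstract 2D feature
spaces ("conceptual spaces") are encoded during mental search, with a
synthetic-fMRI generator that plants every effect of interest as a known
ground truth.

The scientific setting: participants learn that two goal "molecules" (a
blue and a green context) live at fixed points of a two-dimensional
feature space whose axes are the lengths of the molecule's upper and lower
bonds. On each trial a molecule morphs along a straight trajectory, and
the participant must judge — during a 4 s imagination period — whether
continuing that trajectory would ever reach the goal. Each trial therefore
carries an **egocentric condition** (signed angle between the movement
direction and the bearing to the goal: 0°, ±45°, ±90°, ±135°), an
**allocentric direction** (binned into twelve 30° bins), and a **quadrant**
of the feature space. The package implements, end to end:

1. **Task design generation** — 8 runs × 48 trials per subject satisfying
   every structural constraint (12 on-target trials per run, 6 per
   off-target condition, 12 per quadrant, 24 target / 24 filler questions,
   morph segments never crossing quadrant boundaries) with the pooled
   correlation between egocentric condition and start-goal distance held
   at |r| ≤ 0.03 by rejection sampling.
2. **Synthetic BOLD, gaze, and behavior** — trial amplitudes carry a
   von-Mises-tuned egocentric code with multiplicative adaptation release
   `1 + k·log Δt`, quadrant patterns shared across contexts under the
   180° rotation map, and a grid-like code (per-voxel n-fold directional
   tuning with shared phase, plus a repetition-suppression term
   proportional to δ₆₀, the angular distance in 60° rotational space);
   amplitudes drive HRF-convolved boxcars at TR = 1.5 s with AR(1) noise.
3. **Analyses** —
   * egocentric *adaptation*: GLM with a log-recency parametric modulator
     over repeats of the same egocentric condition, plus six control
     variants (off-target only, per context, left-vs-right, distance /
     starting-point / allocentric-recency controlled);
   * *cross-context decoding*: 1-nearest-neighbor (correlation distance)
     classification of the 7 egocentric conditions trained in one context
     and tested in the other, reported as accuracy − chance (chance
     1/7 = 14.29%, or 1/6 without the on-target condition), with a generic
     searchlight and classical MDS;
   * *rotation RSA*: 4×4 cross-context quadrant-pattern correlations with
     one space rotated 180° (matched pairs Q1↔Q4, Q2↔Q3 on the diagonal),
     scored as the Fisher-z on- vs. off-diagonal difference, with
     goal-quadrant-exclusion and Q1/Q4-only controls;
   * *grid-RSA*: cross-context similarity of 12 direction-bin patterns
     against an aligned/misaligned model (aligned = separation a multiple
     of 60°; 3/4/5/7/8-fold control symmetries), Fisher-z scored;
   * *goal modulation*: per-quadrant δ₆₀ parametric modulators whose betas
     are contrasted between the goal-containing ("close") quadrant and the
     opposite ("far") one;
   * *gaze and behavior*: trial-wise horizontal gaze displacement vs.
     egocentric angle, choice-side validation, and hit / false-alarm rates.
4. **Group inference** — one-sample t-tests (Wilcoxon under a Shapiro–Wilk
   normality gate for ROI summaries), with Fisher-z transforms for
   correlation-valued statistics.

Every analysis is validated against the generator's planted ground truth:
planted effects must be recovered across replicate cohorts, planted nulls
must reject at the nominal rate, and structurally different codes
(identity-mapped quadrants, 4-fold direction tuning, flat goal gains) must
not masquerade as the effects of interest.

## Worked example

Simulate a 12-subject cohort at the default (calibrated) gains and run
every analysis:

```python
from conceptnav import synth, pipeline

cfg = synth.CohortConfig(n_subjects=12, n_voxels=200)
result = pipeline.analyze_cohort(cfg, seed=7)
for key in ["adaptation_beta", "decoding_above_chance", "rotation_score",
            "grid_z_6fold", "goalmod_contrast", "gaze_z_horizontal"]:
    t = result.group[key]
    print(f"{key:>22}: mean={t.mean:+.4f}  {t.test}={t.statistic:.2f}  "
          f"p={t.p:.2e} ({t.sided}-sided, n={t.n})")
```

prints

```
       adaptation_beta: mean=+0.0003  t=6.23  p=3.20e-05 (greater-sided, n=12)
 decoding_above_chance: mean=+16.2202  t=8.08  p=2.98e-06 (greater-sided, n=12)
        rotation_score: mean=+0.0705  t=8.16  p=2.71e-06 (greater-sided, n=12)
          grid_z_6fold: mean=+0.6140  t=12.45  p=7.96e-08 (two-sided, n=12)
      goalmod_contrast: mean=+0.0001  t=6.89  p=1.31e-05 (greater-sided, n=12)
     gaze_z_horizontal: mean=+0.0366  t=2.25  p=4.58e-02 (two-sided, n=12)
```

Reading the rows: the positive adaptation beta is the release from
repetition suppression per log-second since the same egocentric condition
last occurred; decoding sits 16 percentage points above the 14.29% chance
level; the rotation score shows quadrant patterns matching across contexts
only after a 180° rotation of one space; the 6-fold Fisher-z score is the
hexadirectional (grid-like) signal; the goal-modulation contrast shows the
grid signal is stronger in the goal quadrant than in the far one; and the
horizontal gaze z tracks where the goal lies relative to the trajectory.

The same analyses are available from the shell:

```bash
conceptnav simulate --seed 1 --n-subjects 2 --out dataset/
conceptnav all --seed 1 --n-subjects 12 --out results/
conceptnav analyze --data dataset/ --out results/
```

## Layout

```
src/conceptnav/
  geometry.py    angle/quadrant conventions of the feature space
  design.py      trial, run, and session generation + events TSV I/O
  synth.py       planted codes, BOLD/gaze/behavior simulation
  glm.py         HRF, design matrices, OLS, contrasts, pattern sets
  adaptation.py  log-recency adaptation analysis and control variants
  decoding.py    NN decoding, searchlight, MDS
  rotation.py    cross-context rotation similarity and controls
  grid.py        symmetry models, grid-RSA, goal modulation
  stats.py       group tests, gaze analyses, behavior metrics
  pipeline.py    subject/cohort orchestration
  io.py, cli.py  dataset I/O and command-line interface
```

See `docs/methods.md` for the modeling choices, calibration, and known
limitations.
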