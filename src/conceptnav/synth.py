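"""Synthetic BOLD, gaze, and behavior with planted representational codes.

Every downstream analysis in this package is validated against data from
this generator, whose ground truth is known exactly.  Three neural codes
can be planted, alone or together, in a trial-by-voxel amplitude matrix:

* an egocentric code: circular (von-Mises-shaped) voxel tuning over the 7
  egocentric conditions, multiplicatively released from adaptation as
  ``1 + k * log(dt)`` where ``dt`` is the time since the last trial of the
  same condition (matching the analysis model's log-recency regressor);
* a quadrant code: per-quadrant multivoxel patterns shared across contexts
  either under the 180-degree rotation correspondence (Q1<->Q4, Q2<->Q3)
  or under identity, plus a context-specific component;
* a grid-like (hexadirectional by default) code: per-voxel sinusoidal
  tuning to movement direction with an n-fold symmetry and a phase shared
  across contexts ("rsa_tuning"), and/or a univariate repetition-
  suppression term proportional to the angular distance in 60-degree
  rotational space from the previous trial; both are scaled by a
  goal-proximity gain (close/medium/far quadrant classes).

Amplitudes drive imagination-period boxcars convolved with the canonical
HRF (the same forward model the GLM engine uses), and AR(1)-filtered white
noise plus slow cosine drift is added.  Gaze traces are per-volume
estimates whose horizontal displacement during the morph-to-imagination
interval is proportional to the egocentric goal angle, and which drift
toward the chosen answer's screen side after question onset.  Behavioral
responses are Bernoulli draws at configurable hit/false-alarm rates.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from . import glm
from .design import DesignConfig, RunSpec, SessionSpec, events_frame, generate_session
from .geometry import EGO_OFFSETS, ROTATION_MAP, QUADRANTS, goal_distance_class
from .grid import delta60

#: fMRI-day hit / false-alarm rates by (context, question type).
DEFAULT_BEHAVIOR_RATES = {
    ("blue", "target"): (0.733, 0.0211),
    ("green", "target"): (0.774, 0.0347),
    ("blue", "filler"): (0.59, 0.159),
    ("green", "filler"): (0.608, 0.14),
}


@dataclass(frozen=True)
class NoiseModel:
    """Additive noise for synthetic BOLD (arbitrary signal units)."""

    white_std: float = 1.0          # innovation std of the AR(1) process
    ar1: float = 0.3
    drift_amplitude: float = 0.5    # amplitude of slow cosine drifts
    subject_std: float = 0.1        # between-subject gain variability

    def __post_init__(self):
        if not 0.0 <= self.ar1 < 1.0:
            raise ValueError("AR(1) coefficient must be in [0, 1)")


@dataclass(frozen=True)
class PlantedCode:
    """Ground-truth neural codes planted in the synthetic BOLD.

    The default gains are the package's calibrated study conditions: each
    planted effect produces a subject-level statistic of modest effect size
    (Cohen's d roughly 1-6 at the default noise), so a 40-subject group
    test recovers it reliably while leaving individual subjects noisy.
    ``PlantedCode.null()`` zeroes every effect for type-I-error checks.
    """

    baseline: float = 100.0
    # egocentric tuning + adaptation
    ego_amplitude: float = 0.006
    ego_concentration: float = 1.0
    adaptation_gain: float = 0.12       # k, fractional release per log-second
    ego_shared_across_contexts: bool = True
    # quadrant patterns
    quadrant_gain: float = 0.0015
    quadrant_mapping: str = "rotation"  # "rotation" | "identity"
    context_specific_frac: float = 0.3
    # grid-like code
    grid_mode: str = "both"             # "rsa_tuning" | "repetition_suppression" | "both" | "none"
    grid_gains: dict = field(
        default_factory=lambda: {"close": 0.0042, "medium": 0.003, "far": 0.0018}
    )
    grid_n_fold: int = 6
    grid_phase: float = 15.0            # degrees, shared across contexts

    @classmethod
    def null(cls, **overrides) -> "PlantedCode":
        """A code with every planted effect switched off."""
        params = dict(
            ego_amplitude=0.0,
            adaptation_gain=0.0,
            quadrant_gain=0.0,
            grid_gains={"close": 0.0, "medium": 0.0, "far": 0.0},
        )
        params.update(overrides)
        return cls(**params)

    def __post_init__(self):
        if self.ego_concentration <= 0:
            raise ValueError("concentration must be positive")
        if any(g < 0 for g in self.grid_gains.values()):
            raise ValueError("grid gains must be non-negative")
        if not 0.0 <= self.grid_phase < 360.0 / max(self.grid_n_fold, 1):
            raise ValueError("grid phase must lie within one symmetry period")

    def scaled(self, factor: float) -> "PlantedCode":
        """Code with all effect gains multiplied by a subject-level factor."""
        return dataclasses.replace(
            self,
            ego_amplitude=self.ego_amplitude * factor,
            quadrant_gain=self.quadrant_gain * factor,
            grid_gains={k: v * factor for k, v in self.grid_gains.items()},
        )


@dataclass
class RealizedCode:
    """Per-voxel realization of a PlantedCode for one subject."""

    code: PlantedCode
    n_voxels: int
    ego_pref: dict                  # context -> (n_voxels,) preferred offsets
    quadrant_patterns: dict         # (context, quadrant) -> (n_voxels,)
    grid_voxel_phase: np.ndarray    # (n_voxels,), degrees


def realize_code(
    code: PlantedCode, n_voxels: int, rng: np.random.Generator
) -> RealizedCode:
    """Draw the per-voxel tuning parameters implied by a PlantedCode."""
    prefs = {}
    shared = rng.choice(EGO_OFFSETS, size=n_voxels)
    for ctx in ("blue", "green"):
        prefs[ctx] = (
            shared
            if code.ego_shared_across_contexts
            else rng.choice(EGO_OFFSETS, size=n_voxels)
        )
    shared_pat = {q: rng.standard_normal(n_voxels) for q in QUADRANTS}
    quad = {}
    for ctx in ("blue", "green"):
        for q in QUADRANTS:
            if ctx == "green" and code.quadrant_mapping == "rotation":
                base = shared_pat[ROTATION_MAP[q]]
            else:
                base = shared_pat[q]
            quad[(ctx, q)] = base + code.context_specific_frac * rng.standard_normal(
                n_voxels
            )
    phases = (code.grid_phase + rng.uniform(0.0, 360.0, size=n_voxels)) % 360.0
    return RealizedCode(
        code=code,
        n_voxels=n_voxels,
        ego_pref=prefs,
        quadrant_patterns=quad,
        grid_voxel_phase=phases,
    )


def _same_condition_lags(onsets: np.ndarray, keys) -> np.ndarray:
    """Elapsed time since the previous trial with the same key (NaN first)."""
    last: dict = {}
    out = np.full(len(onsets), np.nan)
    for i, (t, k) in enumerate(zip(onsets, keys)):
        if k in last:
            out[i] = t - last[k]
        last[k] = t
    return out


def plant_trial_amplitudes(run: RunSpec, realized: RealizedCode) -> np.ndarray:
    """Neural amplitude of each trial in each voxel, shape (48, n_voxels)."""
    code = realized.code
    n = run.n_trials
    V = realized.n_voxels
    ego = np.array([t.ego_offset for t in run.trials], dtype=float)
    onsets = np.array([t.imag_onset_s for t in run.trials])
    amps = np.full((n, V), code.baseline)

    if code.ego_amplitude != 0.0:
        pref = realized.ego_pref[run.context][None, :].astype(float)
        tuning = np.exp(
            code.ego_concentration
            * (np.cos(np.radians(ego[:, None] - pref)) - 1.0)
        )
        lags = _same_condition_lags(onsets, ego)
        release = np.where(np.isnan(lags), 1.0, 1.0 + code.adaptation_gain * np.log(
            np.where(np.isnan(lags), 1.0, lags)
        ))
        amps += code.ego_amplitude * tuning * release[:, None]

    if code.quadrant_gain != 0.0:
        for i, t in enumerate(run.trials):
            amps[i] += code.quadrant_gain * realized.quadrant_patterns[
                (run.context, t.quadrant)
            ]

    gains = np.array(
        [code.grid_gains[goal_distance_class(t.quadrant, run.context)] for t in run.trials]
    )
    if code.grid_mode in ("rsa_tuning", "both") and gains.any():
        theta = np.array([t.allo_bin for t in run.trials], dtype=float)
        tuning = np.cos(
            np.radians(code.grid_n_fold * (theta[:, None] - realized.grid_voxel_phase[None, :]))
        )
        amps += gains[:, None] * tuning
    if code.grid_mode in ("repetition_suppression", "both") and gains.any():
        theta = [t.allo_bin for t in run.trials]
        rs = np.zeros(n)
        for i in range(1, n):
            rs[i] = delta60(theta[i], theta[i - 1]) / 30.0
        amps += (gains * rs)[:, None]
    return amps


@dataclass
class BoldRun:
    """Voxel x time BOLD matrix aligned to a RunSpec's event onsets."""

    data: np.ndarray            # (n_voxels, n_volumes)
    tr_s: float
    run_index: int
    context: str

    @property
    def n_volumes(self) -> int:
        return self.data.shape[1]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def volume_times(self) -> np.ndarray:
        return np.arange(self.n_volumes) * self.tr_s


def n_volumes_for(run: RunSpec, tr_s: float = glm.DEFAULT_TR_S, tail_s: float = 12.0) -> int:
    """Volume count covering the last question period plus an HRF tail."""
    return int(np.ceil((run.duration_s + tail_s) / tr_s))


def simulate_bold_run(
    run: RunSpec,
    amplitudes: np.ndarray,
    noise: NoiseModel,
    rng: np.random.Generator,
    tr_s: float = glm.DEFAULT_TR_S,
) -> BoldRun:
    """HRF-convolved, noisy BOLD for one run.

    Each trial contributes a boxcar over its imagination period scaled by
    its amplitude, built from the same convolved single-trial basis the GLM
    engine uses; AR(1) noise and slow cosine drift are then added.
    """
    n_vol = n_volumes_for(run, tr_s)
    onsets = np.array([t.imag_onset_s for t in run.trials])
    durs = np.array([t.imagine_dur_s for t in run.trials])
    basis = glm.trial_basis(onsets, durs, tr_s, n_vol)
    signal = basis @ amplitudes
    V = amplitudes.shape[1]
    if noise.white_std > 0:
        innov = rng.normal(0.0, noise.white_std, size=(n_vol, V))
        signal = signal + lfilter([1.0], [1.0, -noise.ar1], innov, axis=0)
    if noise.drift_amplitude > 0:
        t = np.arange(n_vol) * tr_s
        periods = (300.0, 180.0)
        drift = sum(
            rng.normal(0.0, noise.drift_amplitude, size=V)[None, :]
            * np.cos(2 * np.pi * t / p)[:, None]
            for p in periods
        )
        signal = signal + drift
    return BoldRun(
        data=np.ascontiguousarray(signal.T),
        tr_s=tr_s,
        run_index=run.run_index,
        context=run.context,
    )


@dataclass
class GazeTrace:
    """Per-volume horizontal/vertical gaze estimates (screen units)."""

    x: np.ndarray
    y: np.ndarray
    tr_s: float

    @property
    def volume_times(self) -> np.ndarray:
        return np.arange(len(self.x)) * self.tr_s


@dataclass(frozen=True)
class GazeModel:
    """Linear gaze model: eyes shift with the egocentric goal angle.

    Calibrated so that the trial-wise correlation between horizontal gaze
    displacement and egocentric angle is small (about 0.02 at default
    noise), matching the weak but group-consistent oculomotor signature the
    analysis is designed to detect.
    """

    ego_slope: float = 0.00032      # screen units per degree
    choice_amplitude: float = 0.04   # shift toward the chosen answer's side
    noise_std: float = 1.0
    answer_lag_s: float = 1.5


def simulate_gaze_run(
    run: RunSpec,
    model: GazeModel,
    rng: np.random.Generator,
    responses: pd.Series | None = None,
    tr_s: float = glm.DEFAULT_TR_S,
    n_volumes: int | None = None,
) -> GazeTrace:
    """Per-volume gaze with ego-angle-locked horizontal displacement.

    Horizontal gaze steps by ``ego_slope * ego_offset`` at imagination
    onset (held through the trial) and, once a response exists, by
    ``choice_amplitude`` toward the chosen option's screen side after the
    question onset.  Vertical gaze is pure noise.
    """
    n_vol = n_volumes or n_volumes_for(run, tr_s)
    t = np.arange(n_vol) * tr_s
    x = rng.normal(0.0, model.noise_std, n_vol)
    y = rng.normal(0.0, model.noise_std, n_vol)
    for i, trial in enumerate(run.trials):
        t_end = trial.question_onset_s + trial.question_dur_s
        in_trial = (t >= trial.imag_onset_s) & (t <= t_end)
        x[in_trial] += model.ego_slope * trial.ego_offset
        if responses is not None:
            resp = responses.iloc[i] if hasattr(responses, "iloc") else responses[i]
            if isinstance(resp, str):
                chosen_side = trial.yes_side if resp == "yes" else (
                    "right" if trial.yes_side == "left" else "left"
                )
                side = 1.0 if chosen_side == "right" else -1.0
                # gaze rests on the chosen option until the next trial starts
                t_next = (
                    run.trials[i + 1].onset_s
                    if i + 1 < len(run.trials)
                    else t[-1] + tr_s
                )
                x[(t > trial.question_onset_s) & (t < t_next)] += (
                    model.choice_amplitude * side
                )
    return GazeTrace(x=x, y=y, tr_s=tr_s)


def simulate_behavior(
    run: RunSpec,
    rng: np.random.Generator,
    rates: dict = None,
    rt_log_mean: float = -0.1,
    rt_log_std: float = 0.3,
) -> pd.DataFrame:
    """Bernoulli yes/no responses at per-(context, question) hit/FA rates."""
    rates = rates or DEFAULT_BEHAVIOR_RATES
    rows = []
    for t in run.trials:
        hit, fa = rates[(t.context, t.question)]
        p_yes = hit if t.expected_answer == "yes" else fa
        resp = "yes" if rng.random() < p_yes else "no"
        rt = float(
            np.clip(rng.lognormal(rt_log_mean, rt_log_std), 0.15, t.question_dur_s)
        )
        rows.append({"response": resp, "rt": rt, "correct": resp == t.expected_answer})
    return pd.DataFrame(rows)


@dataclass
class SubjectData:
    """Everything simulated for one subject, in trial-onset order per run."""

    subject_id: str
    session: SessionSpec
    events: list[pd.DataFrame]      # per run, includes response/rt
    bold: list[BoldRun]
    gaze: list[GazeTrace]
    realized: RealizedCode
    hit_rate: float                 # pooled target-question hit rate
    cache: dict = field(default_factory=dict, repr=False)  # per-run GLM bases


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for a simulated cohort."""

    n_subjects: int = 40
    n_voxels: int = 200
    tr_s: float = glm.DEFAULT_TR_S
    design: DesignConfig = field(default_factory=DesignConfig)
    code: PlantedCode = field(default_factory=PlantedCode)
    noise: NoiseModel = field(default_factory=NoiseModel)
    gaze: GazeModel = field(default_factory=GazeModel)
    simulate_gaze: bool = True
    simulate_bold: bool = True


def simulate_subject(
    subject_id: str,
    seed: int,
    config: CohortConfig,
    code: PlantedCode | None = None,
) -> SubjectData:
    """Simulate one subject's session, BOLD, gaze, and behavior."""
    rng = np.random.default_rng(seed)
    session = generate_session(subject_id, int(rng.integers(2**31)), config.design)
    subj_code = code if code is not None else config.code
    if code is None and config.noise.subject_std > 0:
        factor = max(0.0, 1.0 + rng.normal(0.0, config.noise.subject_std))
        subj_code = subj_code.scaled(factor)
    realized = realize_code(subj_code, config.n_voxels, rng)

    events, bold, gaze = [], [], []
    n_hit = n_target_yes = 0
    for run in session.runs:
        behav = simulate_behavior(run, rng)
        ev = events_frame(run)
        ev["response"] = behav["response"].to_numpy()
        ev["rt"] = behav["rt"].to_numpy()
        events.append(ev)
        if config.simulate_bold:
            amps = plant_trial_amplitudes(run, realized)
            bold.append(simulate_bold_run(run, amps, config.noise, rng, config.tr_s))
        if config.simulate_gaze:
            gaze.append(
                simulate_gaze_run(run, config.gaze, rng, behav["response"], config.tr_s)
            )
        for t, resp in zip(run.trials, behav["response"]):
            if t.question == "target" and t.expected_answer == "yes":
                n_target_yes += 1
                n_hit += resp == "yes"
    return SubjectData(
        subject_id=subject_id,
        session=session,
        events=events,
        bold=bold,
        gaze=gaze,
        realized=realized,
        hit_rate=n_hit / max(n_target_yes, 1),
    )


def iter_cohort(config: CohortConfig, seed: int, codes=None):
    """Yield SubjectData one subject at a time (memory-friendly)."""
    root = np.random.default_rng(seed)
    seeds = root.integers(2**31, size=config.n_subjects)
    for i in range(config.n_subjects):
        code = codes[i] if codes is not None else None
        yield simulate_subject(f"sub-{i + 1:02d}", int(seeds[i]), config, code)


def simulate_cohort(config: CohortConfig, seed: int, codes=None) -> list[SubjectData]:
    """Materialize a full cohort (use iter_cohort for large runs)."""
    return list(iter_cohort(config, seed, codes))


def save_subject(subject: SubjectData, root) -> Path:
    """Write one subject in the documented on-disk layout."""
    sub_dir = Path(root) / subject.subject_id
    sub_dir.mkdir(parents=True, exist_ok=True)
    for i, ev in enumerate(subject.events):
        ev.to_csv(sub_dir / f"run-{i + 1:02d}_events.tsv", sep="\t", index=False)
    for bold in subject.bold:
        np.savez_compressed(
            sub_dir / f"run-{bold.run_index + 1:02d}_bold.npz",
            data=bold.data,
            tr_s=bold.tr_s,
            context=bold.context,
        )
    for i, gz in enumerate(subject.gaze):
        pd.DataFrame({"x": gz.x, "y": gz.y}).to_csv(
            sub_dir / f"run-{i + 1:02d}_gaze.tsv", sep="\t", index=False
        )
    code = subject.realized.code
    manifest = {
        "subject_id": subject.subject_id,
        "seed": subject.session.seed,
        "n_runs": len(subject.session.runs),
        "run_contexts": [r.context for r in subject.session.runs],
        "hit_rate": subject.hit_rate,
        "planted_code": {
            k: (v if not isinstance(v, dict) else dict(v))
            for k, v in dataclasses.asdict(code).items()
        },
    }
    (sub_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return sub_dir
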