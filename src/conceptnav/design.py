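"""Recall-task trial generation under the printed design constraints.

A run holds 48 trials: 12 on-target (egocentric offset 0) and 6 for each of
the six off-target offsets (+/-45, +/-90, +/-135 degrees), with 12 trials
starting in each quadrant.  Half of the trials receive the "target"
question (6 expected-yes, 18 expected-no), the other half a "filler"
question whose probe molecule lies on the current trajectory or 60 degrees
off it.  A session is 8 runs, 4 per color context in shuffled order, and is
rejection-sampled until the pooled correlation between the signed
egocentric condition and the start-to-goal distance is at most 0.03 in
absolute value, so that goal distance cannot stand in for the egocentric
condition in any downstream analysis.

Morph segments never cross a quadrant boundary: the visible part of every
trajectory stays inside the quadrant the trial is assigned to.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import (
    ALLO_BINS,
    CONTEXTS,
    EGO_OFFSETS,
    GOALS,
    QUADRANT_BOXES,
    QUADRANTS,
    assign_quadrant,
    bearing_to,
    bin_allocentric,
    egocentric_offset,
)

FILLER_OFFSETS = ("on", "-60", "+60")


@dataclass(frozen=True)
class DesignConfig:
    """Tunable geometry/timing of the trial generator (units: space / s)."""

    start_margin: float = 0.05      # shrink of each quadrant for start sampling
    morph_length: float = 0.15      # length of the visible morph segment
    static_dur_s: float = 0.5
    morph_dur_s: float = 1.0
    imagine_dur_s: float = 4.0
    question_dur_s: float = 2.0
    iti_range_s: tuple[float, float] = (2.0, 6.0)
    lead_in_s: float = 6.0          # dead time before the first trial
    max_abs_r: float = 0.03         # |r(ego offset, start-goal distance)| cap
    max_session_resamples: int = 10_000
    max_trial_resamples: int = 1_000


@dataclass(frozen=True)
class TrialSpec:
    """One Recall-task trial."""

    context: str
    start: tuple[float, float]
    heading: float                  # allocentric movement direction, [0, 360)
    ego_offset: int                 # signed degrees, one of EGO_OFFSETS
    quadrant: str
    allo_bin: int
    onset_s: float                  # static-image onset
    question: str                   # "target" | "filler"
    filler_offset: str | None       # "on" | "-60" | "+60" for filler trials
    expected_answer: str            # "yes" | "no"
    yes_side: str                   # screen side of the Yes option
    static_dur_s: float = 0.5
    morph_dur_s: float = 1.0
    imagine_dur_s: float = 4.0
    question_dur_s: float = 2.0

    @property
    def morph_onset_s(self) -> float:
        return self.onset_s + self.static_dur_s

    @property
    def imag_onset_s(self) -> float:
        return self.morph_onset_s + self.morph_dur_s

    @property
    def question_onset_s(self) -> float:
        return self.imag_onset_s + self.imagine_dur_s

    @property
    def goal(self) -> tuple[float, float]:
        return GOALS[self.context]

    @property
    def goal_distance(self) -> float:
        gx, gy = self.goal
        return float(np.hypot(gx - self.start[0], gy - self.start[1]))


@dataclass(frozen=True)
class RunSpec:
    context: str
    run_index: int
    trials: tuple[TrialSpec, ...]
    itis_s: tuple[float, ...]

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def duration_s(self) -> float:
        last = self.trials[-1]
        return last.question_onset_s + last.question_dur_s


@dataclass(frozen=True)
class SessionSpec:
    subject_id: str
    seed: int
    runs: tuple[RunSpec, ...]

    @property
    def trials(self) -> list[TrialSpec]:
        return [t for run in self.runs for t in run.trials]


def _sample_trial_geometry(context, quadrants, ego_offsets, rng, cfg):
    """Vectorized rejection sampling of start points and headings.

    Starts are uniform in each trial's quadrant shrunk by the margin;
    headings follow from ``bearing(start, goal) - ego_offset``; a draw is
    rejected when the morph segment would leave the (unshrunk) quadrant.
    """
    n = len(quadrants)
    goal = np.asarray(GOALS[context])
    boxes = np.array([QUADRANT_BOXES[q] for q in quadrants])
    lo = boxes[:, :2] + cfg.start_margin
    hi = boxes[:, 2:] - cfg.start_margin
    eps = 1e-9

    starts = np.empty((n, 2))
    headings = np.empty(n)
    pending = np.arange(n)
    offs = np.asarray(ego_offsets, dtype=float)
    for _ in range(cfg.max_trial_resamples):
        m = len(pending)
        cand = lo[pending] + rng.random((m, 2)) * (hi[pending] - lo[pending])
        vec = goal[None, :] - cand
        bearing = np.degrees(np.arctan2(vec[:, 1], vec[:, 0])) % 360.0
        head = (bearing - offs[pending]) % 360.0
        rad = np.radians(head)
        end = cand + cfg.morph_length * np.stack([np.cos(rad), np.sin(rad)], axis=1)
        inside = (
            (end[:, 0] > boxes[pending, 0] + eps)
            & (end[:, 0] < boxes[pending, 2] - eps)
            & (end[:, 1] > boxes[pending, 1] + eps)
            & (end[:, 1] < boxes[pending, 3] - eps)
        )
        # a start coincident with the goal has no defined bearing
        ok = inside & (np.abs(vec).sum(axis=1) > eps)
        starts[pending[ok]] = cand[ok]
        headings[pending[ok]] = head[ok]
        pending = pending[~ok]
        if pending.size == 0:
            return starts, headings
    raise RuntimeError(
        f"could not place {pending.size} morph segments inside their "
        f"quadrants after {cfg.max_trial_resamples} resamples"
    )


def generate_run(
    context: str,
    run_index: int,
    rng: np.random.Generator,
    cfg: DesignConfig = DesignConfig(),
) -> RunSpec:
    """Generate one 48-trial run satisfying every structural constraint."""
    if context not in CONTEXTS:
        raise ValueError(f"unknown context {context!r}")

    offsets = np.array(
        [0] * 12 + [o for o in EGO_OFFSETS if o != 0 for _ in range(6)]
    )
    rng.shuffle(offsets)
    quadrants = np.repeat(QUADRANTS, 12)

    # question assignment: 6 of the 12 on-target and 18 of the 36 off-target
    # trials get the target question; the rest get fillers (8 per offset type)
    question = np.full(48, "filler", dtype=object)
    on_idx = np.flatnonzero(offsets == 0)
    off_idx = np.flatnonzero(offsets != 0)
    question[rng.choice(on_idx, 6, replace=False)] = "target"
    question[rng.choice(off_idx, 18, replace=False)] = "target"
    filler_offset = np.full(48, None, dtype=object)
    filler_idx = np.flatnonzero(question == "filler")
    filler_types = np.array([f for f in FILLER_OFFSETS for _ in range(8)], dtype=object)
    rng.shuffle(filler_types)
    filler_offset[filler_idx] = filler_types

    expected = np.where(
        question == "target",
        np.where(offsets == 0, "yes", "no"),
        np.where(filler_offset == "on", "yes", "no"),
    )
    yes_side = np.array(["left"] * 24 + ["right"] * 24, dtype=object)
    rng.shuffle(yes_side)

    starts, headings = _sample_trial_geometry(context, quadrants, offsets, rng, cfg)

    order = rng.permutation(48)
    itis = rng.uniform(*cfg.iti_range_s, size=48)
    trial_len = (
        cfg.static_dur_s + cfg.morph_dur_s + cfg.imagine_dur_s + cfg.question_dur_s
    )

    trials = []
    t = cfg.lead_in_s
    for k, i in enumerate(order):
        trials.append(
            TrialSpec(
                context=context,
                start=(float(starts[i, 0]), float(starts[i, 1])),
                heading=float(headings[i]),
                ego_offset=int(offsets[i]),
                quadrant=str(quadrants[i]),
                allo_bin=bin_allocentric(float(headings[i])),
                onset_s=float(t),
                question=str(question[i]),
                filler_offset=filler_offset[i],
                expected_answer=str(expected[i]),
                yes_side=str(yes_side[i]),
                static_dur_s=cfg.static_dur_s,
                morph_dur_s=cfg.morph_dur_s,
                imagine_dur_s=cfg.imagine_dur_s,
                question_dur_s=cfg.question_dur_s,
            )
        )
        t += trial_len + itis[k]
    return RunSpec(
        context=context,
        run_index=run_index,
        trials=tuple(trials),
        itis_s=tuple(float(x) for x in itis),
    )


def _pooled_ego_distance_r(runs) -> float:
    ego = np.array([t.ego_offset for r in runs for t in r.trials], dtype=float)
    dist = np.array([t.goal_distance for r in runs for t in r.trials])
    return float(np.corrcoef(ego, dist)[0, 1])


def generate_session(
    subject_id: str,
    seed: int,
    cfg: DesignConfig = DesignConfig(),
) -> SessionSpec:
    """Generate a full 8-run session (4 blue, 4 green, intermixed).

    The whole layout is rejection-sampled until the pooled correlation
    between signed egocentric offset and start-to-goal distance satisfies
    ``|r| <= cfg.max_abs_r``.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    contexts = np.array(["blue"] * 4 + ["green"] * 4, dtype=object)
    rng.shuffle(contexts)
    for _ in range(cfg.max_session_resamples):
        runs = tuple(
            generate_run(str(c), i, rng, cfg) for i, c in enumerate(contexts)
        )
        if abs(_pooled_ego_distance_r(runs)) <= cfg.max_abs_r:
            return SessionSpec(subject_id=subject_id, seed=seed, runs=runs)
    raise RuntimeError(
        f"no session satisfied |r| <= {cfg.max_abs_r} within "
        f"{cfg.max_session_resamples} resamples"
    )


def design_diagnostics(session: SessionSpec, cfg: DesignConfig = DesignConfig()):
    """Constraint audit of a session: counts, pooled r, boundary crossings.

    Returns a dict with per-run count tables, pooled counts, the pooled
    ego/distance Pearson r, the number of morph segments leaving their
    quadrant, and a ``passes`` flag summarizing every invariant.
    """
    rows = []
    violations = 0
    for run in session.runs:
        ego_counts = {o: 0 for o in EGO_OFFSETS}
        quad_counts = {q: 0 for q in QUADRANTS}
        q_counts = {"target": 0, "filler": 0}
        yes_target = 0
        for t in run.trials:
            ego_counts[t.ego_offset] += 1
            quad_counts[t.quadrant] += 1
            q_counts[t.question] += 1
            if t.question == "target" and t.expected_answer == "yes":
                yes_target += 1
            rad = np.radians(t.heading)
            end = (
                t.start[0] + cfg.morph_length * np.cos(rad),
                t.start[1] + cfg.morph_length * np.sin(rad),
            )
            try:
                same = assign_quadrant(end) == t.quadrant == assign_quadrant(t.start)
            except ValueError:
                same = False
            if not same:
                violations += 1
        rows.append(
            {
                "run": run.run_index,
                "context": run.context,
                "n_trials": run.n_trials,
                **{f"ego_{o}": c for o, c in ego_counts.items()},
                **{q: c for q, c in quad_counts.items()},
                "target_questions": q_counts["target"],
                "filler_questions": q_counts["filler"],
                "expected_yes_target": yes_target,
            }
        )
    per_run = pd.DataFrame(rows)
    pooled_r = _pooled_ego_distance_r(session.runs)
    n_trials = sum(r.n_trials for r in session.runs)
    n_blue = sum(1 for r in session.runs if r.context == "blue")
    passes = (
        violations == 0
        and abs(pooled_r) <= cfg.max_abs_r
        and n_trials == 384
        and n_blue == 4
        and bool((per_run["n_trials"] == 48).all())
        and bool((per_run["ego_0"] == 12).all())
        and all((per_run[f"ego_{o}"] == 6).all() for o in EGO_OFFSETS if o != 0)
        and all((per_run[q] == 12).all() for q in QUADRANTS)
        and bool((per_run["target_questions"] == 24).all())
        and bool((per_run["expected_yes_target"] == 6).all())
    )
    return {
        "per_run": per_run,
        "n_trials": n_trials,
        "n_blue_runs": n_blue,
        "pooled_ego_distance_r": pooled_r,
        "boundary_violations": violations,
        "passes": passes,
    }


EVENT_COLUMNS = [
    "onset",
    "duration",
    "trial_type",
    "context",
    "ego_offset",
    "allo_bin",
    "quadrant",
    "question",
    "filler_offset",
    "expected_answer",
    "yes_side",
    "start_x",
    "start_y",
    "heading",
    "goal_distance",
    "morph_onset",
    "imag_onset",
    "question_onset",
    "response",
    "rt",
]


def events_frame(run: RunSpec) -> pd.DataFrame:
    """BIDS-style events table for one run (one row per trial).

    ``onset``/``duration`` describe the imagination period, the epoch every
    first-level model uses; the stimulus sub-epochs are kept in dedicated
    columns.  ``response``/``rt`` are NaN until behavior is simulated or
    recorded.
    """
    rows = []
    for t in run.trials:
        rows.append(
            {
                "onset": t.imag_onset_s,
                "duration": t.imagine_dur_s,
                "trial_type": "imagination",
                "context": t.context,
                "ego_offset": t.ego_offset,
                "allo_bin": t.allo_bin,
                "quadrant": t.quadrant,
                "question": t.question,
                "filler_offset": t.filler_offset if t.filler_offset else "n/a",
                "expected_answer": t.expected_answer,
                "yes_side": t.yes_side,
                "start_x": t.start[0],
                "start_y": t.start[1],
                "heading": t.heading,
                "goal_distance": t.goal_distance,
                "morph_onset": t.morph_onset_s,
                "imag_onset": t.imag_onset_s,
                "question_onset": t.question_onset_s,
                "response": np.nan,
                "rt": np.nan,
            }
        )
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def write_events(run_or_frame, path) -> None:
    frame = run_or_frame if isinstance(run_or_frame, pd.DataFrame) else events_frame(run_or_frame)
    frame.to_csv(path, sep="\t", index=False)


def read_events(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
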