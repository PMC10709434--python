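"""Subject- and cohort-level orchestration of the analyses.

Each subject-level function consumes a ``SubjectData`` (from the synthetic
generator or loaded from disk), fits the relevant per-run GLMs, and
reduces to one scalar (or small record) per subject.  Cohort wrappers
stream subjects (the full BOLD of a subject never needs to coexist with
another's), collect subject statistics into a table, and run the group
tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import adaptation as adapt_mod
from . import glm
from .decoding import cross_context_decode, within_context_decode
from .geometry import ALLO_BINS, EGO_OFFSETS, QUADRANTS
from .grid import (
    GoalModulationResult,
    N_FOLDS,
    build_symmetry_model,
    goal_modulation_modulators,
    grid_rsa_score,
)
from .rotation import rotation_score, rotation_similarity_matrix
from .stats import (
    behavior_metrics,
    gaze_choice_validation,
    gaze_egocentric_correlation,
    group_test,
)
from .synth import CohortConfig, iter_cohort


def run_forward_basis(ev: pd.DataFrame, n_volumes: int, tr_s: float, cache=None, key=None):
    """Convolved single-trial basis and response regressor for one run.

    One fftconvolve covers the 48 imagination boxcars and the response
    impulses together; the result is memoized in ``cache`` (keyed per run)
    because every analysis of a run shares the same forward model.
    """
    if cache is not None and key in cache:
        return cache[key]
    onsets = ev["onset"].to_numpy()
    durs = ev["duration"].to_numpy()
    rts = np.nan_to_num(ev["rt"].to_numpy(dtype=float), nan=1.0)
    all_onsets = np.concatenate([onsets, ev["question_onset"].to_numpy() + rts])
    all_durs = np.concatenate([durs, np.zeros(len(ev))])
    full = glm.trial_basis(all_onsets, all_durs, tr_s, n_volumes)
    basis = full[:, : len(ev)]
    extra = {"response": full[:, len(ev):].sum(axis=1)}
    out = (basis, extra)
    if cache is not None:
        cache[key] = out
    return out


def fit_condition_glm(
    ev: pd.DataFrame,
    bold,
    condition_col: str,
    tr_s: float = glm.DEFAULT_TR_S,
    modulators=None,
    cache=None,
    cache_key=None,
):
    """One regressor per condition level present in the run, plus extras."""
    ev = ev.sort_values("onset").reset_index(drop=True)
    basis, extra = run_forward_basis(ev, bold.n_volumes, tr_s, cache, cache_key)
    labels = ev[condition_col].astype(str).to_numpy(dtype=object)
    design = glm.compose_design(
        basis, labels, tr_s, modulators=modulators, extra_columns=extra
    )
    return glm.fit_glm(bold, design), ev


def subject_patterns(subject, kind: str, tr_s: float = glm.DEFAULT_TR_S):
    """Per-run condition patterns: kind "ego7", "quad4", or "dir12"."""
    col, conditions = {
        "ego7": ("ego_offset", [str(o) for o in EGO_OFFSETS]),
        "quad4": ("quadrant", list(QUADRANTS)),
        "dir12": ("allo_bin", [str(b) for b in ALLO_BINS]),
    }[kind]
    fits = {}
    cache = getattr(subject, "cache", None)
    for i, (ev, bold) in enumerate(zip(subject.events, subject.bold)):
        fit, _ = fit_condition_glm(ev, bold, col, tr_s, cache=cache, cache_key=i)
        fits[(bold.context, bold.run_index)] = fit
    return glm.extract_condition_patterns(fits, conditions)


def subject_decoding(subject, exclude_on_target=False, tr_s=glm.DEFAULT_TR_S):
    ps = subject_patterns(subject, "ego7", tr_s)
    # run-level betas as exemplars: 4 training patterns per condition
    ps.labels = ps.labels.astype(object)
    cross = cross_context_decode(ps, subject.subject_id, exclude_on_target)
    return cross


def subject_within_decoding(subject, exclude_on_target=False, tr_s=glm.DEFAULT_TR_S):
    ps = subject_patterns(subject, "ego7", tr_s)
    return within_context_decode(ps, subject.subject_id, exclude_on_target)


def subject_rotation(subject, control="none", tr_s=glm.DEFAULT_TR_S):
    ps = subject_patterns(subject, "quad4", tr_s).average_runs()
    blue = {q: ps.pattern("blue", q) for q in QUADRANTS}
    green = {q: ps.pattern("green", q) for q in QUADRANTS}
    return rotation_score(rotation_similarity_matrix(blue, green), control)


def subject_grid_scores(subject, n_folds=N_FOLDS, tr_s=glm.DEFAULT_TR_S):
    ps = subject_patterns(subject, "dir12", tr_s).average_runs()
    pa = np.array([ps.pattern("blue", str(b)) for b in ALLO_BINS])
    pb = np.array([ps.pattern("green", str(b)) for b in ALLO_BINS])
    out = {}
    for n in n_folds:
        model = build_symmetry_model(n)
        out[n] = (
            float("nan") if model.is_degenerate else grid_rsa_score(pa, pb, model)
        )
    return out


def subject_goal_modulation(subject, tr_s=glm.DEFAULT_TR_S) -> GoalModulationResult:
    """Per-quadrant grid-modulation betas mapped to goal-distance classes."""
    accum: dict = {}
    cache = getattr(subject, "cache", None)
    for i, (ev, bold) in enumerate(zip(subject.events, subject.bold)):
        ev = ev.sort_values("onset").reset_index(drop=True)
        delta = goal_modulation_modulators(ev)
        mods = []
        for q in QUADRANTS:
            vals = np.where(ev["quadrant"].to_numpy() == q, delta, np.nan)
            in_q = ~np.isnan(vals)
            if in_q.sum() < 2 or np.nanstd(vals) == 0:
                continue  # unmodulatable quadrant in this run
            mods.append(glm.Modulator(f"{q}_delta60", q, vals))
        fit, _ = fit_condition_glm(
            ev, bold, "quadrant", tr_s, modulators=mods, cache=cache, cache_key=i
        )
        for mod in mods:
            q = mod.condition
            accum.setdefault((bold.context, q), []).append(
                float(fit.beta(mod.name).mean())
            )
    betas = {key: float(np.mean(v)) for key, v in accum.items()}
    return GoalModulationResult.from_quadrant_betas(betas)


ANALYSES = (
    "behavior",
    "gaze",
    "adaptation",
    "decoding",
    "rotation",
    "grid_rsa",
    "goal_modulation",
)


@dataclass
class CohortResult:
    """Per-subject statistics table plus group tests keyed by analysis."""

    table: pd.DataFrame
    group: dict


def analyze_cohort(
    config: CohortConfig,
    seed: int,
    analyses=ANALYSES,
    codes=None,
    adaptation_variant: str = "main",
    rotation_control: str = "none",
    grid_folds=(6,),
) -> CohortResult:
    """Simulate and analyze a cohort subject by subject.

    Returns one row per subject with the requested statistics, plus group
    tests: one-sided (positive) for adaptation, decoding, rotation, and
    goal modulation, two-sided for the grid-RSA and gaze scores, matching
    the sidedness used for each analysis in the original design.
    """
    rows = []
    for subject in iter_cohort(config, seed, codes):
        row: dict = {"subject_id": subject.subject_id, "hit_rate": subject.hit_rate}
        if "behavior" in analyses:
            bm = behavior_metrics(pd.concat(subject.events, ignore_index=True))
            for _, rec in bm.iterrows():
                row[f"hit_{rec.context}_{rec.question}"] = rec.hit_pct
                row[f"fa_{rec.context}_{rec.question}"] = rec.fa_pct
        if "gaze" in analyses and subject.gaze:
            gz = gaze_egocentric_correlation(subject.gaze, subject.events)
            row["gaze_z_horizontal"] = gz["z_horizontal"]
            row["gaze_z_vertical"] = gz["z_vertical"]
            cv = gaze_choice_validation(subject.gaze, subject.events)
            row["gaze_choice_z"] = cv["z"]
        if "adaptation" in analyses:
            for res in adapt_mod.subject_adaptation(
                subject, adaptation_variant, config.tr_s
            ):
                suffix = "" if res.context == "all" else f"_{res.context}"
                row[f"adaptation_beta{suffix}"] = res.beta
        if "decoding" in analyses:
            row["decoding_above_chance"] = subject_decoding(
                subject, tr_s=config.tr_s
            ).above_chance_pct
        if "rotation" in analyses:
            row["rotation_score"] = subject_rotation(
                subject, rotation_control, config.tr_s
            )
        if "grid_rsa" in analyses:
            scores = subject_grid_scores(subject, grid_folds, config.tr_s)
            for n, z in scores.items():
                row[f"grid_z_{n}fold"] = z
        if "goal_modulation" in analyses:
            gm = subject_goal_modulation(subject, config.tr_s)
            row["goalmod_contrast"] = gm.contrast
            row["goalmod_trend"] = gm.linear_trend
            for cls, b in gm.class_betas.items():
                row[f"goalmod_{cls}"] = b
        rows.append(row)
    table = pd.DataFrame(rows)

    group = {}
    one_sided = {
        "adaptation_beta": "greater",
        "decoding_above_chance": "greater",
        "rotation_score": "greater",
        "goalmod_contrast": "greater",
    }
    for col in table.columns:
        if col in ("subject_id",) or table[col].dtype == object:
            continue
        base = col
        sided = one_sided.get(base, "two")
        vals = table[col].dropna().to_numpy()
        if len(vals) >= 3 and np.std(vals) > 0:
            group[col] = group_test(vals, sided=sided, gate_normality=False)
    return CohortResult(table=table, group=group)
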