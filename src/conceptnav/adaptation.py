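"""Egocentric-condition fMRI adaptation analysis with control variants.

A region that codes the seven egocentric conditions separately should show
repetition suppression specific to each condition: the response to a trial
grows with the (log) time elapsed since the last trial of the same
condition ("release from adaptation").  Per run, a GLM models the
imagination periods with one task regressor plus a parametric log-recency
modulator over repeat trials (first presentations of each condition carry
no lag and are modeled by an unmodulated companion regressor); the
modulator beta, averaged over an ROI's voxels and over runs, is the
subject-level adaptation effect, tested against zero at the group level.

Variants reproduce the control analyses: off-target trials only, each
context separately, a coarse left-vs-right condition code, and joint
covariates for goal distance, starting-point recency, and allocentric
("head-direction-like") recency.  Lags never cross run boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import glm

VARIANTS = (
    "main",
    "off_target_only",
    "per_context",
    "left_right",
    "distance_controlled",
    "startpoint_controlled",
    "headdirection_controlled",
)


def adaptation_lags(onsets, keys):
    """Log elapsed time since the previous trial with the same key.

    ``onsets`` must be strictly increasing (one run).  Returns
    ``(log_lags, included)`` where first presentations of each key have
    ``included = False`` and NaN log lag.
    """
    onsets = np.asarray(onsets, dtype=float)
    if len(onsets) > 1 and not np.all(np.diff(onsets) > 0):
        raise ValueError("onsets must be strictly increasing within a run")
    keys = list(keys)
    last: dict = {}
    log_lags = np.full(len(onsets), np.nan)
    for i, (t, k) in enumerate(zip(onsets, keys)):
        if k in last:
            log_lags[i] = np.log(t - last[k])
        last[k] = t
    return log_lags, ~np.isnan(log_lags)


def _variant_plan(events: pd.DataFrame, variant: str):
    """Trial filter, condition key, and covariate keys for a variant.

    Returns (keep mask, key series, covariates) where each covariate is
    ``(name, kind, values-or-key)`` with kind "recency" (log time since the
    same covariate key) or "value" (trial-wise modulator value).
    """
    ego = events["ego_offset"].astype(int)
    keep = pd.Series(True, index=events.index)
    key = ego
    covariates = []
    if variant in ("main", "per_context", "distance_controlled",
                   "startpoint_controlled", "headdirection_controlled"):
        pass
    elif variant == "off_target_only":
        keep = ego != 0
    elif variant == "left_right":
        keep = ego != 0
        key = np.sign(ego)
    else:
        raise ValueError(f"unknown variant {variant!r}")
    if variant == "distance_controlled":
        covariates.append(("distance", "value", events["goal_distance"]))
    elif variant == "startpoint_controlled":
        # starting positions are continuous and never repeat exactly; the
        # starting quadrant is the repeatable granularity of the design
        covariates.append(("start_recency", "recency", events["quadrant"]))
    elif variant == "headdirection_controlled":
        covariates.append(("allo_recency", "recency", events["allo_bin"]))
    return keep, pd.Series(np.asarray(key), index=events.index), covariates


@dataclass
class AdaptationResult:
    subject_id: str
    variant: str
    context: str                # "all" | "blue" | "green"
    beta: float                 # ROI-mean log-recency modulator beta
    covariate_betas: dict


def run_adaptation_glm(
    events: pd.DataFrame,
    bold,
    variant: str = "main",
    tr_s: float = glm.DEFAULT_TR_S,
    cache=None,
    cache_key=None,
) -> dict:
    """Fit the adaptation GLM for one run; returns per-voxel modulator betas.

    Trials dropped by the variant filter are kept in the design as a
    regressor of no interest, so their BOLD response stays modeled.
    """
    ev = events.sort_values("onset").reset_index(drop=True)
    keep, key, covariates = _variant_plan(ev, variant)
    keep = keep.to_numpy()
    log_lags, included = adaptation_lags(
        ev.loc[keep, "onset"].to_numpy(), key[keep]
    )
    n = len(ev)
    recency = np.full(n, np.nan)
    kept_idx = np.flatnonzero(keep)
    recency[kept_idx[included]] = log_lags[included]

    labels = np.where(keep, "task", "excluded").astype(object)
    mods = [glm.Modulator("log_recency", "task", recency)]
    modulated = ~np.isnan(recency)
    for name, kind, values in covariates:
        if kind == "recency":
            cov_lags, cov_inc = adaptation_lags(
                ev.loc[keep, "onset"].to_numpy(), np.asarray(values)[keep]
            )
            cov = np.full(n, np.nan)
            cov[kept_idx[cov_inc]] = cov_lags[cov_inc]
        else:
            cov = np.where(modulated, np.asarray(values, dtype=float), np.nan)
        mods.append(glm.Modulator(name, "task", cov))

    from .pipeline import run_forward_basis

    n_vol = bold.n_volumes if hasattr(bold, "n_volumes") else bold.shape[0]
    basis, extra = run_forward_basis(ev, n_vol, tr_s, cache, cache_key)
    design = glm.compose_design(
        basis, labels, tr_s, modulators=mods, extra_columns=extra
    )
    fit = glm.fit_glm(bold, design)
    out = {"log_recency": fit.beta("log_recency")}
    for name, _, _ in covariates:
        out[name] = fit.beta(name)
    return out


def subject_adaptation(
    subject, variant: str = "main", tr_s: float = glm.DEFAULT_TR_S
) -> list[AdaptationResult]:
    """ROI-mean adaptation beta(s) for one simulated/loaded subject.

    The ROI is the full simulated voxel set.  For the per-context variant
    one result per context is returned; otherwise a single pooled result.
    """
    scopes = (
        [("blue", "blue"), ("green", "green")]
        if variant == "per_context"
        else [("all", None)]
    )
    run_variant = "main" if variant == "per_context" else variant
    results = []
    cache = getattr(subject, "cache", None)
    for label, ctx in scopes:
        betas, cov_accum = [], {}
        for i, (ev, bold) in enumerate(zip(subject.events, subject.bold)):
            if ctx is not None and bold.context != ctx:
                continue
            voxelwise = run_adaptation_glm(
                ev, bold, run_variant, tr_s, cache=cache, cache_key=i
            )
            betas.append(float(voxelwise["log_recency"].mean()))
            for name, vals in voxelwise.items():
                if name != "log_recency":
                    cov_accum.setdefault(name, []).append(float(vals.mean()))
        results.append(
            AdaptationResult(
                subject_id=subject.subject_id,
                variant=variant,
                context=label,
                beta=float(np.mean(betas)),
                covariate_betas={k: float(np.mean(v)) for k, v in cov_accum.items()},
            )
        )
    return results


def brain_behavior_correlation(betas, hit_rates) -> tuple[float, float]:
    """Two-sided Pearson correlation between adaptation betas and hit rates."""
    from scipy import stats as sp_stats

    r, p = sp_stats.pearsonr(np.asarray(betas, float), np.asarray(hit_rates, float))
    return float(r), float(p)
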