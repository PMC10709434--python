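"""First-level GLM machinery: HRF, design matrices, OLS fits, contrasts.

Event regressors are boxcars over the imagination period convolved with a
canonical double-gamma HRF on a grid oversampled 10x relative to the TR and
then sampled at volume acquisition times (volume ``i`` at ``i * TR``).
Parametric modulators are the same boxcars scaled, before convolution, by
trial-wise values mean-centered within run; multiple modulators of one
regressor are entered jointly, with no serial orthogonalization, so that
"controlling for" a covariate means exactly joint OLS estimation.  A
discrete-cosine drift basis (128 s cutoff) plus intercept completes the
design.  Estimation is plain OLS; temporal autocorrelation is absorbed at
the group level, which is where all inference in this package happens.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

DEFAULT_TR_S = 1.5
OVERSAMPLE = 10
DRIFT_CUTOFF_S = 128.0


def canonical_hrf(dt: float, length_s: float = 32.0) -> np.ndarray:
    """Canonical double-gamma HRF sampled every ``dt`` seconds.

    Difference of two gamma densities (peak delay 6 s, undershoot delay
    16 s, unit dispersions, peak:undershoot ratio 6), truncated at
    ``length_s`` and normalized to unit peak.  The value at t=0 is 0.
    """
    t = np.arange(0.0, length_s, dt)
    h = sp_stats.gamma.pdf(t, 6.0) - sp_stats.gamma.pdf(t, 16.0) / 6.0
    return h / h.max()


def trial_basis(
    onsets,
    durations,
    tr_s: float,
    n_volumes: int,
    oversample: int = OVERSAMPLE,
) -> np.ndarray:
    """Convolved single-trial regressors, shape (n_volumes, n_trials).

    Column ``j`` is the boxcar ``[onsets[j], onsets[j] + durations[j])``
    convolved with the canonical HRF and sampled at volume times.  Every
    condition or modulator regressor in this package is a weighted sum of
    these columns, which makes the analysis forward model and the
    synthetic-BOLD forward model literally the same code path.
    """
    onsets = np.atleast_1d(np.asarray(onsets, dtype=float))
    durations = np.broadcast_to(
        np.asarray(durations, dtype=float), onsets.shape
    ).copy()
    dt = tr_s / oversample
    n_hi = n_volumes * oversample
    if onsets.size and (onsets + durations).max() > n_hi * dt:
        raise ValueError("event extends beyond the end of the scan")
    a = np.round(onsets / dt).astype(int)
    b = np.maximum(a + 1, np.round((onsets + durations) / dt).astype(int))
    hrf = canonical_hrf(dt)
    # a boxcar convolved with the HRF is a difference of cumulative HRFs,
    # so the convolution is evaluated in closed form at the volume times
    cum = np.concatenate([[0.0], np.cumsum(hrf)])
    L = len(hrf)
    t_idx = np.arange(n_volumes)[:, None] * oversample
    upper = np.clip(t_idx - a[None, :] + 1, 0, L)
    lower = np.clip(t_idx - b[None, :] + 1, 0, L)
    return cum[upper] - cum[lower]


def cosine_drift_basis(
    n_volumes: int, tr_s: float, cutoff_s: float = DRIFT_CUTOFF_S
) -> np.ndarray:
    """Intercept plus DCT-II low-frequency drift columns (periods > cutoff)."""
    t_total = n_volumes * tr_s
    order = int(np.floor(2.0 * t_total / cutoff_s))
    frame = np.arange(n_volumes)
    cols = [np.ones(n_volumes)]
    for k in range(1, order + 1):
        cols.append(np.cos(np.pi * k * (2 * frame + 1) / (2 * n_volumes)))
    return np.column_stack(cols)


@dataclass
class Modulator:
    """A trial-wise parametric modulator attached to one condition.

    ``values`` aligns with the full trial list of the run; entries for
    trials of other conditions are ignored, and NaN marks trials excluded
    from modulation (e.g. first presentations), which are split into an
    unmodulated companion regressor so they still have a forward model.
    Values are mean-centered over the modulated trials within run.
    """

    name: str
    condition: str
    values: np.ndarray


@dataclass
class DesignMatrix:
    matrix: np.ndarray          # (n_volumes, n_regressors)
    names: list[str]
    n_volumes: int
    tr_s: float

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.names.index(name)]

    @property
    def rank(self) -> int:
        return int(np.linalg.matrix_rank(self.matrix))


def compose_design(
    basis: np.ndarray,
    condition_of_trial,
    tr_s: float,
    modulators: list[Modulator] | None = None,
    extra_columns: dict[str, np.ndarray] | None = None,
    add_drift: bool = True,
    check_rank: bool = True,
) -> DesignMatrix:
    """Assemble a design from a precomputed single-trial basis.

    ``condition_of_trial`` labels each basis column; labels set to ``None``
    drop the trial from the task model entirely.
    """
    n_vol = basis.shape[0]
    labels = np.asarray(condition_of_trial, dtype=object)
    cols: list[np.ndarray] = []
    names: list[str] = []
    conditions = [c for c in pd.unique(labels) if c is not None]
    mods = modulators or []
    modulated = {}  # condition -> boolean mask of modulated trials
    for mod in mods:
        vals = np.asarray(mod.values, dtype=float)
        mask = (labels == mod.condition) & ~np.isnan(
            np.where(labels == mod.condition, vals, np.nan)
        )
        modulated.setdefault(mod.condition, np.zeros(len(labels), bool))
        modulated[mod.condition] |= mask

    for cond in conditions:
        sel = labels == cond
        cols.append(basis[:, sel].sum(axis=1))
        names.append(str(cond))
    for mod in mods:
        vals = np.asarray(mod.values, dtype=float)
        sel = (labels == mod.condition) & ~np.isnan(vals)
        if not sel.any():
            raise ValueError(f"modulator {mod.name!r} has no modulated trials")
        centered = np.zeros(len(labels))
        centered[sel] = vals[sel] - vals[sel].mean()
        cols.append(basis @ centered)
        names.append(mod.name)
    # trials of a modulated condition that are excluded from modulation get
    # their own unmodulated regressor so the modulator stays interpretable
    for cond, mask in modulated.items():
        rest = (labels == cond) & ~mask
        if rest.any():
            cols.append(basis[:, rest].sum(axis=1))
            names.append(f"{cond}_unmodulated")
            # remove those trials from the main condition column
            main = names.index(str(cond))
            cols[main] = basis[:, mask].sum(axis=1)
    for name, col in (extra_columns or {}).items():
        cols.append(np.asarray(col, dtype=float))
        names.append(name)
    if add_drift:
        drift = cosine_drift_basis(n_vol, tr_s)
        for k in range(drift.shape[1]):
            cols.append(drift[:, k])
            names.append("intercept" if k == 0 else f"drift_{k}")
    X = np.column_stack(cols)
    dm = DesignMatrix(matrix=X, names=names, n_volumes=n_vol, tr_s=tr_s)
    if check_rank and dm.rank < X.shape[1]:
        raise ValueError(f"design matrix is rank deficient ({dm.rank}/{X.shape[1]})")
    return dm


def build_design_matrix(
    events: pd.DataFrame,
    tr_s: float,
    n_volumes: int,
    condition_col: str | None = None,
    modulators: list[Modulator] | None = None,
    response_col: str | None = "question_onset",
    nuisance: np.ndarray | None = None,
    oversample: int = OVERSAMPLE,
    add_drift: bool = True,
    check_rank: bool = True,
) -> DesignMatrix:
    """Design matrix from an events table.

    Task regressors are imagination-period boxcars grouped by
    ``condition_col`` (a single "task" regressor when None).  Response
    events (question onset + reaction time, impulses) and optional nuisance
    columns are appended, then the drift basis.
    """
    ev = events.sort_values("onset").reset_index(drop=True)
    basis = trial_basis(
        ev["onset"].to_numpy(), ev["duration"].to_numpy(), tr_s, n_volumes, oversample
    )
    labels = (
        ev[condition_col].astype(object).to_numpy()
        if condition_col
        else np.array(["task"] * len(ev), dtype=object)
    )
    extra: dict[str, np.ndarray] = {}
    if response_col is not None and response_col in ev:
        rts = ev["rt"].to_numpy(dtype=float) if "rt" in ev else np.zeros(len(ev))
        rts = np.nan_to_num(rts, nan=1.0)
        resp_onsets = ev[response_col].to_numpy(dtype=float) + rts
        resp = trial_basis(resp_onsets, 0.0, tr_s, n_volumes, oversample)
        extra["response"] = resp.sum(axis=1)
    if nuisance is not None:
        nuisance = np.atleast_2d(np.asarray(nuisance, dtype=float))
        if nuisance.shape[0] != n_volumes:
            nuisance = nuisance.T
        for k in range(nuisance.shape[1]):
            extra[f"nuisance_{k}"] = nuisance[:, k]
    return compose_design(
        basis,
        labels,
        tr_s,
        modulators=modulators,
        extra_columns=extra,
        add_drift=add_drift,
        check_rank=check_rank,
    )


@dataclass
class GlmFit:
    betas: np.ndarray           # (n_regressors, n_voxels)
    sigma2: np.ndarray          # (n_voxels,) unbiased residual variance
    dof: int
    names: list[str]
    xtx_inv: np.ndarray

    def beta(self, name: str) -> np.ndarray:
        return self.betas[self.names.index(name)]


def fit_glm(bold, design: DesignMatrix) -> GlmFit:
    """Per-voxel OLS fit of a design to a BOLD run.

    ``bold`` is a BoldRun (voxel x time) or an (n_volumes, n_voxels) array.
    """
    Y = (
        bold.data.T
        if hasattr(bold, "n_voxels")
        else np.asarray(bold, dtype=float)
    )
    if Y.ndim == 1:
        Y = Y[:, None]
    X = design.matrix
    if Y.shape[0] != X.shape[0]:
        raise ValueError(
            f"BOLD has {Y.shape[0]} volumes but design expects {X.shape[0]}"
        )
    pinv = np.linalg.pinv(X)
    betas = pinv @ Y
    resid = Y - X @ betas
    rank = design.rank
    dof = X.shape[0] - rank
    sigma2 = (resid**2).sum(axis=0) / dof
    return GlmFit(
        betas=betas,
        sigma2=sigma2,
        dof=dof,
        names=list(design.names),
        xtx_inv=np.linalg.pinv(X.T @ X),
    )


def contrast_t(fit: GlmFit, weights) -> np.ndarray:
    """Per-voxel t statistic for a contrast ``w' beta``."""
    w = np.zeros(len(fit.names))
    if isinstance(weights, dict):
        for name, val in weights.items():
            w[fit.names.index(name)] = val
    else:
        w[: len(weights)] = np.asarray(weights, dtype=float)
    if not np.any(w):
        raise ValueError("contrast weights are all zero")
    num = w @ fit.betas
    den = np.sqrt(fit.sigma2 * (w @ fit.xtx_inv @ w))
    return num / den


@dataclass
class PatternSet:
    """Condition-by-voxel response estimates keyed by context and run."""

    X: np.ndarray               # (n_patterns, n_voxels)
    labels: np.ndarray          # condition label per pattern
    contexts: np.ndarray
    runs: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=object)
        self.contexts = np.asarray(self.contexts, dtype=object)
        self.runs = np.asarray(self.runs)

    def select(self, context=None, run=None) -> "PatternSet":
        mask = np.ones(len(self.labels), dtype=bool)
        if context is not None:
            mask &= self.contexts == context
        if run is not None:
            mask &= self.runs == run
        return PatternSet(
            self.X[mask], self.labels[mask], self.contexts[mask], self.runs[mask]
        )

    def average_runs(self) -> "PatternSet":
        """One pattern per (context, label), averaged over runs."""
        keys, X, labels, contexts = [], [], [], []
        for ctx in pd.unique(self.contexts):
            sub_ctx = self.contexts == ctx
            for lab in pd.unique(self.labels[sub_ctx]):
                sel = sub_ctx & (self.labels == lab)
                keys.append((ctx, lab))
                X.append(self.X[sel].mean(axis=0))
                labels.append(lab)
                contexts.append(ctx)
        return PatternSet(
            np.array(X), np.array(labels, dtype=object),
            np.array(contexts, dtype=object), np.zeros(len(keys), dtype=int),
        )

    def pattern(self, context, label) -> np.ndarray:
        sel = (self.contexts == context) & (self.labels == label)
        if not sel.any():
            raise KeyError((context, label))
        return self.X[sel].mean(axis=0)


def extract_condition_patterns(
    fits: dict, conditions, require_complete: bool = True
) -> PatternSet:
    """Collect named condition betas from per-run fits into a PatternSet.

    ``fits`` maps ``(context, run_index)`` to a GlmFit whose regressor names
    include the condition labels (as strings).  With ``require_complete``,
    a condition absent from every run of a context is an error.
    """
    X, labels, contexts, runs = [], [], [], []
    seen: dict[str, set] = {}
    for (context, run), fit in fits.items():
        for cond in conditions:
            name = str(cond)
            if name in fit.names:
                X.append(fit.beta(name))
                labels.append(cond)
                contexts.append(context)
                runs.append(run)
                seen.setdefault(context, set()).add(cond)
    if require_complete:
        for context, got in seen.items():
            missing = [c for c in conditions if c not in got]
            if missing:
                raise ValueError(
                    f"conditions {missing} missing from every run of {context!r}"
                )
    return PatternSet(np.array(X), labels, contexts, np.array(runs))
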