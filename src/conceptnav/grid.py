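"""Grid-like (hexadirectional) signal analyses.

Two complementary probes of a direction-modulated, grid-cell-like
population signal:

* a cross-context representational similarity analysis: multivoxel
  patterns evoked by 12 allocentric direction bins in one context are
  correlated with those in the other context, and the (symmetrized,
  diagonal-free) similarity matrix is compared with a model that predicts
  higher similarity for direction pairs separated by a multiple of 60
  degrees (with 90-, 120-, 72-, 51.4-, and 45-degree periodicities as
  control symmetries);
* a repetition-suppression probe of goal modulation: trial amplitudes are
  modeled, separately per quadrant, as a function of the angular distance
  in 60-degree rotational space from the previous trial, and the resulting
  grid-modulation betas are contrasted between the goal ("close") quadrant
  and the diagonally opposite ("far") one, with Q1/Q4 ("medium") averaged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import ALLO_BINS, goal_distance_class
from .stats import fisher_z

N_FOLDS = (3, 4, 5, 6, 7, 8)


def delta60(theta1: float, theta2: float) -> float:
    """Angular distance between two directions in 60-degree rotational space.

    Bounded in [0, 30]: 0 for directions a multiple of 60 degrees apart
    (perfectly aligned, maximally suppressed on repetition), 30 for
    directions maximally misaligned (30 degrees off the nearest multiple).
    """
    d = abs(theta1 - theta2) % 60.0
    return min(d, 60.0 - d)


@dataclass(frozen=True)
class SymmetryModel:
    """Aligned/misaligned indicator matrix over the 12 direction bins."""

    n_fold: int
    period: float
    aligned: np.ndarray         # (12, 12) bool; diagonal excluded via mask
    off_diagonal: np.ndarray    # (12, 12) bool

    @property
    def n_aligned_pairs(self) -> int:
        return int(self.aligned[np.tril_indices(12, -1)].sum())

    @property
    def n_misaligned_pairs(self) -> int:
        tri = np.tril_indices(12, -1)
        return int((~self.aligned[tri]).sum())

    @property
    def is_degenerate(self) -> bool:
        """True when no off-diagonal bin pair is classified as aligned.

        On a 30-degree bin grid the 72-degree (5-fold) and 51.4-degree
        (7-fold) periods never hit an exact bin difference, so their model
        matrices are constant and carry no testable prediction.
        """
        n = self.n_aligned_pairs
        return n == 0 or self.n_misaligned_pairs == 0


def build_symmetry_model(n_fold: int) -> SymmetryModel:
    """Model matrix for an n-fold rotational symmetry on 30-degree bins.

    A bin pair is aligned iff its angular difference is a multiple of the
    exact period 360/n (within 1e-6 degrees).
    """
    if n_fold < 1:
        raise ValueError("n_fold must be positive")
    period = 360.0 / n_fold
    bins = np.asarray(ALLO_BINS, dtype=float)
    diff = np.abs(bins[:, None] - bins[None, :]) % 360.0
    rem = diff % period
    aligned = (np.minimum(rem, period - rem) < 1e-6) & ~np.eye(12, dtype=bool)
    return SymmetryModel(
        n_fold=n_fold,
        period=period,
        aligned=aligned,
        off_diagonal=~np.eye(12, dtype=bool),
    )


def grid_rsa_score(
    patterns_a: np.ndarray,
    patterns_b: np.ndarray,
    model: SymmetryModel,
) -> float:
    """Fisher-z correlation between neural and model similarity structure.

    ``patterns_a``/``patterns_b`` are (12, n_voxels) direction-bin patterns
    from the two contexts, rows ordered by bin center 0..330.  The
    cross-context Pearson matrix is symmetrized by triangle averaging, the
    diagonal is dropped, and the lower triangle is correlated with the
    model's aligned/misaligned indicator, then Fisher-z transformed.
    """
    pa = np.asarray(patterns_a, dtype=float)
    pb = np.asarray(patterns_b, dtype=float)
    if pa.shape[0] != 12 or pb.shape[0] != 12:
        raise ValueError("expected 12 direction patterns per context")
    if model.is_degenerate:
        raise ValueError(
            f"{model.n_fold}-fold model is constant on 30-degree bins; "
            "no score is defined"
        )
    za = (pa - pa.mean(axis=1, keepdims=True)) / pa.std(axis=1, keepdims=True)
    zb = (pb - pb.mean(axis=1, keepdims=True)) / pb.std(axis=1, keepdims=True)
    C = za @ zb.T / pa.shape[1]
    S = (C + C.T) / 2.0
    tri = np.tril_indices(12, -1)
    neural = S[tri]
    predicted = model.aligned[tri].astype(float)
    r = float(np.corrcoef(neural, predicted)[0, 1])
    return fisher_z(r)


def grid_rsa_scores(patterns_a, patterns_b, n_folds=N_FOLDS) -> dict:
    """Score every (non-degenerate) control symmetry; NaN where degenerate."""
    out = {}
    for n in n_folds:
        model = build_symmetry_model(n)
        out[n] = (
            float("nan")
            if model.is_degenerate
            else grid_rsa_score(patterns_a, patterns_b, model)
        )
    return out


@dataclass
class GoalModulationResult:
    """Per-subject grid-modulation betas by goal-distance class."""

    class_betas: dict               # {"close", "medium", "far"} -> float
    contrast: float                 # close - far
    linear_trend: float             # slope of betas over (far, medium, close)

    @classmethod
    def from_quadrant_betas(cls, betas_by_context: dict) -> "GoalModulationResult":
        """Map per-(context, quadrant) modulator betas to distance classes.

        Q1/Q4 are averaged within context (equidistant from both goals);
        classes are then averaged across the two contexts.
        """
        per_class: dict = {"close": [], "medium": [], "far": []}
        for (context, quadrant), beta in betas_by_context.items():
            per_class[goal_distance_class(quadrant, context)].append(float(beta))
        class_betas = {k: float(np.mean(v)) for k, v in per_class.items() if v}
        contrast = class_betas["close"] - class_betas["far"]
        ordered = [class_betas["far"], class_betas["medium"], class_betas["close"]]
        trend = float(np.polyfit([-1.0, 0.0, 1.0], ordered, 1)[0])
        return cls(class_betas=class_betas, contrast=contrast, linear_trend=trend)


def goal_modulation_modulators(events) -> np.ndarray:
    """Trial-wise delta60 distance to the previous trial within a run.

    Returns one value per trial (ordered by onset); the run's first trial
    has no predecessor and is NaN (excluded from modulation).
    """
    theta = np.asarray(events["allo_bin"] if hasattr(events, "columns") else events,
                       dtype=float)
    out = np.full(len(theta), np.nan)
    for i in range(1, len(theta)):
        out[i] = delta60(theta[i], theta[i - 1])
    return out
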