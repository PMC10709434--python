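"""Cross-context decoding of egocentric conditions, searchlight, and MDS.

A nearest-neighbor classifier with correlation distance (1 - Pearson r,
configurable to Euclidean) is trained on the run-level condition patterns
of one context and tested on those of the other, in both directions; the
accuracy above chance (1/7, or 1/6 when the on-target condition is
excluded) is the subject-level statistic.  A generic cubic-lattice
searchlight applies any pattern statistic in spheres of a given voxel
radius, and classical multidimensional scaling embeds the seven
egocentric conditions for visualization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import pairwise_distances

from .geometry import EGO_OFFSETS
from .glm import PatternSet


@dataclass
class DecodingResult:
    subject_id: str
    scheme: str                 # "cross_context" | "within_context"
    n_conditions: int
    accuracy_pct: float
    above_chance_pct: float

    @property
    def chance_pct(self) -> float:
        return 100.0 / self.n_conditions


def nn_classify(
    train_X: np.ndarray,
    train_y,
    test_X: np.ndarray,
    metric: str = "correlation",
):
    """1-nearest-neighbor labels for test patterns; ties break to the
    first training index.

    Correlation distance is undefined for a zero-variance pattern, which
    raises ``ValueError``.
    """
    train_X = np.asarray(train_X, dtype=float)
    test_X = np.asarray(test_X, dtype=float)
    train_y = np.asarray(train_y, dtype=object)
    if metric == "correlation":
        if np.any(train_X.std(axis=1) == 0) or np.any(test_X.std(axis=1) == 0):
            raise ValueError("zero-variance pattern: correlation distance undefined")
    D = pairwise_distances(test_X, train_X, metric=metric)
    nearest = D.argmin(axis=1)
    return train_y[nearest]


def _accuracy(pred, truth) -> float:
    pred = np.asarray(pred, dtype=object)
    truth = np.asarray(truth, dtype=object)
    return 100.0 * float((pred == truth).mean())


def cross_context_decode(
    patterns: PatternSet,
    subject_id: str = "",
    exclude_on_target: bool = False,
    metric: str = "correlation",
) -> DecodingResult:
    """Train on all runs of one context, test per run of the other.

    Both context directions are averaged; chance (100/k %) is subtracted.
    """
    conditions = [o for o in EGO_OFFSETS if not (exclude_on_target and o == 0)]
    keep = np.isin(patterns.labels.astype(int), conditions)
    ps = PatternSet(
        patterns.X[keep], patterns.labels[keep], patterns.contexts[keep],
        patterns.runs[keep],
    )
    accs = []
    for train_ctx, test_ctx in (("blue", "green"), ("green", "blue")):
        train = ps.select(context=train_ctx)
        test = ps.select(context=test_ctx)
        for run in np.unique(test.runs):
            fold = test.select(run=run)
            pred = nn_classify(train.X, train.labels, fold.X, metric)
            accs.append(_accuracy(pred, fold.labels))
    acc = float(np.mean(accs))
    return DecodingResult(
        subject_id=subject_id,
        scheme="cross_context",
        n_conditions=len(conditions),
        accuracy_pct=acc,
        above_chance_pct=acc - 100.0 / len(conditions),
    )


def within_context_decode(
    patterns: PatternSet,
    subject_id: str = "",
    exclude_on_target: bool = False,
    metric: str = "correlation",
) -> DecodingResult:
    """Leave-one-run-out decoding within each context, averaged."""
    conditions = [o for o in EGO_OFFSETS if not (exclude_on_target and o == 0)]
    keep = np.isin(patterns.labels.astype(int), conditions)
    ps = PatternSet(
        patterns.X[keep], patterns.labels[keep], patterns.contexts[keep],
        patterns.runs[keep],
    )
    accs = []
    for ctx in ("blue", "green"):
        sub = ps.select(context=ctx)
        for run in np.unique(sub.runs):
            test_mask = sub.runs == run
            pred = nn_classify(
                sub.X[~test_mask], sub.labels[~test_mask], sub.X[test_mask], metric
            )
            accs.append(_accuracy(pred, sub.labels[test_mask]))
    acc = float(np.mean(accs))
    return DecodingResult(
        subject_id=subject_id,
        scheme="within_context",
        n_conditions=len(conditions),
        accuracy_pct=acc,
        above_chance_pct=acc - 100.0 / len(conditions),
    )


def sphere_offsets(radius: int) -> np.ndarray:
    """Integer offsets within a Euclidean sphere of the given voxel radius."""
    r = int(radius)
    grid = np.arange(-r, r + 1)
    dx, dy, dz = np.meshgrid(grid, grid, grid, indexing="ij")
    mask = dx**2 + dy**2 + dz**2 <= r**2
    return np.column_stack([dx[mask], dy[mask], dz[mask]])


def searchlight_map(
    patterns: np.ndarray,
    statistic_fn,
    radius: int = 3,
    min_voxels: int = 10,
):
    """Apply a pattern statistic in a sphere around every lattice voxel.

    ``patterns`` has shape (n_observations, nx, ny, nz); the statistic
    receives the (n_observations, n_sphere_voxels) sub-pattern matrix and
    returns a scalar stored at the sphere center.  Edge spheres with fewer
    than ``min_voxels`` voxels are still computed but flagged.

    Returns ``(stat_map, small_sphere_flags)`` of shape (nx, ny, nz).
    """
    patterns = np.asarray(patterns, dtype=float)
    _, nx, ny, nz = patterns.shape
    offsets = sphere_offsets(radius)
    stat_map = np.empty((nx, ny, nz))
    flags = np.zeros((nx, ny, nz), dtype=bool)
    flat = patterns.reshape(patterns.shape[0], -1)
    for ix in range(nx):
        for iy in range(ny):
            for iz in range(nz):
                pts = offsets + np.array([ix, iy, iz])
                ok = (
                    (pts[:, 0] >= 0) & (pts[:, 0] < nx)
                    & (pts[:, 1] >= 0) & (pts[:, 1] < ny)
                    & (pts[:, 2] >= 0) & (pts[:, 2] < nz)
                )
                pts = pts[ok]
                idx = (pts[:, 0] * ny + pts[:, 1]) * nz + pts[:, 2]
                stat_map[ix, iy, iz] = statistic_fn(flat[:, idx])
                flags[ix, iy, iz] = len(idx) < min_voxels
    return stat_map, flags


def mds_embed(patterns: np.ndarray, labels=None) -> np.ndarray:
    """Classical (Torgerson) MDS of condition patterns into 2D.

    Uses correlation distance between condition patterns.  To fix the
    orientation, the first axis is flipped so that it correlates
    non-negatively with the condition labels (when numeric labels are
    given), and the second axis so its first coordinate is non-negative.
    """
    X = np.asarray(patterns, dtype=float)
    n = X.shape[0]
    if np.allclose(X.std(axis=1), 0):
        return np.zeros((n, 2))
    D = pairwise_distances(X, metric="correlation")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:2]
    coords = vecs[:, order] * np.sqrt(np.clip(vals[order], 0.0, None))
    if labels is not None:
        lab = np.asarray(labels, dtype=float)
        if np.corrcoef(coords[:, 0], lab)[0, 1] < 0:
            coords[:, 0] *= -1
    if coords[0, 1] < 0:
        coords[:, 1] *= -1
    return coords
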