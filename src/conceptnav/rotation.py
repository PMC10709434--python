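"""Cross-context quadrant similarity under a 180-degree map rotation.

If the two conceptual spaces are mentally aligned on their goals, the
multivoxel pattern of each quadrant in one context should resemble the
pattern of its 180-degree rotation image in the other context (Q1<->Q4,
Q2<->Q3).  The analysis correlates the four quadrant patterns of the blue
context (rows, Q1..Q4) with those of the green context in reversed order
(columns, Q4..Q1), putting the rotation-matched pairs on the diagonal, and
scores the Fisher-z on- vs. off-diagonal difference.

Controls: dropping the goal quadrants (the blue-goal row and green-goal
column) shows the effect is not carried by goal quadrants alone; scoring
only the {Q1, Q4} x {Q4, Q1} submatrix (quadrants equidistant from both
goals) shows it is not mere goal-distance similarity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import QUADRANTS
from .stats import fisher_z

#: Column order of the green-context patterns ("reversed", i.e. rotated).
GREEN_ORDER = ("Q4", "Q3", "Q2", "Q1")

CONTROLS = ("none", "exclude_goal_quadrants", "q1q4_only")


@dataclass
class RotationMatrix:
    """4x4 Pearson matrix; rows blue Q1..Q4, columns green Q4..Q1."""

    r: np.ndarray

    @property
    def matched_pairs(self):
        return [("Q1", "Q4"), ("Q2", "Q3"), ("Q3", "Q2"), ("Q4", "Q1")]


def rotation_similarity_matrix(
    blue_patterns: dict, green_patterns: dict
) -> RotationMatrix:
    """Correlate per-quadrant patterns across contexts in rotated order.

    ``blue_patterns``/``green_patterns`` map quadrant labels to voxel
    vectors (typically run-averaged quadrant betas).
    """
    r = np.empty((4, 4))
    for i, qb in enumerate(QUADRANTS):
        for j, qg in enumerate(GREEN_ORDER):
            r[i, j] = np.corrcoef(blue_patterns[qb], green_patterns[qg])[0, 1]
    return RotationMatrix(r=r)


def rotation_score(matrix: RotationMatrix, control: str = "none") -> float:
    """Mean Fisher-z difference between rotation-matched and other cells.

    ``exclude_goal_quadrants`` drops the blue-goal row (Q2) and the
    green-goal column (Q3) before scoring; ``q1q4_only`` scores only the
    2x2 submatrix of the two quadrants equidistant from both goals.
    Correlations of magnitude 1 are clipped before the z transform.
    """
    if control not in CONTROLS:
        raise ValueError(f"unknown control {control!r}")
    r = matrix.r
    rows = list(range(4))
    cols = list(range(4))
    if control == "exclude_goal_quadrants":
        rows.remove(QUADRANTS.index("Q2"))       # blue goal quadrant row
        cols.remove(GREEN_ORDER.index("Q3"))     # green goal quadrant column
    elif control == "q1q4_only":
        rows = [QUADRANTS.index("Q1"), QUADRANTS.index("Q4")]
        cols = [GREEN_ORDER.index("Q4"), GREEN_ORDER.index("Q1")]
    z = np.vectorize(fisher_z)(r)
    on, off = [], []
    for i in rows:
        for j in cols:
            (on if i == j else off).append(z[i, j])
    return float(np.mean(on) - np.mean(off))
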