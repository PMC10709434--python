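"""Geometry of the 2D bond-length feature spaces.

Each "molecule" context (blue or green) is a unit square whose axes are the
lengths of the molecule's upper bond (axis 1, plotted as x) and lower bond
(axis 2, plotted as y), in arbitrary units.  A molecule configuration is a
point; a morphing reaction is a straight trajectory.  Each context has one
goal configuration; the two goals are 180-degree rotation images of each
other about the center of the square.

Conventions (fixed here and used everywhere else in the package):

* Angles are measured counter-clockwise from the positive axis-1 (x)
  direction, in degrees in ``[0, 360)``.
* Quadrants are delimited by the axis midlines (x = 0.5, y = 0.5):
  Q1 = low x / low y, Q2 = high x / low y, Q3 = low x / high y,
  Q4 = high x / high y.  The blue goal sits in Q2 (long upper bond, short
  lower bond) and the green goal in Q3.  A 180-degree rotation of the
  square maps Q1 <-> Q4 and Q2 <-> Q3.
* The signed egocentric offset of a goal relative to a movement direction
  is ``bearing(start -> goal) - heading`` wrapped to ``(-180, 180]``;
  positive means the goal lies counter-clockwise of the heading ("left" by
  our arbitrary convention), negative clockwise ("right").
"""

from __future__ import annotations

import math

CONTEXTS = ("blue", "green")
QUADRANTS = ("Q1", "Q2", "Q3", "Q4")

#: Goal configuration per context (quadrant centers; rotation images).
GOALS = {"blue": (0.75, 0.25), "green": (0.25, 0.75)}

#: The seven egocentric angular conditions (degrees; 0 = on-target).
EGO_OFFSETS = (-135, -90, -45, 0, 45, 90, 135)

#: Centers of the 12 allocentric 30-degree direction bins.
ALLO_BINS = tuple(range(0, 360, 30))

#: Quadrant correspondence under a 180-degree rotation of the space.
ROTATION_MAP = {"Q1": "Q4", "Q2": "Q3", "Q3": "Q2", "Q4": "Q1"}

CENTER = (0.5, 0.5)

#: Axis-aligned bounding box (x0, y0, x1, y1) of each quadrant.
QUADRANT_BOXES = {
    "Q1": (0.0, 0.0, 0.5, 0.5),
    "Q2": (0.5, 0.0, 1.0, 0.5),
    "Q3": (0.0, 0.5, 0.5, 1.0),
    "Q4": (0.5, 0.5, 1.0, 1.0),
}


def wrap_signed(angle: float) -> float:
    """Wrap an angle in degrees to the half-open interval ``(-180, 180]``."""
    wrapped = angle % 360.0
    if wrapped > 180.0:
        wrapped -= 360.0
    return wrapped


def bearing_to(origin, target) -> float:
    """Direction from ``origin`` to ``target``, degrees CCW from +x, in [0, 360).

    Raises ``ValueError`` for coincident points (degenerate trial).
    """
    dx = target[0] - origin[0]
    dy = target[1] - origin[1]
    if dx == 0.0 and dy == 0.0:
        raise ValueError("bearing undefined for coincident points")
    return math.degrees(math.atan2(dy, dx)) % 360.0


def egocentric_offset(heading: float, start, goal) -> float:
    """Signed angular position of the goal relative to a heading.

    Returns ``bearing(start -> goal) - heading`` wrapped to ``(-180, 180]``.
    Zero means the heading points at the goal; positive values place the
    goal counter-clockwise ("left") of the heading.
    """
    return wrap_signed(bearing_to(start, goal) - heading)


def assign_quadrant(point) -> str:
    """Quadrant label of a point strictly inside the unit square.

    Points on an axis midline are ambiguous and raise ``ValueError``; the
    trial generator never places a start or morph endpoint there.
    """
    x, y = point
    if not (0.0 < x < 1.0 and 0.0 < y < 1.0):
        raise ValueError(f"point {point!r} outside the feature space")
    if x == 0.5 or y == 0.5:
        raise ValueError(f"point {point!r} lies on an axis midline")
    if y < 0.5:
        return "Q1" if x < 0.5 else "Q2"
    return "Q3" if x < 0.5 else "Q4"


def bin_allocentric(heading: float) -> int:
    """Nearest 30-degree bin center for a heading in [0, 360).

    Ties (heading exactly 15 degrees from two centers) break toward the
    lower bin; 345 <= heading < 360 wraps to bin 0 when nearer to 360.
    """
    if not 0.0 <= heading < 360.0:
        raise ValueError(f"heading {heading!r} not in [0, 360)")
    lower = int(heading // 30.0)
    remainder = heading - 30.0 * lower
    idx = lower if remainder <= 15.0 else (lower + 1) % 12
    return 30 * idx


def rotate180(point):
    """Image of a point under a 180-degree rotation about the space center."""
    return (1.0 - point[0], 1.0 - point[1])


def goal_distance_class(quadrant: str, context: str) -> str:
    """Goal-proximity class of a quadrant within a context.

    The goal quadrant is "close", the diagonally opposite quadrant is
    "far", and Q1/Q4 (equidistant from both goals) are "medium".
    """
    goal_q = "Q2" if context == "blue" else "Q3"
    if quadrant == goal_q:
        return "close"
    if quadrant == ROTATION_MAP[goal_q]:
        return "far"
    return "medium"
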