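"""Task geometry and the parabolic path-length cost.

The task is a stylus movement from a start point at the origin to a
checkpoint 140 mm straight ahead, passing a 30 mm x 10 mm rectangular
obstacle centred midway (70 mm) on either its left or right side.  The
cost of an action (pass left / pass right) is the arc length of the
shortest parabola connecting start to checkpoint that clears the
obstacle on that side, normalized by the 140 mm straight-line minimum
and inverted so that longer paths give lower valuations.

Coordinates: origin at the start point, x to the right (mm), y toward
the checkpoint (mm).  The obstacle position refers to its centre x.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad

__all__ = [
    "ActionSide",
    "TaskGeometry",
    "ObstaclePositionGrid",
    "make_position_grid",
    "code_position",
    "decode_position",
    "min_parabola_path_length",
    "normalized_cost",
    "cost_table",
]

#: coded-position scale: the extreme obstacle positions +-34.2 mm are
#: re-coded as +-0.9 for the statistical models.
POSITION_EXTREME_MM = 34.2
CODED_EXTREME = 0.9
N_POSITIONS = 29


class ActionSide(str, enum.Enum):
    """Side on which the obstacle is passed."""

    LEFT = "left"
    RIGHT = "right"

    def mirror(self) -> "ActionSide":
        return ActionSide.RIGHT if self is ActionSide.LEFT else ActionSide.LEFT


@dataclass(frozen=True)
class TaskGeometry:
    """Dimensions of the obstacle-avoidance workspace, in mm.

    Defaults correspond to the tablet task: start at (0, 0), checkpoint
    at (0, 140), obstacle 30 mm wide x 10 mm high centred at y = 70,
    inside a 106 mm x 200 mm workspace.
    """

    checkpoint_distance: float = 140.0
    obstacle_half_width: float = 15.0
    obstacle_half_height: float = 5.0
    obstacle_center_y: float = 70.0
    workspace_width: float = 106.0
    workspace_height: float = 200.0

    def __post_init__(self) -> None:
        for name in (
            "checkpoint_distance",
            "obstacle_half_width",
            "obstacle_half_height",
            "obstacle_center_y",
            "workspace_width",
            "workspace_height",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.obstacle_center_y + self.obstacle_half_height >= self.checkpoint_distance:
            raise ValueError("obstacle must lie strictly between start and checkpoint")

    @property
    def start(self) -> tuple[float, float]:
        return (0.0, 0.0)

    @property
    def checkpoint(self) -> tuple[float, float]:
        return (0.0, self.checkpoint_distance)

    def obstacle_y_range(self) -> tuple[float, float]:
        return (
            self.obstacle_center_y - self.obstacle_half_height,
            self.obstacle_center_y + self.obstacle_half_height,
        )


DEFAULT_GEOMETRY = TaskGeometry()


@dataclass(frozen=True)
class ObstaclePositionGrid:
    """The 29 equally spaced horizontal obstacle-centre positions."""

    positions_mm: tuple[float, ...] = field(
        default_factory=lambda: tuple(
            np.linspace(-POSITION_EXTREME_MM, POSITION_EXTREME_MM, N_POSITIONS)
        )
    )

    def __post_init__(self) -> None:
        p = np.asarray(self.positions_mm)
        if p.size != N_POSITIONS:
            raise ValueError(f"grid must have {N_POSITIONS} positions")
        if not np.all(np.diff(p) > 0):
            raise ValueError("grid positions must be strictly ascending")

    @property
    def coded(self) -> tuple[float, ...]:
        return tuple(code_position(x) for x in self.positions_mm)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"position_mm": self.positions_mm, "coded_position": self.coded}
        )


def make_position_grid() -> ObstaclePositionGrid:
    """Build the standard grid: 29 positions spanning [-34.2, 34.2] mm."""
    return ObstaclePositionGrid()


def code_position(x_mm: float) -> float:
    """Map obstacle centre x (mm) to the coded scale where +-34.2 -> +-0.9.

    Raises ``ValueError`` outside the grid range.
    """
    x = np.asarray(x_mm, dtype=float)
    if np.any(np.abs(x) > POSITION_EXTREME_MM + 1e-9):
        raise ValueError(f"position {x_mm} mm outside +-{POSITION_EXTREME_MM} mm range")
    out = x * (CODED_EXTREME / POSITION_EXTREME_MM)
    return float(out) if out.ndim == 0 else out


def decode_position(coded: float) -> float:
    """Inverse of :func:`code_position`."""
    return float(coded) * (POSITION_EXTREME_MM / CODED_EXTREME)


def _arc_length(a: float, length: float) -> float:
    """Arc length of x(y) = a*y*(y - L) over y in [0, L] by adaptive quadrature."""
    if a == 0.0:
        return length

    def integrand(y: float) -> float:
        return math.hypot(1.0, a * (2.0 * y - length))

    val, _ = quad(integrand, 0.0, length, epsrel=1e-9, epsabs=1e-12, limit=200)
    return val


def _min_abs_coefficient(side: ActionSide, obstacle_x: float, geom: TaskGeometry) -> float:
    # The parabola family x(y) = a*y*(y-L) pins both endpoints; |x| over the
    # obstacle's y-band [y0-h, y0+h] is smallest at the band's corners, so the
    # corner rows are the binding clearance constraints for this concave family.
    lo, hi = geom.obstacle_y_range()
    length = geom.checkpoint_distance
    # y*(y-L) < 0 inside (0, L); take the corner with the smaller magnitude
    corner = min(abs(lo * (lo - length)), abs(hi * (hi - length)))
    if side is ActionSide.RIGHT:
        edge = obstacle_x + geom.obstacle_half_width
        if edge <= 0.0:  # straight line already passes on the right (tie allowed)
            return 0.0
        # need x(y) >= edge on the band: a*y*(y-L) >= edge with y*(y-L) < 0
        return -edge / corner
    else:
        edge = obstacle_x - geom.obstacle_half_width
        if edge >= 0.0:
            return 0.0
        return -edge / corner


def min_parabola_path_length(
    side: ActionSide | str,
    obstacle_x: float,
    geom: TaskGeometry = DEFAULT_GEOMETRY,
) -> float:
    """Shortest parabolic path (mm) from start to checkpoint clearing the obstacle.

    The path family is x(y) = a*y*(y - 140): endpoints pinned at start and
    checkpoint, axis horizontal.  Arc length is monotone in |a|, so the
    shortest admissible member is the one with minimal |a| whose x(y)
    clears the obstacle rectangle on the requested side over its full
    vertical extent.  Equals 140 exactly when the straight line already
    passes on that side (touching the obstacle edge counts as passing).
    """
    side = ActionSide(side)
    a = _min_abs_coefficient(side, float(obstacle_x), geom)
    return _arc_length(a, geom.checkpoint_distance)


def normalized_cost(
    side: ActionSide | str,
    obstacle_x: float,
    geom: TaskGeometry = DEFAULT_GEOMETRY,
) -> float:
    """Action cost c in (0, 1]: minimum path length over actual path length.

    c = 140 / path_length, so the unobstructed straight path has cost 1 and
    longer detours have strictly lower valuation.
    """
    return geom.checkpoint_distance / min_parabola_path_length(side, obstacle_x, geom)


def cost_table(
    grid: ObstaclePositionGrid | None = None,
    geom: TaskGeometry = DEFAULT_GEOMETRY,
) -> "np.ndarray":
    """Per-position costs, shape (n_positions, 2): columns (left, right)."""
    grid = grid or make_position_grid()
    out = np.empty((len(grid.positions_mm), 2))
    for i, x in enumerate(grid.positions_mm):
        out[i, 0] = normalized_cost(ActionSide.LEFT, x, geom)
        out[i, 1] = normalized_cost(ActionSide.RIGHT, x, geom)
    return out
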