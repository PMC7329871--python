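"""Flight-chamber geometry: obstacle walls, microphone array, flight sections.

The chamber is a 9 x 4.5 x 2.5 m room.  A straight aisle runs along the
long (x) axis, framed by two chain lines; three obstacle walls hang into
the aisle from alternating sides so the bat is forced onto an S-shaped
path.  Obstacle walls are either acoustically permeable (three 4-cm
chains at 22-cm spacing) or acoustically reflective (a 1 m x 2 m acrylic
board); the inner edges of the two variants coincide, so the flight gap
is identical in both conditions.  Twenty microphones sit on the room
walls at 1.2 m height: 1.1 m apart along the two side walls and 0.75 m
apart along the frontal wall the bats fly towards.

Coordinates: origin at the chamber corner nearest the start position,
x along the aisle (flight direction is +x), y lateral, metres.  The
frontal wall is x = length_m.  Directions follow :mod:`echogaze._angles`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from ._angles import bearing_deg

PERMEABLE = "permeable"
REFLECTIVE = "reflective"

#: lateral extent of a permeable wall: 3 chain centres spanning 2 x 0.22 m
#: plus one 4-cm chain diameter
CHAIN_WALL_SPAN_M = 2 * 0.22 + 0.04
BOARD_SPAN_M = 1.0


class OutOfCourseError(ValueError):
    """Raised for positions outside the obstacle-course x range."""


class UndefinedBearingError(ValueError):
    """Raised when the bat coincides with a microphone."""


@dataclass(frozen=True)
class ObstacleWall:
    """One obstacle wall hanging into the aisle.

    ``side`` is ``"high"`` when the wall is attached to the high-y aisle
    edge and extends towards lower y, ``"low"`` for the opposite.  The
    wall axis is the infinite line x = x_m.
    """

    index: int
    material: str
    x_m: float
    y_lo: float
    y_hi: float
    side: str

    @property
    def y_span(self) -> tuple[float, float]:
        return (self.y_lo, self.y_hi)

    @property
    def inner_edge_y(self) -> float:
        """Free (aisle-facing) edge of the wall."""
        return self.y_lo if self.side == "high" else self.y_hi

    @property
    def attached_edge_y(self) -> float:
        return self.y_hi if self.side == "high" else self.y_lo

    def aligned_y(self, y):
        """Wall-aligned coordinate: 0 at the attached edge, increasing
        towards the aisle, so the wall body occupies [0, span] for every
        wall regardless of side."""
        y = np.asarray(y, dtype=float)
        out = (self.attached_edge_y - y) if self.side == "high" else (y - self.attached_edge_y)
        return float(out) if out.ndim == 0 else out

    def chain_centres(self, spacing: float = 0.22) -> np.ndarray:
        """y positions of the individual chains (permeable walls only)."""
        if self.material != PERMEABLE:
            return np.empty(0)
        inner = self.inner_edge_y
        direction = 1.0 if self.side == "high" else -1.0
        first = inner + direction * 0.02  # half a chain diameter in from the edge
        return first + direction * spacing * np.arange(3)


@dataclass
class ArenaLayout:
    """Chamber, obstacle walls, microphone array and flight sections."""

    length_m: float = 9.0
    width_m: float = 4.5
    height_m: float = 2.5
    condition: str = PERMEABLE
    aisle_y: tuple[float, float] = (1.25, 3.25)
    wall_x: tuple[float, float, float] = (4.5, 5.5, 6.5)
    start_offset_m: float = 1.3
    measurement_band_x: tuple[float, float] = (4.0, 7.0)
    mic_side_spacing_m: float = 1.1
    mic_front_spacing_m: float = 0.75
    mic_height_m: float = 1.2
    extra_mic_positions: list = field(default_factory=list)
    obstacle_walls: list = field(init=False)
    mic_positions: np.ndarray = field(init=False)

    def __post_init__(self):
        if self.condition not in (PERMEABLE, REFLECTIVE):
            raise ValueError(f"unknown condition {self.condition!r}")
        self.obstacle_walls = self._build_walls()
        self.mic_positions = self._build_mics()
        self._validate()

    # -- construction -------------------------------------------------

    def _build_walls(self):
        span = CHAIN_WALL_SPAN_M if self.condition == PERMEABLE else BOARD_SPAN_M
        y_lo_aisle, y_hi_aisle = self.aisle_y
        walls = []
        for i, x in enumerate(self.wall_x, start=1):
            side = "high" if i % 2 == 1 else "low"
            if side == "high":
                # inner edge fixed by the chain-wall geometry; a board
                # grows outward from the same inner edge
                inner = y_hi_aisle - CHAIN_WALL_SPAN_M
                y_lo, y_hi = inner, inner + span
            else:
                inner = y_lo_aisle + CHAIN_WALL_SPAN_M
                y_lo, y_hi = inner - span, inner
            walls.append(ObstacleWall(i, self.condition, float(x), y_lo, y_hi, side))
        return walls

    def _build_mics(self):
        mics = []
        n_front = int(self.width_m // self.mic_front_spacing_m)
        margin = (self.width_m - (n_front - 1) * self.mic_front_spacing_m) / 2
        for k in range(n_front):
            mics.append((self.length_m, margin + k * self.mic_front_spacing_m))
        n_side = (20 - n_front) // 2
        margin = (self.length_m - (n_side - 1) * self.mic_side_spacing_m) / 2
        for y_wall in (0.0, self.width_m):
            for k in range(n_side):
                mics.append((margin + k * self.mic_side_spacing_m, y_wall))
        mics.extend(tuple(map(float, p)) for p in self.extra_mic_positions)
        return np.asarray(mics, dtype=float)

    def _validate(self):
        if len(self.obstacle_walls) != 3:
            raise ValueError("exactly 3 obstacle walls required")
        if len(self.mic_positions) < 20:
            raise ValueError("need at least 20 microphones")
        m = self.mic_positions
        if (m[:, 0] < 0).any() or (m[:, 0] > self.length_m).any() or \
           (m[:, 1] < 0).any() or (m[:, 1] > self.width_m).any():
            raise ValueError("microphone outside chamber bounds")
        xs = [w.x_m for w in self.obstacle_walls]
        if sorted(xs) != xs:
            raise ValueError("obstacle walls must be ordered along x")
        sides = [w.side for w in self.obstacle_walls]
        if sides[0] == sides[1] or sides[1] == sides[2]:
            raise ValueError("obstacle walls must alternate sides of the aisle")
        lo, hi = self.measurement_band_x
        if not all(lo <= x <= hi for x in xs):
            raise ValueError("obstacle walls must lie inside the measurement band")

    # -- derived geometry ---------------------------------------------

    @property
    def start_position(self) -> tuple[float, float]:
        """Flight start, 1.3 m behind wall 1, centred in the aisle."""
        return (self.wall_x[0] - self.start_offset_m,
                0.5 * (self.aisle_y[0] + self.aisle_y[1]))

    @property
    def course_x_range(self) -> tuple[float, float]:
        return (self.start_position[0], self.length_m)

    # -- queries -------------------------------------------------------

    def section_of(self, position) -> int:
        """Flight section (1..3) of a 2D position.

        Section boundaries are the x positions of walls 1 and 2
        (half-open: a point exactly on a boundary belongs to the later
        section); section 3 runs from wall 2 to the end of the flight,
        so wall 3 lies inside it and every pulse of a flight is tagged.
        """
        x = float(np.asarray(position, dtype=float).ravel()[0])
        lo, hi = self.course_x_range
        if x < lo - 1e-9 or x > hi + 1e-9:
            raise OutOfCourseError(f"x={x:.3f} outside course range [{lo:.2f}, {hi:.2f}]")
        if x < self.wall_x[0]:
            return 1
        if x < self.wall_x[1]:
            return 2
        return 3

    def immediate_wall(self, position, heading=(1.0, 0.0)):
        """Nearest obstacle wall not yet passed in the direction of travel.

        Returns ``None`` once the bat is past wall 3 (travelling +x).
        """
        h = np.asarray(heading, dtype=float)
        if not np.any(h):
            raise ValueError("heading must be non-zero")
        x = float(np.asarray(position, dtype=float).ravel()[0])
        forward = h[0] >= 0
        walls = self.obstacle_walls if forward else self.obstacle_walls[::-1]
        for wall in walls:
            if (forward and x < wall.x_m) or (not forward and x > wall.x_m):
                return wall
        return None

    def mic_bearings(self, position) -> np.ndarray:
        """Bearing (deg) of every microphone from a chamber position."""
        p = np.asarray(position, dtype=float).ravel()[:2]
        if not (0 <= p[0] <= self.length_m and 0 <= p[1] <= self.width_m):
            raise OutOfCourseError(f"position {p} outside chamber")
        d = self.mic_positions - p
        if np.any(np.all(np.abs(d) < 1e-12, axis=1)):
            raise UndefinedBearingError("bat coincides with a microphone")
        return bearing_deg(d[:, 0], d[:, 1])

    def mic_distances(self, position) -> np.ndarray:
        p = np.asarray(position, dtype=float).ravel()[:2]
        return np.hypot(*(self.mic_positions - p).T)

    # -- (de)serialisation --------------------------------------------

    def to_dict(self) -> dict:
        return {
            "length_m": self.length_m,
            "width_m": self.width_m,
            "height_m": self.height_m,
            "condition": self.condition,
            "aisle_y": list(self.aisle_y),
            "wall_x": list(self.wall_x),
            "start_offset_m": self.start_offset_m,
            "measurement_band_x": list(self.measurement_band_x),
            "mic_side_spacing_m": self.mic_side_spacing_m,
            "mic_front_spacing_m": self.mic_front_spacing_m,
            "mic_height_m": self.mic_height_m,
            "extra_mic_positions": [list(p) for p in self.extra_mic_positions],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ArenaLayout":
        kw = dict(d)
        for key in ("aisle_y", "wall_x", "measurement_band_x"):
            if key in kw:
                kw[key] = tuple(kw[key])
        return cls(**kw)

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump({"arena": self.to_dict()}, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ArenaLayout":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls.from_dict(d.get("arena", d))


def default_layout(condition: str = PERMEABLE, **overrides) -> "ArenaLayout":
    """Bundled default arena reproducing the reported course layout."""
    return ArenaLayout(condition=condition, **overrides)
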