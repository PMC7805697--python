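"""Arena geometry, coordinate conventions, and zone-membership predicates.

Coordinate frame
----------------
Origin at the corner of the focal compartment; ``x`` runs along the long
(74 cm) axis toward the stimulus compartment, ``y`` across the 30 cm width.
All lengths are in centimetres, time in seconds.

The tank is split by two partitions into a focal compartment (where the
subject swims and is tracked), a middle compartment, and a stimulus
compartment holding the conspecific shoal.  The door partition sits at
``x = focal_len`` and carries two doors, centred at 1/4 and 3/4 of the
width.  A square trigger zone (side = 2 body lengths) abuts the partition
on the focal side of each door.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Tuple

import numpy as np

__all__ = [
    "ArenaGeometry",
    "Zone",
    "ZoneKind",
    "make_default_arena",
    "zone_contains",
    "nearest_wall",
    "wall_distances",
]

Point = Tuple[float, float]


class ZoneKind(str, Enum):
    TRIGGER_ZONE = "trigger_zone"
    WALL_BAND = "wall_band"
    WIDTH_THIRD = "width_third"
    COMPARTMENT = "compartment"


@dataclass(frozen=True)
class Zone:
    """Axis-aligned rectangular region of the arena.

    ``label`` identifies the member within its kind: a door id
    (``"lower"``/``"upper"``) for trigger zones, a wall index 1-4 for wall
    bands, ``"lower"|"middle"|"upper"`` for width thirds, and
    ``"focal"|"middle"|"stimulus"`` for compartments.
    """

    kind: ZoneKind
    label: str
    x_min: float
    x_max: float
    y_min: float
    y_max: float

    def as_tuple(self) -> Tuple[float, float, float, float]:
        return (self.x_min, self.x_max, self.y_min, self.y_max)


@dataclass(frozen=True)
class ArenaGeometry:
    """Tank dimensions and derived landmarks (all cm).

    Defaults describe a 74 x 30 cm tank with 30/34/10 cm sections, 3 cm
    body length, doors 1.5 BL wide at y = W/4 and 3W/4 on the partition at
    ``x = focal_len``, 6 x 6 cm trigger zones, 3 cm wall bands, and an
    8 cm confinement cylinder centred in the focal compartment.
    """

    length: float = 74.0
    width: float = 30.0
    depth: float = 30.0
    focal_len: float = 30.0
    middle_len: float = 34.0
    stimulus_len: float = 10.0
    body_length: float = 3.0
    wall_band: float = 3.0
    cylinder_diameter: float = 8.0

    def __post_init__(self) -> None:
        total = self.focal_len + self.middle_len + self.stimulus_len
        if not np.isclose(total, self.length):
            raise ValueError(
                f"compartment lengths {self.focal_len}+{self.middle_len}+"
                f"{self.stimulus_len} do not sum to tank length {self.length}"
            )
        for name in ("length", "width", "body_length", "wall_band"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    # -- derived landmarks -------------------------------------------------

    @property
    def door_width(self) -> float:
        """Door width: 1.5 body lengths."""
        return 1.5 * self.body_length

    @property
    def trigger_zone_side(self) -> float:
        """Side of the square monitored region in front of each door: 2 BL."""
        return 2.0 * self.body_length

    @property
    def door_centers(self) -> Mapping[str, Point]:
        """Door centres on the partition line, keyed ``lower``/``upper``."""
        x = self.focal_len
        return {
            "lower": (x, self.width / 4.0),
            "upper": (x, 3.0 * self.width / 4.0),
        }

    @property
    def cylinder_center(self) -> Point:
        return (self.focal_len / 2.0, self.width / 2.0)

    @property
    def focal_bounds(self) -> Tuple[float, float, float, float]:
        """(x_min, x_max, y_min, y_max) of the focal compartment."""
        return (0.0, self.focal_len, 0.0, self.width)

    @property
    def tank_bounds(self) -> Tuple[float, float, float, float]:
        return (0.0, self.length, 0.0, self.width)

    # -- zones -------------------------------------------------------------

    def trigger_zone(self, door: str) -> Zone:
        """Square zone of side 2 BL centred on a door, on the focal side."""
        cx, cy = self.door_centers[door]
        s = self.trigger_zone_side
        return Zone(
            ZoneKind.TRIGGER_ZONE, door,
            x_min=cx - s, x_max=cx,
            y_min=cy - s / 2.0, y_max=cy + s / 2.0,
        )

    def wall_band_zone(self, wall: int) -> Zone:
        """Band within ``wall_band`` cm of focal-compartment wall 1-4.

        Wall 1 is the door partition (the wall nearest the conspecific
        shoal); 2 is y=0, 3 is x=0, 4 is y=width.
        """
        b = self.wall_band
        x0, x1, y0, y1 = self.focal_bounds
        if wall == 1:
            return Zone(ZoneKind.WALL_BAND, "1", x1 - b, x1, y0, y1)
        if wall == 2:
            return Zone(ZoneKind.WALL_BAND, "2", x0, x1, y0, y0 + b)
        if wall == 3:
            return Zone(ZoneKind.WALL_BAND, "3", x0, x0 + b, y0, y1)
        if wall == 4:
            return Zone(ZoneKind.WALL_BAND, "4", x0, x1, y1 - b, y1)
        raise ValueError(f"wall index must be 1-4, got {wall}")

    def width_third(self, which: str) -> Zone:
        """One of three equal-area strips along the tank width."""
        h = self.width / 3.0
        idx = {"lower": 0, "middle": 1, "upper": 2}
        try:
            i = idx[which]
        except KeyError:
            raise ValueError(f"width third must be lower/middle/upper, got {which!r}")
        return Zone(ZoneKind.WIDTH_THIRD, which, 0.0, self.length, i * h, (i + 1) * h)

    def compartment(self, which: str) -> Zone:
        edges = {
            "focal": (0.0, self.focal_len),
            "middle": (self.focal_len, self.focal_len + self.middle_len),
            "stimulus": (self.focal_len + self.middle_len, self.length),
        }
        try:
            x0, x1 = edges[which]
        except KeyError:
            raise ValueError(f"unknown compartment {which!r}")
        return Zone(ZoneKind.COMPARTMENT, which, x0, x1, 0.0, self.width)

    def other_door(self, door: str) -> str:
        if door not in ("lower", "upper"):
            raise ValueError(f"door must be 'lower' or 'upper', got {door!r}")
        return "upper" if door == "lower" else "lower"

    # -- (de)serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "length": self.length, "width": self.width, "depth": self.depth,
            "focal_len": self.focal_len, "middle_len": self.middle_len,
            "stimulus_len": self.stimulus_len, "body_length": self.body_length,
            "wall_band": self.wall_band, "cylinder_diameter": self.cylinder_diameter,
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "ArenaGeometry":
        return cls(**dict(d))


def make_default_arena(**overrides: float) -> ArenaGeometry:
    """Return the default arena geometry, optionally overriding fields."""
    return replace(ArenaGeometry(), **overrides) if overrides else ArenaGeometry()


def zone_contains(zone: Zone, p, arena: ArenaGeometry | None = None) -> bool:
    """Boundary-inclusive membership test for a single point.

    Raises ``ValueError`` for points outside the tank (an invalid
    trajectory sample) when ``arena`` is given.
    """
    x, y = float(p[0]), float(p[1])
    if arena is not None:
        x0, x1, y0, y1 = arena.tank_bounds
        if not (x0 <= x <= x1 and y0 <= y <= y1):
            raise ValueError(f"point ({x}, {y}) lies outside the tank bounds")
    return zone.x_min <= x <= zone.x_max and zone.y_min <= y <= zone.y_max


def zone_contains_mask(zone: Zone, xy: np.ndarray) -> np.ndarray:
    """Vectorised boundary-inclusive membership for an (n, 2) array."""
    xy = np.asarray(xy, dtype=float)
    return (
        (xy[:, 0] >= zone.x_min) & (xy[:, 0] <= zone.x_max)
        & (xy[:, 1] >= zone.y_min) & (xy[:, 1] <= zone.y_max)
    )


def wall_distances(arena: ArenaGeometry, xy: np.ndarray) -> np.ndarray:
    """Distances (n, 4) from focal-compartment points to walls 1-4.

    Columns follow the wall indexing of :meth:`ArenaGeometry.wall_band_zone`.
    """
    xy = np.atleast_2d(np.asarray(xy, dtype=float))
    x0, x1, y0, y1 = arena.focal_bounds
    return np.column_stack([
        x1 - xy[:, 0],   # wall 1: door partition
        xy[:, 1] - y0,   # wall 2: y = 0
        xy[:, 0] - x0,   # wall 3: x = 0
        y1 - xy[:, 1],   # wall 4: y = width
    ])


def nearest_wall(arena: ArenaGeometry, p) -> Tuple[int, float]:
    """Nearest focal-compartment wall for a point inside that compartment.

    Returns ``(wall_id, distance_cm)``; ties go to the lowest wall index,
    so wall 1 (the door partition) wins at the exact centre.
    """
    x, y = float(p[0]), float(p[1])
    x0, x1, y0, y1 = arena.focal_bounds
    if not (x0 <= x <= x1 and y0 <= y <= y1):
        raise ValueError(f"point ({x}, {y}) lies outside the focal compartment")
    d = wall_distances(arena, [(x, y)])[0]
    wall = int(np.argmin(d)) + 1  # argmin picks first (lowest index) on ties
    return wall, float(d[wall - 1])
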