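"""Arena geometry and stimulus-protocol configuration.

The assay arena is a circular open field (default 50-cm diameter) with a
concentric circular trigger zone ("central area", default 25-cm diameter)
and an adjoining rectangular refuge alley (default 50 cm x 10 cm) with free
access between compartments.  loomkit places the refuge tangent to the field
circle on the +y side; the entrance is a 10-cm segment of the shared wall
centred on the tangency point.  All lengths are centimetres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError


@dataclass
class ArenaGeometry:
    """Circular open field + trigger circle + rectangular refuge.

    The coordinate frame has the field centre at ``field_center`` (default the
    origin).  The refuge rectangle spans ``refuge_length`` along x and
    ``refuge_width`` along y, its lower edge tangent to the field circle at
    ``(cx, cy + field_radius)``.
    """

    field_center: tuple[float, float] = (0.0, 0.0)
    field_diameter: float = 50.0
    trigger_diameter: float = 25.0
    refuge_length: float = 50.0
    refuge_width: float = 10.0
    entrance_width: float = 10.0
    wall_height: float = 30.0  # informational only

    def __post_init__(self) -> None:
        if not 0 < self.trigger_diameter < self.field_diameter:
            raise ConfigError("trigger_diameter must lie in (0, field_diameter)")
        if min(self.refuge_length, self.refuge_width, self.entrance_width) <= 0:
            raise ConfigError("refuge dimensions must be positive")

    # -- derived geometry -------------------------------------------------
    @property
    def field_radius(self) -> float:
        return self.field_diameter / 2.0

    @property
    def trigger_radius(self) -> float:
        return self.trigger_diameter / 2.0

    @property
    def refuge_rect(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) of the refuge rectangle."""
        cx, cy = self.field_center
        half = self.refuge_length / 2.0
        ymin = cy + self.field_radius
        return (cx - half, cx + half, ymin, ymin + self.refuge_width)

    @property
    def entrance_segment(self) -> tuple[tuple[float, float], tuple[float, float]]:
        """Endpoints of the field/refuge entrance on the shared wall."""
        cx, cy = self.field_center
        y = cy + self.field_radius
        half = self.entrance_width / 2.0
        return ((cx - half, y), (cx + half, y))

    @property
    def entrance_mid(self) -> tuple[float, float]:
        (x0, y0), (x1, y1) = self.entrance_segment
        return ((x0 + x1) / 2.0, (y0 + y1) / 2.0)

    # -- point predicates (vectorised over (..., 2) arrays) ----------------
    def _xy(self, p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        p = np.asarray(p, dtype=float)
        return p[..., 0], p[..., 1]

    def in_field(self, p) -> np.ndarray:
        cx, cy = self.field_center
        x, y = self._xy(p)
        return (x - cx) ** 2 + (y - cy) ** 2 <= self.field_radius**2

    def in_trigger(self, p) -> np.ndarray:
        """Strictly inside the trigger circle (boundary counts as outside)."""
        cx, cy = self.field_center
        x, y = self._xy(p)
        return (x - cx) ** 2 + (y - cy) ** 2 < self.trigger_radius**2

    def in_refuge(self, p) -> np.ndarray:
        """Inside the refuge rectangle (closed boundary)."""
        xmin, xmax, ymin, ymax = self.refuge_rect
        x, y = self._xy(p)
        return (x >= xmin) & (x <= xmax) & (y >= ymin) & (y <= ymax)

    def in_entrance_channel(self, p) -> np.ndarray:
        """In the doorway band between field circle and refuge rectangle.

        The circle is tangent to the rectangle, so a path crossing the shared
        wall anywhere but the exact tangency point passes through a thin
        sliver outside both shapes; the channel (entrance width wide, 1 cm
        deep) covers that doorway.
        """
        cx, cy = self.field_center
        x, y = self._xy(p)
        half = self.entrance_width / 2.0
        ymin = cy + self.field_radius
        return (np.abs(x - cx) <= half) & (y >= ymin - 1.0) & (y <= ymin)

    def in_domain(self, p) -> np.ndarray:
        """Inside arena ∪ refuge ∪ entrance channel (small wall tolerance)."""
        cx, cy = self.field_center
        x, y = self._xy(p)
        r = np.sqrt((x - cx) ** 2 + (y - cy) ** 2)
        near_field = r <= self.field_radius + 1e-6
        return near_field | self.in_refuge(p) | self.in_entrance_channel(p)

    def distance_to_entrance(self, p) -> np.ndarray:
        ex, ey = self.entrance_mid
        x, y = self._xy(p)
        return np.sqrt((x - ex) ** 2 + (y - ey) ** 2)


#: the twelve named movements of the behavior map, plus the two defensive ones
MOVEMENT_VOCABULARY: tuple[str, ...] = (
    "left turning",
    "right turning",
    "looking up",
    "stretching up",
    "stepping",
    "hunching",
    "sniffing",
    "trotting",
    "running",
    "walking",
    "rearing",
    "grooming",
)
DEFENSIVE_MOVEMENTS: tuple[str, ...] = ("flight", "freezing")
ALL_CATEGORIES: tuple[str, ...] = MOVEMENT_VOCABULARY + DEFENSIVE_MOVEMENTS  # 14


@dataclass
class StimulusProtocol:
    """Looming or auditory threat-stimulus protocol.

    Looming defaults: a dark overhead disc expanding from 2° to 40° of visual
    angle in 300 ms, held 50 ms, repeated 15 times with 30-ms inter-stimulus
    intervals.  Auditory defaults: 80 dB SPL broadband noise for 5 s.
    """

    kind: str = "looming"
    start_deg: float = 2.0
    end_deg: float = 40.0
    expand_ms: float = 300.0
    hold_ms: float = 50.0
    repeats: int = 15
    isi_ms: float = 30.0
    sound_db: float = 80.0
    sound_s: float = 5.0

    def __post_init__(self) -> None:
        if self.kind not in ("looming", "auditory"):
            raise ConfigError(f"unknown protocol kind {self.kind!r}")
        if self.kind == "looming":
            if not self.end_deg > self.start_deg:
                raise ConfigError("end_deg must exceed start_deg")
            if min(self.expand_ms, self.hold_ms, self.isi_ms) <= 0 or self.repeats < 1:
                raise ConfigError("all looming durations must be positive, repeats >= 1")
        else:
            if self.sound_s <= 0:
                raise ConfigError("sound duration must be positive")

    @property
    def total_ms(self) -> float:
        """Total stimulus-train duration (no trailing ISI after the last repeat)."""
        if self.kind != "looming":
            return self.sound_s * 1000.0
        return self.repeats * (self.expand_ms + self.hold_ms) + (self.repeats - 1) * self.isi_ms


def arena_from_dict(d: dict) -> ArenaGeometry:
    known = {k: v for k, v in d.items() if k in ArenaGeometry.__dataclass_fields__}
    if "field_center" in known:
        known["field_center"] = tuple(known["field_center"])
    return ArenaGeometry(**known)


def protocol_from_dict(d: dict) -> StimulusProtocol:
    known = {k: v for k, v in d.items() if k in StimulusProtocol.__dataclass_fields__}
    return StimulusProtocol(**known)


def heading_of(vec: np.ndarray) -> float:
    """Angle of a 2D vector in radians, in (-pi, pi]."""
    return math.atan2(vec[1], vec[0])
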