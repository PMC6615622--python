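"""World geometry of the lunge simulator.

Coordinate frame
----------------
``x`` is antero-posterior (positive from the fencer toward the screen,
origin at the initial rear-foot position), ``y`` mediolateral (positive
to the fencer's right as they face the screen), ``z`` vertical (floor at
``z = 0``).  The projected plastron lives in the touch plane
``x = screen_x``, so touch detection is a plane crossing.

The plastron is a fixed 0.26 x 0.82 m rectangle (shoulder-to-shoulder by
shoulder-to-knee of an average fencer).  Its antero-posterior distance is
standardized to 1.5x the fencer's standing height (a long-lunge
distance) and its vertical placement scales with the fencer's height.
Targets are circles (0.05 or 0.10 m diameter) drawn uniformly inside
rectangular zones flush with the four plastron corners.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: standard gravity, m s^-2, used to convert mass to body weight
G = 9.81

#: plastron dimensions, m (mediolateral width, vertical height)
PLASTRON_WIDTH = 0.26
PLASTRON_HEIGHT = 0.82

#: corner-zone labels: Upper/Lower x Left/Right from the fencer's viewpoint;
#: "left" is the negative-y side.
ZONE_LABELS = ("UL", "UR", "LL", "LR")

#: default lunge-distance multiple of standing height
DISTANCE_COEFF = 1.5

#: default vertical position of the plastron centre as a fraction of the
#: fencer's height (approximate mid-point of the shoulder-to-knee band)
VERTICAL_COEFF = 0.47

#: default corner-zone size as fractions of plastron (width, height)
ZONE_FRACTION = (0.45, 0.30)

#: tested target diameters, m
DIAMETERS = (0.05, 0.10)


class InvalidConfigError(ValueError):
    """A geometric configuration that cannot be realized."""


@dataclass(frozen=True)
class FencerProfile:
    """Anthropometrics of one fencer; all simulator distances and force
    thresholds scale from it."""

    id: str
    height: float  # m
    mass: float  # kg
    handedness: str  # "left" | "right"
    level: str = "unknown"

    def __post_init__(self) -> None:
        if not 1.0 < self.height < 2.3:
            raise ValueError(f"height {self.height} m outside (1.0, 2.3)")
        if not 30.0 < self.mass < 200.0:
            raise ValueError(f"mass {self.mass} kg outside (30, 200)")
        if self.handedness not in ("left", "right"):
            raise ValueError(f"handedness {self.handedness!r} not left/right")

    @property
    def bw(self) -> float:
        """Body weight in newtons."""
        return self.mass * G


@dataclass(frozen=True)
class Plastron:
    """The opponent's torso surface projected in the touch plane."""

    width: float  # m, mediolateral
    height: float  # m, vertical
    center: tuple[float, float]  # (y, z) m
    screen_x: float  # m, antero-posterior position of the touch plane

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("plastron dimensions must be positive")

    @property
    def y_min(self) -> float:
        return self.center[0] - self.width / 2

    @property
    def y_max(self) -> float:
        return self.center[0] + self.width / 2

    @property
    def z_min(self) -> float:
        return self.center[1] - self.height / 2

    @property
    def z_max(self) -> float:
        return self.center[1] + self.height / 2


@dataclass(frozen=True)
class TargetZone:
    """A rectangle in which target centres may be drawn."""

    label: str
    y_min: float
    y_max: float
    z_min: float
    z_max: float

    def __post_init__(self) -> None:
        if self.label not in ZONE_LABELS:
            raise ValueError(f"unknown zone label {self.label!r}")
        if self.y_max <= self.y_min or self.z_max <= self.z_min:
            raise ValueError("degenerate zone rectangle")

    @property
    def width(self) -> float:
        return self.y_max - self.y_min

    @property
    def height(self) -> float:
        return self.z_max - self.z_min

    @property
    def center(self) -> tuple[float, float]:
        return ((self.y_min + self.y_max) / 2, (self.z_min + self.z_max) / 2)

    def contains_circle(self, y: float, z: float, diameter: float) -> bool:
        r = diameter / 2
        return (
            self.y_min <= y - r
            and y + r <= self.y_max
            and self.z_min <= z - r
            and z + r <= self.z_max
        )


@dataclass(frozen=True)
class TargetSpec:
    """A concrete circular target inside one zone."""

    y: float
    z: float
    diameter: float
    zone: str

    @property
    def center(self) -> tuple[float, float]:
        return (self.y, self.z)


def build_plastron(
    profile: FencerProfile,
    vertical_coeff: float = VERTICAL_COEFF,
    distance_coeff: float = DISTANCE_COEFF,
) -> Plastron:
    """Place the fixed-size plastron for one fencer.

    The rectangle is always 0.26 x 0.82 m; only its vertical centre
    (``vertical_coeff * height`` above the floor) and the touch-plane
    distance (``distance_coeff * height`` from the rear foot) depend on
    the fencer.
    """
    return Plastron(
        width=PLASTRON_WIDTH,
        height=PLASTRON_HEIGHT,
        center=(0.0, vertical_coeff * profile.height),
        screen_x=distance_coeff * profile.height,
    )


def corner_zones(
    plastron: Plastron, zone_fraction: tuple[float, float] = ZONE_FRACTION
) -> dict[str, TargetZone]:
    """Four target zones flush with the plastron corners.

    ``zone_fraction = (fy, fz)`` gives each zone's size as a fraction of
    the plastron width and height; fractions of 0.5 tile the plastron
    exactly.
    """
    fy, fz = zone_fraction
    if not (0.0 < fy <= 0.5 and 0.0 < fz <= 0.5):
        raise InvalidConfigError(f"zone fractions {zone_fraction} outside (0, 0.5]")
    zw = fy * plastron.width
    zh = fz * plastron.height
    y0, y1 = plastron.y_min, plastron.y_max
    z0, z1 = plastron.z_min, plastron.z_max
    return {
        "UL": TargetZone("UL", y0, y0 + zw, z1 - zh, z1),
        "UR": TargetZone("UR", y1 - zw, y1, z1 - zh, z1),
        "LL": TargetZone("LL", y0, y0 + zw, z0, z0 + zh),
        "LR": TargetZone("LR", y1 - zw, y1, z0, z0 + zh),
    }


def sample_target(
    zone: TargetZone, diameter: float, rng: np.random.Generator
) -> TargetSpec:
    """Draw a target centre uniformly so the whole circle fits in the zone.

    The centre is uniform over the zone rectangle shrunk by the radius on
    each side (not rejection sampling), so every sampled circle lies
    entirely inside the zone.
    """
    r = diameter / 2
    if zone.width < diameter or zone.height < diameter:
        raise InvalidConfigError(
            f"a {diameter} m target cannot fit in zone {zone.label} "
            f"({zone.width:.3f} x {zone.height:.3f} m)"
        )
    y = rng.uniform(zone.y_min + r, zone.y_max - r)
    z = rng.uniform(zone.z_min + r, zone.z_max - r)
    return TargetSpec(y=y, z=z, diameter=diameter, zone=zone.label)
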