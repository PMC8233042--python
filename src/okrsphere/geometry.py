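"""Fish-centred spherical geometry for the LED arena.

Coordinates follow an East-North-Up geographic convention: azimuth is the
horizontal angle in degrees, zero directly rostral and positive to the
animal's right; elevation is the vertical angle, zero in the horizontal
plane and positive above.  The matching Cartesian frame is x = East
(right), y = North (rostral), z = Up, so a direction is

    u = (cos(el)·sin(az), cos(el)·cos(az), sin(el)).

All public interfaces use degrees; radians appear only internally.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate

__all__ = [
    "GeoCoord",
    "ArenaModel",
    "geo_to_unit",
    "unit_to_geo",
    "great_circle_angle",
    "cap_fraction",
    "band_fraction",
    "effective_coverage",
    "tile_solid_angle",
    "tile_solid_angle_closed_form",
    "arena_coverage",
    "reflect",
    "build_arena",
]


@dataclass(frozen=True)
class GeoCoord:
    """A direction on the fish-centred sphere, in degrees.

    azimuth ∈ [−180, 180], positive to the right; elevation ∈ [−90, 90],
    positive above.  (0, 0) is directly rostral.
    """

    azimuth: float
    elevation: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.azimuth) and math.isfinite(self.elevation)):
            raise ValueError("GeoCoord components must be finite")
        if not -180.0 <= self.azimuth <= 180.0:
            raise ValueError(f"azimuth {self.azimuth} outside [-180, 180]")
        if not -90.0 <= self.elevation <= 90.0:
            raise ValueError(f"elevation {self.elevation} outside [-90, 90]")

    def as_tuple(self) -> tuple[float, float]:
        return (self.azimuth, self.elevation)


def geo_to_unit(g: GeoCoord | tuple[float, float]) -> np.ndarray:
    """Unit Cartesian vector (x=right, y=rostral, z=up) for a direction."""
    if not isinstance(g, GeoCoord):
        g = GeoCoord(*g)
    az = math.radians(g.azimuth)
    el = math.radians(g.elevation)
    return np.array(
        [math.cos(el) * math.sin(az), math.cos(el) * math.cos(az), math.sin(el)]
    )


def unit_to_geo(v: np.ndarray, *, tol: float = 1e-6) -> GeoCoord:
    """Inverse of :func:`geo_to_unit`.

    Azimuth ±180 is normalised to +180; at the poles (|z| = 1) the azimuth
    is set to 0 by convention so round-trips are deterministic.
    """
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0.0 or not np.isfinite(n):
        raise ValueError("cannot convert zero or non-finite vector")
    if abs(n - 1.0) > max(tol, 1e-9):
        v = v / n
    x, y, z = v
    el = math.degrees(math.asin(min(1.0, max(-1.0, z))))
    if abs(z) >= 1.0 - 1e-15 or (abs(x) < 1e-15 and abs(y) < 1e-15):
        az = 0.0
    else:
        az = math.degrees(math.atan2(x, y))
        if az <= -180.0 + 1e-12 and az >= -180.0 - 1e-12:
            az = 180.0
    return GeoCoord(az, el)


def great_circle_angle(a: GeoCoord | tuple, b: GeoCoord | tuple) -> float:
    """Central angle between two directions, degrees in [0, 180]."""
    ua, ub = geo_to_unit(a), geo_to_unit(b)
    d = float(np.clip(np.dot(ua, ub), -1.0, 1.0))
    return math.degrees(math.acos(d))


def cap_fraction(half_angle: float) -> float:
    """Fraction of the sphere's surface inside a cap of the given half-angle.

    The half-angle is the polar angle from the cap centre, in [0, 180]
    degrees; the fraction is (1 − cos θ)/2.  A "stimulus diameter" quoted as
    a full planar angle is twice the half-angle.
    """
    if not 0.0 <= half_angle <= 180.0:
        raise ValueError(f"half_angle {half_angle} outside [0, 180]")
    return (1.0 - math.cos(math.radians(half_angle))) / 2.0


def band_fraction(lat_limit: float) -> float:
    """Fraction of the sphere between latitudes ±lat_limit degrees.

    Equals 1 − 2·cap_fraction(90 − lat_limit) = cos(90° − lat_limit)... the
    two polar caps above/below the band are removed from the full sphere.
    """
    if not 0.0 <= lat_limit <= 90.0:
        raise ValueError(f"lat_limit {lat_limit} outside [0, 90]")
    return 1.0 - 2.0 * cap_fraction(90.0 - lat_limit)


def effective_coverage(lat_limit: float, keel_span: float) -> float:
    """Band fraction further reduced by an LED-free azimuthal keel strip.

    keel_span is the azimuthal width (degrees of longitude) occupied by the
    structural keel and therefore dark.
    """
    if not 0.0 <= keel_span <= 360.0:
        raise ValueError(f"keel_span {keel_span} outside [0, 360]")
    return band_fraction(lat_limit) * (360.0 - keel_span) / 360.0


def tile_solid_angle(D: float, R_S: float) -> float:
    """Solid angle (sr) subtended by one flat square LED tile.

    The tile has edge D mm, mounted tangent to a sphere of radius R_S mm and
    centred on the line of sight.  Computed by numerical integration of the
    central projection onto the unit sphere:

        Ω = ∫∫_{|x|,|y| ≤ tan θ_h} (1 + x² + y²)^(−3/2) dx dy,

    with θ_h = arctan(D / 2R_S).  Agrees with the rectangular-pyramid closed
    form to ~1e−10.
    """
    if D <= 0 or R_S <= 0:
        raise ValueError("tile edge and sphere radius must be positive")
    h = D / (2.0 * R_S)  # tan of the half-angle to an edge midpoint
    val, _ = integrate.dblquad(
        lambda y, x: (1.0 + x * x + y * y) ** -1.5,
        -h, h, -h, h, epsabs=1e-10, epsrel=1e-10,
    )
    return val


def tile_solid_angle_closed_form(D: float, R_S: float) -> float:
    """Rectangular-pyramid closed form: Ω = 4·arctan(ab / (2d·√(4d²+a²+b²)))."""
    if D <= 0 or R_S <= 0:
        raise ValueError("tile edge and sphere radius must be positive")
    a = b = D
    d = R_S
    return 4.0 * math.atan(a * b / (2.0 * d * math.sqrt(4 * d * d + a * a + b * b)))


_PLANES = ("sagittal", "horizontal", "coronal")


def reflect(g: GeoCoord | tuple, plane: str) -> GeoCoord:
    """Mirror a direction through one of the three symmetry planes.

    sagittal: left/right (az → −az); horizontal: up/down (el → −el);
    coronal: front/rear (az → sign(az)·(180 − |az|)).  Each is an involution.
    """
    if not isinstance(g, GeoCoord):
        g = GeoCoord(*g)
    if plane == "sagittal":
        az = -g.azimuth
        if az == -180.0:
            az = 180.0
        return GeoCoord(az, g.elevation)
    if plane == "horizontal":
        return GeoCoord(g.azimuth, -g.elevation)
    if plane == "coronal":
        if g.azimuth == 0.0:
            return GeoCoord(180.0, g.elevation)
        if abs(g.azimuth) == 180.0:
            return GeoCoord(0.0, g.elevation)
        az = math.copysign(180.0 - abs(g.azimuth), g.azimuth)
        return GeoCoord(az, g.elevation)
    raise ValueError(f"plane must be one of {_PLANES}, got {plane!r}")


# ---------------------------------------------------------------------------
# Arena model


@dataclass
class ArenaModel:
    """Geometric model of the spherical LED arena.

    232 flat 21 mm tiles (8×8 LEDs each, 14,848 LEDs) hot-glued to a
    scaffold of radius 106.5 mm, arranged on rings of latitude with a dark
    keel strip on the prime meridian and holes above |latitude| ≈ 69°.
    """

    sphere_radius: float = 106.5  # mm
    tile_edge: float = 21.0  # mm
    n_tiles: int = 232
    leds_per_tile: int = 64
    tile_centres: list[GeoCoord] = field(default_factory=list)
    tile_basis: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)
    led_positions: list[GeoCoord] = field(default_factory=list)

    def coverage(self) -> float:
        return arena_coverage(self)

    def to_json(self) -> str:
        obj = {
            "radius_mm": self.sphere_radius,
            "tile_edge_mm": self.tile_edge,
            "leds_per_tile": self.leds_per_tile,
            "tiles": [
                {"centre_az": c.azimuth, "centre_el": c.elevation}
                for c in self.tile_centres
            ],
        }
        return json.dumps(obj, indent=1)


def arena_coverage(arena: ArenaModel) -> float:
    """Fraction of the sphere covered by the arena's tiles.

    n_tiles × Ω_tile / 4π, treating tiles as non-overlapping.  With the
    default dimensions this evaluates to ≈ 0.711; the build documentation
    quotes "around 66.5%", which this projection-based estimate does not
    reproduce (gaps and the exact mounting distance are not modelled).
    """
    if arena.n_tiles == 0:
        return 0.0
    return arena.n_tiles * tile_solid_angle(arena.tile_edge, arena.sphere_radius) / (
        4.0 * math.pi
    )


def _tile_frame(centre: GeoCoord) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal (u_az, u_el) pair spanning the tile plane at `centre`."""
    n = geo_to_unit(centre)
    zhat = np.array([0.0, 0.0, 1.0])
    u_az = np.cross(zhat, n)
    norm = np.linalg.norm(u_az)
    if norm < 1e-9:  # tile at a pole: pick rostral as the azimuth axis
        u_az = np.array([1.0, 0.0, 0.0])
    else:
        u_az = u_az / norm
    u_el = np.cross(n, u_az)
    return u_az, u_el


def build_arena(
    sphere_radius: float = 106.5,
    tile_edge: float = 21.0,
    n_tiles: int = 232,
    leds_per_tile: int = 64,
    lat_limit: float = 69.0,
    keel_span: float = 30.0,
) -> ArenaModel:
    """Construct a procedural arena layout.

    Tiles are packed on rings of latitude between ±lat_limit, skipping the
    keel strip centred on the caudal prime meridian; ring spacing equals the
    tile's angular extent.  The layout reproduces the tile/LED counts and
    approximate distribution, not the physical CAD.
    """
    tile_ang = 2.0 * math.degrees(math.atan(tile_edge / (2.0 * sphere_radius)))
    n_rings = max(1, int(2.0 * lat_limit // tile_ang))
    ring_lats = [(-lat_limit + tile_ang / 2.0) + i * tile_ang for i in range(n_rings)]

    # provisional per-ring capacity, then trim the fullest rings to n_tiles
    caps = []
    for lat in ring_lats:
        circ = 360.0 * math.cos(math.radians(lat))
        caps.append(max(1, int(circ // tile_ang)))
    total = sum(caps)
    while total > n_tiles:
        i = int(np.argmax(caps))
        caps[i] -= 1
        total -= 1
    while total < n_tiles:
        i = int(np.argmin(caps))
        caps[i] += 1
        total += 1

    centres: list[GeoCoord] = []
    for lat, cap in zip(ring_lats, caps):
        # spread tiles over azimuth, leaving the caudal keel strip dark
        span = 360.0 - keel_span
        for j in range(cap):
            az = -span / 2.0 + (j + 0.5) * span / cap
            centres.append(GeoCoord(az, lat))

    n_side = int(round(math.sqrt(leds_per_tile)))
    if n_side * n_side != leds_per_tile:
        raise ValueError("leds_per_tile must be a perfect square")
    pitch = tile_edge / n_side

    basis = []
    leds: list[GeoCoord] = []
    for c in centres:
        u_az, u_el = _tile_frame(c)
        basis.append((u_az, u_el))
        n = geo_to_unit(c) * sphere_radius
        for i in range(n_side):
            for j in range(n_side):
                dx = (i - (n_side - 1) / 2.0) * pitch
                dy = (j - (n_side - 1) / 2.0) * pitch
                p = n + dx * u_az + dy * u_el
                leds.append(unit_to_geo(p / np.linalg.norm(p)))

    return ArenaModel(
        sphere_radius=sphere_radius,
        tile_edge=tile_edge,
        n_tiles=n_tiles,
        leds_per_tile=leds_per_tile,
        tile_centres=centres,
        tile_basis=basis,
        led_positions=leds,
    )
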