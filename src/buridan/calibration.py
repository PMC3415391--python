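"""Arena geometry and pixel-to-millimetre calibration.

The walking platform is a disk (117 mm diameter by default) filmed from
above.  Calibration fits a circle through three user-clicked points on the
platform rim; pixel coordinates are then mapped into an orthogonal frame
with its origin at the platform centre and a unit of 1 mm.  Pixel y grows
downward, so the mm frame flips y to stay right-handed.

The module also computes the angular (retinal) size of the black stripes
taped to the surrounding diffuser, as seen by an eye in the plane of the
stripe base.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateGeometryError, ValidationError

__all__ = [
    "ArenaGeometry",
    "PixelCircle",
    "circle_from_3_points",
    "to_arena_mm",
    "px_to_mm",
    "mm_to_px",
    "retinal_height_deg",
    "retinal_width_deg",
]


@dataclass(frozen=True)
class ArenaGeometry:
    """Physical dimensions of the arena, all in millimetres.

    Defaults describe a 117 mm platform surrounded by a cylindrical
    diffuser of radius 147.5 mm carrying two opposing stripes 313 mm tall,
    whose centres project to (0, +146.5) and (0, -146.5) in the arena frame.
    ``stripe_width_mm`` is ``None`` for experiments without visual targets
    (endogenous locomotion).
    """

    platform_radius_mm: float = 58.5
    stripe_distance_mm: float = 146.5
    diffuser_radius_mm: float = 147.5
    stripe_height_mm: float = 313.0
    stripe_width_mm: float | None = None

    def __post_init__(self) -> None:
        if self.platform_radius_mm <= 0:
            raise ValidationError("platform_radius_mm must be > 0")

    @property
    def stripe_centers_mm(self) -> tuple[tuple[float, float], tuple[float, float]]:
        """The two stripe centres, symmetric about the origin on the y axis."""
        s = self.stripe_distance_mm
        return ((0.0, s), (0.0, -s))

    @property
    def stripe_axis(self) -> tuple[float, float]:
        """Unit vector from the origin toward the first stripe centre."""
        return (0.0, 1.0)


@dataclass(frozen=True)
class PixelCircle:
    """The platform rim as seen by the camera, in pixel coordinates."""

    cx_px: float
    cy_px: float
    r_px: float

    def __post_init__(self) -> None:
        if self.r_px <= 0:
            raise ValidationError("r_px must be > 0")


def circle_from_3_points(
    p1: tuple[float, float],
    p2: tuple[float, float],
    p3: tuple[float, float],
) -> PixelCircle:
    """Fit the unique circle through three non-collinear points.

    This is the semi-automatic platform calibration: the experimenter
    clicks three points on the platform edge, spaced as far apart as
    possible, and the rim circle is solved from the perpendicular-bisector
    equations.

    Raises
    ------
    DegenerateGeometryError
        If the points are collinear (no finite circle exists).
    """
    (x1, y1), (x2, y2), (x3, y3) = p1, p2, p3
    # Twice the signed area of the triangle; zero iff collinear.
    d = 2.0 * (x1 * (y2 - y3) + x2 * (y3 - y1) + x3 * (y1 - y2))
    scale = max(abs(v) for v in (x1, y1, x2, y2, x3, y3, 1.0))
    if abs(d) <= 1e-12 * scale * scale:
        raise DegenerateGeometryError(
            f"points {p1}, {p2}, {p3} are collinear; cannot fit a circle"
        )
    s1 = x1 * x1 + y1 * y1
    s2 = x2 * x2 + y2 * y2
    s3 = x3 * x3 + y3 * y3
    cx = (s1 * (y2 - y3) + s2 * (y3 - y1) + s3 * (y1 - y2)) / d
    cy = (s1 * (x3 - x2) + s2 * (x1 - x3) + s3 * (x2 - x1)) / d
    r = math.hypot(x1 - cx, y1 - cy)
    return PixelCircle(cx, cy, r)


def px_to_mm(
    x_px: np.ndarray,
    y_px: np.ndarray,
    circle: PixelCircle,
    platform_radius_mm: float = 58.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Map pixel coordinates to the arena-centred mm frame.

    The rim circle maps to radius ``platform_radius_mm``; y is flipped so
    the mm frame is right-handed (pixel y grows downward).
    """
    k = platform_radius_mm / circle.r_px
    x_mm = (np.asarray(x_px, dtype=float) - circle.cx_px) * k
    y_mm = -(np.asarray(y_px, dtype=float) - circle.cy_px) * k
    return x_mm, y_mm


def mm_to_px(
    x_mm: np.ndarray,
    y_mm: np.ndarray,
    circle: PixelCircle,
    platform_radius_mm: float = 58.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`px_to_mm`."""
    k = platform_radius_mm / circle.r_px
    x_px = np.asarray(x_mm, dtype=float) / k + circle.cx_px
    y_px = -np.asarray(y_mm, dtype=float) / k + circle.cy_px
    return x_px, y_px


def to_arena_mm(track, circle: PixelCircle, platform_radius_mm: float = 58.5):
    """Convert a raw pixel track to an arena-centred mm trajectory.

    Returns a :class:`~buridan.preprocess.Trajectory` with one burst per
    burst number in the track, timestamps converted from ms to seconds.
    The trajectory is *not* yet resampled or filtered.
    """
    from .preprocess import Burst, Trajectory

    bursts = []
    for burst_id in np.unique(track.burst):
        sel = track.burst == burst_id
        x_mm, y_mm = px_to_mm(track.x_px[sel], track.y_px[sel], circle, platform_radius_mm)
        bursts.append(Burst(t=track.t_ms[sel] / 1000.0, x=x_mm, y=y_mm))
    return Trajectory(bursts=bursts)


def retinal_height_deg(stripe_height_mm: float, distance_mm: float) -> float:
    """Angular height of a stripe whose base lies in the observer's plane.

    For an eye at horizontal distance ``distance_mm`` from a vertical
    stripe of height ``stripe_height_mm``, the subtended height is
    ``atan(height / distance)``.  From the platform centre (147.5 mm) a
    313 mm stripe subtends about 65 degrees.
    """
    if stripe_height_mm < 0 or distance_mm <= 0:
        raise ValidationError("stripe height must be >= 0 and distance > 0")
    return math.degrees(math.atan2(stripe_height_mm, distance_mm))


def retinal_width_deg(stripe_width_mm: float, distance_mm: float) -> float:
    """Full angular width of a stripe seen face-on at a given distance.

    Computed as twice the half-angle of the half-width: ``2*atan(w/2d)``
    (planar-target convention).
    """
    if stripe_width_mm < 0 or distance_mm <= 0:
        raise ValidationError("stripe width must be >= 0 and distance > 0")
    if stripe_width_mm >= 2.0 * distance_mm:
        raise ValidationError("stripe width must be < 2 * distance")
    return 2.0 * math.degrees(math.atan2(stripe_width_mm / 2.0, distance_mm))
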