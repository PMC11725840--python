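"""Spatial bookkeeping: recording geometry, bar-edge crossing times, and the
per-cell, per-direction PRE / Central / POST analysis windows.

Conventions
-----------
Coordinates are right-handed; directions are degrees counterclockwise with
0 deg = +x.  A moving bar is modeled as an infinite strip perpendicular to
its motion vector, so crossing times of a circle centered on the receptive
field depend only on the bar width, speed and circle radius — not on the
motion direction.  Time t = 0 of a sweep is the moment the bar *center* is
aligned with the RF center.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Point, Polygon

#: The eight standard motion / grating directions, degrees CCW from +x.
DIRECTIONS_DEG = np.arange(0.0, 360.0, 45.0)


def unit_vector(angle_deg: float) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    return np.array([np.cos(a), np.sin(a)])


class CellExcluded(Exception):
    """A cell failed an inclusion gate; carries the reason string."""

    def __init__(self, cell_id, reason: str):
        self.cell_id = cell_id
        self.reason = reason
        super().__init__(f"{cell_id}: {reason}")


@dataclass(frozen=True)
class RetinaGeometry:
    """Recording-chamber geometry.

    ``edge_polygon`` is the recorded-tissue boundary (retinal edge, or the
    stimulation-screen rectangle for thalamic recordings).  ``units`` is
    "um" for retina, "deg" for visual-angle (LGN) mode; the code path is
    identical in either unit system.
    """

    edge_polygon: tuple
    optic_disc: tuple = (0.0, 0.0)
    units: str = "um"
    central_radius: float = 350.0
    distance_min_required: float = 450.0

    def __post_init__(self):
        poly = self.polygon
        if not poly.is_valid or poly.area <= 0:
            raise ValueError("edge_polygon must be a simple closed polygon")
        if self.central_radius >= self.distance_min_required:
            raise ValueError("central_radius must be < distance_min_required")
        if self.units not in ("um", "deg"):
            raise ValueError(f"unknown units {self.units!r}")

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.edge_polygon)

    @classmethod
    def rectangle(cls, width: float, height: float, center=(0.0, 0.0),
                  **kwargs) -> "RetinaGeometry":
        cx, cy = center
        w2, h2 = width / 2.0, height / 2.0
        verts = ((cx - w2, cy - h2), (cx + w2, cy - h2),
                 (cx + w2, cy + h2), (cx - w2, cy + h2))
        return cls(edge_polygon=verts, **kwargs)

    def bounding_radius(self) -> float:
        """Radius of the smallest origin-centered circle covering the tissue."""
        xy = np.asarray(self.edge_polygon, float)
        return float(np.hypot(xy[:, 0], xy[:, 1]).max())


def distance_min(rf_center, geometry: RetinaGeometry) -> float:
    """Minimum Euclidean distance from an RF center to the recording edge.

    This is the per-cell Distance_min; cells whose value falls below the
    geometry's requirement are excluded from the extraclassical screen so
    that the annulus under analysis lies entirely within recorded tissue.
    """
    p = Point(float(rf_center[0]), float(rf_center[1]))
    poly = geometry.polygon
    if not poly.covers(p):
        raise ValueError(f"rf_center {tuple(rf_center)} lies outside the "
                         "recording boundary")
    return float(poly.exterior.distance(p))


def bar_crossing_times(speed: float, bar_width: float,
                       radius: float) -> tuple[float, float]:
    """Times at which a moving bar's leading edge enters and trailing edge
    exits a circle of ``radius`` about the RF center.

    t = 0 when the bar center is aligned with the RF center.  For an
    infinite strip these times are independent of motion direction:

        t_lead_enter = -(radius + width/2) / speed
        t_trail_exit = +(radius + width/2) / speed
    """
    if speed <= 0:
        raise ValueError("speed must be positive")
    if radius < 0:
        raise ValueError("radius must be non-negative")
    t = (radius + bar_width / 2.0) / speed
    return (-t, +t)


@dataclass(frozen=True)
class AnalysisWindows:
    """PRE / Central / POST windows for one cell and one bar protocol.

    Times are seconds relative to bar-center / RF-center alignment; because
    the bar is an infinite strip the windows are identical across the eight
    directions.  ``post_exclusion``, when set, is the sub-interval of the
    POST window during which the bar's *leading* edge is still inside the
    annulus; the unmasked POST analysis omits it because that epoch
    coincides with the trailing edge crossing the classical RF.
    """

    annulus_radius: float
    central_radius: float
    bar_width: float
    speed: float
    directions: tuple = tuple(DIRECTIONS_DEG)
    post_exclusion: tuple | None = None

    def __post_init__(self):
        if self.annulus_radius <= self.central_radius:
            raise ValueError("annulus radius must exceed the Central radius")

    @property
    def t_lead_enter_annulus(self) -> float:
        return bar_crossing_times(self.speed, self.bar_width,
                                  self.annulus_radius)[0]

    @property
    def t_lead_enter_central(self) -> float:
        return bar_crossing_times(self.speed, self.bar_width,
                                  self.central_radius)[0]

    @property
    def t_trail_exit_central(self) -> float:
        return bar_crossing_times(self.speed, self.bar_width,
                                  self.central_radius)[1]

    @property
    def t_trail_exit_annulus(self) -> float:
        return bar_crossing_times(self.speed, self.bar_width,
                                  self.annulus_radius)[1]

    @property
    def pre_window(self) -> tuple[float, float]:
        return (self.t_lead_enter_annulus, self.t_lead_enter_central)

    @property
    def central_window(self) -> tuple[float, float]:
        return (self.t_lead_enter_central, self.t_trail_exit_central)

    @property
    def post_window(self) -> tuple[float, float]:
        return (self.t_trail_exit_central, self.t_trail_exit_annulus)

    def window(self, kind: str) -> tuple[float, float]:
        kind = kind.upper()
        if kind == "PRE":
            return self.pre_window
        if kind == "CENTRAL":
            return self.central_window
        if kind == "POST":
            return self.post_window
        raise ValueError(f"unknown window kind {kind!r}")


def build_windows(rf_center, geometry: RetinaGeometry, bar_width: float,
                  speed: float, cell_id=None,
                  exclude_post_leading_edge: bool = True) -> AnalysisWindows:
    """Construct per-cell analysis windows for a moving-bar protocol.

    The annulus radius is the cell's Distance_min; cells closer than
    ``geometry.distance_min_required`` to the edge raise
    :class:`CellExcluded` (an explicit record, never a silent drop).
    """
    dmin = distance_min(rf_center, geometry)
    if dmin < geometry.distance_min_required:
        raise CellExcluded(
            cell_id, f"distance_min {dmin:.1f} {geometry.units} < required "
                     f"{geometry.distance_min_required:g}")
    post_excl = None
    if exclude_post_leading_edge:
        # leading edge exits the annulus at +(R - w/2)/v; while it is still
        # inside, the trailing edge occupies the classical RF
        t_lead_exit_annulus = (dmin - bar_width / 2.0) / speed
        t0, t1 = bar_crossing_times(speed, bar_width,
                                    geometry.central_radius)[1], \
            bar_crossing_times(speed, bar_width, dmin)[1]
        if t_lead_exit_annulus > t0:
            post_excl = (t0, min(t1, t_lead_exit_annulus))
    return AnalysisWindows(
        annulus_radius=dmin,
        central_radius=geometry.central_radius,
        bar_width=bar_width,
        speed=speed,
        post_exclusion=post_excl,
    )


def bar_alignment_time(onset: float, p0: float, speed: float,
                       direction_deg: float, rf_center) -> float:
    """Absolute time at which a sweeping bar's center crosses an RF center.

    ``p0`` is the bar-center's signed position along the motion axis at
    trial ``onset`` (projection onto the unit motion vector, origin at the
    coordinate origin)."""
    d = float(np.dot(np.asarray(rf_center, float), unit_vector(direction_deg)))
    return onset + (d - p0) / speed
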