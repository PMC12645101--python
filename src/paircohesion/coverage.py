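"""Array-coverage diagnostics for the strongest-detection method.

Under the strongest-detection rule with an RSS cutoff, a tag is localizable
only within a fixed radius (23.5 m for the -80 dB cutoff under the reference
curve) of some receiver.  This module computes the detectable area implied by
that radius — both as the simple per-receiver sum (n*pi*r**2, the convention
used in field reports) and as the geometrically correct union of disks — and
relates it to the array footprint and to per-individual use areas (minimum
convex polygons), yielding the expected localization fraction an individual
would achieve if it used its range homogeneously.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import MultiPoint, Point, Polygon
from shapely.ops import unary_union

from .errors import DegenerateGeometryError, InvalidParameterError
from .synthetic_data import ReceiverArray

__all__ = [
    "CoverageReport",
    "detectable_area",
    "minimum_convex_polygon",
    "expected_localization_fraction",
    "coverage_report",
    "printed_summed_fraction",
]

#: Circle approximation: shapely buffer quadrant segments (64-gon, <0.2% area error).
_QUAD_SEGS = 16


def detectable_area(array: ReceiverArray, radius: float, mode: str = "summed") -> float:
    """Detectable area (km**2) around all receivers at the given radius.

    ``summed`` is n*pi*r**2 regardless of overlap (the conventional field
    arithmetic; double-counts overlapping disks and duplicated receivers);
    ``union`` is the area of the geometric union of the disks.
    """
    if not radius > 0:
        raise InvalidParameterError("radius must be > 0")
    if mode == "summed":
        return len(array.ids) * math.pi * radius**2 / 1e6
    if mode == "union":
        disks = [Point(xy).buffer(radius, quad_segs=_QUAD_SEGS) for xy in array.xy]
        return unary_union(disks).area / 1e6
    raise InvalidParameterError(f"unknown mode {mode!r}")


def minimum_convex_polygon(points: np.ndarray, percent: int = 100) -> tuple[Polygon, float]:
    """Minimum convex polygon home-range estimate.

    ``percent=100`` is the convex hull of all points; ``percent=95`` first
    removes the 5% of points farthest from the centroid (standard peeling
    convention).  Returns (polygon, area_km2).

    Raises DegenerateGeometryError for <3 points or a collinear point set.
    """
    pts = np.asarray(points, dtype=float)
    if percent not in (95, 100):
        raise InvalidParameterError("percent must be 95 or 100")
    if len(pts) < 3:
        raise DegenerateGeometryError("need at least 3 points for an MCP")
    if percent == 95:
        centroid = pts.mean(axis=0)
        d = np.sqrt(((pts - centroid) ** 2).sum(axis=1))
        keep = math.ceil(0.95 * len(pts))
        pts = pts[np.argsort(d, kind="stable")[:keep]]
        if len(pts) < 3:
            raise DegenerateGeometryError("too few points after 95% peeling")
    hull = MultiPoint([tuple(p) for p in pts]).convex_hull
    if hull.geom_type != "Polygon" or hull.area == 0:
        raise DegenerateGeometryError("points are collinear; hull has no area")
    return hull, hull.area / 1e6


def expected_localization_fraction(
    array: ReceiverArray, polygon: Polygon, radius: float
) -> float:
    """Percent of a use polygon covered by per-receiver detection disks.

    Sum over receivers of (disk intersect polygon) area, divided by the
    polygon area, x100.  Because per-receiver intersections are summed (not
    unioned), pathological overlap can exceed 100%; that follows the summed
    field arithmetic and is flagged in :func:`coverage_report`.
    """
    if not radius > 0:
        raise InvalidParameterError("radius must be > 0")
    if polygon.area == 0:
        raise DegenerateGeometryError("zero-area polygon")
    total = 0.0
    for xy in array.xy:
        disk = Point(xy).buffer(radius, quad_segs=_QUAD_SEGS)
        total += disk.intersection(polygon).area
    return 100.0 * total / polygon.area


def printed_summed_fraction(array: ReceiverArray, radius: float, array_area_km2: float) -> float:
    """Summed detectable area as a percent of the array, rounded-input style.

    Mirrors the arithmetic convention of field summaries that round the
    summed area to 2 decimals (km**2) before dividing, then truncate the
    percentage to 2 decimals — e.g. 0.16/1.27 -> 12.59%.  The exact value is
    available from :func:`coverage_report`.
    """
    summed = round(detectable_area(array, radius, "summed"), 2)
    return math.floor(summed / array_area_km2 * 100 * 100) / 100


@dataclass(frozen=True)
class CoverageReport:
    """Detectable-area bookkeeping for one array (and optional individuals)."""

    radius_m: float
    n_receivers: int
    per_receiver_area_m2: float
    summed_area_km2: float
    union_area_km2: float
    array_area_km2: float
    summed_fraction_pct: float  # exact arithmetic
    summed_fraction_printed_pct: float  # rounded-input convention
    union_fraction_pct: float
    individuals: dict = field(default_factory=dict)
    # individuals: id -> {"mcp_area_km2", "detectable_within_mcp_km2", "expected_fraction_pct"}


def coverage_report(
    array: ReceiverArray,
    radius: float,
    array_area_km2: float | None = None,
    individual_points: dict[str, np.ndarray] | None = None,
) -> CoverageReport:
    """Full coverage report: array-level areas plus per-individual MCP coverage.

    ``array_area_km2`` defaults to the area of the array's bounding rectangle.
    ``individual_points`` maps individual id to an (n, 2) location array; for
    each, the 100% MCP, the summed detectable area within it, and the
    expected localization fraction are reported.
    """
    if array_area_km2 is None:
        xmin, ymin, xmax, ymax = array.bounds
        array_area_km2 = max((xmax - xmin) * (ymax - ymin), 1e-12) / 1e6
    summed = detectable_area(array, radius, "summed")
    union = detectable_area(array, radius, "union")
    individuals = {}
    for ind, pts in (individual_points or {}).items():
        poly, mcp_km2 = minimum_convex_polygon(pts, percent=100)
        frac = expected_localization_fraction(array, poly, radius)
        individuals[ind] = {
            "mcp_area_km2": mcp_km2,
            "detectable_within_mcp_km2": frac / 100.0 * mcp_km2,
            "expected_fraction_pct": frac,
        }
    return CoverageReport(
        radius_m=radius,
        n_receivers=len(array.ids),
        per_receiver_area_m2=math.pi * radius**2,
        summed_area_km2=summed,
        union_area_km2=union,
        array_area_km2=array_area_km2,
        summed_fraction_pct=100.0 * summed / array_area_km2,
        summed_fraction_printed_pct=printed_summed_fraction(array, radius, array_area_km2),
        union_fraction_pct=100.0 * union / array_area_km2,
        individuals=individuals,
    )
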