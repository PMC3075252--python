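"""Planar geometric kernel for track congruence.

All distances are planar Euclidean in decimal-degree space.  This is a
deliberate fidelity choice: the congruence thresholds of the method
(cut value, lmin, lmax, lmax.line) are expressed in degrees and only make
sense in the flat lon/lat plane; a geodesic mode is out of scope.

The central primitive is the point-to-segment distance with explicit
*perpendicular foot* detection: whether the orthogonal projection of a
point onto the supporting line of a segment lands inside the segment.
The foot pattern of the four endpoint projections between two segments
(none / partial / full overlap) drives the congruence decision rules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import IntEnum
from typing import Optional

import numpy as np

__all__ = [
    "TOL",
    "GeoPoint",
    "Segment",
    "PointProjection",
    "OverlapPattern",
    "SegmentPairGeometry",
    "InputError",
    "point_segment_distance",
    "segment_pair_geometry",
    "segments_as_array",
    "pairwise_segment_geometry",
]

#: Floating-point tolerance (degrees) for foot/boundary tests.
TOL = 1e-9


class InputError(ValueError):
    """Invalid input data (non-finite coordinates, empty inputs...)."""


@dataclass(frozen=True, order=True)
class GeoPoint:
    """A georeferenced position: longitude (x) and latitude (y) in decimal degrees.

    Range checks (|lat| <= 90, |lon| <= 180) are applied at ingestion by
    :mod:`pantracks.io_formats`; after ingestion points are plain planar
    coordinates.
    """

    lon: float
    lat: float

    def distance_to(self, other: "GeoPoint") -> float:
        return math.hypot(self.lon - other.lon, self.lat - other.lat)


@dataclass(frozen=True)
class Segment:
    """An edge between two endpoint vertices; the basic unit of congruence."""

    a: GeoPoint
    b: GeoPoint

    @property
    def length(self) -> float:
        return self.a.distance_to(self.b)

    @property
    def is_degenerate(self) -> bool:
        return self.length <= TOL


@dataclass(frozen=True)
class PointProjection:
    """Result of projecting a point onto a segment.

    ``has_foot`` is true iff the perpendicular foot lies within the segment
    (projection parameter t in the closed interval [0, 1], with tolerance);
    otherwise ``distance`` is the distance to the nearer endpoint and
    ``foot`` is absent.
    """

    distance: float
    has_foot: bool
    foot: Optional[GeoPoint] = None


class OverlapPattern(IntEnum):
    """Foot pattern of the four endpoint projections between two segments."""

    NONE = 0          # no projection has a perpendicular foot
    PARTIAL = 1       # at least one foot, but no side fully overlaps
    FULL_OVERLAP = 2  # both endpoints of one segment have feet on the other


@dataclass(frozen=True)
class SegmentPairGeometry:
    """Distance summary between two segments.

    dmin is the true minimum distance between the two segments: the
    minimum of the four endpoint-to-opposite-segment distances, or 0 when
    the segments properly cross (so dmin = 0 iff the segments intersect or
    touch).  dmax is the maximum of the four endpoint distances (the
    segment-pair maximum is always attained at an endpoint).  dmax_line is
    defined only in the full-overlap
    configuration: the larger of the two foot-bearing endpoint distances on
    the side achieving full overlap (the smaller of the two side-maxima if
    both sides qualify).  All fields are symmetric in the two segments.
    """

    dmin: float
    dmax: float
    pattern: OverlapPattern
    dmax_line: Optional[float] = None


def _require_finite(*values: float) -> None:
    for v in values:
        if not math.isfinite(v):
            raise InputError(f"non-finite coordinate: {v!r}")


def point_segment_distance(p: GeoPoint, s: Segment) -> PointProjection:
    """Shortest distance from point *p* to segment *s*, with foot detection.

    The perpendicular extension of *p* towards the segment is computed via
    the projection parameter ``t = (p-a)·(b-a) / |b-a|²``.  If t falls in
    [0, 1] (closed, tolerance :data:`TOL`) the distance is to the foot
    ``a + t(b-a)``; otherwise it is the distance to the nearer endpoint.
    A degenerate segment (a == b) is treated as a point (no foot).
    """
    _require_finite(p.lon, p.lat, s.a.lon, s.a.lat, s.b.lon, s.b.lat)
    dx = s.b.lon - s.a.lon
    dy = s.b.lat - s.a.lat
    l2 = dx * dx + dy * dy
    if l2 <= TOL * TOL:
        return PointProjection(distance=p.distance_to(s.a), has_foot=False)
    t = ((p.lon - s.a.lon) * dx + (p.lat - s.a.lat) * dy) / l2
    if -TOL <= t <= 1.0 + TOL:
        tc = min(max(t, 0.0), 1.0)
        foot = GeoPoint(s.a.lon + tc * dx, s.a.lat + tc * dy)
        return PointProjection(distance=p.distance_to(foot), has_foot=True, foot=foot)
    da = p.distance_to(s.a)
    db = p.distance_to(s.b)
    return PointProjection(distance=min(da, db), has_foot=False)


# ---------------------------------------------------------------------------
# Vectorised kernel.  congruent_segment_map and the similarity index compare
# every edge of one track against every edge of another; the scalar API above
# would dominate runtime, so the same formulas are evaluated with numpy
# broadcasting over (n, m) edge pairs.  segment_pair_geometry delegates to
# this kernel with 1x1 arrays, which keeps the two code paths identical.
# ---------------------------------------------------------------------------

def segments_as_array(segments) -> np.ndarray:
    """Pack segments into an (n, 4) float array [ax, ay, bx, by]."""
    out = np.empty((len(segments), 4), dtype=float)
    for i, s in enumerate(segments):
        out[i] = (s.a.lon, s.a.lat, s.b.lon, s.b.lat)
    return out


def _project(px, py, ax, ay, bx, by):
    """Broadcast point-to-segment distance; returns (distance, has_foot)."""
    dx = bx - ax
    dy = by - ay
    l2 = dx * dx + dy * dy
    degenerate = l2 <= TOL * TOL
    safe_l2 = np.where(degenerate, 1.0, l2)
    t = ((px - ax) * dx + (py - ay) * dy) / safe_l2
    has_foot = ~degenerate & (t >= -TOL) & (t <= 1.0 + TOL)
    tc = np.clip(t, 0.0, 1.0)
    # the clipped foot coincides with the nearer endpoint when t is outside
    # [0,1], so a single distance expression covers both branches
    fx = ax + np.where(degenerate, 0.0, tc) * dx
    fy = ay + np.where(degenerate, 0.0, tc) * dy
    dist = np.hypot(px - fx, py - fy)
    return dist, has_foot


def pairwise_segment_geometry(segs1: np.ndarray, segs2: np.ndarray):
    """All-pairs segment geometry between two edge arrays.

    Parameters
    ----------
    segs1, segs2 : (n, 4) and (m, 4) arrays from :func:`segments_as_array`.

    Returns
    -------
    dmin, dmax : (n, m) arrays of the four-projection min/max distances.
    pattern : (n, m) int array of :class:`OverlapPattern` codes.
    dmax_line : (n, m) array, NaN where the pattern is not FULL_OVERLAP.
    """
    a1x, a1y, b1x, b1y = (segs1[:, k][:, None] for k in range(4))
    a2x, a2y, b2x, b2y = (segs2[:, k][None, :] for k in range(4))

    d0, f0 = _project(a1x, a1y, a2x, a2y, b2x, b2y)  # a1 -> s2
    d1, f1 = _project(b1x, b1y, a2x, a2y, b2x, b2y)  # b1 -> s2
    d2, f2 = _project(a2x, a2y, a1x, a1y, b1x, b1y)  # a2 -> s1
    d3, f3 = _project(b2x, b2y, a1x, a1y, b1x, b1y)  # b2 -> s1

    deg1 = np.hypot(b1x - a1x, b1y - a1y) <= TOL
    deg2 = np.hypot(b2x - a2x, b2y - a2y) <= TOL
    full1 = f0 & f1 & ~deg1  # degenerate segments never trigger full overlap
    full2 = f2 & f3 & ~deg2

    dmin = np.minimum(np.minimum(d0, d1), np.minimum(d2, d3))
    dmax = np.maximum(np.maximum(d0, d1), np.maximum(d2, d3))

    # dmin must be the true inter-segment minimum: for properly crossing
    # segments the minimum (zero) is interior, not at an endpoint, so the
    # four projections alone would overestimate it.  Orientation test:
    c1 = (b2x - a2x) * (a1y - a2y) - (b2y - a2y) * (a1x - a2x)
    c2 = (b2x - a2x) * (b1y - a2y) - (b2y - a2y) * (b1x - a2x)
    c3 = (b1x - a1x) * (a2y - a1y) - (b1y - a1y) * (a2x - a1x)
    c4 = (b1x - a1x) * (b2y - a1y) - (b1y - a1y) * (b2x - a1x)
    crossing = (c1 * c2 < 0) & (c3 * c4 < 0)
    dmin = np.where(crossing, 0.0, dmin)

    any_foot = f0 | f1 | f2 | f3
    pattern = np.where(full1 | full2, int(OverlapPattern.FULL_OVERLAP),
                       np.where(any_foot, int(OverlapPattern.PARTIAL),
                                int(OverlapPattern.NONE)))

    side1 = np.maximum(d0, d1)
    side2 = np.maximum(d2, d3)
    dmax_line = np.where(
        full1 & full2, np.minimum(side1, side2),
        np.where(full1, side1, np.where(full2, side2, np.nan)),
    )
    return dmin, dmax, pattern, dmax_line


def segment_pair_geometry(s1: Segment, s2: Segment) -> SegmentPairGeometry:
    """Distance summary between two segments (symmetric in its arguments)."""
    for s in (s1, s2):
        _require_finite(s.a.lon, s.a.lat, s.b.lon, s.b.lat)
    dmin, dmax, pattern, dmax_line = pairwise_segment_geometry(
        segments_as_array([s1]), segments_as_array([s2])
    )
    pat = OverlapPattern(int(pattern[0, 0]))
    dl = float(dmax_line[0, 0])
    return SegmentPairGeometry(
        dmin=float(dmin[0, 0]),
        dmax=float(dmax[0, 0]),
        pattern=pat,
        dmax_line=dl if pat == OverlapPattern.FULL_OVERLAP else None,
    )
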