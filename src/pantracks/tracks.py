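"""Individual tracks: cut-value deduplication and minimum spanning trees.

An *individual track* is the minimum spanning tree (MST) over a species'
occurrence points under planar Euclidean distance — the panbiogeographic
representation of its distribution.  Before the MST is built, points closer
than the user's *cut value* are collapsed to a single point, which removes
sampling redundancy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Sequence, Tuple

import numpy as np
from networkx.utils import UnionFind

from .geometry import GeoPoint, InputError, Segment, segments_as_array

__all__ = [
    "ParameterError",
    "SpeciesRecordSet",
    "Track",
    "CongruenceParams",
    "deduplicate_points",
    "build_mst",
    "individual_track",
]


class ParameterError(ValueError):
    """A congruence parameter violates its constraint."""


@dataclass
class SpeciesRecordSet:
    """All occurrence points of one taxon, in input-file order."""

    taxon: str
    points: List[GeoPoint]

    def __post_init__(self) -> None:
        if not self.taxon:
            raise InputError("taxon name must be non-empty")
        if not self.points:
            raise InputError(f"species {self.taxon!r} has no points")


@dataclass(frozen=True)
class CongruenceParams:
    """The five user parameters of the congruence analysis.

    All distance parameters are in decimal degrees and must satisfy the
    constraining rule ``0 <= cut_value <= lmin <= lmax <= lmax_line``;
    ``min_si`` is a fraction in [0, 1].  Violations raise
    :class:`ParameterError` naming the violated inequality.
    """

    cut_value: float
    lmin: float
    lmax: float
    lmax_line: float
    min_si: float

    def __post_init__(self) -> None:
        if not self.cut_value >= 0:
            raise ParameterError("constraint violated: 0 <= cut value")
        if not self.cut_value <= self.lmin:
            raise ParameterError("constraint violated: cut value <= lmin")
        if not self.lmin <= self.lmax:
            raise ParameterError("constraint violated: lmin <= lmax")
        if not self.lmax <= self.lmax_line:
            raise ParameterError("constraint violated: lmax <= lmax.line")
        if not 0.0 <= self.min_si <= 1.0:
            raise ParameterError("constraint violated: 0 <= min-SI <= 1")


@dataclass(frozen=True)
class Track:
    """An MST over a vertex set, carrying the taxa it summarizes.

    Serves as both individual and generalized track.  ``edges`` are
    vertex-index pairs (i, j) with i < j; for n vertices a valid track has
    exactly n - 1 edges forming a spanning tree (0 edges for a single
    vertex).
    """

    vertices: Tuple[GeoPoint, ...]
    edges: Tuple[Tuple[int, int], ...]
    taxa: frozenset
    kind: str = "individual"  # or "generalized"

    # Tracks are immutable, so derived geometry is memoised on the instance
    # (object.__setattr__ sidesteps the frozen dataclass; fields are tuples).

    def segments(self) -> List[Segment]:
        return [Segment(self.vertices[i], self.vertices[j]) for i, j in self.edges]

    def edge_array(self) -> np.ndarray:
        """(E, 4) array of edge endpoint coordinates for the vectorised kernel."""
        arr = self.__dict__.get("_edge_array")
        if arr is None:
            arr = segments_as_array(self.segments())
            object.__setattr__(self, "_edge_array", arr)
        return arr

    def edge_lengths(self) -> np.ndarray:
        lens = self.__dict__.get("_edge_lengths")
        if lens is None:
            e = self.edge_array()
            lens = np.hypot(e[:, 2] - e[:, 0], e[:, 3] - e[:, 1])
            object.__setattr__(self, "_edge_lengths", lens)
        return lens

    @property
    def total_length(self) -> float:
        return float(self.edge_lengths().sum()) if self.edges else 0.0


def deduplicate_points(points: Sequence[GeoPoint], cut_value: float) -> List[GeoPoint]:
    """Collapse points within *cut_value* of each other to a single point.

    Greedy single pass in input order: a point is dropped iff it lies within
    ``cut_value`` of an already-retained point; retained points keep their
    original coordinates.  ``cut_value = 0`` removes exact duplicates only.
    Idempotent, and the retained count is non-increasing in ``cut_value``.
    """
    if cut_value < 0:
        raise ParameterError("constraint violated: 0 <= cut value")
    kept_x: List[float] = []
    kept_y: List[float] = []
    kept: List[GeoPoint] = []
    for p in points:
        if kept:
            dx = np.asarray(kept_x) - p.lon
            dy = np.asarray(kept_y) - p.lat
            if float(np.min(np.hypot(dx, dy))) <= cut_value:
                continue
        kept.append(p)
        kept_x.append(p.lon)
        kept_y.append(p.lat)
    return kept


def build_mst(points: Sequence[GeoPoint],
              taxa: Iterable[str] = (),
              kind: str = "individual") -> Track:
    """Minimum spanning tree over *points* under planar Euclidean distance.

    Kruskal with a fully deterministic tie-break: edges are processed in
    (weight, i, j) order, so among equal-weight edges the lexicographically
    smallest index pair wins.  Exact coordinate duplicates are merged first
    (zero-length edges are forbidden in tracks).  A single point yields a
    0-edge track.
    """
    if len(points) == 0:
        raise InputError("cannot build an MST over zero points")
    # merge exact duplicates, keeping first occurrence order
    seen = {}
    verts: List[GeoPoint] = []
    for p in points:
        key = (p.lon, p.lat)
        if key not in seen:
            seen[key] = len(verts)
            verts.append(p)
    n = len(verts)
    if n == 1:
        return Track(tuple(verts), (), frozenset(taxa), kind)

    xy = np.array([(p.lon, p.lat) for p in verts])
    diff = xy[:, None, :] - xy[None, :, :]
    dist = np.hypot(diff[..., 0], diff[..., 1])
    iu, ju = np.triu_indices(n, k=1)
    w = dist[iu, ju]
    order = np.lexsort((ju, iu, w))  # weight first, then (i, j)

    uf = UnionFind(range(n))
    edges: List[Tuple[int, int]] = []
    for k in order:
        i, j = int(iu[k]), int(ju[k])
        if uf[i] != uf[j]:
            uf.union(i, j)
            edges.append((i, j))
            if len(edges) == n - 1:
                break
    return Track(tuple(verts), tuple(edges), frozenset(taxa), kind)


def individual_track(recs: SpeciesRecordSet, params: CongruenceParams) -> Track:
    """Deduplicate a species' points by the cut value, then build its MST."""
    pts = deduplicate_points(recs.points, params.cut_value)
    return build_mst(pts, taxa={recs.taxon}, kind="individual")
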