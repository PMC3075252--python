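"""Segment-pair congruence rules and congruent-track merging.

Two MST segments are *congruent* when their endpoint projections overlap
and the inter-segment distances stay within the user's limits:

* **Rule 1** (partial or full overlap): ``0 <= dmin <= lmin`` and
  ``0 <= dmax <= lmax``.
* **Rule 2** (full overlap only): ``0 <= dmax.line <= lmax.line``.  Because
  ``lmax <= lmax.line``, rule 2 deliberately relaxes rule 1 for segment
  pairs that run alongside each other.

Segments with no perpendicular feet in either direction are never
congruent, however close they are.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Set, Tuple

import numpy as np

from .geometry import (
    TOL,
    OverlapPattern,
    Segment,
    SegmentPairGeometry,
    pairwise_segment_geometry,
    segment_pair_geometry,
)
from .tracks import CongruenceParams, Track, build_mst

__all__ = [
    "Rule",
    "CongruenceVerdict",
    "segments_congruent",
    "congruence_masks",
    "congruent_segment_map",
    "merge_tracks",
]


class Rule(Enum):
    RULE1 = "rule1"
    RULE2 = "rule2"
    NONE = "none"


@dataclass(frozen=True)
class CongruenceVerdict:
    congruent: bool
    rule: Rule
    geometry: SegmentPairGeometry


def segments_congruent(s1: Segment, s2: Segment,
                       params: CongruenceParams) -> CongruenceVerdict:
    """Decide congruence of two segments under the two decision rules.

    Rule 2 is checked first (it is the full-overlap specialisation with the
    looser bound); the verdict records the first rule that fires.  The
    congruent/not-congruent outcome is independent of that order.
    """
    g = segment_pair_geometry(s1, s2)
    if g.pattern == OverlapPattern.FULL_OVERLAP and g.dmax_line <= params.lmax_line + TOL:
        return CongruenceVerdict(True, Rule.RULE2, g)
    if (g.pattern != OverlapPattern.NONE
            and g.dmin <= params.lmin + TOL
            and g.dmax <= params.lmax + TOL):
        return CongruenceVerdict(True, Rule.RULE1, g)
    return CongruenceVerdict(False, Rule.NONE, g)


def congruence_masks(segs1: np.ndarray, segs2: np.ndarray,
                     params: CongruenceParams):
    """Vectorised all-pairs congruence between two edge arrays.

    Returns (congruent, rule1, rule2) boolean (n, m) masks; ``congruent``
    is their union.  Identical in outcome to :func:`segments_congruent`
    applied pairwise (both run on the same kernel).
    """
    dmin, dmax, pattern, dmax_line = pairwise_segment_geometry(segs1, segs2)
    full = pattern == int(OverlapPattern.FULL_OVERLAP)
    with np.errstate(invalid="ignore"):
        rule2 = full & (dmax_line <= params.lmax_line + TOL)
    rule1 = ((pattern != int(OverlapPattern.NONE))
             & (dmin <= params.lmin + TOL)
             & (dmax <= params.lmax + TOL))
    return rule1 | rule2, rule1, rule2


def congruent_segment_map(t1: Track, t2: Track,
                          params: CongruenceParams) -> Set[Tuple[int, int]]:
    """All congruent (edge-of-t1, edge-of-t2) index pairs.

    Every segment of one track is compared against every segment of the
    other; the result for (t1, t2) is the transpose of the result for
    (t2, t1).  Tracks without edges (single-vertex tracks) are never
    congruent with anything.
    """
    if not t1.edges or not t2.edges:
        return set()
    mask, _, _ = congruence_masks(t1.edge_array(), t2.edge_array(), params)
    ii, jj = np.nonzero(mask)
    return {(int(i), int(j)) for i, j in zip(ii, jj)}


def merge_tracks(t1: Track, t2: Track,
                 pairs: Set[Tuple[int, int]]) -> Track:
    """Connect the points of congruent segments through a new MST.

    Collects the endpoint vertices of every congruent segment from both
    tracks (only those — not the tracks' full vertex sets), deduplicates
    exact coordinate duplicates, and spans them with a new MST.  The result
    is a generalized track carrying the union of both taxa sets.
    """
    if not pairs:
        raise ValueError("merge_tracks requires a non-empty congruent-pair set")
    points = []
    for i in sorted({i for i, _ in pairs}):
        a, b = t1.edges[i]
        points.extend((t1.vertices[a], t1.vertices[b]))
    for j in sorted({j for _, j in pairs}):
        a, b = t2.edges[j]
        points.extend((t2.vertices[a], t2.vertices[b]))
    return build_mst(points, taxa=t1.taxa | t2.taxa, kind="generalized")
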