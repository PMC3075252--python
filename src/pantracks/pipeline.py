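"""Full track analysis: individual tracks, merging, and SI reduction.

The pipeline builds one MST per species, merges every spatially congruent
pair of tracks into a candidate generalized track, and then reduces the
candidate set with the asymmetric similarity index (SI):

    SI(a -> b) = length of a's segments congruent with b / total length of a

The index is asymmetric because it is normalised by each track's own
length (a short track embedded in a long one scores 1 toward it, while the
long track scores low toward the short one).  Candidate pairs whose larger
directional SI reaches the ``min_si`` threshold are joined into one MST;
this repeats to a fixed point, so no two surviving generalized tracks are
redundant at the chosen threshold.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

from .congruence import congruence_masks, congruent_segment_map, merge_tracks
from .tracks import (
    CongruenceParams,
    SpeciesRecordSet,
    Track,
    build_mst,
    individual_track,
)

__all__ = ["SimilarityResult", "AnalysisResult", "similarity_index", "run_analysis"]

logger = logging.getLogger("pantracks")


@dataclass(frozen=True)
class SimilarityResult:
    """Directional similarity indices between two tracks."""

    si_ab: float
    si_ba: float

    @property
    def si_max(self) -> float:
        return max(self.si_ab, self.si_ba)


@dataclass
class AnalysisResult:
    individual_tracks: List[Track]
    generalized_tracks: List[Track]
    params: CongruenceParams
    log: List[dict] = field(default_factory=list)


def similarity_index(t1: Track, t2: Track,
                     params: CongruenceParams) -> SimilarityResult:
    """Asymmetric similarity index between two tracks.

    A whole edge's length counts toward the numerator if the edge is
    congruent with at least one edge of the other track (no partial-length
    proration).  A zero-total-length track (single vertex or fully
    collapsed) has SI 0 toward the other.
    """
    len1 = t1.total_length
    len2 = t2.total_length
    if len1 <= 0 or len2 <= 0 or not t1.edges or not t2.edges:
        return SimilarityResult(0.0, 0.0)
    mask, _, _ = congruence_masks(t1.edge_array(), t2.edge_array(), params)
    si_ab = float(t1.edge_lengths()[mask.any(axis=1)].sum() / len1)
    si_ba = float(t2.edge_lengths()[mask.any(axis=0)].sum() / len2)
    return SimilarityResult(si_ab, si_ba)


def _taxa_key(t: Track) -> Tuple[str, ...]:
    return tuple(sorted(t.taxa))


def _pair_key(ta: Track, tb: Track):
    return tuple(sorted((_taxa_key(ta), _taxa_key(tb))))


def run_analysis(dataset: Sequence[SpeciesRecordSet],
                 params: CongruenceParams) -> AnalysisResult:
    """Run the complete congruence analysis on a multi-species dataset.

    1. Build an individual track (cut-value dedup + MST) for every species,
       in input order.
    2. For every unordered species pair, collect the congruent segment
       pairs; each non-empty comparison yields a candidate generalized
       track (MST over the congruent segments' endpoints).
    3. Reduce: repeatedly join the candidate pair with the highest
       ``si_max`` (ties broken by lexicographic taxa) while
       ``si_max >= min_si``, replacing the pair with the MST over the
       union of their vertices; iterate to a fixed point.
    4. Discard any surviving candidate whose taxa are a proper subset of
       another's and whose SI toward it still reaches ``min_si``.

    Deterministic for a given input order.
    """
    if len(dataset) == 0:
        raise ValueError("dataset must contain at least one species")
    log: List[dict] = []

    individual = [individual_track(r, params) for r in dataset]

    # --- candidate generation: all unordered species pairs, input order ---
    candidates: Dict[int, Track] = {}
    next_id = itertools.count()
    for i, j in itertools.combinations(range(len(individual)), 2):
        t1, t2 = individual[i], individual[j]
        pairs = congruent_segment_map(t1, t2, params)
        if not pairs:
            continue
        cand = merge_tracks(t1, t2, pairs)
        candidates[next(next_id)] = cand
        event = {"event": "candidate", "taxa": sorted(cand.taxa),
                 "n_congruent_pairs": len(pairs)}
        log.append(event)
        logger.info("candidate track %s (%d congruent segment pairs)",
                    "+".join(sorted(cand.taxa)), len(pairs))

    # --- fixed-point SI reduction ---
    si_cache: Dict[Tuple[int, int], SimilarityResult] = {}
    while len(candidates) > 1:
        ids = sorted(candidates)
        best = None
        for a, b in itertools.combinations(ids, 2):
            sim = si_cache.get((a, b))
            if sim is None:
                sim = similarity_index(candidates[a], candidates[b], params)
                si_cache[(a, b)] = sim
            # a merge needs positive similarity besides clearing the
            # threshold: min_si = 0 must not join fully disjoint tracks
            if sim.si_max >= params.min_si and sim.si_max > 0:
                key = (-sim.si_max, _pair_key(candidates[a], candidates[b]))
                if best is None or key < best[0]:
                    best = (key, a, b, sim)
        if best is None:
            break
        _, a, b, sim = best
        ta, tb = candidates.pop(a), candidates.pop(b)
        merged = build_mst(list(ta.vertices) + list(tb.vertices),
                           taxa=ta.taxa | tb.taxa, kind="generalized")
        si_cache = {k: v for k, v in si_cache.items()
                    if a not in k and b not in k}
        candidates[next(next_id)] = merged
        log.append({"event": "reduce", "taxa_a": sorted(ta.taxa),
                    "taxa_b": sorted(tb.taxa),
                    "si_ab": sim.si_ab, "si_ba": sim.si_ba})
        logger.info("reduced %s + %s (SI %.3f / %.3f)",
                    "+".join(sorted(ta.taxa)), "+".join(sorted(tb.taxa)),
                    sim.si_ab, sim.si_ba)

    # --- subset-taxa cleanup (vacuous at the fixed point, kept as a guard) ---
    ids = sorted(candidates)
    surviving: List[Track] = []
    for a in ids:
        ta = candidates[a]
        absorbed = False
        for b in ids:
            if a == b:
                continue
            tb = candidates[b]
            if ta.taxa < tb.taxa:
                sim = similarity_index(ta, tb, params)
                if sim.si_ab >= params.min_si:
                    absorbed = True
                    log.append({"event": "discard_subset",
                                "taxa": sorted(ta.taxa),
                                "into": sorted(tb.taxa), "si": sim.si_ab})
                    break
        if not absorbed:
            surviving.append(ta)

    return AnalysisResult(individual_tracks=individual,
                          generalized_tracks=surviving,
                          params=params, log=log)
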