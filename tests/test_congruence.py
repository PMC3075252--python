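import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pantracks as pt
from conftest import chain_track, gp, seg
from _oracles import enumerate_spanning_tree_lengths

coord = st.floats(-50, 50, allow_nan=False, allow_infinity=False)


# ---------------------------------------------------------------------------
# Hand-derived truth table under the reference parameters
# (cut 2, lmin 2.5, lmax 3, lmax.line 4).  Patterns cover no-overlap,
# partial and full-overlap configurations, and both decision rules.
# ---------------------------------------------------------------------------
TRUTH_TABLE = [
    # (s1, s2, congruent, rule, pattern)
    # identical segments: everything zero, full overlap
    ((0, 0, 4, 0), (0, 0, 4, 0), True, pt.Rule.RULE2, "FULL_OVERLAP"),
    # parallel at offset 1: congruent by rule 2 (rule 1 would also hold)
    ((0, 0, 4, 0), (0, 1, 4, 1), True, pt.Rule.RULE2, "FULL_OVERLAP"),
    # parallel at offset 3.5: rule 2 passes (3.5 <= 4) where rule 1 fails
    # (dmin = 3.5 > lmin = 2.5) -- the full-overlap relaxation
    ((0, 0, 4, 0), (0, 3.5, 4, 3.5), True, pt.Rule.RULE2, "FULL_OVERLAP"),
    # parallel at offset 5: full overlap but beyond every limit
    ((0, 0, 4, 0), (0, 5, 4, 5), False, pt.Rule.NONE, "FULL_OVERLAP"),
    # collinear disjoint: no feet, never congruent
    ((0, 0, 1, 0), (5, 0, 6, 0), False, pt.Rule.NONE, "NONE"),
    # staggered parallel, far end too far: dmax ~ 4.12 > lmax = 3
    ((0, 0, 4, 0), (3, 1, 8, 1), False, pt.Rule.NONE, "PARTIAL"),
    # staggered parallel, close: rule 1 (dmin 0.5, dmax ~ 1.118)
    ((2, 0, 4, 0), (3, 0.5, 5, 0.5), True, pt.Rule.RULE1, "PARTIAL"),
    # perpendicular crossing: full overlap via the short side, dmax_line 1
    ((0, 0, 4, 0), (2, -1, 2, 1), True, pt.Rule.RULE2, "FULL_OVERLAP"),
    # L-shape sharing an endpoint: boundary feet count, dmax_line 3
    ((0, 0, 4, 0), (4, 0, 4, 3), True, pt.Rule.RULE2, "FULL_OVERLAP"),
    # parallel at offset 100: geometry fine, distances hopeless
    ((0, 0, 4, 0), (0, 100, 4, 100), False, pt.Rule.NONE, "FULL_OVERLAP"),
    # degenerate second segment sitting on s1: point can satisfy rule 1
    # (dmin 0, dmax 2) but can never produce full overlap
    ((0, 0, 4, 0), (2, 0, 2, 0), True, pt.Rule.RULE1, "PARTIAL"),
    # nearby but all four projections miss both segments
    ((0, 0, 1, 0), (2, 1, 3, 2), False, pt.Rule.NONE, "NONE"),
    # T-shape: both bar endpoints project onto the stem's base vertex
    # (boundary feet count), so this is full overlap; dmax_line = 2
    ((0, 0, 4, 0), (2, 0, 2, 2), True, pt.Rule.RULE2, "FULL_OVERLAP"),
]


@pytest.mark.parametrize("s1, s2, congruent, rule, pattern", TRUTH_TABLE)
def test_congruence_truth_table(s1, s2, congruent, rule, pattern, fig7_params):
    v = pt.segments_congruent(seg(*s1), seg(*s2), fig7_params)
    assert v.congruent is congruent
    assert v.rule == rule
    assert v.geometry.pattern == pt.OverlapPattern[pattern]
    # symmetric in the segment order
    w = pt.segments_congruent(seg(*s2), seg(*s1), fig7_params)
    assert w.congruent is congruent


def test_rule2_fires_before_rule1_on_full_overlap(fig7_params):
    v = pt.segments_congruent(seg(0, 0, 4, 0), seg(0, 1, 4, 1), fig7_params)
    assert v.rule == pt.Rule.RULE2
    assert v.geometry.dmax_line == pytest.approx(1.0)


def test_zero_params_only_coincident_segments():
    params = pt.CongruenceParams(0, 0, 0, 0, 0)
    assert pt.segments_congruent(seg(0, 0, 4, 0), seg(0, 0, 4, 0), params).congruent
    assert not pt.segments_congruent(seg(0, 0, 4, 0), seg(0, 0.01, 4, 0.01),
                                     params).congruent


@settings(max_examples=300, derandomize=True, deadline=None)
@given(coord, coord, coord, coord, coord, coord, coord, coord,
       st.floats(0, 10), st.floats(0, 10), st.floats(0, 10))
def test_verdict_symmetric(ax, ay, bx, by, cx, cy, dx, dy, p1, p2, p3):
    lmin, lmax, lmax_line = sorted((p1, p2, p3))
    params = pt.CongruenceParams(0, lmin, lmax, lmax_line, 0.5)
    s1, s2 = seg(ax, ay, bx, by), seg(cx, cy, dx, dy)
    v12 = pt.segments_congruent(s1, s2, params)
    v21 = pt.segments_congruent(s2, s1, params)
    assert v12.congruent == v21.congruent
    assert v12.rule == v21.rule


@settings(max_examples=300, derandomize=True, deadline=None)
@given(coord, coord, coord, coord, coord, coord, coord, coord,
       st.floats(0, 5), st.floats(0, 5), st.floats(0, 5),
       st.floats(0, 3), st.floats(0, 3), st.floats(0, 3))
def test_congruence_monotone_in_limits(ax, ay, bx, by, cx, cy, dx, dy,
                                       p1, p2, p3, e1, e2, e3):
    """Jointly enlarging (lmin, lmax, lmax.line) never loses congruence."""
    lmin, lmax, lmax_line = sorted((p1, p2, p3))
    d1, d2, d3 = sorted((e1, e2, e3))
    small = pt.CongruenceParams(0, lmin, lmax, lmax_line, 0.5)
    big = pt.CongruenceParams(0, lmin + d1, lmax + d2, lmax_line + d3, 0.5)
    s1, s2 = seg(ax, ay, bx, by), seg(cx, cy, dx, dy)
    if pt.segments_congruent(s1, s2, small).congruent:
        assert pt.segments_congruent(s1, s2, big).congruent


# --- congruent_segment_map ---------------------------------------------------

def test_map_track_with_itself(fig7_params):
    t = chain_track([(0, 0), (5, 0), (10, 0), (10, 5)])
    pairs = pt.congruent_segment_map(t, t, fig7_params)
    assert {(i, i) for i in range(len(t.edges))} <= pairs


def test_map_disjoint_regions_empty(fig7_params):
    t1 = chain_track([(0, 0), (1, 0)])
    t2 = chain_track([(500, 500), (501, 500)])
    assert pt.congruent_segment_map(t1, t2, fig7_params) == set()


def test_map_is_transpose_symmetric_and_bounded(fig7_params):
    t1 = chain_track([(0, 0), (3, 0), (6, 0), (9, 0)])   # 3 edges
    t2 = chain_track([(0, 1), (4, 1), (8, 1)])           # 2 edges
    p12 = pt.congruent_segment_map(t1, t2, fig7_params)
    p21 = pt.congruent_segment_map(t2, t1, fig7_params)
    assert len(p12) <= 6
    assert p21 == {(j, i) for i, j in p12}


def test_map_single_vertex_track_never_congruent(fig7_params):
    t1 = pt.Track((gp(0, 0),), (), frozenset({"a"}), "individual")
    t2 = chain_track([(0, 0), (1, 0)])
    assert pt.congruent_segment_map(t1, t2, fig7_params) == set()


# --- merge_tracks ------------------------------------------------------------

def test_merge_identical_one_edge_tracks(fig7_params):
    t1 = chain_track([(0, 0), (4, 0)], taxa=("a",))
    t2 = chain_track([(0, 0), (4, 0)], taxa=("b",))
    pairs = pt.congruent_segment_map(t1, t2, fig7_params)
    m = pt.merge_tracks(t1, t2, pairs)
    assert m.kind == "generalized"
    assert m.taxa == frozenset({"a", "b"})
    assert len(m.vertices) == 2
    assert m.total_length == pytest.approx(4.0)


def test_merge_parallel_tracks_is_minimum_over_all_k4_trees(fig7_params):
    """MST over the 4 merged points beats all 16 labelled spanning trees."""
    t1 = chain_track([(0, 0), (4, 0)], taxa=("a",))
    t2 = chain_track([(0, 1), (4, 1)], taxa=("b",))
    pairs = pt.congruent_segment_map(t1, t2, fig7_params)
    m = pt.merge_tracks(t1, t2, pairs)
    xy = np.array([(v.lon, v.lat) for v in m.vertices])
    lengths = enumerate_spanning_tree_lengths(xy)
    assert len(lengths) == 16
    assert m.total_length == pytest.approx(min(lengths), abs=1e-12)
    assert m.total_length == pytest.approx(6.0)


def test_merge_collects_only_congruent_segment_endpoints():
    """Vertices of non-congruent edges must not leak into the merged track."""
    params = pt.CongruenceParams(0, 0.3, 0.5, 0.5, 0.5)
    t1 = chain_track([(0, 0), (1, 0), (2, 0), (3, 0)], taxa=("a",))
    t2 = chain_track([(0, 0.1), (1, 0.1), (6, 6), (12, 12)], taxa=("b",))
    pairs = pt.congruent_segment_map(t1, t2, params)
    assert pairs == {(0, 0)}
    m = pt.merge_tracks(t1, t2, pairs)
    assert set(m.vertices) == {gp(0, 0), gp(1, 0), gp(0, 0.1), gp(1, 0.1)}


def test_merge_empty_pair_set_is_a_contract_violation():
    t = chain_track([(0, 0), (1, 0)])
    with pytest.raises(ValueError):
        pt.merge_tracks(t, t, set())


def test_merge_output_is_valid_track(fig7_params, rng):
    import networkx as nx

    base = rng.uniform(0, 8, (6, 2))
    t1 = pt.build_mst([gp(x, y) for x, y in base], taxa={"a"})
    t2 = pt.build_mst([gp(x + 0.5, y + 0.5) for x, y in base], taxa={"b"})
    pairs = pt.congruent_segment_map(t1, t2, fig7_params)
    m = pt.merge_tracks(t1, t2, pairs)
    g = nx.Graph(list(m.edges))
    g.add_nodes_from(range(len(m.vertices)))
    assert len(m.edges) == len(m.vertices) - 1
    assert nx.is_connected(g)
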