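import numpy as np
import pytest

import pantracks as pt


def gp(x, y):
    """Shorthand GeoPoint constructor: gp(lon, lat)."""
    return pt.GeoPoint(float(x), float(y))


def seg(ax, ay, bx, by):
    return pt.Segment(gp(ax, ay), gp(bx, by))


def chain_track(coords, taxa=("t",), kind="individual"):
    """A path-shaped track through consecutive coordinate pairs."""
    verts = tuple(gp(x, y) for x, y in coords)
    edges = tuple((i, i + 1) for i in range(len(verts) - 1))
    return pt.Track(verts, edges, frozenset(taxa), kind)


@pytest.fixture
def fig7_params():
    """The reference parameter set: cut 2, lmin 2.5, lmax 3, lmax.line 4."""
    return pt.CongruenceParams(cut_value=2, lmin=2.5, lmax=3, lmax_line=4,
                               min_si=0.8)


@pytest.fixture(scope="session")
def corridor_world():
    """The three-corridor benchmark world, seed fixed a priori."""
    return pt.three_corridor_world(seed=0)


@pytest.fixture(scope="session")
def corridor_dataset(corridor_world):
    return pt.generate_dataset(corridor_world, min_separation=40.0)


@pytest.fixture(scope="session")
def corridor_result(corridor_dataset):
    """Full pipeline run on the benchmark world (expensive; run once)."""
    return pt.run_analysis(corridor_dataset, pt.THREE_CORRIDOR_PARAMS)


@pytest.fixture
def rng():
    return np.random.default_rng(20260918)
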