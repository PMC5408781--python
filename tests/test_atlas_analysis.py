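"""Tests of atlas construction, module algebra and decomposition."""

import numpy as np
import pytest

from latcirc.atlas_analysis import (ComplexityAtlas, Conflict, build_atlas,
                                    classify_bifunctional, compatible_union,
                                    contains_module, enumerate_hybrid_candidates,
                                    minimal_topologies, one_link_extensions,
                                    robustness_score, stalactites)
from latcirc.circuit_model import LINK_KEYS, ParameterSet, Topology
from latcirc.screen_pipeline import (BifunctionalHit, ScreenConfig,
                                     TopologyResult)

T0 = Topology(((0, 0), (0, 0)), (1, 0))               # one link
T1 = Topology(((1, 0), (0, 0)), (1, 0))               # T0 + intra DD+
T1_FLIP = Topology(((-1, 0), (0, 0)), (1, 0))         # sign flip of the new link
T2 = Topology(((1, 0), (0, 1)), (1, 0))               # T1 + intra AA+


def _result(topology, ind=1, inh=0):
    return TopologyResult(topology=topology, n_samples=10,
                          n_induction=ind, n_inhibition=inh, hits=[])


# ---------------------------------------------------------------------------
# Atlas structure
# ---------------------------------------------------------------------------

def test_atlas_edges_single_link_only():
    atlas = build_atlas([_result(T0), _result(T1), _result(T1_FLIP), _result(T2)])
    g = atlas.graph
    assert g.has_edge(T0.encode(), T1.encode())
    assert g.has_edge(T0.encode(), T1_FLIP.encode())
    assert g.has_edge(T1.encode(), T2.encode())
    assert not g.has_edge(T1.encode(), T1_FLIP.encode())   # sign flip: distance 2
    assert not g.has_edge(T0.encode(), T2.encode())        # two links apart
    for u, v in g.edges:
        assert abs(atlas.layer(u) - atlas.layer(v)) == 1


def test_atlas_layers_equal_link_count():
    atlas = build_atlas([_result(T0), _result(T1)])
    assert atlas.layer(T0.encode()) == 1
    assert atlas.layer(T1.encode()) == 2


def test_atlas_excludes_unsuccessful_topologies():
    atlas = build_atlas([_result(T0), _result(T1, ind=0, inh=0)])
    assert T1.encode() not in atlas.graph


def test_stalactites_and_minimal_members():
    atlas = build_atlas([_result(t) for t in (T0, T1, T2)])
    stals = stalactites(atlas, "induction")
    assert len(stals) == 1
    assert stals[0]["minimal"] == [T0.encode()]
    assert stals[0]["bottom_layer"] == 1


def test_minimal_topologies_exclude_supersets():
    results = [_result(t) for t in (T0, T1, T2)]
    mins = minimal_topologies(results, "induction")
    assert [t.encode() for t in mins] == [T0.encode()]


def test_atlas_insertion_order_invariance():
    results = [_result(t) for t in (T0, T1, T2)]
    a1 = build_atlas(results)
    a2 = build_atlas(results[::-1])
    assert {frozenset(e) for e in a1.graph.edges} == \
        {frozenset(e) for e in a2.graph.edges}
    assert dict(a1.graph.nodes(data="layer")) == dict(a2.graph.nodes(data="layer"))


# ---------------------------------------------------------------------------
# Module algebra
# ---------------------------------------------------------------------------

def test_contains_module_basics():
    empty = Topology(((0, 0), (0, 0)), (0, 0))
    assert contains_module(T2, T1)
    assert contains_module(T2, T0)
    assert not contains_module(T1, T2)           # superset cannot be contained
    assert not contains_module(T2, T1_FLIP)      # sign must match
    assert contains_module(T2, empty)            # anything contains empty
    assert contains_module(T1, T1)               # reflexive


def test_contains_module_is_transitive():
    assert contains_module(T1, T0) and contains_module(T2, T1)
    assert contains_module(T2, T0)


def test_contains_module_aligns_signaling_roles():
    assert contains_module(T2.mirror(), T0)
    assert contains_module(T2, T0.mirror())


def test_compatible_union_merges_and_conflicts():
    u = compatible_union(T0, T1)
    assert isinstance(u, Topology) and u == T1
    c = compatible_union(T1, T1_FLIP)
    assert isinstance(c, Conflict)
    assert not c
    assert c.keys == (("intra", 0, 0),)


def test_compatible_union_commutative_idempotent():
    a = Topology(((0, 1), (0, 0)), (0, 1))
    b = Topology(((0, 1), (-1, 0)), (0, 0))
    assert compatible_union(a, b) == compatible_union(b, a)
    assert compatible_union(a, a) == a


def test_union_link_set_is_union_of_parts():
    a = Topology(((0, 1), (0, 0)), (0, 1))
    b = Topology(((0, 1), (-1, 0)), (0, 0))
    u = compatible_union(a, b)
    assert set(u.links) == set(a.links) | set(b.links)


def test_one_link_extensions_cover_all_absent_links():
    exts = one_link_extensions(T0)
    assert len(exts) == 2 * (6 - T0.n_links)
    assert all(e.n_links == T0.n_links + 1 for e in exts)


# ---------------------------------------------------------------------------
# Hybrid candidates and classification mechanics
# ---------------------------------------------------------------------------

def test_enumerate_hybrid_candidates_mechanics():
    lib = {"D0": Topology(((0, 0), (0, 0)), (1, 0)),
           "D1": Topology(((0, 1), (0, 0)), (0, 1)),
           "H0": Topology(((0, 0), (0, 0)), (-1, 0)),
           "H1": Topology(((0, -1), (0, 0)), (0, 1))}
    out = enumerate_hybrid_candidates(lib)
    assert out["n_pairs"] == 4
    # D0 u H0 conflicts (inter D opposite); D1 u H1 conflicts (intra DA)
    conflict_pairs = {tuple(c["pair"]) for c in out["conflicts"]}
    assert ("D0", "H0") in conflict_pairs and ("D1", "H1") in conflict_pairs
    for label, cand in out["candidates"].items():
        topo = cand["topology"]
        for dn, hn in cand["pairs"]:
            assert contains_module(topo, lib[dn])
            assert contains_module(topo, lib[hn])
            assert set(topo.links) == set(lib[dn].links) | set(lib[hn].links)


def test_classify_bifunctional_partition():
    lib = {"D0": Topology(((0, 0), (0, 0)), (1, 0)),
           "H0": Topology(((0, 0), (0, 0)), (-1, 0)),
           "H1": Topology(((0, -1), (0, 0)), (0, 1))}
    hybrid = Topology(((0, -1), (0, 0)), (1, 1))       # contains D0 and H1
    emergent = Topology(((0, -1), (1, 0)), (0, 1))     # contains H1, no D module
    rh = classify_bifunctional(hybrid, lib)
    re_ = classify_bifunctional(emergent, lib)
    assert rh.klass == "hybrid" and rh.missing_function is None
    assert re_.klass == "emergent" and re_.missing_function == "induction"
    assert rh.induction_modules and rh.inhibition_modules


# ---------------------------------------------------------------------------
# Robustness score
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def inhibition_hit():
    """A seed-robust activate-inhibitor circuit posed as a pseudo-hit.

    The context gene's activation threshold is far above the context
    amplitude, so the function map is inhibition in both tissues.
    """
    topo = Topology(((0, -1), (0, 0)), (0, 1))
    params = ParameterSet(((0, -4.09), (0, 0)), (0, 7.72), (3.16, 52.14), 10.0)
    return BifunctionalHit(topology_id=topo.encode(), params=params,
                           trigger_gene=0, context_gene=1,
                           function_map={0.0: "inhibition", 1.0: "inhibition"},
                           sample_index=0)


def test_robustness_score_bounds_and_delta_zero(inhibition_hit):
    sc = ScreenConfig()
    s0 = robustness_score(inhibition_hit, delta=0.0, n=3, seed=1, screen=sc)
    assert s0 == 1.0
    s1 = robustness_score(inhibition_hit, delta=0.1, n=6, seed=1, screen=sc)
    assert 0.0 <= s1 <= 1.0
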