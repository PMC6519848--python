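"""Traversing paths, path statistics, direct links and feedback loops."""

import numpy as np
import pytest

from regmet.graph import AnnotatedGraph, EdgeRecord, VertexRecord
from regmet.graph import largest_strongly_connected_component
from regmet.partition import Partition, affiliate_functional
from regmet.paths import (
    PathExplosionError,
    TraversingPath,
    count_direct_links,
    enumerate_traversing_paths,
    find_feedback_loops,
    iter_traversing_paths,
    path_statistics,
    scc_containment,
)
from conftest import random_digraph, traversing_paths_oracle


def random_partitioned_graph(n: int, p: float, seed: int):
    """Random digraph with random MD/PI/RD labels."""
    g = random_digraph(n, p, seed)
    rng = np.random.default_rng(seed + 999)
    labels = {v: ("MD", "PI", "RD")[int(rng.integers(3))] for v in g.nx.nodes}
    return g, Partition("functional", 3, labels)


class TestEnumeration:
    def test_toy8_downwards(self, toy):
        part = affiliate_functional(toy.graph, 3)
        got = enumerate_traversing_paths(toy.graph, part, "downwards")
        assert [p.vertices for p in got] == [("g1", "p1", "r1")]
        assert got[0].length == 2

    def test_toy8_upwards(self, toy):
        part = affiliate_functional(toy.graph, 3)
        got = enumerate_traversing_paths(toy.graph, part, "upwards")
        assert [p.vertices for p in got] == [("c2", "pc1", "g1"), ("c2", "pc1", "g2")]

    def test_no_boundary_edges_no_paths(self):
        g = AnnotatedGraph()
        for v, vt in [("g", "gene"), ("p", "protein-monomer"), ("c", "compound")]:
            g.add_vertex(VertexRecord(v, vt, compartment=None if vt == "gene" else "c"))
        part = Partition("functional", 3, {"g": "RD", "p": "PI", "c": "MD"})
        assert enumerate_traversing_paths(g, part, "downwards") == []

    def test_two_domain_partition_rejected(self, toy):
        part = affiliate_functional(toy.graph, 2)
        with pytest.raises(ValueError, match="three-domain"):
            enumerate_traversing_paths(toy.graph, part, "downwards")

    def test_direct_edges_are_not_traversing_paths(self):
        # an RD -> MD edge is a direct link; minimum traversing length is 2
        g = AnnotatedGraph()
        g.add_vertex(VertexRecord("g", "gene"))
        g.add_vertex(VertexRecord("c", "compound", compartment="c"))
        g.add_edge(EdgeRecord("g", "c", "regulation", regulation_mode=1))
        part = Partition("functional", 3, {"g": "RD", "c": "MD"})
        part.labels["x"] = "PI"
        g.add_vertex(VertexRecord("x", "protein-monomer", compartment="c"))
        assert enumerate_traversing_paths(g, part, "downwards") == []
        assert count_direct_links(g, part, "RD", "MD") == 1

    def test_streaming_iterator_is_lazy_and_lexicographic(self, toy):
        part = affiliate_functional(toy.graph, 3)
        it = iter_traversing_paths(toy.graph, part, "upwards")
        first = next(it)
        assert first.vertices == ("c2", "pc1", "g1")
        rest = list(it)
        assert [p.vertices for p in rest] == [("c2", "pc1", "g2")]

    def test_path_cap_raises(self, toy):
        part = affiliate_functional(toy.graph, 3)
        with pytest.raises(PathExplosionError):
            enumerate_traversing_paths(toy.graph, part, "upwards", max_paths=1)

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_simple_path_oracle(self, seed):
        g, part = random_partitioned_graph(12, 0.18, seed)
        for direction in ("downwards", "upwards"):
            got = {p.vertices for p in
                   enumerate_traversing_paths(g, part, direction)}
            assert got == traversing_paths_oracle(g, part.labels, direction)

    @pytest.mark.parametrize("seed", range(10))
    def test_reversal_symmetry(self, seed):
        """Reversing every edge maps downwards paths bijectively onto the
        reversed graph's upwards paths (RD -> MD becomes MD -> RD)."""
        g, part = random_partitioned_graph(10, 0.2, seed)
        rev = AnnotatedGraph()
        for vid in g.vertex_ids():
            rev.add_vertex(g.vertex(vid))
        for e in g.edge_records():
            e.source, e.target = e.target, e.source
            rev.add_edge(e)
        down = {p.vertices for p in enumerate_traversing_paths(g, part, "downwards")}
        up_rev = {tuple(reversed(p.vertices)) for p in
                  enumerate_traversing_paths(rev, part, "upwards")}
        assert down == up_rev

    @pytest.mark.parametrize("seed", range(10))
    def test_emitted_paths_satisfy_type_invariants(self, seed):
        g, part = random_partitioned_graph(11, 0.2, seed)
        for direction, (src, dst) in [("downwards", ("RD", "MD")),
                                      ("upwards", ("MD", "RD"))]:
            for p in enumerate_traversing_paths(g, part, direction):
                assert part.labels[p.start] == src
                assert part.labels[p.end] == dst
                assert all(part.labels[v] == "PI" for v in p.interior)
                assert len(set(p.interior)) == len(p.interior)
                assert len(p.interior) >= 1
                for a, b in zip(p.vertices, p.vertices[1:]):
                    assert g.nx.has_edge(a, b)


class TestDirectLinks:
    def test_toy8_no_direct_downwards(self, toy):
        part = affiliate_functional(toy.graph, 3)
        assert count_direct_links(toy.graph, part, "RD", "MD") == 0

    def test_same_domain_counts_internal_edges(self, toy):
        part = affiliate_functional(toy.graph, 3)
        # r1->c2 and c1->r1 are the two MD-internal directed edges
        assert count_direct_links(toy.graph, part, "MD", "MD") == 2


class TestPathStatistics:
    def test_toy8_upwards_participation(self, toy):
        part = affiliate_functional(toy.graph, 3)
        stats = path_statistics(enumerate_traversing_paths(toy.graph, part, "upwards"))
        assert stats.vertex_participation["pc1"] == 1.0
        assert stats.distinct_interior_vertices == 1
        assert stats.length_histogram == {2: 2}

    def test_toy8_downwards_distinct_interior(self, toy):
        part = affiliate_functional(toy.graph, 3)
        stats = path_statistics(enumerate_traversing_paths(toy.graph, part, "downwards"))
        assert stats.distinct_interior_vertices == 1

    def test_single_path_histogram(self):
        p = TraversingPath("downwards", ("a", "b", "c", "d", "e"))
        stats = path_statistics([p])
        assert stats.length_histogram == {4: 1}
        assert stats.pair_participation[("b", "c")] == 1.0
        assert stats.triple_participation[("b", "c", "d")] == 1.0

    def test_empty_pool_all_zero(self):
        stats = path_statistics([])
        assert stats.n_paths == 0
        assert stats.length_histogram == {}
        assert stats.vertex_participation == {}
        assert stats.distinct_interior_vertices == 0

    def test_histogram_sums_to_path_count(self, toy):
        part = affiliate_functional(toy.graph, 3)
        ps = enumerate_traversing_paths(toy.graph, part, "upwards")
        stats = path_statistics(ps)
        assert sum(stats.length_histogram.values()) == stats.n_paths


class TestSccContainment:
    def test_universal_set(self, toy):
        part = affiliate_functional(toy.graph, 3)
        ps = enumerate_traversing_paths(toy.graph, part, "upwards")
        assert scc_containment(ps, set(toy.graph.nx.nodes)) == 1.0

    def test_empty_set(self, toy):
        part = affiliate_functional(toy.graph, 3)
        ps = enumerate_traversing_paths(toy.graph, part, "upwards")
        assert scc_containment(ps, set()) == 0.0

    def test_toy8_against_membership_check(self, toy):
        part = affiliate_functional(toy.graph, 3)
        scc = largest_strongly_connected_component(toy.graph)
        for direction in ("downwards", "upwards"):
            ps = enumerate_traversing_paths(toy.graph, part, direction)
            expect = sum(all(v in scc for v in p.vertices) for p in ps) / len(ps)
            assert scc_containment(ps, scc) == expect


class TestFeedbackLoops:
    def test_toy8_single_loop_under_edge_closure(self, toy):
        part = affiliate_functional(toy.graph, 3)
        up = enumerate_traversing_paths(toy.graph, part, "upwards")
        down = enumerate_traversing_paths(toy.graph, part, "downwards")
        loops = find_feedback_loops(toy.graph, part, up, down,
                                    rd_closure=0, md_closure=1)
        assert len(loops) == 1
        lp = loops[0]
        assert lp.down.vertices == ("g1", "p1", "r1")
        assert lp.up.vertices == ("c2", "pc1", "g1")
        assert lp.md_closure == ("r1", "c2")
        assert lp.rd_closure == ("g1",)

    def test_no_md_edge_no_loop(self, toy):
        g = toy.graph.copy()
        g.nx.remove_edge("r1", "c2", key="product")
        g.add_edge(EdgeRecord("r1", "c1", "product"))
        part = Partition("functional", 3, dict(affiliate_functional(toy.graph, 3).labels))
        up = enumerate_traversing_paths(g, part, "upwards")
        down = enumerate_traversing_paths(g, part, "downwards")
        assert find_feedback_loops(g, part, up, down, md_closure=1) == []

    def test_zero_length_rd_closure_equals_identity(self, toy):
        part = affiliate_functional(toy.graph, 3)
        up = enumerate_traversing_paths(toy.graph, part, "upwards")
        down = enumerate_traversing_paths(toy.graph, part, "downwards")
        a = find_feedback_loops(toy.graph, part, up, down, rd_closure=0)
        b = find_feedback_loops(toy.graph, part, up, down, rd_closure=0, md_closure=1)
        assert [(l.up, l.down) for l in a] == [(l.up, l.down) for l in b]

    def test_longer_md_closure_finds_two_step_paths(self, toy):
        # replace the direct r1->c2 product edge by a two-step MD detour
        g = toy.graph.copy()
        g.nx.remove_edge("r1", "c2", key="product")
        g.add_vertex(VertexRecord("r2", "reaction"))
        g.add_edge(EdgeRecord("r1", "c1", "product"))
        g.add_edge(EdgeRecord("c1", "r2", "educt"))
        g.add_edge(EdgeRecord("r2", "c2", "product"))
        part = affiliate_functional(g, 3)
        up = enumerate_traversing_paths(g, part, "upwards")
        down = enumerate_traversing_paths(g, part, "downwards")
        assert find_feedback_loops(g, part, up, down, md_closure=1) == []
        loops = find_feedback_loops(g, part, up, down, md_closure=3)
        assert len(loops) == 1
        assert loops[0].md_closure == ("r1", "c1", "r2", "c2")
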