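import networkx as nx
import pytest
from hypothesis import given, settings, strategies as st

from coexnet.coexpression import CoexprPair
from coexnet.errors import ValidationError
from coexnet.io_formats import GeneLocus
from coexnet.regulation_network import (
    RegulatoryPair,
    build_trans_network,
    classify_cis_trans,
    interval_gap,
    mnc_scores,
    regulation_counts,
    top_k_pairs,
)
from tests.conftest import make_annotation


def brute_force_mnc(g: nx.Graph, node, neighborhood: str) -> int:
    """Independent oracle: enumerate the neighborhood, build the induced
    subgraph explicitly and take the largest connected component."""
    nodes = set(g[node])
    if neighborhood == "closed":
        nodes.add(node)
    if not nodes:
        return 0
    sub = nx.Graph()
    sub.add_nodes_from(nodes)
    for u in nodes:
        for v in nodes:
            if u != v and g.has_edge(u, v):
                sub.add_edge(u, v)
    return max(len(c) for c in nx.connected_components(sub))


def pair(lnc="L1", mrna="M1", r=0.9, p=0.001, lnc_sym=None, mrna_sym=None):
    return CoexprPair(lnc, lnc_sym or f"sym_{lnc}", mrna, mrna_sym or f"sym_{mrna}", r, p, 8)


class TestIntervalGap:
    def test_overlap_and_touch_give_zero(self):
        a = GeneLocus("chr1", 100, 200)
        assert interval_gap(a, GeneLocus("chr1", 150, 300)) == 0
        assert interval_gap(a, GeneLocus("chr1", 200, 300)) == 0

    def test_half_open_gap(self):
        assert interval_gap(GeneLocus("chr1", 100, 200), GeneLocus("chr1", 500, 600)) == 300

    def test_different_chromosomes_absent(self):
        assert interval_gap(GeneLocus("chr1", 100, 200), GeneLocus("chr2", 100, 200)) is None

    @given(st.integers(0, 1000), st.integers(1, 100), st.integers(0, 1000), st.integers(1, 100))
    @settings(max_examples=50, deadline=None)
    def test_symmetry(self, s1, l1, s2, l2):
        a = GeneLocus("chr1", s1, s1 + l1)
        b = GeneLocus("chr1", s2, s2 + l2)
        assert interval_gap(a, b) == interval_gap(b, a)


class TestClassifyCisTrans:
    ann = staticmethod(
        lambda: make_annotation(
            {
                "L1": ("lncA", "lncRNA", "chr1", 0, 10_000, "+"),
                "M_near": ("gNear", "mRNA", "chr1", 110_000, 120_000, "+"),
                "M_edge": ("gEdge", "mRNA", "chr1", 310_000, 320_000, "+"),
                "M_far": ("gFar", "mRNA", "chr1", 310_001, 320_000, "+"),
                "M_other": ("gOther", "mRNA", "chr2", 0, 10_000, "+"),
                "M_noloc": ("gNoLoc", "mRNA", None, None, None, None),
            }
        )
    )

    def test_geometry_boundaries(self):
        pairs = [pair("L1", m) for m in ("M_near", "M_edge", "M_far", "M_other", "M_noloc")]
        rp = classify_cis_trans(pairs, self.ann())
        by = {r.pair.mrna_probe: r for r in rp}
        assert by["M_near"].regulation == "cis" and by["M_near"].distance_bp == 100_000
        # gap exactly 300,000 is still cis (trans is "larger than 300 kb")
        assert by["M_edge"].regulation == "cis" and by["M_edge"].distance_bp == 300_000
        assert by["M_far"].regulation == "trans" and by["M_far"].distance_bp == 300_001
        assert by["M_other"].regulation == "trans" and by["M_other"].distance_bp is None
        assert by["M_noloc"].regulation == "unclassified"

    def test_partition_counts_sum_to_input(self):
        pairs = [pair("L1", m) for m in ("M_near", "M_far", "M_other", "M_noloc")]
        counts = regulation_counts(classify_cis_trans(pairs, self.ann()))
        assert sum(counts.values()) == len(pairs)
        assert counts == {"cis": 1, "trans": 2, "unclassified": 1}


class TestTransNetwork:
    def test_empty_and_single_edge(self):
        assert build_trans_network([]).number_of_nodes() == 0
        g = build_trans_network([RegulatoryPair(pair(), "trans", None)])
        assert g.number_of_nodes() == 2 and g.number_of_edges() == 1
        assert g.nodes["sym_L1"]["role"] == "lncRNA"
        assert g["sym_L1"]["sym_M1"]["weight"] == pytest.approx(0.9)

    def test_star_from_shared_lncrna(self):
        rps = [RegulatoryPair(pair("L1", f"M{i}"), "trans", None) for i in range(3)]
        g = build_trans_network(rps)
        assert g.degree("sym_L1") == 3

    def test_cis_pairs_excluded(self):
        rps = [
            RegulatoryPair(pair("L1", "M1"), "trans", None),
            RegulatoryPair(pair("L1", "M2"), "cis", 100),
        ]
        assert build_trans_network(rps).number_of_edges() == 1

    def test_symbol_collision_gets_role_suffix(self):
        rp = RegulatoryPair(
            pair("L1", "M1", lnc_sym="DUP", mrna_sym="DUP"), "trans", None
        )
        g = build_trans_network([rp])
        assert set(g.nodes) == {"DUP(lncRNA)", "DUP(mRNA)"}


class TestMncScores:
    def test_triangle_open(self):
        g = nx.complete_graph(3)
        assert all(s.mnc == 2 for s in mnc_scores(g, "open"))
        assert all(s.mnc == 3 for s in mnc_scores(g, "closed"))

    def test_star_center_open(self):
        g = nx.star_graph(3)  # center 0, leaves 1..3
        scores = {s.node_symbol: s.mnc for s in mnc_scores(g, "open")}
        assert scores[0] == 1  # leaves are mutually non-adjacent
        assert all(scores[leaf] == 1 for leaf in (1, 2, 3))
        closed = {s.node_symbol: s.mnc for s in mnc_scores(g, "closed")}
        assert closed[0] == 4 and closed[1] == 2

    def test_isolated_node(self):
        g = nx.Graph()
        g.add_node("x")
        assert mnc_scores(g, "open")[0].mnc == 0
        assert mnc_scores(g, "closed")[0].mnc == 1

    def test_sorted_descending_with_symbol_ties(self):
        g = nx.path_graph(4)
        scores = mnc_scores(g, "open")
        assert [s.mnc for s in scores] == sorted([s.mnc for s in scores], reverse=True)

    @pytest.mark.parametrize("neighborhood", ["open", "closed"])
    def test_matches_brute_force_on_random_graphs(self, neighborhood, rng):
        for _ in range(40):
            n = int(rng.integers(2, 13))
            g = nx.gnp_random_graph(n, float(rng.uniform(0.1, 0.9)),
                                    seed=int(rng.integers(2**31)))
            expected = {v: brute_force_mnc(g, v, neighborhood) for v in g}
            got = {s.node_symbol: s.mnc for s in mnc_scores(g, neighborhood)}
            assert got == expected

    def test_open_mnc_degenerate_on_bipartite_graphs(self, rng):
        # structural theorem: neighbors of any node lie on one side of a
        # bipartition, hence induce an edgeless subgraph
        for _ in range(20):
            g = nx.bipartite.random_graph(
                int(rng.integers(1, 8)), int(rng.integers(1, 8)), 0.6,
                seed=int(rng.integers(2**31)),
            )
            assert all(s.mnc <= 1 for s in mnc_scores(g, "open"))

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValidationError):
            mnc_scores(nx.Graph(), "half-open")


class TestTopKPairs:
    def test_fewer_than_k_returns_all(self):
        rps = [RegulatoryPair(pair("L1", f"M{i}", r=0.8), "trans", None) for i in range(3)]
        assert len(top_k_pairs(rps, k=100)) == 3

    def test_tied_abs_r_breaks_by_p(self):
        a = RegulatoryPair(pair("L1", "M1", r=0.9, p=0.02), "trans", None)
        b = RegulatoryPair(pair("L2", "M2", r=-0.9, p=0.001), "trans", None)
        assert top_k_pairs([a, b], k=1) == [b]

    def test_top_100_matches_full_sort_oracle(self, rng):
        rs = rng.uniform(0.701, 0.999, size=150) * rng.choice([-1, 1], size=150)
        rps = [
            RegulatoryPair(pair(f"L{i}", f"M{i}", r=float(r), p=1e-4), "trans", None)
            for i, r in enumerate(rs)
        ]
        top = top_k_pairs(rps, k=100)
        expected = sorted(rps, key=lambda rp: -abs(rp.pair.r))[:100]
        assert {t.pair.lnc_probe for t in top} == {e.pair.lnc_probe for e in expected}

    def test_class_filter(self):
        rps = [
            RegulatoryPair(pair("L1", "M1"), "cis", 5),
            RegulatoryPair(pair("L2", "M2"), "trans", None),
            RegulatoryPair(pair("L3", "M3"), "unclassified", None),
        ]
        assert len(top_k_pairs(rps, k=10, class_filter="cis")) == 1
        assert len(top_k_pairs(rps, k=10, class_filter="any")) == 3
        with pytest.raises(ValidationError):
            top_k_pairs(rps, k=0)
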