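"""Link inference, subnetwork partition, tiers and graph export."""

import itertools

import networkx as nx
import pytest

from tfrn.classification import NETWORK_CLASSES, TFClassification
from tfrn.genomic_io import InputError, PeakInterval, PeakSet, PromoterRegion
from tfrn.network import (
    MEANINGFUL_PAIRS,
    assign_tiers,
    audit_graph,
    build_graph,
    compare_link_sets,
    export_graph,
    infer_links,
    is_meaningful_pair,
)


def mk_class(tf, cls):
    gd = {"DA": "down", "DS": "down", "UA": "up", "US": "up"}[cls]
    return TFClassification(tf, cls, cls in ("UA", "DS"), cls in ("DA", "US"), gd)


def da_graph(edges, classes=None):
    """Small graph of DA nodes (plus any given classes) from an edge list."""
    nodes = sorted({n for e in edges for n in e})
    classified = [mk_class(n, (classes or {}).get(n, "DA")) for n in nodes]
    g = nx.DiGraph()
    for c in classified:
        g.add_node(c.tf_gene_id, tf_class=c.tf_class, tier=0, subnetwork="R")
    for u, v in edges:
        g.add_edge(u, v, sign="activation")
    return g


class TestMeaningfulPairs:
    def test_listed_pairs(self):
        assert is_meaningful_pair("UA", "US")
        assert not is_meaningful_pair("UA", "DA")

    def test_enumeration_matches_consistency_rule(self):
        """Brute force over all 16 ordered pairs: exactly the eight pairs in
        which an activator targets a co-directional gene or a suppressor an
        anti-directional gene are admitted."""
        gene_dir = {"DA": "down", "DS": "down", "UA": "up", "US": "up"}
        admitted = set()
        for reg, tgt in itertools.product(NETWORK_CLASSES, repeat=2):
            is_activator = reg in ("DA", "UA")
            consistent = (
                gene_dir[tgt] == gene_dir[reg]
                if is_activator
                else gene_dir[tgt] != gene_dir[reg]
            )
            assert is_meaningful_pair(reg, tgt) == consistent
            if consistent:
                admitted.add((reg, tgt))
        assert admitted == set(MEANINGFUL_PAIRS)
        assert len(admitted) == 8

    def test_non_network_class_rejected(self):
        with pytest.raises(InputError):
            is_meaningful_pair("NTR", "DA")


class TestInferLinks:
    def _setup(self):
        # two DA TFs and one US; promoters 1 kb, spaced apart
        proms = [
            PromoterRegion("da1", "chr1", 1000, 2000, "+"),
            PromoterRegion("da2", "chr1", 4000, 5000, "+"),
            PromoterRegion("ua1", "chr1", 7000, 8000, "+"),
        ]
        classified = [mk_class("da1", "DA"), mk_class("da2", "DA"), mk_class("ua1", "UA")]
        return proms, classified

    def test_da_da_activation_link(self):
        proms, classified = self._setup()
        sets = [PeakSet("da1", "col", [PeakInterval("chr1", 4400, 4600)])]
        (link,) = infer_links(classified, proms, sets)
        assert (link.regulator, link.target, link.sign) == ("da1", "da2", "activation")
        assert len(link.supporting_peaks) == 1

    def test_non_meaningful_pair_suppressed(self):
        proms, classified = self._setup()
        # da1 peak in ua1's promoter: DA-UA is not meaningful
        sets = [PeakSet("da1", "col", [PeakInterval("chr1", 7400, 7600)])]
        assert infer_links(classified, proms, sets) == []

    def test_self_link_da_da(self):
        proms, classified = self._setup()
        sets = [PeakSet("da1", "col", [PeakInterval("chr1", 1400, 1600)])]
        (link,) = infer_links(classified, proms, sets)
        assert (link.regulator, link.target) == ("da1", "da1")

    def test_monotone_in_peaks(self):
        """Removing peaks never adds links."""
        proms, classified = self._setup()
        peaks = [PeakInterval("chr1", 4400, 4600), PeakInterval("chr1", 1400, 1600)]
        full = infer_links(classified, proms, [PeakSet("da1", "col", peaks)])
        reduced = infer_links(classified, proms, [PeakSet("da1", "col", peaks[:1])])
        pairs = lambda ls: {(l.regulator, l.target) for l in ls}
        assert pairs(reduced) <= pairs(full)

    def test_planted_recovery_exact(self, planted_result, planted_inputs):
        *_, truth = planted_inputs
        got = sorted([l.regulator, l.target] for l in planted_result.links)
        assert got == truth["edges"]


class TestSubnetworks:
    def test_partition_and_edge_kinds(self, planted_result):
        g = planted_result.graph
        for n, d in g.nodes(data=True):
            assert d["subnetwork"] == ("R" if d["tf_class"] in ("DA", "DS") else "A")
        kinds = {(u, v): d["kind"] for u, v, d in g.edges(data=True)}
        assert kinds[("TF_DA1", "TF_DA2")] == "within-R"
        assert kinds[("TF_US1", "TF_DA2")] == "A->R"
        assert kinds[("TF_DS1", "TF_UA1")] == "R->A"
        assert kinds[("TF_UA1", "TF_UA2")] == "within-A"

    def test_empty_a_side_is_valid(self):
        g = da_graph([("a", "b")])
        from tfrn.network import partition_subnetworks

        partition_subnetworks(g)
        assert all(d["subnetwork"] == "R" for _, d in g.nodes(data=True))


class TestTiers:
    def test_chain(self):
        g = assign_tiers(da_graph([("a", "b"), ("b", "c")]))
        assert [g.nodes[n]["tier"] for n in "abc"] == [1, 2, 3]

    def test_self_loop_excluded_from_in_degree(self):
        g = assign_tiers(da_graph([("a", "a")]))
        assert g.nodes["a"]["tier"] == 1

    def test_pure_cycle_all_tier3_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            g = assign_tiers(da_graph([("a", "b"), ("b", "a")]))
        assert [g.nodes[n]["tier"] for n in "ab"] == [3, 3]
        assert "tier-1" in caplog.text

    def test_tier2_rule_any_vs_all_parents(self):
        # b receives from tier-1 a and from tier-3-ish c (cycle with d)
        edges = [("a", "b"), ("c", "b"), ("c", "d"), ("d", "c")]
        g_any = assign_tiers(da_graph(edges), tier2_rule="any-parent")
        assert g_any.nodes["b"]["tier"] == 2
        g_all = assign_tiers(da_graph(edges), tier2_rule="all-parents")
        assert g_all.nodes["b"]["tier"] == 3

    def test_partition_disjoint_exhaustive(self, planted_result):
        g = planted_result.graph
        da = {n for n, d in g.nodes(data=True) if d["tf_class"] == "DA"}
        core = {n for u, v in g.edges if u in da and v in da for n in (u, v)}
        tiers = {n: g.nodes[n]["tier"] for n in core}
        assert set(tiers.values()) <= {1, 2, 3}
        for n in set(g.nodes) - core:
            assert g.nodes[n]["tier"] == 0
        # tier-1 non-self in-degree is zero within the core
        for n, t in tiers.items():
            if t == 1:
                assert not any(
                    u in da and v == n and u != n for u, v in g.edges
                )


class TestExport:
    def test_graphml_round_trip(self, planted_result, tmp_path):
        path = export_graph(planted_result.graph, tmp_path / "g.graphml")
        back = nx.read_graphml(path)
        assert set(back.nodes) == set(planted_result.graph.nodes)
        assert {(u, v) for u, v in back.edges} == set(planted_result.graph.edges)
        for u, v in back.edges:
            assert back.edges[u, v]["sign"] in ("activation", "inhibition")
            assert back.edges[u, v]["sign"] == planted_result.graph.edges[u, v]["sign"]
        for n in back.nodes:
            assert back.nodes[n]["tf_class"] == planted_result.graph.nodes[n]["tf_class"]

    def test_empty_graph_valid_documents(self, tmp_path):
        g = build_graph([], [])
        for fmt, name in [("graphml", "g.graphml"), ("json", "g.json"),
                          ("dot", "g.dot"), ("tsv-edgelist", "g.tsv")]:
            p = export_graph(g, tmp_path / name, format=fmt)
            assert p.exists() and p.stat().st_size > 0

    def test_unknown_format_errors(self, planted_result, tmp_path):
        with pytest.raises(InputError):
            export_graph(planted_result.graph, tmp_path / "x", format="xml")

    def test_audit_clean_on_pipeline_graph(self, planted_result):
        assert audit_graph(planted_result.graph) == []

    def test_audit_catches_bad_sign(self, planted_result):
        g = planted_result.graph.copy()
        u, v = next(iter(g.edges))
        g.edges[u, v]["sign"] = "inhibition" if g.edges[u, v]["sign"] == "activation" \
            else "activation"
        assert audit_graph(g)


class TestCompareLinkSets:
    def test_difference_and_intersection(self):
        only_a, only_b, common = compare_link_sets(
            [("a", "b"), ("b", "c")], [("b", "c")]
        )
        assert (only_a, only_b, common) == ({("a", "b")}, set(), {("b", "c")})

    def test_identical_and_disjoint(self):
        a = [("a", "b")]
        assert compare_link_sets(a, a)[:2] == (set(), set())
        only_a, only_b, common = compare_link_sets([("a", "b")], [("c", "d")])
        assert common == set() and len(only_a) == len(only_b) == 1

    def test_size_identity(self):
        a = [("a", "b"), ("b", "c"), ("c", "d")]
        b = [("b", "c"), ("x", "y")]
        only_a, _, common = compare_link_sets(a, b)
        assert len(only_a) + len(common) == len(set(a))
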