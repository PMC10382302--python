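"""Enrichment statistics: hypergeometric tables, target genes, TSS
distances, shortest-PPI-path internal nodes."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

from chromcooc.intervals import GenomicInterval
from chromcooc.network import BindingMap
from chromcooc.enrich import (
    ContingencyTable2x2,
    assign_target_genes,
    domain_interaction_pairs,
    factor_target_genes,
    gene_set_enrichment,
    hypergeom_enrichment,
    pair_interaction_table,
    pooled_distances,
    read_gene_list,
    read_group_labels,
    read_pair_list,
    shortest_path_internal_tfs,
    tss_distance_cdf,
)

from conftest import make_network

GI = GenomicInterval


def enumeration_hypergeom(a, b, c, d):
    """Upper-tail p by direct enumeration over the hypergeometric support."""
    N, K, n = a + b + c + d, a + b, a + c
    total = 0.0
    for x in range(a, min(K, n) + 1):
        total += comb(K, x) * comb(N - K, n - x) / comb(N, n)
    return total


class TestHypergeom:
    def test_small_table_by_enumeration(self):
        assert hypergeom_enrichment(ContingencyTable2x2(2, 0, 0, 2)) == (
            pytest.approx(1 / 6)
        )

    @pytest.mark.parametrize("table", [(3, 2, 4, 6), (5, 1, 2, 9), (0, 4, 7, 2)])
    def test_matches_enumeration_oracle(self, table):
        assert hypergeom_enrichment(ContingencyTable2x2(*table)) == pytest.approx(
            enumeration_hypergeom(*table)
        )

    def test_column_swap_antisymmetry(self):
        """Swapping columns maps the upper tail to the lower tail:
        p_upper(a,b,c,d) + p_lower(b,a,d,c) counts the boundary twice."""
        a, b, c, d = 6, 3, 4, 8
        up = hypergeom_enrichment(ContingencyTable2x2(a, b, c, d))
        swapped_up = hypergeom_enrichment(ContingencyTable2x2(b, a, d, c))
        assert up + swapped_up >= 1.0  # both tails include equality

    def test_degenerate_table(self):
        assert hypergeom_enrichment(ContingencyTable2x2(0, 0, 0, 0)) == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(-1, 0, 0, 0)


class TestPairTables:
    def _calls(self):
        rows = [
            ("a", "b", "attract"), ("a", "c", "attract"), ("b", "c", "repel"),
            ("a", "d", "neutral"), ("c", "d", "repel"), ("b", "d", "attract"),
        ]
        return pd.DataFrame(rows, columns=["factor_i", "factor_j", "call"])

    def test_membership_counting(self):
        inter = {("b", "a"), ("c", "b")}  # order-insensitive
        t = pair_interaction_table(self._calls(), inter)
        assert (t.a, t.b, t.c, t.d) == (1, 1, 2, 1)

    def test_empty_interaction_list(self):
        t = pair_interaction_table(self._calls(), set())
        assert t.a == 0 and t.b == 0
        assert hypergeom_enrichment(t) == 1.0

    def test_matches_brute_force_membership(self):
        rng = np.random.default_rng(12)
        factors = [f"f{i}" for i in range(8)]
        rows = []
        for i, a in enumerate(factors):
            for b in factors[i + 1:]:
                rows.append((a, b, rng.choice(["attract", "repel", "neutral"])))
        calls = pd.DataFrame(rows, columns=["factor_i", "factor_j", "call"])
        inter = {tuple(sorted(rng.choice(factors, 2, replace=False)))
                 for _ in range(10)}
        t = pair_interaction_table(calls, inter)
        a = sum(1 for r in rows if r[2] == "attract" and (r[0], r[1]) in inter)
        b = sum(1 for r in rows if r[2] == "repel" and (r[0], r[1]) in inter)
        c = sum(1 for r in rows if r[2] == "attract") - a
        d = sum(1 for r in rows if r[2] == "repel") - b
        assert (t.a, t.b, t.c, t.d) == (a, b, c, d)

    def test_domain_derived_pairs(self):
        fd = {"x": ["PF1", "PF2"], "y": ["PF3"], "z": ["PF9"]}
        dpairs = {("PF1", "PF3")}
        out = domain_interaction_pairs(fd, dpairs)
        assert out == {("x", "y")}


class TestTargetGenes:
    def _setup(self):
        # regions 0-1 interact; gene g1 near region 1, g2 far from all
        net = make_network([(0, 1)], length=1000, gap=5000)
        tss = {
            "g1": GI("chrT", net.regions[1].interval.start - 1500,
                     net.regions[1].interval.start - 1499),
            "g2": GI("chrT", 500_000, 500_001),
        }
        return net, tss

    def test_sequential_and_spatial_routes(self):
        net, tss = self._setup()
        bm = BindingMap(["near", "spatial", "far"], {
            "near": {1},     # within 2 kb of g1's TSS
            "spatial": {0},  # interacts with region 1, which is near g1
            "far": set(),
        })
        targets = factor_target_genes(bm, net, tss)
        assert targets["near"] == {"g1"}
        assert targets["spatial"] == {"g1"}
        assert targets["far"] == set()

    @pytest.mark.parametrize(
        "c1,c2,expected", [(5, 2, 1), (5, 4, 0), (4, 0, 0), (6, 3, 1)]
    )
    def test_five_three_rule(self, c1, c2, expected):
        net, tss = self._setup()
        factors = [f"a{i}" for i in range(c1)] + [f"b{i}" for i in range(c2)]
        bm = BindingMap(factors, {f: {1} for f in factors})
        groups = {f: (1 if f.startswith("a") else 2) for f in factors}
        calls = assign_target_genes(bm, net, tss, groups)
        call = next(c for c in calls if c.gene == "g1")
        assert (call.count_group1, call.count_group2) == (c1, c2)
        assert call.assigned_group == expected

    def test_strict_three_zero_variant(self):
        net, tss = self._setup()
        factors = ["a0", "a1", "a2", "b0"]
        bm = BindingMap(factors, {f: {1} for f in factors})
        groups = {f: (1 if f.startswith("a") else 2) for f in factors}
        loose = assign_target_genes(bm, net, tss, groups, min_in=3, max_out=0)
        assert loose[0].assigned_group == 0  # one group-2 factor blocks it
        bm2 = BindingMap(factors[:3], {f: {1} for f in factors[:3]})
        strict = assign_target_genes(bm2, net, tss, groups, min_in=3, max_out=0)
        assert strict[0].assigned_group == 1

    def test_monotone_in_binding(self):
        net, tss = self._setup()
        bm_small = BindingMap(["a"], {"a": {0}})
        bm_big = BindingMap(["a"], {"a": {0, 1}})
        t_small = factor_target_genes(bm_small, net, tss)["a"]
        t_big = factor_target_genes(bm_big, net, tss)["a"]
        assert t_small <= t_big


class TestGeneSetEnrichment:
    def test_disjoint_reference_is_one(self):
        p, _ = gene_set_enrichment({"g1", "g2"}, {"g3"}, {"x", "y"})
        assert p == 1.0

    def test_extreme_table_is_minimal_p(self):
        g1, g2 = {"a", "b", "c"}, {"d", "e"}
        p, t = gene_set_enrichment(g1, g2, g1)
        assert p == pytest.approx(1 / comb(5, 3))

    def test_matches_enumeration(self):
        g1, g2 = {"a", "b", "c", "d"}, {"e", "f", "g"}
        ref = {"a", "b", "e"}
        p, t = gene_set_enrichment(g1, g2, ref)
        assert p == pytest.approx(enumeration_hypergeom(t.a, t.b, t.c, t.d))

    def test_empty_sets_rejected(self):
        with pytest.raises(ValueError):
            gene_set_enrichment(set(), {"a"}, {"a"})


class TestTssDistances:
    def test_midpoint_examples(self):
        tss = [GI("c", 1000, 1001)]
        peaks = {"F": [GI("c", 990, 1010), GI("c", 1990, 2010)]}
        d = tss_distance_cdf(peaks, tss)["F"]
        assert list(d) == [0, 1000]

    def test_matches_brute_force_nearest(self):
        rng = np.random.default_rng(13)
        tss = [GI("c", int(p), int(p) + 1) for p in rng.integers(0, 100_000, 30)]
        peaks = {"F": [GI("c", int(s), int(s) + 200)
                       for s in rng.integers(0, 100_000, 40)]}
        got = tss_distance_cdf(peaks, tss)["F"]
        expected = sorted(
            min(abs((p.start + p.end) // 2 - t.start) for t in tss)
            for p in peaks["F"]
        )
        assert list(got) == expected

    def test_chromosome_without_tss_excluded(self):
        tss = [GI("c1", 10, 11)]
        peaks = {"F": [GI("c1", 0, 20), GI("c2", 0, 20)]}
        assert len(tss_distance_cdf(peaks, tss)["F"]) == 1

    def test_pooled_group_curve(self):
        d = {"a": np.array([1, 5]), "b": np.array([3])}
        assert list(pooled_distances(d, ["a", "b"])) == [1, 3, 5]

    def test_empty_tss_rejected(self):
        with pytest.raises(ValueError):
            tss_distance_cdf({"F": []}, [])


class TestShortestPaths:
    def test_unique_internal_node(self):
        edges = [("A", "X"), ("X", "B")]
        out = shortest_path_internal_tfs(edges, {"cat": [("A", "B")]}, {"X"})
        assert out.to_dict("records") == [
            {"tf": "X", "category": "cat", "count": 1}]

    def test_direct_edge_has_no_internal_nodes(self):
        edges = [("A", "B"), ("A", "X"), ("X", "B")]
        out = shortest_path_internal_tfs(edges, {"cat": [("A", "B")]}, {"X"})
        assert out.empty

    def test_union_over_tied_shortest_paths(self):
        edges = [("A", "X"), ("X", "B"), ("A", "Y"), ("Y", "B"), ("A", "Z")]
        out = shortest_path_internal_tfs(
            edges, {"cat": [("A", "B")]}, {"X", "Y", "Z"})
        counts = dict(zip(out.tf, out["count"]))
        assert counts == {"X": 1, "Y": 1}  # Z is off every shortest path

    def test_unannotated_internal_nodes_not_counted(self):
        edges = [("A", "X"), ("X", "B")]
        out = shortest_path_internal_tfs(edges, {"cat": [("A", "B")]}, {"Q"})
        assert out.empty

    def test_disconnected_pair_contributes_nothing(self):
        edges = [("A", "X"), ("B", "Y")]
        out = shortest_path_internal_tfs(edges, {"cat": [("A", "B")]}, {"X", "Y"})
        assert out.empty

    def test_invariant_to_edge_order(self):
        edges = [("A", "X"), ("X", "Y"), ("Y", "B"), ("A", "P"), ("P", "Q"),
                 ("Q", "B")]
        ann = {"X", "Y", "P", "Q"}
        a = shortest_path_internal_tfs(edges, {"c": [("A", "B")]}, ann)
        b = shortest_path_internal_tfs(edges[::-1], {"c": [("A", "B")]}, ann)
        pd.testing.assert_frame_equal(a, b)


def test_side_table_readers(tmp_path):
    (tmp_path / "ppi.tsv").write_text("b\ta\nx\ty\n# note\n")
    assert read_pair_list(tmp_path / "ppi.tsv") == {("a", "b"), ("x", "y")}
    (tmp_path / "groups.tsv").write_text("TF1\t1\nTF2\t2\n")
    assert read_group_labels(tmp_path / "groups.tsv") == {"TF1": 1, "TF2": 2}
    (tmp_path / "genes.txt").write_text("g1\n\ng2\n# skip\n")
    assert read_gene_list(tmp_path / "genes.txt") == {"g1", "g2"}
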