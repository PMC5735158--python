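import pandas as pd
import pytest

from mbco import (
    CompetitionEdge,
    GeneSCPTable,
    SCPUnit,
    Taxonomy,
    build_units,
    dynamic_enrichment,
    extract_context_network,
    standard_enrichment,
)
from mbco.ontology import SCPNode

from _oracles import fisher_upper_tail_enum


def flat_level3_tax(scps):
    nodes = [SCPNode("R", "root", 0, None), SCPNode("L1", "area", 1, "R"),
             SCPNode("L2", "family", 2, "L1")]
    nodes += [SCPNode(s, f"name {s}", 3, "L2") for s in scps]
    return Taxonomy(nodes)


def table_for(sets):
    rows = [{"gene": g, "scp_id": s} for s, gs in sets.items() for g in sorted(gs)]
    return GeneSCPTable(pd.DataFrame(rows))


class TestStandardEnrichment:
    def test_pvalue_matches_enumeration_oracle(self):
        universe = {f"u{i}" for i in range(100)}
        gene_set = set(sorted(universe)[:10])
        query = set(sorted(universe)[5:15])  # overlap 5
        [res] = standard_enrichment(query, {"S": gene_set}, universe)
        a = len(query & gene_set)
        b = len(query - gene_set)
        c = len(gene_set - query)
        d = len(universe) - a - b - c
        assert res.p == pytest.approx(fisher_upper_tail_enum(a, b, c, d), abs=1e-10)
        assert res.overlap_genes == frozenset(query & gene_set)

    def test_zero_overlap_gives_large_p(self):
        universe = {f"u{i}" for i in range(50)}
        sets = {"S": set(sorted(universe)[:10])}
        [res] = standard_enrichment(set(sorted(universe)[40:45]), sets, universe)
        assert res.p == pytest.approx(1.0, abs=1e-9) or res.p > 0.3

    def test_query_equal_to_set_is_extremal(self):
        universe = {f"u{i}" for i in range(40)}
        sets = {f"S{i}": set(sorted(universe)[i * 10:(i + 1) * 10]) for i in range(4)}
        results = standard_enrichment(sets["S1"], sets, universe)
        assert results[0].name == "S1"
        assert all(results[0].p <= r.p for r in results[1:])

    def test_disjoint_query_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            standard_enrichment({"nope"}, {"S": {"a"}}, {"a", "b"})

    def test_ranks_are_gapless_and_sorted(self):
        universe = {f"u{i}" for i in range(30)}
        sets = {f"S{i}": set(sorted(universe)[i:i + 8]) for i in range(5)}
        results = standard_enrichment(set(sorted(universe)[:6]), sets, universe)
        assert [r.rank for r in results] == list(range(1, 6))
        assert all(results[i].p <= results[i + 1].p for i in range(len(results) - 1))


class TestBuildUnits:
    sets = {"A": {"g1", "g2"}, "B": {"g3"}, "C": {"g5"}, "D": {"g7"}}

    def test_chain_yields_pairs_and_path_triple(self):
        edges = [CompetitionEdge("A", "B", 1.0), CompetitionEdge("B", "C", 0.5)]
        units = build_units({"g1", "g3", "g5", "g7"}, self.sets, edges)
        assert sorted(u.unit_name for u in units) == ["A + B", "A + B + C", "B + C"]

    def test_triangle_emits_each_unit_once(self):
        edges = [CompetitionEdge("A", "B", 1.0), CompetitionEdge("B", "C", 0.5),
                 CompetitionEdge("C", "A", 0.7), CompetitionEdge("A", "C", 0.2)]
        units = build_units({"g1", "g3", "g5"}, self.sets, edges)
        assert sorted(u.unit_name for u in units) == [
            "A + B", "A + B + C", "A + C", "B + C"
        ]

    def test_isolated_candidate_in_no_unit(self):
        edges = [CompetitionEdge("A", "B", 1.0)]
        units = build_units({"g1", "g3", "g7"}, self.sets, edges)
        assert all("D" not in u.member_scps for u in units)

    def test_member_without_perturbed_gene_excluded(self):
        edges = [CompetitionEdge("A", "B", 1.0)]
        units = build_units({"g1"}, self.sets, edges)  # B has no perturbed gene
        assert units == []

    def test_edge_insertion_order_invariance(self):
        e = [CompetitionEdge("A", "B", 1.0), CompetitionEdge("B", "C", 0.5),
             CompetitionEdge("C", "A", 0.7)]
        u1 = build_units({"g1", "g3", "g5"}, self.sets, e)
        u2 = build_units({"g1", "g3", "g5"}, self.sets, list(reversed(e)))
        assert u1 == u2

    def test_unit_gene_set_is_union(self):
        edges = [CompetitionEdge("A", "B", 1.0)]
        [u] = build_units({"g1", "g3"}, self.sets, edges)
        assert u.gene_set == frozenset({"g1", "g2", "g3"})

    def test_unit_size_bounds_enforced(self):
        with pytest.raises(ValueError):
            SCPUnit(frozenset({"A"}), frozenset(), "A")


class TestDynamicEnrichment:
    def setup_method(self):
        self.sets = {
            "A": {f"a{i}" for i in range(8)},
            "B": {f"b{i}" for i in range(8)},
            "C": {f"c{i}" for i in range(8)},
            "D": {f"d{i}" for i in range(8)},
        }
        self.tax = flat_level3_tax(self.sets)
        self.table = table_for(self.sets)
        self.edges = [CompetitionEdge("A", "B", 2.0)]

    def test_empty_edge_list_equals_standard_exactly(self):
        query = {"a0", "a1", "b0"}
        universe = set().union(*self.sets.values())
        dyn = dynamic_enrichment(query, self.table, self.tax, [], q=0.25, top_k=None)
        std = standard_enrichment(query, self.sets, universe)
        assert [(r.name, r.p) for r in dyn] == [(r.name, r.p) for r in std]

    def test_split_perturbation_ranks_merged_unit_first(self):
        query = {"a0", "a1", "a2", "b0", "b1", "b2"}
        results = dynamic_enrichment(query, self.table, self.tax, self.edges, q=1.0)
        assert results[0].name == "A + B"
        assert results[0].p < results[1].p

    def test_single_scp_perturbation_ranks_singleton_first(self):
        query = {"a0", "a1", "a2", "a3"}
        results = dynamic_enrichment(query, self.table, self.tax, self.edges, q=1.0)
        assert results[0].name == "A"

    def test_unit_p_not_always_better_and_not_always_worse(self):
        # split query: unit beats both singletons
        split = dynamic_enrichment({"a0", "a1", "b0", "b1"}, self.table, self.tax,
                                   self.edges, q=1.0, top_k=None)
        p_unit = next(r.p for r in split if r.name == "A + B")
        p_a = next(r.p for r in split if r.name == "A")
        assert p_unit < p_a
        # concentrated query: singleton beats the diluted unit
        conc = dynamic_enrichment({"a0", "a1", "a2", "a3", "b0"}, self.table,
                                  self.tax, self.edges, q=1.0, top_k=None)
        p_unit = next(r.p for r in conc if r.name == "A + B")
        p_a = next(r.p for r in conc if r.name == "A")
        assert p_a < p_unit


class TestContextNetwork:
    def make_results(self, names):
        return [
            type("R", (), {"member_scps": frozenset({n}), "rank": i + 1})()
            for i, n in enumerate(names)
        ]

    def test_largest_component_wins(self):
        scps = ["A", "B", "C", "D", "E", "F"]
        tax = flat_level3_tax(scps)
        results = self.make_results(scps)
        edges = [CompetitionEdge("A", "B", 1.0), CompetitionEdge("B", "C", 1.0),
                 CompetitionEdge("C", "D", 1.0), CompetitionEdge("E", "F", 1.0)]
        net = extract_context_network(results, edges, tax)
        members = {n for n in net.nodes if net.nodes[n]["role"] == "member"}
        assert members == {"A", "B", "C", "D"}

    def test_all_unconnected_returns_best_p_node(self):
        scps = ["A", "B", "C"]
        tax = flat_level3_tax(scps)
        results = self.make_results(["B", "A", "C"])  # B has rank 1
        net = extract_context_network(results, [], tax)
        members = {n for n in net.nodes if net.nodes[n]["role"] == "member"}
        assert members == {"B"}

    def test_decoration_adds_exactly_the_distinct_ancestors(self):
        scps = ["A", "B"]
        tax = flat_level3_tax(scps)
        results = self.make_results(scps)
        edges = [CompetitionEdge("A", "B", 1.0)]
        net = extract_context_network(results, edges, tax)
        roles = {n: net.nodes[n]["role"] for n in net.nodes}
        assert roles == {"A": "member", "B": "member", "L2": "parent", "L1": "grandparent"}

    def test_empty_results_rejected(self):
        tax = flat_level3_tax(["A"])
        with pytest.raises(ValueError):
            extract_context_network([], [], tax)
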