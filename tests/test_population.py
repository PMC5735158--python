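import io

import numpy as np
import pandas as pd
import pytest

from mbco import (
    CountMatrix,
    OntologyError,
    PopulationConfig,
    ValidationLabelSet,
    apply_abstract_minimum,
    apply_validation_adjustments,
    fisher_upper_tail,
    gene_pvalues,
    inherit_filter,
    largest_gap_filter,
    normalize_scp_counts,
    populate,
    propagate_upward,
    rank_genes,
    remove_false_positives,
    save_associations,
)
from mbco.population import _gap_keep_mask, enrich_and_filter

from _oracles import fisher_upper_tail_enum, largest_gap_oracle


def cm(rows, totals=None):
    return CountMatrix(pd.DataFrame(rows, columns=["gene", "scp_id", "count"]),
                       totals or {})


class TestFisherUpperTail:
    def test_zero_count_gives_one(self):
        assert fisher_upper_tail(0, 10, 5, 85) == 1.0

    def test_hand_enumerated_two_by_two(self):
        # margins (2,2)/(2,2): only table with a=2 has prob C(2,2)C(2,0)/C(4,2)=1/6
        assert fisher_upper_tail(2, 0, 0, 2) == pytest.approx(1 / 6, abs=1e-12)

    def test_negative_entry_rejected(self):
        with pytest.raises(ValueError):
            fisher_upper_tail(-1, 1, 1, 1)
        with pytest.raises(ValueError):
            fisher_upper_tail(0, 0, 0, 0)

    def test_matches_enumeration_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            a, b, c, d = (int(x) for x in rng.integers(0, 25, size=4))
            if a + b + c + d == 0:
                continue
            assert fisher_upper_tail(a, b, c, d) == pytest.approx(
                fisher_upper_tail_enum(a, b, c, d), abs=1e-12
            )


class TestLargestGapFilter:
    def test_keeps_group_above_largest_gap(self):
        vals = [("A", 8.1), ("B", 7.9), ("C", 2.0), ("D", 1.5)]
        assert largest_gap_filter(vals) == {"A", "B"}

    def test_single_value_kept(self):
        assert largest_gap_filter([("A", 0.3)]) == {"A"}

    def test_tied_gaps_resolve_to_topmost(self):
        assert largest_gap_filter([("A", 5.0), ("B", 3.0), ("C", 1.0)]) == {"A"}

    def test_all_equal_profile_kept_in_full(self):
        assert largest_gap_filter([("A", 2.0), ("B", 2.0), ("C", 2.0)]) == {"A", "B", "C"}

    def test_empty_and_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            largest_gap_filter([])
        with pytest.raises(ValueError):
            largest_gap_filter([("A", float("inf"))])

    def test_matches_cut_position_oracle_on_random_lists(self):
        rng = np.random.default_rng(1)
        for _ in range(500):
            n = int(rng.integers(1, 9))
            vals = [(f"S{i}", float(np.round(rng.uniform(0, 10), 3))) for i in range(n)]
            assert largest_gap_filter(vals) == largest_gap_oracle(vals)

    def test_vectorized_mask_agrees_with_scalar_filter(self):
        rng = np.random.default_rng(2)
        rows = []
        for g in range(40):
            for i in range(int(rng.integers(1, 7))):
                rows.append({"gene": f"G{g}", "scp_id": f"S{i}",
                             "p": float(10 ** -rng.uniform(0, 12))})
        pdf = pd.DataFrame(rows)
        mask = _gap_keep_mask(pdf)
        for g, grp in pdf.groupby("gene"):
            vals = [(s, -np.log10(p)) for s, p in zip(grp["scp_id"], grp["p"])]
            expected = largest_gap_filter(vals)
            got = set(grp.loc[mask[grp.index], "scp_id"])
            assert got == expected, g


class TestThresholdAndAdjustments:
    def test_per_level_minimums(self, small_tax):
        counts = cm([("g", "X", 1), ("g", "Y", 2), ("g", "X4", 1), ("g", "P1", 2)])
        out = apply_abstract_minimum(counts, small_tax, PopulationConfig())
        kept = set(zip(out.counts["gene"], out.counts["scp_id"]))
        assert kept == {("g", "Y"), ("g", "X4")}  # L3 needs 2, L4 needs 1, L2 needs 3

    def test_empty_matrix_passthrough(self, small_tax):
        out = apply_abstract_minimum(cm([]), small_tax, PopulationConfig())
        assert out.counts.empty

    def test_unknown_scp_rejected(self, small_tax):
        with pytest.raises(OntologyError, match="missing from taxonomy"):
            apply_abstract_minimum(cm([("g", "NOPE", 5)]), small_tax, PopulationConfig())

    def test_m_removed_s_penalized_t_untouched(self):
        counts = cm([("g1", "X", 7), ("g2", "X", 100), ("g3", "X", 9), ("g4", "X", 5)])
        labels = ValidationLabelSet({
            ("g1", "X"): "M", ("g2", "X"): "S", ("g3", "X"): "T",
        })
        out = apply_validation_adjustments(counts, labels, PopulationConfig())
        d = {g: c for g, c in zip(out.counts["gene"], out.counts["count"])}
        assert "g1" not in d
        assert d["g2"] == pytest.approx(34.0)
        assert d["g3"] == 9 and d["g4"] == 5


class TestNormalization:
    def test_equal_counts_split_target(self, small_tax):
        out = normalize_scp_counts(cm([("g1", "X", 2), ("g2", "X", 2)]),
                                   small_tax, PopulationConfig())
        assert sorted(out.counts["count"]) == [500.0, 500.0]

    def test_already_at_target(self, small_tax):
        out = normalize_scp_counts(cm([("g1", "P1", 3000)]), small_tax, PopulationConfig())
        assert out.counts["count"].iloc[0] == pytest.approx(3000.0)

    def test_sums_hit_level_targets(self, small_tax):
        rng = np.random.default_rng(5)
        rows = [(f"g{i}", s, int(rng.integers(1, 30)))
                for s in ("X", "Y", "P1") for i in range(8)]
        out = normalize_scp_counts(cm(rows), small_tax, PopulationConfig())
        sums = out.counts.groupby("scp_id")["count"].sum()
        assert sums["X"] == pytest.approx(1000.0, abs=1e-6)
        assert sums["Y"] == pytest.approx(1000.0, abs=1e-6)
        assert sums["P1"] == pytest.approx(3000.0, abs=1e-6)


class TestGenePvalues:
    def test_concentrated_gene_low_p_uniform_gene_high_p(self, small_tax):
        # one gene concentrated in X, another spread evenly over the level
        rows = [("hot", "X", 40)]
        rows += [("flat", s, 10) for s in ("X", "Y", "Z", "W")]
        rows += [(f"f{i}", s, 10) for s in ("X", "Y", "Z", "W") for i in range(6)]
        counts = normalize_scp_counts(cm(rows), small_tax, PopulationConfig())
        pdf = gene_pvalues(counts, small_tax, "same_level", 3)
        p_hot = pdf[(pdf.gene == "hot")]["p"].iloc[0]
        p_flat = pdf[(pdf.gene == "flat") & (pdf.scp_id == "X")]["p"].iloc[0]
        assert p_hot < 1e-6 < 0.2 < p_flat

    def test_identical_sibling_count_vectors_give_identical_p(self, small_tax):
        rows = [("g1", "X", 5), ("g2", "X", 7), ("g1", "Y", 5), ("g2", "Y", 7)]
        counts = normalize_scp_counts(cm(rows), small_tax, PopulationConfig())
        pdf = gene_pvalues(counts, small_tax, "children_set", "P1")
        for g in ("g1", "g2"):
            ps = pdf[pdf.gene == g]["p"]
            assert ps.nunique() == 1

    def test_same_level_background_of_one_rejected(self, small_tax):
        counts = normalize_scp_counts(cm([("g", "X", 5)]), small_tax, PopulationConfig())
        with pytest.raises(OntologyError, match="more than one"):
            gene_pvalues(counts, small_tax, "same_level", 3)

    def test_monotone_in_own_count(self, small_tax):
        base = [("g", "Y", 10)] + [(f"f{i}", s, 10) for s in ("X", "Y", "Z", "W")
                                   for i in range(5)]
        prev = 1.1
        for own in (2, 6, 12, 24, 48):
            counts = normalize_scp_counts(cm(base + [("g", "X", own)]),
                                          small_tax, PopulationConfig())
            pdf = gene_pvalues(counts, small_tax, "same_level", 3)
            p = pdf[(pdf.gene == "g") & (pdf.scp_id == "X")]["p"].iloc[0]
            assert p <= prev + 1e-12
            prev = p


class TestEnrichAndFilter:
    def test_true_label_reinstated_despite_poor_p(self, small_tax):
        rows = [("g", "X", 30), ("g", "Y", 3)]
        rows += [(f"f{i}", s, 10) for s in ("X", "Y", "Z", "W") for i in range(5)]
        counts = normalize_scp_counts(cm(rows), small_tax, PopulationConfig())
        labels = ValidationLabelSet({("g", "Y"): "T"})
        filtered, pdf = enrich_and_filter(counts, small_tax, "same_level", 3, labels)
        kept = set(zip(filtered.counts["gene"], filtered.counts["scp_id"]))
        assert ("g", "Y") in kept and ("g", "X") in kept
        rein = pdf[(pdf.gene == "g") & (pdf.scp_id == "Y")]["reinstated"].iloc[0]
        assert bool(rein)

    def test_without_label_poor_association_removed(self, small_tax):
        rows = [("g", "X", 30), ("g", "Y", 3)]
        rows += [(f"f{i}", s, 10) for s in ("X", "Y", "Z", "W") for i in range(5)]
        counts = normalize_scp_counts(cm(rows), small_tax, PopulationConfig())
        filtered, _ = enrich_and_filter(counts, small_tax, "same_level", 3, None)
        kept = set(zip(filtered.counts["gene"], filtered.counts["scp_id"]))
        assert ("g", "X") in kept and ("g", "Y") not in kept


class TestInheritanceAndPropagation:
    def test_level1_candidate_needs_child_or_grandchild(self, small_tax):
        populated = pd.DataFrame(
            [{"gene": "ga", "scp_id": "X"}, {"gene": "gb", "scp_id": "P1"}]
        )
        cand = cm([("ga", "A1", 6), ("gb", "A1", 6), ("gc", "A1", 6)])
        out = inherit_filter(cand, populated, small_tax, 1)
        kept = set(out.counts["gene"])
        assert kept == {"ga", "gb"}  # gc appears nowhere below

    def test_level4_candidate_needs_level3_parent(self, small_tax):
        populated = pd.DataFrame([{"gene": "ga", "scp_id": "X"},
                                  {"gene": "gb", "scp_id": "Y"}])
        cand = cm([("ga", "X4", 2), ("gb", "X4", 2)])
        out = inherit_filter(cand, populated, small_tax, 4)
        assert set(out.counts["gene"]) == {"ga"}

    def test_level4_with_empty_parent_loses_all(self, small_tax):
        populated = pd.DataFrame([{"gene": "gb", "scp_id": "Y"}])
        out = inherit_filter(cm([("ga", "X4", 2)]), populated, small_tax, 4)
        assert out.counts.empty

    def test_inherit_before_population_rejected(self, small_tax):
        with pytest.raises(OntologyError, match="before levels 2-3"):
            inherit_filter(cm([("g", "A1", 5)]), pd.DataFrame(columns=["gene", "scp_id"]),
                           small_tax, 1)

    def test_propagation_lifts_level3_genes_without_duplicates(self, small_tax):
        df = pd.DataFrame([
            {"gene": "ga", "scp_id": "X", "origin": "enriched"},
            {"gene": "ga", "scp_id": "P1", "origin": "enriched"},
            {"gene": "gb", "scp_id": "Y", "origin": "enriched"},
        ])
        out = propagate_upward(df, small_tax)
        pairs = set(zip(out["gene"], out["scp_id"]))
        assert {("ga", "P1"), ("ga", "A1"), ("gb", "P1"), ("gb", "A1")} <= pairs
        assert len(pairs) == len(out)  # no duplicate rows
        # containment: children union subset of parent, for every parent
        for parent, lvl in (("P1", 3), ("A1", 2)):
            children = small_tax.children(parent)
            union = {g for g, s in pairs if s in children}
            parent_genes = {g for g, s in pairs if s == parent}
            assert union <= parent_genes


class TestRanking:
    def test_rank_by_pvalue_then_count_then_symbol(self):
        df = pd.DataFrame([
            {"gene": "g1", "scp_id": "X", "p_children_set": 1e-5, "adjusted_count": 1.0},
            {"gene": "g2", "scp_id": "X", "p_children_set": 1e-2, "adjusted_count": 1.0},
            {"gene": "g3", "scp_id": "X", "p_children_set": 1e-2, "adjusted_count": 10.0},
            {"gene": "g4", "scp_id": "Y", "p_children_set": 0.5, "adjusted_count": 1.0},
        ])
        out = rank_genes(df)
        ranks = {(r.gene, r.scp_id): r.rank for r in out.itertuples(index=False)}
        assert ranks[("g1", "X")] == 1
        assert ranks[("g3", "X")] == 2  # tie on p broken by higher count
        assert ranks[("g2", "X")] == 3
        assert ranks[("g4", "Y")] == 1  # singleton SCP


class TestPopulate:
    def test_false_positive_removed_true_and_unlabeled_kept(self, small_study):
        spec, tax, truth, counts = small_study
        genes = sorted(truth)
        g_fp = genes[0]
        labels = ValidationLabelSet({(g_fp, truth[g_fp]): "F"})
        table = populate(counts, tax, labels)
        assert (g_fp, truth[g_fp]) not in set(zip(table.df["gene"], table.df["scp_id"]))

    def test_deterministic_byte_identical_output(self, small_study):
        spec, tax, truth, counts = small_study
        outs = []
        for _ in range(2):
            buf = io.StringIO()
            save_associations(populate(counts, tax, None), buf)
            outs.append(buf.getvalue())
        assert outs[0] == outs[1]

    def test_hierarchical_containment_after_populate(self, small_study):
        spec, tax, truth, counts = small_study
        table = populate(counts, tax, None).df
        pairs = set(zip(table["gene"], table["scp_id"]))
        for gene, scp in pairs:
            lvl = tax.level(scp)
            if lvl >= 2:
                assert (gene, tax.parent(scp)) in pairs
            if lvl == 3:
                gp = tax.ancestor_at_level(scp, 1)
                assert (gene, gp) in pairs

    def test_planted_membership_recovered_on_small_fixture(self, small_study):
        spec, tax, truth, counts = small_study
        table = populate(counts, tax, None).df
        lv3 = table[table["scp_id"].map(lambda s: tax.level(s) == 3).astype(bool)]
        pred = set(zip(lv3["gene"], lv3["scp_id"]))
        true = set(truth.items())
        tp = len(pred & true)
        assert tp / len(pred) >= 0.8
        assert tp / len(true) >= 0.7

    def test_remove_false_positives_only_drops_f(self):
        df = pd.DataFrame([
            {"gene": "g1", "scp_id": "X"}, {"gene": "g2", "scp_id": "X"},
            {"gene": "g3", "scp_id": "X"},
        ])
        labels = ValidationLabelSet({("g1", "X"): "F", ("g2", "X"): "T"})
        out = remove_false_positives(df, labels)
        assert set(out["gene"]) == {"g2", "g3"}
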