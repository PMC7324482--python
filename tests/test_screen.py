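"""Expression screen: fold-change classification, candidate selection,
Venn bookkeeping, and ARE enrichment statistics."""

import numpy as np
import pandas as pd
import pytest

from arescreen.screen import (
    ScreenConfig,
    are_enrichment,
    classify_regulation,
    compute_fold_change,
    filter_by_gene_set,
    proportion_percent,
    read_expression_table,
    select_candidates,
)


class TestFoldChange:
    @pytest.mark.parametrize(
        ("control", "treatment", "pc", "expected"),
        [
            (4.0, 1.0, 0.0, ("down", 4.0)),
            (2.0, 2.0, 0.01, ("flat", 1.0)),
            (0.0, 3.0, 0.01, ("up", 301.0)),
            (1.0, 4.0, 0.0, ("up", 4.0)),
        ],
    )
    def test_examples(self, control, treatment, pc, expected):
        direction, magnitude = compute_fold_change(control, treatment, pc)
        assert direction == expected[0]
        assert magnitude == pytest.approx(expected[1])

    def test_negative_pseudocount_rejected(self):
        with pytest.raises(ValueError):
            compute_fold_change(1.0, 2.0, -0.1)

    def test_magnitude_always_at_least_one(self):
        rng = np.random.default_rng(0)
        for a, b in rng.uniform(0, 50, size=(200, 2)):
            _, mag = compute_fold_change(a, b)
            assert mag >= 1.0


class TestClassifyRegulation:
    def test_abundance_filter_boundary(self):
        df = pd.DataFrame(
            {"gene_id": ["x"], "fpkm_control": [1.9], "fpkm_treatment": [1.0]}
        )
        up, down = classify_regulation(df)
        assert up == set() and down == set()

    def test_inclusive_threshold_at_exact_ratio(self):
        # with pseudocount 0 the ratio is exactly 1.5 and >= is inclusive
        df = pd.DataFrame(
            {"gene_id": ["x"], "fpkm_control": [3.0], "fpkm_treatment": [2.0]}
        )
        _, down = classify_regulation(df, ScreenConfig(pseudocount=0.0))
        assert down == {"x"}

    def test_toy_table_hand_enumeration(self, toy_expression):
        up, down = classify_regulation(toy_expression)
        assert up == {"u1", "u2"}
        assert down == {"d1", "d2", "d3"}
        assert up & down == set()

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            classify_regulation(pd.DataFrame(columns=["gene_id", "fpkm_control", "fpkm_treatment"]))


class TestSelectCandidates:
    def test_toy_hand_enumerated_venn(self, toy_expression):
        # ARE-positive: d1, d3 (both candidates: expressed + >=2-fold down),
        # u1 (expressed, not down), low (neither expressed nor down)
        are = {"d1", "d3", "u1", "low"}
        result = select_candidates(toy_expression, are)
        assert result.candidate_set == {"d1", "d3"}
        # expressed = all except low/zz; >=2-fold down = {d1, d3}
        assert result.venn_counts == {
            "expressed_only": 5,   # u2, d2, flat, mild, mildup
            "down_only": 0,
            "are_only": 1,         # low
            "expressed_down": 0,
            "expressed_are": 1,    # u1
            "down_are": 0,
            "expressed_down_are": 2,
        }
        union = (
            result.expressed_set | result.down2fold_set | result.are_positive_set
        )
        assert sum(result.venn_counts.values()) == len(union)

    def test_empty_are_set_gives_no_candidates(self, toy_expression):
        result = select_candidates(toy_expression, set())
        assert result.candidate_set == set()

    def test_all_criteria_degenerate_overlap(self):
        df = pd.DataFrame(
            {
                "gene_id": ["a", "b"],
                "fpkm_control": [10.0, 20.0],
                "fpkm_treatment": [2.0, 4.0],
            }
        )
        result = select_candidates(df, {"a", "b"})
        assert result.candidate_set == {"a", "b"}
        nonzero = {k: v for k, v in result.venn_counts.items() if v}
        assert nonzero == {"expressed_down_are": 2}

    def test_unknown_are_gene_rejected(self, toy_expression):
        with pytest.raises(ValueError, match="absent"):
            select_candidates(toy_expression, {"nope"})

    def test_raising_candidate_fc_never_grows_candidates(self):
        rng = np.random.default_rng(42)
        df = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(300)],
                "fpkm_control": rng.uniform(0, 20, 300),
                "fpkm_treatment": rng.uniform(0, 20, 300),
            }
        )
        are = set(df["gene_id"][rng.random(300) < 0.3])
        previous = None
        for fc in (1.5, 2.0, 3.0, 5.0, 10.0):
            current = select_candidates(df, are, ScreenConfig(fc_candidate=fc)).candidate_set
            if previous is not None:
                assert current <= previous
            previous = current


class TestEnrichment:
    def test_reported_proportions_round_to_one_decimal(self):
        assert proportion_percent(233, 620) == 37.6
        assert proportion_percent(4368, 24941) == 17.5

    def test_chi2_matches_hand_formula(self):
        # universe partitioned into the down set and the rest
        universe = {f"g{i}" for i in range(1000)}
        in_set = {f"g{i}" for i in range(100)}
        are = {f"g{i}" for i in range(60)} | {f"g{i}" for i in range(100, 280)}
        result = are_enrichment(in_set, are, universe)
        observed = result.table.astype(float)
        row = observed.sum(axis=1, keepdims=True)
        col = observed.sum(axis=0, keepdims=True)
        expected = row @ col / observed.sum()
        chi2_oracle = np.sum((observed - expected) ** 2 / expected)
        assert result.chi2 == pytest.approx(chi2_oracle, abs=1e-10)

    def test_odds_ratio_and_infinity_flag(self):
        universe = {f"g{i}" for i in range(100)}
        in_set = {f"g{i}" for i in range(10)}
        # every in-set gene ARE-positive -> b = 0 -> infinite odds ratio
        are = set(in_set) | {"g50"}
        result = are_enrichment(in_set, are, universe, method="fisher")
        assert result.odds_ratio_infinite

    def test_empty_in_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            are_enrichment(set(), {"g1"}, {"g1", "g2"})

    def test_permutation_drives_odds_ratio_to_one(self):
        # shuffling ARE labels across genes breaks the association
        rng = np.random.default_rng(7)
        universe = [f"g{i}" for i in range(2000)]
        in_set = set(universe[:300])
        odds = []
        for _ in range(40):
            labels = rng.permutation(2000) < 400
            are = {g for g, flag in zip(universe, labels) if flag}
            odds.append(are_enrichment(in_set, are, set(universe)).odds_ratio)
        median = float(np.median(odds))
        assert 0.8 < median < 1.25


class TestGeneSetFilter:
    def test_tf_intersection_preserves_order(self):
        candidates = ["Klf2", "Irf8", "Ikzf2", "Gzmb"]
        tf_set = ["Foxp3", "Ikzf2", "Irf8", "Klf2"]
        assert filter_by_gene_set(candidates, tf_set) == ["Klf2", "Irf8", "Ikzf2"]

    def test_disjoint_sets(self):
        assert filter_by_gene_set(["a", "b"], ["c"]) == []

    def test_identity(self):
        assert filter_by_gene_set(["a", "b"], ["a", "b"]) == ["a", "b"]

    def test_case_sensitive(self):
        assert filter_by_gene_set(["Klf2"], ["klf2"]) == []


class TestExpressionIO:
    def test_round_trip(self, tmp_path, toy_expression):
        path = tmp_path / "expr.tsv"
        toy_expression.to_csv(path, sep="\t", index=False)
        df = read_expression_table(path)
        pd.testing.assert_frame_equal(df, toy_expression)

    def test_duplicate_gene_rejected(self, tmp_path):
        path = tmp_path / "expr.tsv"
        path.write_text(
            "gene_id\tfpkm_control\tfpkm_treatment\ng1\t1\t2\ng1\t3\t4\n"
        )
        with pytest.raises(ValueError, match="duplicate"):
            read_expression_table(path)

    def test_negative_fpkm_rejected(self, tmp_path):
        path = tmp_path / "expr.tsv"
        path.write_text("gene_id\tfpkm_control\tfpkm_treatment\ng1\t-1\t2\n")
        with pytest.raises(ValueError, match="negative"):
            read_expression_table(path)
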