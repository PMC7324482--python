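"""Reporter normalisation, ARE deletion constructs, CFSE indices, and
group-comparison statistics."""

import math

import numpy as np
import pandas as pd
import pytest

from arescreen.are_scan import UTRRecord, find_are_sites, scan_utr_set
from arescreen.readouts import (
    GenerationCounts,
    delete_are_from_utr,
    group_compare,
    proliferation_summary,
    relative_reporter_activity,
)


def wells_frame(rows):
    return pd.DataFrame(rows, columns=["condition", "firefly", "renilla"])


class TestReporter:
    def test_exact_halving(self):
        wells = wells_frame(
            [("ctrl", 2.0, 1.0), ("ctrl", 2.0, 1.0), ("test", 1.0, 1.0), ("test", 1.0, 1.0)]
        )
        summary = relative_reporter_activity(wells, "ctrl")
        assert summary.loc["ctrl", "relative_activity"] == 1.0
        assert summary.loc["test", "relative_activity"] == pytest.approx(0.5)

    def test_hand_computed_three_conditions(self):
        wells = wells_frame(
            [
                ("ctrl", 4.0, 2.0),   # ratio 2
                ("ctrl", 6.0, 2.0),   # ratio 3 -> mean 2.5
                ("a", 1.0, 1.0),      # ratio 1
                ("a", 4.0, 2.0),      # ratio 2 -> mean 1.5
                ("b", 10.0, 1.0),     # ratio 10
                ("b", 10.0, 2.0),     # ratio 5 -> mean 7.5
            ]
        )
        summary = relative_reporter_activity(wells, "ctrl")
        assert summary.loc["a", "relative_activity"] == pytest.approx(1.5 / 2.5)
        assert summary.loc["b", "relative_activity"] == pytest.approx(7.5 / 2.5)
        # mean of per-well ratios, not ratio of means
        assert summary.loc["b", "mean_ratio"] == pytest.approx(7.5)

    def test_missing_control_rejected(self):
        with pytest.raises(ValueError, match="control"):
            relative_reporter_activity(wells_frame([("a", 1.0, 1.0)]), "ctrl")

    def test_nonpositive_reading_rejected(self):
        with pytest.raises(ValueError, match="> 0"):
            relative_reporter_activity(wells_frame([("ctrl", 0.0, 1.0)]), "ctrl")

    def test_invariance_under_uniform_rescaling(self):
        rng = np.random.default_rng(1)
        rows = [
            (cond, float(f), float(r))
            for cond in ("ctrl", "a", "b")
            for f, r in rng.uniform(1, 10, size=(3, 2))
        ]
        base = relative_reporter_activity(wells_frame(rows), "ctrl")
        scaled_rows = [(c, f * 7.0, r) for c, f, r in rows]
        scaled = relative_reporter_activity(wells_frame(scaled_rows), "ctrl")
        np.testing.assert_allclose(
            base["relative_activity"], scaled["relative_activity"]
        )


class TestDeleteAre:
    def test_splice_arithmetic(self):
        utr = UTRRecord(gene_id="g1", sequence="AATATTTATCC")
        hits = scan_utr_set([utr])[0]["g1"]
        assert (hits[0].start, hits[0].end) == (2, 9)
        out = delete_are_from_utr(utr, hits, which=1)
        assert out.sequence == "AACC"
        assert out.length == utr.length - 7

    def test_sequential_deletion_removes_all_hits(self):
        seq = "GG" + "TATTTAT" + "CCCC" + "TATTTAT" + "GG"
        utr = UTRRecord(gene_id="g", sequence=seq)
        hits = scan_utr_set([utr])[0]["g"]
        assert len(hits) == 2
        once = delete_are_from_utr(utr, hits, which=1)
        hits2 = scan_utr_set([once])[0].get(once.gene_id, [])
        assert len(hits2) == 1
        twice = delete_are_from_utr(once, hits2, which=1)
        assert find_are_sites(twice.normalized) == []

    def test_ordinal_out_of_range(self):
        utr = UTRRecord(gene_id="g", sequence="AATATTTATCC")
        hits = scan_utr_set([utr])[0]["g"]
        with pytest.raises(ValueError, match="out of range"):
            delete_are_from_utr(utr, hits, which=4)

    def test_fusion_warning_when_splice_recreates_motif(self):
        # deleting the single hit fuses TATTT + AT into a fresh motif
        seq = "CCTATTT" + "TATTTAT" + "ATCC"
        utr = UTRRecord(gene_id="g", sequence=seq)
        hits = scan_utr_set([utr])[0]["g"]
        assert len(hits) == 1
        with pytest.warns(UserWarning, match="splice junction"):
            out = delete_are_from_utr(utr, hits, which=1)
        assert len(find_are_sites(out.normalized)) == 1


class TestProliferation:
    def test_no_division(self):
        s = proliferation_summary([100, 0, 0])
        assert s.percent_undivided == 100.0
        assert s.division_index == 0.0
        assert s.proliferation_index is None

    def test_all_divided_once(self):
        s = proliferation_summary([0, 200])
        assert s.percent_undivided == 0.0
        assert s.division_index == 1.0
        assert s.proliferation_index == 1.0

    def test_hand_arithmetic(self):
        # counts [50, 100, 200] -> precursors [50, 50, 50]
        s = proliferation_summary([50, 100, 200])
        assert s.division_index == pytest.approx(1.0)
        assert s.proliferation_index == pytest.approx(1.5)
        assert s.percent_undivided == pytest.approx(100 * 50 / 350)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            proliferation_summary([0, 0, 0])

    def test_division_index_scale_invariant(self):
        base = proliferation_summary([30, 60, 90, 20])
        scaled = proliferation_summary([300, 600, 900, 200])
        assert base.division_index == pytest.approx(scaled.division_index)
        assert base.proliferation_index == pytest.approx(scaled.proliferation_index)

    def test_division_never_exceeds_proliferation_index(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            counts = rng.integers(0, 500, size=6)
            if counts.sum() == 0:
                continue
            s = proliferation_summary(counts.tolist())
            if s.proliferation_index is not None:
                assert s.division_index <= s.proliferation_index + 1e-12

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            GenerationCounts((10, -1))


class TestGroupCompare:
    def test_two_group_matches_pooled_variance_formula(self):
        a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        result = group_compare({"a": a, "b": b}, "two-group")
        # hand-computed pooled-variance t
        sp2 = (2 * 1.0 + 2 * 1.0) / 4
        t_oracle = (np.mean(a) - np.mean(b)) / math.sqrt(sp2 * (1 / 3 + 1 / 3))
        assert result.statistic == pytest.approx(t_oracle, rel=1e-12)
        assert result.method == "student_t"
        assert result.p_value < 0.05

    def test_identical_groups_null(self):
        result = group_compare({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]}, "two-group")
        assert result.statistic == pytest.approx(0.0, abs=1e-12)
        assert result.p_value == pytest.approx(1.0)

    def test_welch_option(self):
        result = group_compare(
            {"a": [1.0, 2.0, 3.0], "b": [4.0, 8.0, 12.0]}, "two-group", welch=True
        )
        assert result.method == "welch_t"

    def test_multi_group_anova_with_tukey(self):
        groups = {
            "a": [1.0, 2.0, 3.0],
            "b": [1.5, 2.5, 3.5],
            "c": [9.0, 10.0, 11.0],
        }
        result = group_compare(groups, "multi-group")
        assert result.method == "anova_tukey"
        assert result.p_value < 0.05
        assert len(result.pairwise) == 3  # all pairs

    def test_anova_type_i_error_roughly_calibrated(self):
        rng = np.random.default_rng(123)
        pvals = []
        for _ in range(200):
            groups = {k: rng.normal(0, 1, 20) for k in "abc"}
            pvals.append(group_compare(groups, "multi-group").p_value)
        # under the null, p-values should be roughly uniform
        rate = np.mean(np.asarray(pvals) < 0.05)
        assert 0.01 <= rate <= 0.10

    def test_categorical_chi2(self):
        result = group_compare(np.array([[20, 80], [40, 60]]), "categorical")
        assert result.method == "chi2"
        assert result.p_value < 0.05

    def test_degenerate_group_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            group_compare({"a": [1.0], "b": [1.0, 2.0]}, "two-group")
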