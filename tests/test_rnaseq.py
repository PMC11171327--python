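"""Read assignment, FPKM, BH adjustment, and the DE filter."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from xenoresp.rnaseq import (
    GeneRecord,
    ReadPairSummary,
    ResponderGrouping,
    assign_read,
    assign_reads,
    bh_adjust,
    de_filter,
    de_filter_table,
    fpkm,
    retained_for_quantification,
)
from xenoresp.syndata import simulate_read_pairs


def pair(**kw):
    base = dict(read_id="r1")
    base.update(kw)
    return ReadPairSummary(**base)


class TestAssignRead:
    def test_four_classes(self):
        assert assign_read(pair()) == "unaligned"
        assert assign_read(pair(aligned_h=True, score_h=90)) == "human_only"
        assert assign_read(pair(aligned_m=True, score_m=90)) == "mouse_only"
        tie = pair(aligned_h=True, aligned_m=True, score_h=90, score_m=90,
                   mismatches_h=1, mismatches_m=1, matchlen_h=180, matchlen_m=180)
        assert assign_read(tie) == "common"

    def test_score_dominates(self):
        p = pair(aligned_h=True, aligned_m=True, score_h=90, score_m=80)
        assert assign_read(p) == "human_only"

    def test_mismatches_break_score_ties(self):
        p = pair(aligned_h=True, aligned_m=True, score_h=90, score_m=90,
                 mismatches_h=3, mismatches_m=1)
        assert assign_read(p) == "mouse_only"

    def test_matchlen_breaks_remaining_ties(self):
        p = pair(aligned_h=True, aligned_m=True, score_h=90, score_m=90,
                 mismatches_h=1, mismatches_m=1, matchlen_h=190, matchlen_m=150)
        assert assign_read(p) == "human_only"

    def test_tolerance_turns_near_ties_into_common(self):
        p = pair(aligned_h=True, aligned_m=True, score_h=90, score_m=88)
        assert assign_read(p, tolerance=0) == "human_only"
        assert assign_read(p, tolerance=5) == "common"

    def test_negative_matchlen_rejected(self):
        with pytest.raises(ValueError):
            pair(matchlen_h=-1)

    def test_synthetic_truth_recovered_and_ties_common(self):
        df = simulate_read_pairs(300, 300, 100, score_margin=8.0, seed=2)
        assigned = assign_reads(df, tolerance=0.0)
        truth = df["true_origin"]
        assert (assigned[truth == "human"] == "human_only").all()
        assert (assigned[truth == "mouse"] == "mouse_only").all()
        assert (assigned[truth == "ambiguous"] == "common").all()


class TestRetained:
    def test_keeps_human_only_and_common(self):
        s = pd.Series(["human_only", "mouse_only", "common", "unaligned"])
        assert retained_for_quantification(s).tolist() == [True, False, True, False]

    def test_all_mouse_yields_empty(self):
        s = pd.Series(["mouse_only"] * 4)
        assert retained_for_quantification(s).sum() == 0


class TestFpkm:
    def test_unit_construction(self):
        assert fpkm(10, 1000, 10**6) == pytest.approx(10.0)

    def test_zero_counts_zero_fpkm(self):
        assert fpkm(0, 500, 10**6) == 0.0

    def test_scales_inversely_with_library_size(self):
        a = fpkm(100, 2000, 1_000_000)
        b = fpkm(100, 2000, 2_000_000)
        assert a == pytest.approx(2 * b)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            fpkm(1, 0, 100)
        with pytest.raises(ValueError):
            fpkm(1, 100, 0)


def brute_force_bh(p):
    """Adjusted p straight from the step-up definition."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    out = np.empty(n)
    for i, pi in enumerate(p):
        candidates = []
        for j, pj in enumerate(p):
            if pj >= pi:
                # smallest q at which hypothesis i is rejected
                candidates.append(pj * n / np.sum(p <= pj))
        out[i] = min(1.0, min(candidates))
    return out


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_hand_worked_vector(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_order_preserving(self):
        # smaller raw p never gets a larger adjusted p
        rng = np.random.default_rng(9)
        p = rng.uniform(size=50)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_bounded_by_max_p_and_one(self):
        p = np.array([0.001, 0.2, 0.04, 0.9, 0.04])
        adj = bh_adjust(p)
        assert np.all(adj <= 1.0)
        assert adj.max() == pytest.approx(p.max())

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=12))
    @settings(max_examples=200, deadline=None)
    def test_equals_brute_force_definition(self, p):
        assert np.allclose(bh_adjust(p), brute_force_bh(p))

    def test_agrees_with_statsmodels(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=200)
        ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(bh_adjust(p), ref)


class TestDeFilter:
    def rec(self, gene, fc, p, mean_fpkm=5.0):
        return GeneRecord(gene_id=gene, length_bp=1000, mean_fpkm=mean_fpkm,
                          log2fc=np.log2(fc), pvalue=p)

    def test_strong_up_and_down_regulation(self):
        recs = [
            self.rec("BRINP3", 52.6, 3.8e-6),     # log2fc ~ 5.72 -> up
            self.rec("FOXP1", 0.005, 9.0e-7),     # log2fc ~ -7.64 -> down
            self.rec("FLAT", 1.1, 0.9),
        ]
        out = {r.gene_id: r.call for r in de_filter(recs)}
        assert out == {"BRINP3": "up", "FOXP1": "down", "FLAT": "unchanged"}

    def test_boundary_log2fc_is_strict(self):
        recs = [self.rec("G", 2.0, 1e-5)]  # log2fc exactly 1.0
        assert de_filter(recs)[0].call == "unchanged"

    def test_low_expression_suppresses_call(self):
        recs = [self.rec("G", 50.0, 1e-5, mean_fpkm=0.5)]
        assert de_filter(recs)[0].call == "unchanged"

    def test_adjusted_p_gate(self):
        # raw p below 0.05 but BH-adjusted above it
        recs = [self.rec("A", 8.0, 0.04)] + [self.rec(f"N{i}", 1.0, 0.9)
                                             for i in range(9)]
        out = de_filter(recs)
        assert out[0].padj == pytest.approx(0.4)
        assert out[0].call == "unchanged"

    def test_stable_under_row_permutation(self):
        rng = np.random.default_rng(4)
        recs = [self.rec(f"g{i}", fc, p)
                for i, (fc, p) in enumerate(zip(rng.uniform(0.01, 60, 30),
                                                rng.uniform(0, 1, 30)))]
        calls = {r.gene_id: (r.call, r.padj) for r in de_filter(recs)}
        shuffled = list(recs)
        rng.shuffle(shuffled)
        calls2 = {r.gene_id: (r.call, r.padj) for r in de_filter(shuffled)}
        assert calls == calls2

    def test_table_front_end(self):
        df = pd.DataFrame({
            "gene_id": ["A", "B"], "length_bp": [1000, 2000],
            "mean_fpkm": [5.0, 5.0], "log2fc": [2.0, -2.0],
            "pvalue": [1e-4, 1e-4],
        })
        out = de_filter_table(df)
        assert out["call"].tolist() == ["up", "down"]
        assert "padj" in out.columns


class TestResponderGrouping:
    def test_disjoint_partition(self):
        g = ResponderGrouping(good={"WT-16", "Rh-18", "RBD2"},
                              poor={"RBD1", "BT-29", "G401"})
        assert not (g.good & g.poor)

    def test_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            ResponderGrouping(good={"A"}, poor={"A", "B"})

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            ResponderGrouping(good=set(), poor={"B"})
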