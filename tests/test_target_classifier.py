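"""Evidence flags, timing classification, upset summaries and set algebra."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import brute_force_overlaps
from tfcascade.genomic_core import Gene, GenomicInterval, REM, tss_window
from tfcascade.target_classifier import (
    METHODS,
    classify_degs,
    combine_flags,
    compare_deg_sets,
    flag_motif_targets,
    flag_rem_targets,
    flag_window_targets,
    percentage,
    summarize_upset,
)


def make_gene(i, tss, chrom="chr1"):
    return Gene(f"G{i}", chrom, "+", tss, tss + 1_000)


class TestWindowFlags:
    def test_containment_and_boundary(self):
        gene = make_gene(0, 100_000)
        inside = [GenomicInterval("chr1", 99_000, 99_400)]
        at_end = [GenomicInterval("chr1", 125_000, 125_400)]  # starts at window end
        assert flag_window_targets(inside, [gene])["G0"]
        assert not flag_window_targets(at_end, [gene])["G0"]

    def test_agrees_with_brute_force_double_loop(self):
        rng = np.random.default_rng(3)
        genes = [
            make_gene(i, int(rng.integers(30_000, 2_000_000)),
                      chrom=f"chr{rng.integers(1, 3)}")
            for i in range(200)
        ]
        peaks = []
        for _ in range(200):
            start = int(rng.integers(0, 2_000_000))
            peaks.append(
                GenomicInterval(f"chr{rng.integers(1, 3)}", start,
                                start + int(rng.integers(100, 2_000)))
            )
        flags = flag_window_targets(peaks, genes)
        windows = [tss_window(g) for g in genes]
        expected_hits = {i for i, _ in brute_force_overlaps(windows, peaks)}
        for i, g in enumerate(genes):
            assert flags[g.gene_id] == (i in expected_hits)


class TestRemFlags:
    def test_link_direction_and_overlap_rule(self):
        peaks = [GenomicInterval("chr1", 500, 700)]
        rems = [
            REM(GenomicInterval("chr1", 600, 900), "R1", "G1"),   # overlaps
            REM(GenomicInterval("chr1", 5_000, 5_200), "R2", "G2"),  # does not
        ]
        flags = flag_rem_targets(peaks, rems)
        assert flags["G1"] and not flags["G2"]

    def test_unresolved_gene_excluded_with_warning(self, caplog):
        peaks = [GenomicInterval("chr1", 0, 100)]
        rems = [REM(GenomicInterval("chr1", 50, 80), "R1", "GHOST")]
        with caplog.at_level("WARNING"):
            flags = flag_rem_targets(peaks, rems, known_genes=["G1"])
        assert "GHOST" not in flags.index
        assert "unresolved" in caplog.text

    def test_counts_match_brute_force_set_logic(self):
        rng = np.random.default_rng(4)
        peaks = []
        for _ in range(50):
            start = int(rng.integers(0, 100_000))
            peaks.append(GenomicInterval("chr1", start, start + 300))
        rems = []
        for i in range(80):
            start = int(rng.integers(0, 100_000))
            rems.append(
                REM(GenomicInterval("chr1", start, start + 400), f"R{i}",
                    f"G{rng.integers(0, 20)}")
            )
        flags = flag_rem_targets(peaks, rems)
        overlapping = {i for i, _ in brute_force_overlaps(
            [r.region for r in rems], peaks)}
        expected = {}
        for i, rem in enumerate(rems):
            expected[rem.linked_gene] = expected.get(rem.linked_gene, False) or (
                i in overlapping
            )
        assert dict(flags) == expected


class TestMotifFlags:
    def matrix(self):
        return pd.DataFrame(
            {"VDR": [0.5, 0.0, 1e-9], "OTHER": [0.0, 1.0, 0.0]},
            index=["G1", "G2", "G3"],
        )

    def test_positive_score_rule(self):
        flags = flag_motif_targets(self.matrix(), "VDR")
        assert flags["G1"] and not flags["G2"] and flags["G3"]

    def test_missing_tf_raises(self):
        with pytest.raises(KeyError):
            flag_motif_targets(self.matrix(), "ABSENT")

    def test_invariant_under_row_shuffle(self):
        base = flag_motif_targets(self.matrix(), "VDR")
        shuffled = flag_motif_targets(
            self.matrix().sample(frac=1.0, random_state=0), "VDR"
        )
        assert dict(shuffled) == dict(base)


def deg(genes_padj):
    return pd.DataFrame(
        [{"gene_id": g, "log2fc": 1.0, "padj": p} for g, p in genes_padj]
    )


class TestClassifyDegs:
    def setup_method(self):
        self.flags = combine_flags(
            ["A", "B", "C", "D"],
            window_peak=pd.Series({"A": True, "B": True}),
            rem_overlap=pd.Series({"B": True}),
        )
        self.tables = {
            "4h": deg([("A", 0.01), ("B", 0.2), ("C", 0.5), ("D", 0.9)]),
            "24h": deg([("A", 0.001), ("B", 0.001), ("C", 0.01), ("D", 0.9)]),
        }

    def classify(self, k=1):
        return classify_degs(self.tables, self.flags, ["4h"], ["24h"], k_methods=k)

    def test_timing_rules(self):
        cls = self.classify()
        assert cls.at["A", "timing"] == "early"    # significant at 4 h and 24 h
        assert cls.at["B", "timing"] == "late"     # 24 h only
        assert "D" not in cls.index                # never significant

    def test_stringency_rule(self):
        k1, k2 = self.classify(1), self.classify(2)
        assert k1.at["B", "is_primary"] and k2.at["B", "is_primary"]  # 2 methods
        assert k1.at["A", "is_primary"] and not k2.at["A", "is_primary"]
        assert not k1.at["C", "is_primary"]

    def test_stringency_monotone_on_random_inputs(self):
        rng = np.random.default_rng(12)
        gene_ids = [f"G{i}" for i in range(60)]
        flags = combine_flags(
            gene_ids,
            window_peak=pd.Series(rng.random(60) < 0.5, index=gene_ids),
            rem_overlap=pd.Series(rng.random(60) < 0.3, index=gene_ids),
            motif_open_chromatin=pd.Series(rng.random(60) < 0.4, index=gene_ids),
        )
        tables = {
            "4h": deg([(g, float(rng.random())) for g in gene_ids]),
            "24h": deg([(g, float(rng.random())) for g in gene_ids]),
        }
        primaries = [
            set(
                classify_degs(tables, flags, ["4h"], ["24h"], k_methods=k)
                .query("is_primary").index
            )
            for k in (1, 2, 3)
        ]
        assert primaries[2] <= primaries[1] <= primaries[0]

    def test_padj_cutoff_is_strict(self):
        tables = {"4h": deg([("A", 0.05)]), "24h": deg([("A", 0.05)])}
        cls = classify_degs(tables, self.flags, ["4h"], ["24h"])
        assert len(cls) == 0

    def test_early_plus_late_covers_all_significant(self):
        cls = self.classify()
        sig = {"A", "B", "C"}
        assert (cls["timing"] == "early").sum() + (cls["timing"] == "late").sum() == len(sig)


class TestPercentage:
    def test_one_decimal_rounding(self):
        assert percentage(234, 383) == 61.1
        assert percentage(1, 3) == 33.3
        assert percentage(2, 3) == 66.7

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            percentage(1, 0)
        with pytest.raises(ValueError):
            percentage(5, 3)


class TestUpsetSummary:
    def toy(self):
        flags = combine_flags(
            ["A", "B", "C"],
            window_peak=pd.Series({"A": True, "B": True}),
            rem_overlap=pd.Series({"B": True}),
            motif_open_chromatin=pd.Series({"C": True}),
        )
        tables = {
            "4h": deg([("A", 0.01), ("B", 0.5), ("C", 0.5)]),
            "24h": deg([("A", 0.01), ("B", 0.01), ("C", 0.01)]),
        }
        cls = classify_degs(tables, flags, ["4h"], ["24h"])
        return summarize_upset(cls, flags), cls

    def test_toy_counts_match_hand_enumeration(self):
        upset, _ = self.toy()
        assert upset.counts["early"] == {("window_peak",): 1}
        assert upset.counts["late"] == {
            ("window_peak", "rem_overlap"): 1,
            ("motif_open_chromatin",): 1,
        }
        assert upset.n_predicted == {"early": 1, "late": 2}

    def test_totals_consistent_with_classification(self):
        upset, cls = self.toy()
        for timing in ("early", "late"):
            assert upset.n_degs[timing] == (cls["timing"] == timing).sum()
            assert upset.n_predicted[timing] == (
                (cls["timing"] == timing) & (cls["n_methods"] >= 1)
            ).sum()

    def test_percentages_recomputed_from_counts(self):
        upset, _ = self.toy()
        assert upset.percent_at_least(2, "late") == percentage(1, 2)
        frame = upset.to_frame()
        row = frame[(frame.timing == "late") & (frame.combination == "motif_open_chromatin")]
        assert row["percent"].iloc[0] == 50.0


class TestCompareDegSets:
    def test_identical_and_disjoint(self):
        s = {"x", "y"}
        both = compare_deg_sets({"a": s, "b": set(s)})
        assert both["a&b"] == 2 and both["a_only"] == 0 and both["b_only"] == 0
        disjoint = compare_deg_sets({"a": {"x"}, "b": {"y"}})
        assert disjoint["a&b"] == 0

    def test_three_set_partition(self):
        parts = compare_deg_sets(
            {"a": {1, 2, 3}, "b": {2, 3, 4}, "c": {3, 4, 5}}
        )
        assert parts["a&b&c"] == 1        # {3}
        assert parts["a&b"] == 1          # {2}
        assert parts["b&c"] == 1          # {4}
        assert parts["a&c"] == 0
        assert parts["a_only"] == 1 and parts["c_only"] == 1

    @given(
        a=st.sets(st.integers(0, 30)),
        b=st.sets(st.integers(0, 30)),
        c=st.sets(st.integers(0, 30)),
    )
    @settings(max_examples=50, derandomize=True)
    def test_partition_sizes_sum_to_union(self, a, b, c):
        parts = compare_deg_sets({"a": a, "b": b, "c": c})
        total = sum(v for k, v in parts.items() if k != "union")
        assert total == len(a | b | c) == parts["union"]

    def test_wrong_cardinality_rejected(self):
        with pytest.raises(ValueError):
            compare_deg_sets({"a": {1}})
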