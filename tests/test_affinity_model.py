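"""TRAP scanning, threshold calibration and decayed gene-score tests."""

import math

import numpy as np
import pandas as pd
import pytest

from conftest import naive_trap_affinity, random_dna
from tfcascade.affinity_model import (
    PWM,
    EnergyMatrix,
    TFGeneScoreMatrix,
    calibrate_threshold,
    compute_gene_tf_scores,
    dinucleotide_shuffle,
    make_background,
    parse_motifs,
    pwm_to_energy_matrix,
    trap_affinity,
)
from tfcascade.genomic_core import Gene, GenomicInterval, reverse_complement


def uniform_pwm(m=8, tf="U"):
    return PWM(tf_name=tf, matrix=np.full((4, m), 0.25))


def consensus_pwm(consensus, p=0.85, tf="C"):
    off = (1 - p) / 3
    mat = np.full((4, len(consensus)), off)
    for i, base in enumerate(consensus):
        mat["ACGT".index(base), i] = p
    return PWM(tf_name=tf, matrix=mat)


class TestEnergyMatrix:
    def test_uniform_column_gives_zero_energies(self):
        em = pwm_to_energy_matrix(uniform_pwm())
        assert np.allclose(em.energies, 0.0)

    def test_consensus_base_has_zero_energy(self):
        em = pwm_to_energy_matrix(consensus_pwm("ACGTACGT"))
        assert np.allclose(em.energies.min(axis=0), 0.0)

    def test_log_ratio_energy_value(self):
        # column (0.85, 0.05, 0.05, 0.05) at lambda 0.7: ln(17)/0.7
        pwm = PWM(tf_name="x", matrix=np.tile([[0.85], [0.05], [0.05], [0.05]], 8))
        em = pwm_to_energy_matrix(pwm, lambda_param=0.7)
        assert em.energies[1, 0] == pytest.approx(math.log(17) / 0.7, rel=1e-12)

    def test_r0_scaling_with_width(self):
        em = pwm_to_energy_matrix(uniform_pwm(m=12))
        assert em.ln_r0 == pytest.approx(0.584 * 12 - 5.66)

    def test_invalid_lambda(self):
        with pytest.raises(ValueError):
            pwm_to_energy_matrix(uniform_pwm(), lambda_param=0.0)

    def test_pseudocount_prevents_zero_probability(self):
        counts = np.zeros((4, 6))
        counts[0] = 100  # all-A consensus with zero counts elsewhere
        pwm = PWM.from_counts("a", counts)
        assert (pwm.matrix > 0).all()
        assert np.allclose(pwm.matrix.sum(axis=0), 1.0, atol=1e-6)


class TestTrapAffinity:
    def test_all_n_sequence_scores_zero(self):
        em = pwm_to_energy_matrix(consensus_pwm("ACGTAC"))
        assert trap_affinity(em, "N" * 40) == 0.0

    def test_short_sequence_warns_and_scores_zero(self, caplog):
        em = pwm_to_energy_matrix(consensus_pwm("ACGTACGT"))
        with caplog.at_level("WARNING"):
            assert trap_affinity(em, "ACG") == 0.0
        assert "shorter than motif" in caplog.text

    def test_zero_energy_single_window_closed_form(self):
        # uniform matrix: every window has E = 0 on both strands
        em = pwm_to_energy_matrix(uniform_pwm(m=6))
        r0 = math.exp(em.ln_r0)
        assert trap_affinity(em, "ACGTAC") == pytest.approx(
            2 * r0 / (1 + r0), rel=1e-12
        )

    def test_matches_naive_loop_oracle(self):
        rng = np.random.default_rng(5)
        em = pwm_to_energy_matrix(consensus_pwm("ACGTTGCAAC"))
        for _ in range(100):
            seq = random_dna(rng, 60)
            assert trap_affinity(em, seq) == pytest.approx(
                naive_trap_affinity(em, seq), abs=1e-9
            )

    def test_reverse_complement_invariance(self):
        rng = np.random.default_rng(6)
        em = pwm_to_energy_matrix(consensus_pwm("GATTACAGT"))
        for _ in range(20):
            seq = random_dna(rng, 80)
            assert trap_affinity(em, seq) == pytest.approx(
                trap_affinity(em, reverse_complement(seq)), abs=1e-9
            )

    def test_n_containing_windows_skipped(self):
        em = pwm_to_energy_matrix(consensus_pwm("ACGTAC"))
        clean = trap_affinity(em, "ACGTACGTAC")
        masked = trap_affinity(em, "ACGTACGTACNNNNNNACGTACGTAC")
        assert masked == pytest.approx(2 * clean, rel=1e-9)

    def test_monotone_under_planted_consensus(self):
        rng = np.random.default_rng(7)
        consensus = "GATTACAGTC"
        em = pwm_to_energy_matrix(consensus_pwm(consensus))
        for _ in range(10):
            seq = random_dna(rng, 50)
            assert trap_affinity(em, seq + consensus) >= trap_affinity(em, seq)


class TestCalibration:
    def test_dinucleotide_shuffle_preserves_doublets(self):
        rng = np.random.default_rng(8)
        seq = random_dna(rng, 200)
        shuffled = dinucleotide_shuffle(seq, rng)
        def doublets(s):
            counts = {}
            for a, b in zip(s, s[1:]):
                counts[a + b] = counts.get(a + b, 0) + 1
            return counts
        assert doublets(shuffled) == doublets(seq)
        assert shuffled[0] == seq[0] and shuffled[-1] == seq[-1]

    def test_threshold_matches_sorting_oracle(self):
        rng = np.random.default_rng(9)
        em = pwm_to_energy_matrix(consensus_pwm("ACGTTGCA"))
        base = [random_dna(rng, 60) for _ in range(5)]
        background = make_background(base, 1_000, rng)
        threshold = calibrate_threshold(em, background, p_value=0.05)
        affinities = sorted(trap_affinity(em, s) for s in background)
        # ceiling order statistic at the 95th percentile
        k = math.ceil(0.95 * (len(affinities) - 1))
        assert threshold == pytest.approx(affinities[k], rel=1e-12)

    def test_extreme_p_value_yields_maximum(self):
        rng = np.random.default_rng(10)
        em = pwm_to_energy_matrix(consensus_pwm("ACGTTGCA"))
        seqs = [random_dna(rng, 40) for _ in range(120)]
        affinities = [trap_affinity(em, s) for s in seqs]
        threshold = calibrate_threshold(em, seqs, p_value=1.0 / len(seqs))
        assert threshold == pytest.approx(max(affinities), rel=1e-12)

    def test_threshold_monotone_in_p_value(self):
        rng = np.random.default_rng(11)
        em = pwm_to_energy_matrix(consensus_pwm("ACGTTGCA"))
        seqs = [random_dna(rng, 40) for _ in range(150)]
        thresholds = [
            calibrate_threshold(em, seqs, p) for p in (0.01, 0.05, 0.2, 0.5, 0.95)
        ]
        assert all(a >= b for a, b in zip(thresholds, thresholds[1:]))

    def test_empty_random_set_rejected(self):
        em = pwm_to_energy_matrix(consensus_pwm("ACGTTG"))
        with pytest.raises(ValueError):
            calibrate_threshold(em, [], 0.05)


class TestGeneScores:
    def genes(self):
        return [Gene("g1", "chr1", "+", 100_000, 101_000)]

    def test_region_at_tss_has_decay_weight_one(self):
        regions = [GenomicInterval("chr1", 99_950, 100_050)]  # centre == tss
        aff = pd.DataFrame({"TF": [0.8]})
        mat = compute_gene_tf_scores(regions, aff, self.genes(), decay_constant=5_000)
        assert mat.scores.at["g1", "TF"] == pytest.approx(0.8, rel=1e-12)

    def test_region_at_decay_constant_weighted_e_minus_one(self):
        d0 = 5_000
        regions = [GenomicInterval("chr1", 100_000 + d0 - 50, 100_000 + d0 + 50)]
        aff = pd.DataFrame({"TF": [0.8]})
        mat = compute_gene_tf_scores(regions, aff, self.genes(), decay_constant=d0)
        assert mat.scores.at["g1", "TF"] == pytest.approx(
            0.8 * math.exp(-1), rel=1e-12
        )

    def test_additivity_over_regions(self):
        regions = [
            GenomicInterval("chr1", 99_000, 99_200),
            GenomicInterval("chr1", 104_000, 104_400),
        ]
        aff = pd.DataFrame({"TF": [0.5, 1.2]})
        combined = compute_gene_tf_scores(regions, aff, self.genes())
        parts = [
            compute_gene_tf_scores([r], aff.iloc[[i]].reset_index(drop=True),
                                   self.genes())
            for i, r in enumerate(regions)
        ]
        assert combined.scores.at["g1", "TF"] == pytest.approx(
            sum(p.scores.at["g1", "TF"] for p in parts), rel=1e-12
        )

    def test_monotone_decay_with_distance(self):
        aff = pd.DataFrame({"TF": [1.0]})
        scores = []
        for offset in (0, 2_000, 8_000, 20_000):
            regions = [GenomicInterval("chr1", 100_000 + offset - 100,
                                       100_000 + offset + 100)]
            mat = compute_gene_tf_scores(regions, aff, self.genes())
            scores.append(mat.scores.at["g1", "TF"])
        assert all(a > b for a, b in zip(scores, scores[1:]))

    def test_thresholding_zeroes_subthreshold_regions(self):
        regions = [GenomicInterval("chr1", 99_900, 100_100)]
        aff = pd.DataFrame({"TF": [0.3]})
        below = compute_gene_tf_scores(
            regions, aff, self.genes(), thresholds={"TF": 0.5}
        )
        at = compute_gene_tf_scores(
            regions, aff, self.genes(), thresholds={"TF": 0.3}
        )
        assert below.scores.at["g1", "TF"] == 0.0
        assert at.scores.at["g1", "TF"] > 0.0

    def test_gene_without_regions_scores_zero(self):
        regions = [GenomicInterval("chr2", 0, 100)]
        aff = pd.DataFrame({"TF": [5.0]})
        mat = compute_gene_tf_scores(regions, aff, self.genes())
        assert (mat.scores.to_numpy() == 0).all()

    def test_region_outside_window_excluded(self):
        regions = [GenomicInterval("chr1", 126_000, 126_200)]  # beyond +25 kb
        aff = pd.DataFrame({"TF": [5.0]})
        mat = compute_gene_tf_scores(regions, aff, self.genes())
        assert mat.scores.at["g1", "TF"] == 0.0

    def test_invalid_decay_constant(self):
        with pytest.raises(ValueError):
            compute_gene_tf_scores([], pd.DataFrame(), self.genes(),
                                   decay_constant=0.0)

    def test_motif_variant_max_aggregation(self):
        regions = [GenomicInterval("chr1", 99_950, 100_050)]
        aff = pd.DataFrame({"m1": [0.2], "m2": [0.9]})
        mat = compute_gene_tf_scores(
            regions, aff, self.genes(),
            motif_to_tf={"m1": "TF", "m2": "TF"}, variant_agg="max",
        )
        assert mat.scores.at["g1", "TF"] == pytest.approx(0.9, rel=1e-12)

    def test_tsv_round_trip(self, tmp_path):
        regions = [GenomicInterval("chr1", 99_950, 100_050)]
        aff = pd.DataFrame({"TF": [0.8]})
        mat = compute_gene_tf_scores(regions, aff, self.genes(), condition="treated")
        path = tmp_path / "scores.tsv"
        mat.to_tsv(path)
        back = TFGeneScoreMatrix.from_tsv(path)
        assert back.condition == "treated"
        pd.testing.assert_frame_equal(back.scores, mat.scores)


class TestMotifParsing:
    def test_jaspar_dialect(self, tmp_path):
        path = tmp_path / "m.jaspar"
        path.write_text(
            ">MA0001.1 TFA\n"
            "A [ 10 0 0 5 ]\n"
            "C [ 0 10 0 5 ]\n"
            "G [ 0 0 10 0 ]\n"
            "T [ 0 0 0 0 ]\n"
        )
        (pwm,) = parse_motifs(path)
        assert pwm.tf_name == "TFA" and pwm.width == 4
        assert pwm.consensus == "ACGA"

    def test_transfac_like_dialect(self, tmp_path):
        path = tmp_path / "m.txt"
        path.write_text(
            ">M1 TFB\n"
            "P0 A C G T\n"
            "01 8 1 1 0\n"
            "02 0 9 1 0\n"
            "03 0 0 0 10\n"
            "04 10 0 0 0\n"
        )
        (pwm,) = parse_motifs(path)
        assert pwm.consensus == "ACTA"
        assert pwm.width == 4

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.txt"
        path.write_text("\n")
        with pytest.raises(ValueError):
            parse_motifs(path)
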