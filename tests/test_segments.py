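"""Segment usage, TRBD frame enumeration, D annotation, Fisher enrichment."""

import math

import numpy as np
import pytest

import repseq as rq
from repseq import Clonotype, RepertoireSample
from repseq.germline import TRBD1, TRBD2, TRBJ_SEGMENTS, TRBV_SEGMENTS, GermlineSegment


def _sample(v_calls, freqs=None):
    n = len(v_calls)
    freqs = freqs or [1.0 / n] * n

    def unique_nt(i):  # distinct junction per row so keys never collide
        digits = "".join("ACGT"[(i >> (2 * k)) & 3] for k in range(8))
        return "TGTG" + digits

    clones = [
        Clonotype("TRB", unique_nt(i), "CASS", v, "TRBJ2-1*01", frequency=f, count=1)
        for i, (v, f) in enumerate(zip(v_calls, freqs))
    ]
    return RepertoireSample(sample_id="U", clonotypes=clones)


class TestUsageProfile:
    def test_single_gene_clonal_weighting(self):
        profile = rq.usage_profile(_sample(["TRBV7-2*01", "TRBV7-2*02"]), "V", "clonal")
        assert profile == {"TRBV7-2": 1.0}

    def test_frequency_weighting_follows_abundance(self):
        profile = rq.usage_profile(_sample(["TRBV7-2*01", "TRBV5-1*01"], [0.9, 0.1]), "V", "frequency")
        assert profile == pytest.approx({"TRBV7-2": 0.9, "TRBV5-1": 0.1})

    def test_empty_sample_rejected(self):
        with pytest.raises(rq.AnalysisError):
            rq.usage_profile(RepertoireSample(sample_id="E"), "V")

    def test_sampled_usage_close_to_truth_in_total_variation(self, rng):
        genes = ["TRBV7-2*01", "TRBV5-1*01", "TRBV19*01", "TRBV28*01"]
        truth = np.array([0.4, 0.3, 0.2, 0.1])
        draws = rng.choice(len(genes), size=10000, p=truth)
        sample = _sample([genes[i] for i in draws])
        profile = rq.usage_profile(sample, "V", "clonal")
        tv = 0.5 * sum(abs(profile.get(g.split("*")[0], 0.0) - t) for g, t in zip(genes, truth))
        assert tv < 0.03


class TestTrbdFrames:
    def test_canonical_segments_have_exactly_one_q_combination(self):
        frames = rq.enumerate_trbd_frames([TRBD1, TRBD2])
        assert len(frames) == 12
        q_rows = frames[frames.contains_q]
        assert len(q_rows) == 1
        row = q_rows.iloc[0]
        assert (row.segment, row.orientation, row.frame) == ("TRBD1*01", "direct", 1)
        assert "Q" in row.peptide

    def test_row_count_is_six_per_segment(self):
        extra = GermlineSegment("TRBDX*01", "D", "GGGGGGGGG")
        assert len(rq.enumerate_trbd_frames([TRBD1, TRBD2, extra])) == 18
        assert len(rq.enumerate_trbd_frames([])) == 0

    def test_segment_without_q_codon_all_negative(self):
        seg = GermlineSegment("TRBDX*01", "D", "GGGGGGGGGGGG")
        frames = rq.enumerate_trbd_frames([seg])
        assert not frames.contains_q.any()

    def test_palindromic_segment_identical_in_both_orientations(self):
        # reverse complement of GAATTC is GAATTC
        seg = GermlineSegment("TRBDP*01", "D", "GAATTCGAATTC")
        frames = rq.enumerate_trbd_frames([seg])
        for frame in range(3):
            rows = frames[frames.frame == frame]
            direct = rows[rows.orientation == "direct"].iloc[0]
            inverted = rows[rows.orientation == "inverted"].iloc[0]
            assert direct.peptide == inverted.peptide

    def test_stop_codon_truncates_translation(self):
        frames = rq.enumerate_trbd_frames([TRBD2])
        truncated = frames[frames.truncated]
        assert len(truncated) > 0
        assert all("*" not in p for p in frames.peptide)


class TestAnnotateDUsage:
    @pytest.mark.parametrize(
        "d, orientation, frame",
        [(TRBD1, "direct", 1), (TRBD1, "inverted", 0), (TRBD2, "direct", 0), (TRBD2, "inverted", 1)],
    )
    def test_recovers_planted_segment_orientation_frame(self, d, orientation, frame):
        re = rq.recombine_vdj(
            TRBV_SEGMENTS[2], d, TRBJ_SEGMENTS[1], orientation, frame, rng_seed=13, d_core_start=frame
        )
        assert len(re.d_core) >= 8
        annotation = rq.annotate_d_usage(re.clonotype.cdr3_nt, [TRBD1, TRBD2])
        assert annotation is not None
        assert annotation.d_call == d.name
        assert annotation.orientation == orientation
        assert annotation.frame == frame

    def test_pure_vj_junction_unassigned(self):
        re = rq.recombine_vdj(TRBV_SEGMENTS[0], None, TRBJ_SEGMENTS[0], rng_seed=2)
        assert rq.annotate_d_usage(re.clonotype.cdr3_nt, [TRBD1, TRBD2]) is None

    def test_out_of_frame_junction_rejected(self):
        with pytest.raises(rq.AnalysisError):
            rq.annotate_d_usage("TGTGCCA", [TRBD1, TRBD2])


class TestFisherEnrichment:
    def test_equal_proportions_give_p_one(self):
        assert rq.fisher_enrichment(5, 10, 50, 100).p_value >= 0.99

    def test_diagonal_table_matches_hypergeometric_tail(self):
        # oracle: enumerate the hypergeometric support for margins (10,10|10)
        n, r1, cs = 20, 10, 10
        denom = math.comb(n, cs)
        pmf = {x: math.comb(r1, x) * math.comb(n - r1, cs - x) / denom for x in range(11)}
        expected = sum(p for p in pmf.values() if p <= pmf[10] * (1 + 1e-7))
        result = rq.fisher_enrichment(10, 10, 0, 10)
        assert result.p_value == pytest.approx(expected, abs=1e-12)

    def test_haldane_corrected_odds_ratio_when_zero_cell(self):
        result = rq.fisher_enrichment(10, 10, 0, 10)
        assert result.odds_ratio == pytest.approx((10.5 * 10.5) / (0.5 * 0.5))

    def test_counts_validated(self):
        with pytest.raises(rq.ParameterError):
            rq.fisher_enrichment(11, 10, 0, 10)
        with pytest.raises(rq.ParameterError):
            rq.fisher_enrichment(-1, 10, 0, 10)


class TestCentralResidueEnrichment:
    def test_absent_residue_is_null(self):
        result = rq.central_residue_enrichment(["CASSGGF"] * 5, ["CASSTTF"] * 50, "Q")
        assert result.count_reactive == 0 and result.p_value == 1.0

    def test_complete_separation_is_significant(self):
        # closed form: all 8 reactive central-Q, none of 100 baseline
        result = rq.central_residue_enrichment(["CASSQETQYF"] * 8, ["CASSLEGTQYF"] * 100, "Q")
        assert result.count_reactive == 8 and result.count_baseline == 0
        assert result.p_value < 1e-4

    def test_central_window_excludes_flanks(self):
        # glutamine only in the first third must not count as central
        result = rq.central_residue_enrichment(["CQSSLEGTF"] * 4, ["CASSLEGTF"] * 10, "Q")
        assert result.count_reactive == 0

    def test_planted_enrichment_detected_at_study_scale(self, rng):
        reactive = ["CASSQETQYF" if rng.random() < 0.8 else "CASSLETGYF" for _ in range(34)]
        baseline = ["CASSQETQYF" if rng.random() < 0.05 else "CASSLETGYF" for _ in range(1000)]
        result = rq.central_residue_enrichment(reactive, baseline, "Q")
        assert result.p_value < 1e-3
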