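"""Synthetic-data generators: determinism, planted structure, truth labels."""

import numpy as np
import pytest
from Bio.Seq import Seq

import repseq as rq
from repseq.germline import TRBD1, TRBD2, TRBJ_SEGMENTS, TRBV_SEGMENTS
from repseq.io import translate_nt


class TestRecombineVdj:
    def test_no_d_segment_junction_and_determinism(self):
        a = rq.recombine_vdj(TRBV_SEGMENTS[0], None, TRBJ_SEGMENTS[0], rng_seed=5)
        b = rq.recombine_vdj(TRBV_SEGMENTS[0], None, TRBJ_SEGMENTS[0], rng_seed=5)
        assert a.d_core == "" and a.clonotype.d_call is None
        assert a.clonotype.cdr3_nt == b.clonotype.cdr3_nt

    def test_planted_q_frame_translates_to_glutamine(self):
        # brute-force frame bookkeeping: translate the recorded D core in the
        # frame it was planted in and check the glutamine appears in the CDR3
        re = rq.recombine_vdj(
            TRBV_SEGMENTS[0], TRBD1, TRBJ_SEGMENTS[0], "direct", 1, rng_seed=3, d_core_start=1
        )
        junction = re.clonotype.cdr3_nt
        start = re.d_core_start
        assert junction[start : start + len(re.d_core)] == re.d_core
        assert start % 3 == 0  # core planted on a codon boundary for frame 1 at offset 1
        core_aa = translate_nt(re.d_core)
        assert "Q" in core_aa
        assert core_aa in re.clonotype.cdr3_aa

    def test_different_seeds_share_retained_core(self):
        a = rq.recombine_vdj(TRBV_SEGMENTS[1], TRBD2, TRBJ_SEGMENTS[2], "inverted", 2, rng_seed=1)
        b = rq.recombine_vdj(TRBV_SEGMENTS[1], TRBD2, TRBJ_SEGMENTS[2], "inverted", 2, rng_seed=2)
        assert a.d_core == b.d_core
        assert a.clonotype.cdr3_nt != b.clonotype.cdr3_nt

    def test_core_longer_than_segment_rejected(self):
        with pytest.raises(rq.ParameterError):
            rq.recombine_vdj(
                TRBV_SEGMENTS[0], TRBD1, TRBJ_SEGMENTS[0], d_core_start=0, d_core_len=len(TRBD1.sequence_nt) + 1
            )

    def test_junction_is_productive_and_in_frame(self):
        for seed in range(10):
            re = rq.recombine_vdj(TRBV_SEGMENTS[seed % 5], TRBD1, TRBJ_SEGMENTS[seed % 4], rng_seed=seed)
            assert len(re.clonotype.cdr3_nt) % 3 == 0
            assert "*" not in re.clonotype.cdr3_aa
            assert re.clonotype.cdr3_aa == translate_nt(re.clonotype.cdr3_nt)


class TestSimulateStudy:
    def test_deterministic_given_seed(self):
        a = rq.simulate_study(rq.SimConfig(n_clonotypes=200, depth=2000, seed=7))
        b = rq.simulate_study(rq.SimConfig(n_clonotypes=200, depth=2000, seed=7))
        for cond in a.samples:
            assert [c.key for c in a.samples[cond].clonotypes] == [c.key for c in b.samples[cond].clonotypes]
            assert [c.count for c in a.samples[cond].clonotypes] == [c.count for c in b.samples[cond].clonotypes]
        assert a.truth.responder_keys == b.truth.responder_keys

    def test_frequencies_sum_to_one(self):
        study = rq.simulate_study(rq.SimConfig(n_clonotypes=300, depth=10000, seed=2))
        for sample in study.samples.values():
            assert sum(c.frequency for c in sample.clonotypes) == pytest.approx(1.0, abs=1e-9)

    def test_null_fold_leaves_responders_unexpanded(self):
        study = rq.simulate_study(rq.SimConfig(n_clonotypes=300, depth=50000, expansion_fold=1.0, seed=3))
        k = study.samples["k27m_expanded"].frequencies()
        w = study.samples["wt_expanded"].frequencies()
        ratios = [
            np.log2(k.get(key, 1e-9) / w.get(key, 1e-9))
            for key in study.truth.responder_keys
            if key in k and key in w
        ]
        assert abs(np.mean(ratios)) < 0.5  # only noise, no systematic expansion

    def test_convergent_groups_planted_by_construction(self):
        study = rq.simulate_study(
            rq.SimConfig(n_clonotypes=200, depth=5000, n_convergent_groups=2, convergent_group_size=3, seed=1)
        )
        assert len(study.truth.convergent_groups) == 2
        base = study.truth.base_frequencies
        for group in study.truth.convergent_groups:
            assert len(group) == 3
            v_calls = {k[0] for k in group}
            j_calls = {k[1] for k in group}
            nts = {k[2] for k in group}
            assert len(v_calls) == 1 and len(j_calls) == 1 and len(nts) == 3
            aas = {translate_nt(nt) for nt in nts}
            assert len(aas) == 1
            assert all(k in base for k in group)

    def test_top_clone_frequency_matches_power_law(self):
        # independent oracle: the planted abundance law says the top clone holds
        # 1 / sum(i^-a) of the repertoire; the sequenced estimate is multinomial
        config = rq.SimConfig(n_clonotypes=500, abundance_exponent=2.5, depth=100000, n_responders=0,
                              n_convergent_groups=0, seed=11)
        study = rq.simulate_study(config)
        expected_top = 1.0 / np.sum(np.arange(1, 501, dtype=float) ** -2.5)
        observed_top = max(c.frequency for c in study.samples["baseline"].clonotypes)
        se = np.sqrt(expected_top * (1 - expected_top) / config.depth)
        assert abs(observed_top - expected_top) < 5 * se

    def test_truth_labels_not_leaked_into_tables(self, tmp_path):
        study = rq.simulate_study(rq.SimConfig(n_clonotypes=100, depth=2000, seed=4))
        path = tmp_path / "baseline.tsv"
        rq.write_airr(study.samples["baseline"], path)
        header = path.read_text().splitlines()[0].lower()
        assert "responder" not in header and "truth" not in header and "convergent" not in header


class TestSimulateFlow:
    def test_non_reactive_scores_near_zero(self):
        sim = rq.simulate_flow(False, 50000, seed=1)
        assert sim.true_positive_fraction == 0.0
        score = rq.overton_percent_positive(sim.test, sim.control, smooth_window=51)
        assert score < 3.0

    def test_planted_mixture_fraction_recovered(self):
        sim = rq.simulate_flow(True, 50000, shift=1.5, seed=2, positive_fraction=0.5)
        score = rq.overton_percent_positive(sim.test, sim.control)
        assert score == pytest.approx(50.0, abs=2.0)

    def test_bit_identical_given_seed(self):
        a = rq.simulate_flow(True, 10000, seed=9)
        b = rq.simulate_flow(True, 10000, seed=9)
        assert np.array_equal(a.test.counts, b.test.counts)
        assert np.array_equal(a.control.counts, b.control.counts)
        assert a.test.n_events == 10000


class TestSimulatePanel:
    @pytest.fixture
    def genotypes(self):
        return [
            rq.LineGenotype(f"LCL{i}", {"DRB1*13:02"} if i in {1, 4, 7} else {"DRB1*01:01"})
            for i in range(1, 11)
        ]

    def test_noise_free_matches_allele_indicator(self, genotypes):
        sim = rq.simulate_panel("DRB1*13:02", genotypes, noise_rate=0.0, seed=0)
        expected = [i in {1, 4, 7} for i in range(1, 11)]
        assert sim.matrix.calls[0].tolist() == expected
        assert [sim.truth_calls[f"LCL{i}"] for i in range(1, 11)] == expected

    def test_absent_allele_warns_all_negative(self, genotypes):
        with pytest.warns(UserWarning):
            sim = rq.simulate_panel("DQB1*06:02", genotypes, seed=0)
        assert not sim.matrix.calls.any()

    def test_flip_rate_matches_noise_rate(self, genotypes):
        genotypes = genotypes * 2  # 20 lines
        flips = 0
        for seed in range(200):
            sim = rq.simulate_panel("DRB1*13:02", genotypes, noise_rate=0.05, seed=seed)
            flips += len(sim.flipped_lines)
        rate = flips / (200 * len(genotypes))
        assert rate == pytest.approx(0.05, abs=0.01)


class TestSimulateBcr:
    def test_zero_rate_members_identical_to_germline(self):
        sim = rq.simulate_bcr_lineage(4, 0.0, seed=0)
        for clone in sim.clones:
            assert clone.heavy_seq_nt == sim.germline_heavy_nt
            assert clone.shm_heavy == 0 and clone.shm_light == 0

    def test_members_share_genes_and_junction_length(self):
        sim = rq.simulate_bcr_lineage(2, 0.02, seed=5)
        a, b = sim.clones
        assert a.heavy.v_call == b.heavy.v_call and a.heavy.j_call == b.heavy.j_call
        assert len(a.heavy.cdr3_nt) == len(b.heavy.cdr3_nt)

    def test_mean_shm_matches_binomial_expectation(self):
        sim = rq.simulate_bcr_lineage(1000, 0.02, seed=1, heavy_len=350)
        # expectation: 350 * 0.02 = 7 mutations per member
        assert np.mean(sim.true_shm_heavy) == pytest.approx(7.0, abs=0.5)
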