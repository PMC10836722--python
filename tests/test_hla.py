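"""HLA locus assignment, allele deconvolution, population coverage."""

import itertools

import numpy as np
import pytest

import repseq as rq
from repseq import LineGenotype

AUTOLOGOUS = {"DRB1*13:02", "DRB1*07:01", "DQB1*06:02", "DQB1*06:03"}


class TestAssignLocus:
    def test_dr_knockout_abrogation_assigns_dr(self):
        call = rq.assign_locus({"parental": True, "DRA_ko": False, "DQA_ko": True, "DPA_ko": True})
        assert call.locus == "DR" and call.diagnostic is None

    def test_non_reactive_parental_unresolved(self):
        call = rq.assign_locus({"parental": False, "DRA_ko": False, "DQA_ko": True, "DPA_ko": True})
        assert call.locus == "unresolved"

    def test_multiple_abrogating_knockouts_unresolved(self):
        call = rq.assign_locus({"parental": True, "DRA_ko": False, "DQA_ko": False, "DPA_ko": True})
        assert call.locus == "unresolved" and "multiple" in call.diagnostic

    def test_missing_entry_named(self):
        with pytest.raises(rq.ParameterError, match="DPA_ko"):
            rq.assign_locus({"parental": True, "DRA_ko": True, "DQA_ko": True})


class TestThresholdPanel:
    def test_all_zero_values_all_negative(self):
        assert not rq.threshold_panel(np.zeros((2, 5)), 10.0).any()

    def test_zero_threshold_all_positive(self):
        assert rq.threshold_panel(np.zeros((2, 5)), 0.0).all()

    def test_separated_signal_recovers_truth(self):
        truth = np.array([[True, False, True], [False, False, True]])
        values = np.where(truth, 30.0, 1.0)
        assert (rq.threshold_panel(values, 10.0) == truth).all()

    def test_monotone_in_threshold(self, rng):
        values = rng.uniform(0, 100, size=(4, 8))
        low = rq.threshold_panel(values, 5.0)
        high = rq.threshold_panel(values, 50.0)
        assert (high <= low).all()


def _panel(allele_map):
    return [LineGenotype(line, alleles) for line, alleles in allele_map.items()]


class TestDeconvolveAllele:
    def test_unique_carrier_pattern_is_exact(self):
        genotypes = _panel({
            "L1": {"DRB1*13:02", "DQB1*06:02"},
            "L2": {"DRB1*07:01"},
            "L3": {"DRB1*13:02"},
            "L4": {"DRB1*01:01"},
        })
        calls = [True, False, True, False]
        result = rq.deconvolve_allele(calls, genotypes, "DR", AUTOLOGOUS)
        assert result.primary_alleles == {"DRB1*13:02"}
        assert result.confidence == "exact"
        assert result.cross_reactive_alleles == set()

    def test_confounded_co_occurring_alleles_ambiguous(self):
        calls = [True, True, False]
        genotypes = _panel({
            "L1": {"DRB1*13:02", "DRB1*07:01"},
            "L2": {"DRB1*13:02", "DRB1*07:01"},
            "L3": {"DRB1*01:01"},
        })
        result = rq.deconvolve_allele(calls, genotypes, "DR", AUTOLOGOUS)
        assert result.primary_alleles == {"DRB1*13:02", "DRB1*07:01"}
        assert result.confidence == "ambiguous"

    def test_cross_reactive_allele_explains_extra_lines(self):
        genotypes = _panel({
            "L1": {"DRB1*13:02"},
            "L2": {"DRB1*13:01"},  # non-autologous, cross-reactive
            "L3": {"DRB1*01:01"},
        })
        result = rq.deconvolve_allele([True, True, False], genotypes, "DR", AUTOLOGOUS)
        assert result.primary_alleles == {"DRB1*13:02"}
        assert result.cross_reactive_alleles == {"DRB1*13:01"}

    def test_irrelevant_negative_line_changes_nothing(self):
        genotypes = _panel({
            "L1": {"DRB1*13:02"},
            "L2": {"DRB1*07:01"},
        })
        base = rq.deconvolve_allele([True, False], genotypes, "DR", AUTOLOGOUS)
        extended = rq.deconvolve_allele(
            [True, False, False], genotypes + [LineGenotype("L9", {"DPB1*04:01"})], "DR", AUTOLOGOUS
        )
        assert base.primary_alleles == extended.primary_alleles
        assert base.confidence == extended.confidence

    def test_coverage_gap_lists_untestable_alleles(self):
        genotypes = _panel({"L1": {"DPB1*04:01"}})
        with pytest.raises(rq.CoverageGapError) as exc:
            rq.deconvolve_allele([True], genotypes, "DR", AUTOLOGOUS)
        assert "DRB1*13:02" in exc.value.alleles

    def test_no_reactive_line_rejected(self):
        genotypes = _panel({"L1": {"DRB1*13:02"}})
        with pytest.raises(rq.AnalysisError):
            rq.deconvolve_allele([False], genotypes, "DR", AUTOLOGOUS)

    def test_noise_free_panels_always_recover_planted_allele(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            genotypes = rq.random_panel_genotypes(AUTOLOGOUS, 20, rng=rng)
            sim = rq.simulate_panel("DQB1*06:02", genotypes, noise_rate=0.0, seed=int(rng.integers(2**31)))
            result = rq.deconvolve_allele(sim.matrix.calls[0], genotypes, "DQ", AUTOLOGOUS)
            assert result.primary_alleles == {"DQB1*06:02"}
            assert result.confidence == "exact"


class TestPopulationCoverage:
    def test_single_allele_hwe_carrier_probability(self):
        assert rq.population_coverage([{"DRB1*13:02"}], {"DRB1*13:02": 0.3}) == pytest.approx(0.51)

    def test_zero_frequency_zero_coverage(self):
        assert rq.population_coverage([{"DRB1*13:02"}], {"DRB1*13:02": 0.0}) == 0.0

    def test_two_unlinked_loci_match_genotype_enumeration(self):
        freqs = {"DRB1*13:02": 0.2, "DQB1*06:02": 0.15}
        covered = rq.population_coverage([{"DRB1*13:02"}, {"DQB1*06:02"}], freqs)
        # oracle: enumerate diploid genotypes at two independent loci
        p, q = 0.2, 0.15
        total = 0.0
        for a1, a2, b1, b2 in itertools.product([True, False], repeat=4):
            prob = (
                (p if a1 else 1 - p) * (p if a2 else 1 - p) * (q if b1 else 1 - q) * (q if b2 else 1 - q)
            )
            if a1 or a2 or b1 or b2:
                total += prob
        assert covered == pytest.approx(total, abs=1e-12)

    def test_monotone_in_frequency_and_inclusion(self):
        low = rq.population_coverage([{"DRB1*13:02"}], {"DRB1*13:02": 0.1, "DQB1*06:02": 0.2})
        more_freq = rq.population_coverage([{"DRB1*13:02"}], {"DRB1*13:02": 0.2, "DQB1*06:02": 0.2})
        more_alleles = rq.population_coverage(
            [{"DRB1*13:02"}, {"DQB1*06:02"}], {"DRB1*13:02": 0.1, "DQB1*06:02": 0.2}
        )
        assert low <= more_freq and low <= more_alleles

    def test_unknown_allele_frequency_listed(self):
        with pytest.raises(rq.ParameterError, match="DQB1"):
            rq.population_coverage([{"DQB1*06:02"}], {"DRB1*13:02": 0.1})
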