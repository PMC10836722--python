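"""Two-step HLA-restriction mapping and population-coverage estimation.

Step one assigns the restricting class-II locus (DR, DQ or DP) from knockout
presenting lines: disrupting the restricting locus abrogates reactivity
completely. Step two deconvolves the restricting allele from a panel of
partially HLA-matched B-LCL lines of known genotype: the combination of
response-inducing lines identifies the presenting allele, with additional
reactive lines explained by cross-reactive alleles. Coverage of a TCR set in
a target population is estimated from allele frequencies under
Hardy-Weinberg carrier probabilities.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .errors import AnalysisError, CoverageGapError, ParameterError

LOCUS_PREFIXES = {
    "DR": ("DRA", "DRB1", "DRB3", "DRB4", "DRB5"),
    "DQ": ("DQA1", "DQB1"),
    "DP": ("DPA1", "DPB1"),
}
_KO_TO_LOCUS = {"DRA_ko": "DR", "DQA_ko": "DQ", "DPA_ko": "DP"}


def allele_locus(allele: str) -> str:
    """Gene name of a two-field allele: ``DRB1*13:02`` -> ``DRB1``."""
    return allele.split("*", 1)[0]


def _at_locus(allele: str, locus: str) -> bool:
    return allele_locus(allele) in LOCUS_PREFIXES.get(locus, (locus,))


@dataclass
class LineGenotype:
    """HLA genotype of one presenting (B-LCL) line."""

    line_id: str
    alleles: frozenset[str]

    def __init__(self, line_id: str, alleles):
        self.line_id = line_id
        self.alleles = frozenset(alleles)
        per_locus: dict[str, int] = {}
        for a in self.alleles:
            per_locus[allele_locus(a)] = per_locus.get(allele_locus(a), 0) + 1
        for gene, n in per_locus.items():
            if n > 2:
                raise ParameterError(f"line {line_id}: more than 2 alleles at {gene}")


@dataclass
class PanelReactivityMatrix:
    """TCR x presenting-line reactivity values (percent HA-positive) and calls."""

    tcr_ids: list[str]
    line_ids: list[str]
    values: np.ndarray
    calls: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.tcr_ids), len(self.line_ids)):
            raise ParameterError("values must be shaped (n_tcrs, n_lines)")
        if np.any(self.values < 0) or np.any(self.values > 100):
            raise ParameterError("reactivity values must be percentages in [0, 100]")
        if self.calls is not None:
            self.calls = np.asarray(self.calls, dtype=bool)
            if self.calls.shape != self.values.shape:
                raise ParameterError("calls must match values in shape")

    def threshold(self, min_pct: float) -> np.ndarray:
        self.calls = threshold_panel(self.values, min_pct)
        return self.calls


@dataclass
class LocusAssignment:
    locus: str  # "DR" | "DQ" | "DP" | "unresolved"
    diagnostic: str | None = None


@dataclass
class RestrictionResult:
    tcr_id: str
    locus: str
    primary_alleles: set[str] = field(default_factory=set)
    cross_reactive_alleles: set[str] = field(default_factory=set)
    inconsistent_lines: list[str] = field(default_factory=list)
    confidence: str = "exact"  # "exact" | "ambiguous" | "inconsistent"


def assign_locus(knockout_calls: dict[str, bool]) -> LocusAssignment:
    """Restricting locus from knockout abrogation.

    The parental (knockout-free) line must be reactive; the unique knockout
    that loses reactivity names the locus. Zero or multiple abrogating
    knockouts leave the locus unresolved with a diagnostic.
    """
    for key in ("parental", "DRA_ko", "DQA_ko", "DPA_ko"):
        if key not in knockout_calls:
            raise ParameterError(f"missing knockout entry {key!r}")
    if not knockout_calls["parental"]:
        return LocusAssignment("unresolved", "parental line non-reactive")
    abrogating = [ko for ko in _KO_TO_LOCUS if not knockout_calls[ko]]
    if len(abrogating) == 1:
        return LocusAssignment(_KO_TO_LOCUS[abrogating[0]])
    if not abrogating:
        return LocusAssignment("unresolved", "no knockout abrogates reactivity")
    return LocusAssignment("unresolved", "multiple loci abrogate reactivity: " + ", ".join(sorted(abrogating)))


def threshold_panel(values, min_pct: float) -> np.ndarray:
    """Boolean reactivity calls: value >= min_pct."""
    arr = np.asarray(values, dtype=float)
    if np.any(arr < 0) or np.any(arr > 100):
        raise ParameterError("panel values must be percentages in [0, 100]")
    return arr >= min_pct


def _min_set_cover(targets: set[str], candidates: dict[str, set[str]], exhaustive_limit: int = 12):
    """Smallest set of candidate alleles whose carrier sets cover ``targets``.

    Exhaustive over subsets when few candidates, greedy otherwise. Returns
    (chosen alleles, uncovered targets).
    """
    useful = {a: c & targets for a, c in candidates.items() if c & targets}
    if not targets:
        return set(), set()
    if len(useful) <= exhaustive_limit:
        for size in range(1, len(useful) + 1):
            best = None
            for combo in itertools.combinations(sorted(useful), size):
                covered = set().union(*(useful[a] for a in combo))
                if covered >= targets:
                    return set(combo), set()
                if best is None or len(covered) > len(best[1]):
                    best = (set(combo), covered)
            if size == len(useful) and best is not None:
                return best[0], targets - best[1]
        return set(), set(targets)
    chosen: set[str] = set()
    remaining = set(targets)
    while remaining:
        pick = max(sorted(useful), key=lambda a: len(useful[a] & remaining))
        if not useful[pick] & remaining:
            break
        chosen.add(pick)
        remaining -= useful[pick]
    return chosen, remaining


def deconvolve_allele(
    tcr_vector,
    genotypes: list[LineGenotype],
    locus: str,
    autologous_alleles,
    tcr_id: str = "",
) -> RestrictionResult:
    """Identify the restricting allele from a boolean panel reactivity vector.

    Candidates are the autologous alleles at the assigned locus. The strict
    solution prefers an allele whose carrier lines are exactly the reactive
    lines; failing that, alleles carried only by reactive lines (no
    non-reactive carrier falsifying them), taking those with the widest
    coverage and explaining the remaining reactive lines by a minimal set of
    cross-reactive panel alleles. If no allele survives even that — expected
    only with call noise — the fallback picks the autologous allele(s)
    minimizing the number of lines whose call contradicts the carrier
    pattern, flagging those lines inconsistent. Confidence: ``exact`` (unique
    strict solution), ``ambiguous`` (several, e.g. alleles confounded by
    co-occurrence), ``inconsistent`` (relaxation used or reactive lines left
    unexplained).
    """
    calls = [bool(v) for v in tcr_vector]
    if len(calls) != len(genotypes):
        raise ParameterError("tcr_vector length must match the number of panel lines")
    if not any(calls):
        raise AnalysisError("no reactive line: allele deconvolution needs at least one positive call")

    autologous = {a for a in autologous_alleles if _at_locus(a, locus)}
    carriers = {
        a: {g.line_id for g in genotypes if a in g.alleles}
        for a in {al for g in genotypes for al in g.alleles if _at_locus(al, locus)} | autologous
    }
    testable = {a for a in autologous if carriers.get(a)}
    if not testable:
        raise CoverageGapError(
            f"no panel line carries any autologous {locus} allele", alleles=sorted(autologous)
        )

    reactive = {g.line_id for g, c in zip(genotypes, calls) if c}
    nonreactive = {g.line_id for g, c in zip(genotypes, calls) if not c}

    full = {a for a in testable if carriers[a] == reactive}
    subset = {a for a in testable if carriers[a] and carriers[a] <= reactive}
    inconsistent: set[str] = set()
    if full:
        primary = full
        confidence = "exact" if len(full) == 1 else "ambiguous"
    elif subset:
        widest = max(len(carriers[a]) for a in subset)
        primary = {a for a in subset if len(carriers[a]) == widest}
        confidence = "exact" if len(primary) == 1 else "ambiguous"
    else:
        cost = {a: len(carriers[a] ^ reactive) for a in testable}
        best = min(cost.values())
        primary = {a for a in testable if cost[a] == best}
        inconsistent |= set().union(*(carriers[a] ^ reactive for a in primary))
        confidence = "inconsistent"

    covered = set().union(*(carriers[a] for a in primary)) & reactive
    uncovered = reactive - covered
    cross: set[str] = set()
    if uncovered:
        # clean explainers first: panel alleles with no non-reactive carrier
        candidates = {
            a: c for a, c in carriers.items() if a not in primary and c and not c & nonreactive
        }
        cross, still = _min_set_cover(uncovered, candidates)
        if still:
            inconsistent |= still
            confidence = "inconsistent"
    return RestrictionResult(
        tcr_id=tcr_id,
        locus=locus,
        primary_alleles=primary,
        cross_reactive_alleles=cross,
        inconsistent_lines=sorted(inconsistent),
        confidence=confidence,
    )


def population_coverage(allele_sets, freqs: dict[str, float], model: str = "HWE") -> float:
    """Fraction of a population carrying at least one usable allele.

    The union of alleles across the TCR set is grouped by gene; within a gene
    the carrier probability under Hardy-Weinberg equilibrium is
    ``1 - (1 - sum(f))**2``, and genes combine under independence as
    ``1 - prod(1 - carrier_g)``. Haplotype linkage between loci is not
    modeled here; pass haplotype-pooled frequencies for linked genes.
    """
    if model.upper() != "HWE":
        raise ParameterError(f"unsupported model {model!r}")
    usable = sorted(set().union(*[set(s) for s in allele_sets])) if allele_sets else []
    missing = [a for a in usable if a not in freqs]
    if missing:
        raise ParameterError("unknown allele frequency for: " + ", ".join(missing))
    by_gene: dict[str, float] = {}
    for a in usable:
        f = freqs[a]
        if not 0.0 <= f <= 1.0:
            raise ParameterError(f"allele frequency for {a} outside [0, 1]")
        by_gene[allele_locus(a)] = by_gene.get(allele_locus(a), 0.0) + f
    not_covered = 1.0
    for gene, total in by_gene.items():
        if total > 1.0 + 1e-9:
            raise ParameterError(f"allele frequencies at {gene} sum to {total} > 1")
        carrier = 1.0 - (1.0 - min(total, 1.0)) ** 2
        not_covered *= 1.0 - carrier
    return 1.0 - not_covered
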