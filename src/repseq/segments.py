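"""Gene-segment usage, TRBD orientation/frame analysis, enrichment statistics.

The TRB diversity locus holds two short D segments that recombination can
insert directly or inverted and that translation can read in three frames;
which (segment, orientation, frame) combinations encode a given residue — in
particular the central glutamine enriched among mutant-peptide-reactive TCRs
— is answered by exhaustive enumeration. Feature enrichment between a
reactive TCR set and the baseline repertoire uses two-sided Fisher's exact
tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio.Seq import Seq
from scipy.stats import fisher_exact

from .errors import AnalysisError, ParameterError
from .germline import GermlineSegment, gene_name
from .io import RepertoireSample, translate_nt


def usage_profile(sample: RepertoireSample, segment: str = "V", weighting: str = "clonal") -> dict[str, float]:
    """Gene-level usage fractions of V or J segments in one sample.

    ``clonal`` weighting counts each clonotype once; ``frequency`` weighting
    weights by clonotype frequency. Fractions sum to 1.
    """
    if segment not in {"V", "J"}:
        raise ParameterError("segment must be 'V' or 'J'")
    if weighting not in {"clonal", "frequency"}:
        raise ParameterError("weighting must be 'clonal' or 'frequency'")
    if not sample.clonotypes:
        raise AnalysisError("cannot profile an empty sample")
    weights: dict[str, float] = {}
    for c in sample.clonotypes:
        gene = gene_name(c.v_call if segment == "V" else c.j_call)
        weights[gene] = weights.get(gene, 0.0) + (1.0 if weighting == "clonal" else c.frequency)
    total = sum(weights.values())
    if total == 0:
        raise AnalysisError("sample carries zero total weight")
    return {gene: w / total for gene, w in sorted(weights.items())}


# ---------------------------------------------------------------------------
# TRBD orientation / reading frame
# ---------------------------------------------------------------------------


@dataclass
class TrbdFrameRow:
    segment: str
    orientation: str  # "direct" | "inverted"
    frame: int  # 0 | 1 | 2
    peptide: str  # translation up to (excluding) the first stop codon
    truncated: bool  # a stop codon cut the translation short
    contains_q: bool


def enumerate_trbd_frames(d_segments: list[GermlineSegment]) -> pd.DataFrame:
    """All 2 orientations x 3 frames translations of each D segment.

    Inverted means reverse complement. Translation stops at the first stop
    codon (recorded as truncated); ``contains_q`` flags a glutamine in the
    translated peptide. Always emits exactly 6 rows per segment.
    """
    rows = []
    for seg in d_segments:
        seq = seg.sequence_nt.upper()
        for orientation, oriented in (("direct", seq), ("inverted", str(Seq(seq).reverse_complement()))):
            for frame in range(3):
                full = translate_nt(oriented[frame:])
                peptide, _, _ = full.partition("*")
                rows.append(
                    TrbdFrameRow(
                        segment=seg.name,
                        orientation=orientation,
                        frame=frame,
                        peptide=peptide,
                        truncated="*" in full,
                        contains_q="Q" in peptide,
                    )
                )
    return pd.DataFrame([vars(r) for r in rows])


@dataclass
class DUsageAnnotation:
    d_call: str
    orientation: str
    frame: int
    match_length: int
    cdr3_start: int  # 0-based position of the match within the CDR3


def _longest_match(cdr3: str, oriented: str):
    """Longest exact common substring; first occurrence on ties."""
    best = (0, 0, 0)  # (length, cdr3_pos, d_pos)
    n, m = len(cdr3), len(oriented)
    for p in range(n):
        for q in range(m):
            length = 0
            while p + length < n and q + length < m and cdr3[p + length] == oriented[q + length]:
                length += 1
            if length > best[0]:
                best = (length, p, q)
    return best


def annotate_d_usage(
    cdr3_nt: str,
    d_segments: list[GermlineSegment],
    min_match: int = 5,
) -> DUsageAnnotation | None:
    """Assign D segment, orientation and reading frame to a CDR3 junction.

    Exact substring matching (no mismatches: junctional D cores are short and
    mismatch tolerance would inflate false assignments) of the CDR3 against
    each D segment in both orientations. Returns ``None`` when the best match
    is shorter than ``min_match``. The frame is where codon boundaries of the
    in-frame CDR3 fall within the D segment: ``(d_offset - cdr3_offset) % 3``.
    Ties break toward the longer match, direct over inverted, then the D
    segment listed first (TRBD1 before TRBD2 in the default reference).
    """
    if min_match < 3:
        raise ParameterError("min_match must be >= 3")
    cdr3 = cdr3_nt.upper()
    if len(cdr3) % 3 != 0:
        raise AnalysisError("CDR3 length is not a multiple of 3: reading frame undefined")
    best: tuple[int, int, int] | None = None
    best_meta = None
    for seg_rank, seg in enumerate(d_segments):
        seq = seg.sequence_nt.upper()
        for ori_rank, (orientation, oriented) in enumerate(
            (("direct", seq), ("inverted", str(Seq(seq).reverse_complement())))
        ):
            length, p, q = _longest_match(cdr3, oriented)
            score = (-length, ori_rank, seg_rank)
            if best is None or score < best:
                best = score
                best_meta = (seg.name, orientation, length, p, q)
    name, orientation, length, p, q = best_meta
    if length < min_match:
        return None
    return DUsageAnnotation(
        d_call=name,
        orientation=orientation,
        frame=(q - p) % 3,
        match_length=length,
        cdr3_start=p,
    )


# ---------------------------------------------------------------------------
# Enrichment statistics
# ---------------------------------------------------------------------------


@dataclass
class EnrichmentResult:
    feature: str
    count_reactive: int
    n_reactive: int
    count_baseline: int
    n_baseline: int
    odds_ratio: float
    p_value: float


def fisher_enrichment(
    count_reactive: int,
    n_reactive: int,
    count_baseline: int,
    n_baseline: int,
    feature: str = "",
) -> EnrichmentResult:
    """Two-sided Fisher's exact test on the 2x2 feature-by-set table.

    Sidedness follows the standard convention (sum of all tables with
    probability <= the observed one). The odds ratio uses the Haldane
    0.5-correction when any cell is zero.
    """
    counts = (count_reactive, n_reactive, count_baseline, n_baseline)
    if any(c < 0 for c in counts):
        raise ParameterError("counts must be non-negative")
    if count_reactive > n_reactive or count_baseline > n_baseline:
        raise ParameterError("feature counts cannot exceed set totals")
    a, b = count_reactive, n_reactive - count_reactive
    c, d = count_baseline, n_baseline - count_baseline
    _, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if 0 in (a, b, c, d):
        a2, b2, c2, d2 = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        a2, b2, c2, d2 = a, b, c, d
    return EnrichmentResult(
        feature=feature,
        count_reactive=count_reactive,
        n_reactive=n_reactive,
        count_baseline=count_baseline,
        n_baseline=n_baseline,
        odds_ratio=(a2 * d2) / (b2 * c2),
        p_value=min(1.0, float(p)),
    )


def central_window(length: int, central_fraction: float = 1.0 / 3.0) -> tuple[int, int]:
    """Half-open index range of the central fraction of a sequence."""
    if not 0 < central_fraction <= 1:
        raise ParameterError("central_fraction must be in (0, 1]")
    margin = int(length * (1.0 - central_fraction) / 2.0)
    return margin, length - margin


def central_residue_enrichment(
    reactive_cdr3s: list[str],
    baseline_cdr3s: list[str],
    residue: str = "Q",
    central_fraction: float = 1.0 / 3.0,
) -> EnrichmentResult:
    """Enrichment of a residue in the central CDR3 region, reactive vs baseline.

    A CDR3 is central-positive when the residue occurs within the central
    third (by default) of its amino-acid sequence; the counts feed a
    two-sided Fisher's exact test.
    """
    if not reactive_cdr3s or not baseline_cdr3s:
        raise ParameterError("both CDR3 lists must be non-empty")
    if len(residue) != 1:
        raise ParameterError("residue must be a single amino-acid letter")

    def central_positive(aa: str) -> bool:
        start, end = central_window(len(aa), central_fraction)
        return residue.upper() in aa.upper()[start:end]

    count_r = sum(central_positive(s) for s in reactive_cdr3s)
    count_b = sum(central_positive(s) for s in baseline_cdr3s)
    return fisher_enrichment(
        count_r,
        len(reactive_cdr3s),
        count_b,
        len(baseline_cdr3s),
        feature=f"central_{residue.upper()}",
    )
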