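"""Minimal embedded germline reference for TCRβ junction simulation.

The V entries are the 3' junction-proximal ends of a handful of TRBV genes
(starting at the conserved CDR3 cysteine codon) and the J entries are the 5'
junction-proximal starts of common TRBJ genes (ending at the conserved
phenylalanine codon), which is all the junction simulator needs. The two TRBD
diversity segments are the full-length IMGT *01 allele sequences; their exact
nucleotide content matters because the orientation/reading-frame analysis of
the D locus (only one of the twelve segment x orientation x frame combinations
encodes a glutamine) depends on it.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ParameterError

_DNA = set("ACGT")


@dataclass(frozen=True)
class GermlineSegment:
    """One germline gene segment: IMGT-style name, type (V/D/J), sequence."""

    name: str
    segment_type: str  # "V", "D" or "J"
    sequence_nt: str

    def __post_init__(self):
        if self.segment_type not in {"V", "D", "J"}:
            raise ParameterError(f"segment_type must be V, D or J, got {self.segment_type!r}")
        if not self.sequence_nt or set(self.sequence_nt.upper()) - _DNA:
            raise ParameterError(f"segment {self.name}: sequence must be non-empty A/C/G/T")


# 3' ends of V regions, beginning at the conserved cysteine (TGT/TGC) that
# opens the CDR3.
TRBV_SEGMENTS = [
    GermlineSegment("TRBV7-2*01", "V", "TGTGCCAGCAGCTTAGC"),
    GermlineSegment("TRBV5-1*01", "V", "TGCGCCAGCAGCTTGG"),
    GermlineSegment("TRBV19*01", "V", "TGTGCCAGTAGTATA"),
    GermlineSegment("TRBV28*01", "V", "TGTGCCAGCAGTCTCTC"),
    GermlineSegment("TRBV6-5*01", "V", "TGTGCCAGCAGTTACTC"),
    GermlineSegment("TRBV20-1*01", "V", "TGTAGTGCTAGAGA"),
]

# Full-length TRBD diversity segments (IMGT *01 alleles).
TRBD1 = GermlineSegment("TRBD1*01", "D", "GGGACAGGGGGC")
TRBD2 = GermlineSegment("TRBD2*01", "D", "GGGACTAGCGGGGGGG")
TRBD_SEGMENTS = [TRBD1, TRBD2]

# 5' starts of J regions, ending at the conserved phenylalanine codon that
# closes the CDR3.
TRBJ_SEGMENTS = [
    GermlineSegment("TRBJ1-1*01", "J", "AACACTGAAGCTTTCTTT"),
    GermlineSegment("TRBJ1-2*01", "J", "AACTATGGCTACACCTTC"),
    GermlineSegment("TRBJ2-1*01", "J", "AATGAGCAGTTCTTC"),
    GermlineSegment("TRBJ2-3*01", "J", "AGCACAGATACGCAGTATTTT"),
    GermlineSegment("TRBJ2-7*01", "J", "TCCTACGAGCAGTACTTC"),
]


def gene_name(call: str) -> str:
    """Truncate an allele-level call to gene level: ``TRBV7-2*01`` -> ``TRBV7-2``."""
    return call.split("*", 1)[0]
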