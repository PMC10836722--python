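"""Detection of convergently recombined clonotypes.

Convergent recombination produces the identical CDR3 amino-acid sequence from
independent rearrangement events with distinct junction nucleotide sequences
— a signature associated with antigen-driven selection. Because a sequencing
error can also fake a nucleotide variant, detection filters on UMI and read
support before grouping, and reports where the divergent nucleotides fall:
genuine convergence diverges at the V(D)J junction itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import AnalysisError, ParameterError
from .germline import gene_name
from .io import Clonotype, PairedTcr


@dataclass
class ConvergenceGroup:
    """Clonotypes sharing one CDR3 amino-acid sequence via distinct junctions."""

    group_key: tuple
    members: list
    divergent_positions: list[int] = field(default_factory=list)
    length_divergent: bool = False

    @property
    def size(self) -> int:
        return len(self.members)


def _beta(entry) -> Clonotype:
    return entry.beta if isinstance(entry, PairedTcr) else entry


def _group_key(entry, require_same_vj: bool):
    if isinstance(entry, PairedTcr):
        # paired data: the amino-acid CDR3s of both chains identify the group
        return (entry.beta.cdr3_aa, tuple(sorted(a.cdr3_aa for a in entry.alphas)))
    if require_same_vj:
        return (entry.cdr3_aa, gene_name(entry.v_call), gene_name(entry.j_call))
    return (entry.cdr3_aa,)


def _divergent_positions(sequences: list[str]) -> tuple[list[int], bool]:
    lengths = {len(s) for s in sequences}
    if len(lengths) != 1:
        return [], True
    positions = [i for i in range(lengths.pop()) if len({s[i] for s in sequences}) > 1]
    return positions, False


def find_convergent_groups(
    clonotypes,
    min_read_support: int = 2,
    min_umi_support: int = 2,
    require_same_vj: bool = True,
) -> list[ConvergenceGroup]:
    """Group clonotypes convergent at the amino-acid level.

    Entries below either support threshold are excluded before grouping.
    Bulk clonotypes group on (CDR3β aa, V gene, J gene) — gene calls
    truncated to gene level, allele miscalls being common — or on CDR3 aa
    alone with ``require_same_vj=False``; paired TCRs group on the amino-acid
    CDR3s of both chains. Within a group, entries with identical junction
    nucleotide sequence collapse to one member (same rearrangement, not
    convergent); groups need >= 2 distinct junctions to be reported.
    """
    if min_read_support < 1 or min_umi_support < 1:
        raise ParameterError("support thresholds must be >= 1")
    supported = [
        e
        for e in clonotypes
        if _beta(e).read_support >= min_read_support and _beta(e).umi_support >= min_umi_support
    ]
    grouped: dict[tuple, dict[str, object]] = {}
    for entry in supported:
        grouped.setdefault(_group_key(entry, require_same_vj), {}).setdefault(_beta(entry).cdr3_nt, entry)
    groups = []
    for key in sorted(grouped, key=repr):
        by_nt = grouped[key]
        if len(by_nt) < 2:
            continue
        members = list(by_nt.values())
        positions, length_divergent = _divergent_positions(sorted(by_nt))
        groups.append(
            ConvergenceGroup(
                group_key=key,
                members=members,
                divergent_positions=positions,
                length_divergent=length_divergent,
            )
        )
    return groups


def divergence_location_score(group: ConvergenceGroup, junction_window: int) -> float:
    """Fraction of divergent nucleotide positions inside the junctional window.

    The window is the central ``junction_window`` nucleotides of the CDR3.
    Scores near 1 support genuine convergent recombination (divergence at the
    recombination junction); low scores point at sequencing artifacts spread
    over the germline-encoded ends.
    """
    if group.length_divergent:
        raise AnalysisError("divergence location is undefined for length-divergent groups")
    if junction_window < 1:
        raise ParameterError("junction_window must be >= 1")
    if not group.divergent_positions:
        raise AnalysisError("group has no divergent positions")
    length = len(_beta(group.members[0]).cdr3_nt)
    start = max(0, (length - junction_window) // 2)
    end = min(length, start + junction_window)
    inside = sum(1 for p in group.divergent_positions if start <= p < end)
    return inside / len(group.divergent_positions)
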