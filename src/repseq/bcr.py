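"""BCR clonal-lineage grouping, somatic hypermutation counting, clonality.

Lineages are defined on the heavy chain (shared V and J gene, equal junction
length, CDR3 amino-acid identity above threshold, single linkage), with the
light chain used as a confirmation tie-break when present — standard clonal
grouping practice. SHM is counted against a caller-supplied gapless germline
reconstruction; no internal aligner is involved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import AnalysisError, ParameterError
from .germline import gene_name
from .io import Clonotype

ISOTYPES = {"IGM", "IGD", "IGG1", "IGG2", "IGG3", "IGG4", "IGA1", "IGA2", "IGE"}


@dataclass
class BcrClone:
    """Paired heavy/light BCR of one cell, with mutation counts.

    ``heavy_seq_nt``/``light_seq_nt`` optionally carry the full gapless
    V-region nucleotide strings that the SHM counts refer to.
    """

    cell_id: str
    heavy: Clonotype
    light: Clonotype | None = None
    isotype: str | None = None
    shm_heavy: int = 0
    shm_light: int = 0
    heavy_seq_nt: str | None = None
    light_seq_nt: str | None = None

    def __post_init__(self):
        if self.heavy.chain != "IGH":
            raise ParameterError("heavy chain must be IGH")
        if self.light is not None and self.light.chain not in {"IGK", "IGL"}:
            raise ParameterError("light chain must be IGK or IGL")
        if self.isotype is not None and self.isotype not in ISOTYPES:
            raise ParameterError(f"unknown isotype {self.isotype!r}")
        if self.shm_heavy < 0 or self.shm_light < 0:
            raise ParameterError("SHM counts must be non-negative")


@dataclass
class ClonalLineage:
    lineage_id: str
    members: list[BcrClone]
    v_call: str = ""
    j_call: str = ""
    isotypes: set[str] = field(default_factory=set)

    @property
    def n_cells(self) -> int:
        return len(self.members)


def _aa_identity(a: str, b: str) -> float:
    if len(a) != len(b):
        return 0.0
    return sum(x == y for x, y in zip(a, b)) / len(a)


def _light_compatible(a: BcrClone, b: BcrClone) -> bool:
    if a.light is None or b.light is None:
        return True
    return (
        gene_name(a.light.v_call) == gene_name(b.light.v_call)
        and gene_name(a.light.j_call) == gene_name(b.light.j_call)
        and len(a.light.cdr3_nt) == len(b.light.cdr3_nt)
    )


def group_lineages(clones: list[BcrClone], min_junction_identity: float = 0.85) -> list[ClonalLineage]:
    """Partition clones into clonal lineages.

    Two clones link when their heavy V and J genes match, heavy junction
    lengths are equal, heavy CDR3 amino-acid identity reaches the threshold,
    and the light chains (when both present) do not contradict the pairing.
    Single-linkage closure within each (V, J, length) bucket.
    """
    if not 0.5 <= min_junction_identity <= 1.0:
        raise ParameterError("min_junction_identity must be in [0.5, 1]")
    parent = list(range(len(clones)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    buckets: dict[tuple[str, str, int], list[int]] = {}
    for i, c in enumerate(clones):
        key = (gene_name(c.heavy.v_call), gene_name(c.heavy.j_call), len(c.heavy.cdr3_aa))
        buckets.setdefault(key, []).append(i)
    for members in buckets.values():
        for pos, i in enumerate(members):
            for j in members[pos + 1 :]:
                if (
                    _aa_identity(clones[i].heavy.cdr3_aa, clones[j].heavy.cdr3_aa) >= min_junction_identity
                    and _light_compatible(clones[i], clones[j])
                ):
                    union(i, j)

    groups: dict[int, list[int]] = {}
    for i in range(len(clones)):
        groups.setdefault(find(i), []).append(i)
    lineages = []
    for n, members in enumerate(sorted(groups.values(), key=lambda m: (-len(m), m)), start=1):
        clones_m = [clones[i] for i in members]
        lineages.append(
            ClonalLineage(
                lineage_id=f"L{n}",
                members=clones_m,
                v_call=gene_name(clones_m[0].heavy.v_call),
                j_call=gene_name(clones_m[0].heavy.j_call),
                isotypes={c.isotype for c in clones_m if c.isotype},
            )
        )
    return lineages


def clones_from_contigs(path) -> list[BcrClone]:
    """Build BcrClones from a 10x-style filtered-contig CSV with IG chains.

    Cells are grouped by barcode; the first IGH contig becomes the heavy
    chain and the first IGK/IGL contig (if any) the light chain. Cells
    without an IGH contig are skipped.
    """
    import pandas as pd

    from .io import CONTIG_REQUIRED, FormatError

    table = pd.read_csv(path, dtype=str)
    for col in CONTIG_REQUIRED:
        if col not in table.columns:
            raise FormatError(f"{path}: missing mandatory contig column {col!r}")
    clones = []
    for barcode, rows in table.groupby("barcode", sort=False):
        heavy = light = None
        isotype = None
        for _, row in rows.iterrows():
            chain = str(row["chain"])
            clone = Clonotype(
                chain=chain if chain in {"IGH", "IGK", "IGL"} else "IGH",
                cdr3_nt=str(row["cdr3_nt"]).upper(),
                cdr3_aa=str(row["cdr3"]).upper(),
                v_call=str(row["v_gene"]),
                j_call=str(row["j_gene"]),
                count=1,
            )
            if chain == "IGH" and heavy is None:
                heavy = clone
                c_gene = str(row.get("c_gene", "") or "").upper().replace("IGH", "IG")
                isotype = c_gene if c_gene in ISOTYPES else None
            elif chain in {"IGK", "IGL"} and light is None:
                light = clone
        if heavy is not None:
            clones.append(BcrClone(cell_id=str(barcode), heavy=heavy, light=light, isotype=isotype))
    return clones


def count_shm(observed_nt: str, germline_nt: str) -> int:
    """Hamming mutation count over non-ambiguous positions.

    The caller supplies equal-length gapless sequences; positions where either
    base is N are excluded. No internal alignment is performed.
    """
    if len(observed_nt) != len(germline_nt):
        raise ParameterError("observed and germline sequences differ in length; align upstream")
    if not observed_nt:
        raise ParameterError("sequences must be non-empty")
    obs, germ = observed_nt.upper(), germline_nt.upper()
    return sum(a != b for a, b in zip(obs, germ) if a != "N" and b != "N")


def top_n_fraction(clones_or_abundances, n: int) -> float:
    """Fraction of the repertoire held by the ``n`` most frequent lineages.

    Accepts either a list of :class:`BcrClone` (grouped into lineages, cells
    counted) or a plain per-lineage abundance vector.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    items = list(clones_or_abundances)
    if not items:
        raise AnalysisError("empty repertoire")
    if isinstance(items[0], BcrClone):
        abundances = [lin.n_cells for lin in group_lineages(items)]
    else:
        abundances = [float(x) for x in items]
        if any(a < 0 for a in abundances):
            raise ParameterError("abundances must be non-negative")
    total = sum(abundances)
    if total == 0:
        raise AnalysisError("repertoire has zero total abundance")
    return sum(sorted(abundances, reverse=True)[:n]) / total
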