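"""Reading and writing the tabular repertoire formats the pipeline touches.

Bulk TCRβ repertoires travel as AIRR-C Rearrangement TSV files; paired-chain
single-cell data arrive as 10x-style ``filtered_contig_annotations.csv``
tables. Both readers validate strictly: rows that fail validation are dropped
and counted rather than silently kept, and missing mandatory columns raise a
:class:`~repseq.errors.FormatError` naming the column.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio.Seq import Seq

from .errors import EmptySampleError, FormatError, ParameterError

CHAINS = {"TRB", "TRA", "IGH", "IGK", "IGL"}
CONDITIONS = {"baseline", "k27m_expanded", "wt_expanded", "unstimulated"}
COMPARTMENTS = {"PBMC", "CSF"}
CELL_FRACTIONS = {"bulk", "CD4", "CD8"}

_DNA = set("ACGTN")
_AA = set("ACDEFGHIKLMNPQRSTVWY*X")


def translate_nt(nt: str) -> str:
    """Standard-code translation of an in-frame nucleotide string."""
    trimmed = nt[: len(nt) // 3 * 3]
    return str(Seq(trimmed).translate())


@dataclass
class Clonotype:
    """One rearranged receptor chain with junction sequences and abundance.

    ``count`` is in templates or UMIs; ``read_support``/``umi_support`` carry
    the raw sequencing evidence used by the convergence filters.
    """

    chain: str
    cdr3_nt: str
    cdr3_aa: str
    v_call: str
    j_call: str
    d_call: str | None = None
    count: int = 0
    frequency: float = 0.0
    read_support: int = 1
    umi_support: int = 1
    productive: bool = True

    def __post_init__(self):
        if self.chain not in CHAINS:
            raise ParameterError(f"unknown chain {self.chain!r}")
        if self.count < 0:
            raise ParameterError("count must be non-negative")
        if self.read_support < 1 or self.umi_support < 1:
            raise ParameterError("read/umi support must be positive")

    @property
    def key(self) -> tuple[str, str, str]:
        """Nucleotide-level clonotype identity: (v_call, j_call, cdr3_nt)."""
        return (self.v_call, self.j_call, self.cdr3_nt)

    @property
    def aa_key(self) -> tuple[str, str, str]:
        return (self.v_call, self.j_call, self.cdr3_aa)


@dataclass
class RepertoireSample:
    """A set of clonotypes from one sample (timepoint, condition, compartment)."""

    sample_id: str
    subject: str = ""
    timepoint_weeks: float = 0.0
    condition: str = "unstimulated"
    compartment: str = "PBMC"
    cell_fraction: str = "bulk"
    clonotypes: list[Clonotype] = field(default_factory=list)
    qc: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise ParameterError(f"unknown condition {self.condition!r}")
        if self.compartment not in COMPARTMENTS:
            raise ParameterError(f"unknown compartment {self.compartment!r}")
        if self.cell_fraction not in CELL_FRACTIONS:
            raise ParameterError(f"unknown cell fraction {self.cell_fraction!r}")
        keys = [c.key for c in self.clonotypes]
        if len(keys) != len(set(keys)):
            raise ParameterError("duplicate clonotype keys within one sample")
        total = sum(c.frequency for c in self.clonotypes)
        if total > 1.0 + 1e-9:
            raise ParameterError(f"frequencies sum to {total} > 1")

    def __len__(self) -> int:
        return len(self.clonotypes)

    @property
    def total_count(self) -> int:
        return sum(c.count for c in self.clonotypes)

    def frequencies(self) -> dict[tuple[str, str, str], float]:
        return {c.key: c.frequency for c in self.clonotypes}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([_clonotype_row(c) for c in self.clonotypes])


@dataclass
class PairedTcr:
    """A paired αβ TCR reconstituted from single-cell contigs.

    Cells natively expressing two α chains keep both; the β chain defines the
    clone. ``clone_id`` follows the P/C naming convention: origin letter
    (P = expanded PBMC, C = CSF) plus the frequency rank.
    """

    clone_id: str
    beta: Clonotype
    alphas: list[Clonotype]
    origin: str = "PBMC_expanded"
    frequency_rank: int = 1

    def __post_init__(self):
        if not 1 <= len(self.alphas) <= 2:
            raise ParameterError("a paired TCR must carry one or two alpha chains")
        if self.origin not in {"PBMC_expanded", "CSF"}:
            raise ParameterError(f"unknown origin {self.origin!r}")
        if self.frequency_rank < 1:
            raise ParameterError("frequency_rank must be positive")


# ---------------------------------------------------------------------------
# AIRR-C Rearrangement TSV
# ---------------------------------------------------------------------------

AIRR_REQUIRED = ["junction", "junction_aa", "v_call", "j_call", "duplicate_count"]
AIRR_COLUMNS = [
    "sequence_id",
    "locus",
    "v_call",
    "d_call",
    "j_call",
    "junction",
    "junction_aa",
    "duplicate_count",
    "consensus_count",
    "umi_count",
    "productive",
]


def _clonotype_row(c: Clonotype) -> dict:
    return {
        "locus": c.chain,
        "v_call": c.v_call,
        "d_call": c.d_call or "",
        "j_call": c.j_call,
        "junction": c.cdr3_nt,
        "junction_aa": c.cdr3_aa,
        "duplicate_count": c.count,
        "consensus_count": c.read_support,
        "umi_count": c.umi_support,
        "productive": c.productive,
        "frequency": c.frequency,
    }


def _valid_row(junction: str, junction_aa: str, productive: bool) -> bool:
    if not junction or set(junction.upper()) - _DNA:
        return False
    if junction_aa and set(junction_aa.upper()) - _AA:
        return False
    # translation consistency is only enforceable for in-frame junctions
    if junction_aa and productive and len(junction) % 3 == 0 and "N" not in junction.upper():
        if translate_nt(junction.upper()) != junction_aa.upper():
            return False
    return True


def read_airr(
    path,
    *,
    sample_id: str | None = None,
    subject: str = "",
    timepoint_weeks: float = 0.0,
    condition: str = "unstimulated",
    compartment: str = "PBMC",
    cell_fraction: str = "bulk",
    chain: str = "TRB",
    keep_nonproductive: bool = False,
) -> RepertoireSample:
    """Read an AIRR-C Rearrangement TSV into a validated :class:`RepertoireSample`.

    Rows failing validation are dropped and counted in ``sample.qc``; duplicate
    clonotype keys are merged by summing counts (replicate sequencing of one
    rearrangement); non-productive rearrangements are excluded unless
    ``keep_nonproductive``. Frequencies are recomputed as count / total count.
    """
    path = Path(path)
    try:
        table = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise EmptySampleError(f"{path}: file is empty")
    for col in AIRR_REQUIRED:
        if col not in table.columns:
            raise FormatError(f"{path}: missing mandatory AIRR column {col!r}")
    if len(table) == 0:
        raise EmptySampleError(f"{path}: no rearrangement rows")

    qc = {"n_rows": len(table), "dropped_invalid": 0, "dropped_nonproductive": 0, "merged_duplicates": 0}
    merged: dict[tuple[str, str, str], Clonotype] = {}
    def clean(value) -> str:
        text = "" if value is None else str(value)
        return "" if text.lower() in {"", "nan", "none"} else text

    for row in table.itertuples(index=False):
        junction = clean(getattr(row, "junction", "")).upper()
        junction_aa = clean(getattr(row, "junction_aa", "")).upper()
        v_call = clean(getattr(row, "v_call", ""))
        j_call = clean(getattr(row, "j_call", ""))
        productive = (clean(getattr(row, "productive", "")) or "T").upper() in {"T", "TRUE", "1"}
        try:
            count = int(float(getattr(row, "duplicate_count")))
        except (TypeError, ValueError):
            qc["dropped_invalid"] += 1
            continue
        if not v_call or not j_call or count < 0 or not _valid_row(junction, junction_aa, productive):
            qc["dropped_invalid"] += 1
            continue
        if not productive and not keep_nonproductive:
            qc["dropped_nonproductive"] += 1
            continue
        if not junction_aa and len(junction) % 3 == 0:
            junction_aa = translate_nt(junction)
        d_call = clean(getattr(row, "d_call", "")) or None
        reads = _opt_int(getattr(row, "consensus_count", None), default=1)
        umis = _opt_int(getattr(row, "umi_count", None), default=1)
        locus = str(getattr(row, "locus", "") or "") or chain
        clone = Clonotype(
            chain=locus if locus in CHAINS else chain,
            cdr3_nt=junction,
            cdr3_aa=junction_aa,
            v_call=v_call,
            j_call=j_call,
            d_call=d_call,
            count=count,
            read_support=reads,
            umi_support=umis,
            productive=productive,
        )
        if clone.key in merged:
            prev = merged[clone.key]
            prev.count += clone.count
            prev.read_support += clone.read_support
            prev.umi_support += clone.umi_support
            qc["merged_duplicates"] += 1
        else:
            merged[clone.key] = clone

    clonotypes = list(merged.values())
    if not clonotypes:
        raise EmptySampleError(f"{path}: all rows were dropped during validation")
    total = sum(c.count for c in clonotypes)
    if total > 0:
        for c in clonotypes:
            c.frequency = c.count / total
    return RepertoireSample(
        sample_id=sample_id or path.stem,
        subject=subject,
        timepoint_weeks=timepoint_weeks,
        condition=condition,
        compartment=compartment,
        cell_fraction=cell_fraction,
        clonotypes=clonotypes,
        qc=qc,
    )


def _opt_int(value, default: int) -> int:
    try:
        out = int(float(value))
    except (TypeError, ValueError):
        return default
    return out if out >= 1 else default


def write_airr(sample: RepertoireSample, path) -> None:
    """Write a sample as an AIRR-C Rearrangement TSV (header-only when empty)."""
    rows = []
    for i, c in enumerate(sample.clonotypes):
        row = _clonotype_row(c)
        row["sequence_id"] = f"{sample.sample_id}_{i + 1}"
        row["productive"] = "T" if c.productive else "F"
        rows.append(row)
    columns = AIRR_COLUMNS + ["frequency"]
    frame = pd.DataFrame(rows, columns=columns)
    frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# 10x-style filtered contig CSV
# ---------------------------------------------------------------------------

CONTIG_REQUIRED = [
    "barcode",
    "chain",
    "v_gene",
    "d_gene",
    "j_gene",
    "cdr3",
    "cdr3_nt",
    "reads",
    "umis",
    "raw_clonotype_id",
]


@dataclass
class PairingReport:
    """Exclusion bookkeeping for contig pairing."""

    n_clonotypes: int = 0
    n_paired: int = 0
    n_beta_only: int = 0
    n_alpha_only: int = 0
    n_ambiguous: int = 0
    ambiguous_ids: list[str] = field(default_factory=list)


def read_paired_contigs(path, *, origin: str = "PBMC_expanded") -> tuple[list[PairedTcr], PairingReport]:
    """Group 10x filtered contigs into paired αβ TCRs.

    Cells (clonotypes) with exactly one β and one or two α chains yield a
    :class:`PairedTcr`; β-only and α-only clonotypes are excluded and counted;
    clonotypes with more than one β or more than two α contigs are flagged
    ambiguous and excluded. Clone ids follow the P/C + frequency-rank
    convention, ranked by descending cell count.
    """
    path = Path(path)
    try:
        table = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        raise EmptySampleError(f"{path}: file is empty")
    for col in CONTIG_REQUIRED:
        if col not in table.columns:
            raise FormatError(f"{path}: missing mandatory contig column {col!r}")

    report = PairingReport()
    prefix = "P" if origin == "PBMC_expanded" else "C"
    grouped: list[tuple[str, int, Clonotype, list[Clonotype]]] = []
    for clonotype_id, contig_rows in table.groupby("raw_clonotype_id", sort=False):
        report.n_clonotypes += 1
        n_cells = contig_rows["barcode"].nunique()
        chains: dict[str, list[Clonotype]] = {"TRB": [], "TRA": []}
        for _, row in contig_rows.drop_duplicates(subset=["chain", "v_gene", "j_gene", "cdr3_nt"]).iterrows():
            chain = str(row["chain"])
            if chain not in chains:
                continue
            d_gene = str(row.get("d_gene", "") or "")
            chains[chain].append(
                Clonotype(
                    chain=chain,
                    cdr3_nt=str(row["cdr3_nt"]).upper(),
                    cdr3_aa=str(row["cdr3"]).upper(),
                    v_call=str(row["v_gene"]),
                    j_call=str(row["j_gene"]),
                    d_call=d_gene if d_gene and d_gene.lower() not in {"nan", "none"} else None,
                    count=n_cells,
                    read_support=max(1, _opt_int(row["reads"], default=1)),
                    umi_support=max(1, _opt_int(row["umis"], default=1)),
                )
            )
        n_beta, n_alpha = len(chains["TRB"]), len(chains["TRA"])
        if n_beta > 1 or n_alpha > 2:
            report.n_ambiguous += 1
            report.ambiguous_ids.append(str(clonotype_id))
        elif n_beta == 0 and n_alpha >= 1:
            report.n_alpha_only += 1
        elif n_beta == 1 and n_alpha == 0:
            report.n_beta_only += 1
        elif n_beta == 1:
            grouped.append((str(clonotype_id), n_cells, chains["TRB"][0], chains["TRA"]))

    grouped.sort(key=lambda item: (-item[1], item[0]))
    pairs = [
        PairedTcr(clone_id=f"{prefix}{rank}", beta=beta, alphas=alphas, origin=origin, frequency_rank=rank)
        for rank, (_, _, beta, alphas) in enumerate(grouped, start=1)
    ]
    report.n_paired = len(pairs)
    return pairs, report
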