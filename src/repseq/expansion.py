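"""Candidate nomination by peptide-driven expansion and longitudinal tracking.

The screen compares the clonotype frequency of mutant-peptide-expanded
PBMC against the wild-type-peptide-expanded control: clonotypes whose
frequency rises specifically under the mutant peptide are nominated for
functional validation, with preference to the greatest ex vivo expansion.
Validated clonotypes are then tracked through bulk repertoires over time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .errors import AnalysisError, ParameterError
from .io import RepertoireSample

Key = tuple[str, str, str]  # (v_call, j_call, cdr3_nt)


@dataclass
class ExpansionRecord:
    key: Key
    freq_k27m: float
    freq_wt: float
    freq_unstim: float | None
    log2_ratio: float
    rank: int = 0


def default_pseudocount(*samples: RepertoireSample) -> float:
    """One template in the shallower sample: 1 / min total count."""
    totals = [s.total_count for s in samples if s is not None and s.total_count > 0]
    if not totals:
        raise ParameterError("cannot derive a pseudocount from empty samples")
    return 1.0 / min(totals)


def expansion_table(
    k27m: RepertoireSample,
    wt: RepertoireSample,
    unstim: RepertoireSample | None = None,
    pseudo: float | None = None,
) -> list[ExpansionRecord]:
    """Per-clonotype mutant-over-wild-type expansion ratios, dense-ranked.

    The table covers the union of clonotype keys across inputs (missing keys
    contribute frequency 0); ``log2_ratio = log2((f_mut + pseudo) /
    (f_wt + pseudo))``. Ranking is dense by descending ratio, then descending
    mutant frequency. The default pseudocount is one template of the
    shallower sample, making an absent clonotype indistinguishable from a
    single-template one.
    """
    if pseudo is None:
        pseudo = default_pseudocount(k27m, wt)
    if not pseudo > 0:
        raise ParameterError("pseudocount must be positive")
    f_mut = k27m.frequencies()
    f_wt = wt.frequencies()
    f_un = unstim.frequencies() if unstim is not None else None
    keys = set(f_mut) | set(f_wt) | (set(f_un) if f_un else set())
    records = []
    for key in keys:
        fm = f_mut.get(key, 0.0)
        fw = f_wt.get(key, 0.0)
        records.append(
            ExpansionRecord(
                key=key,
                freq_k27m=fm,
                freq_wt=fw,
                freq_unstim=f_un.get(key, 0.0) if f_un is not None else None,
                log2_ratio=math.log2((fm + pseudo) / (fw + pseudo)),
            )
        )
    records.sort(key=lambda r: (-r.log2_ratio, -r.freq_k27m, r.key))
    rank = 0
    last = None
    for r in records:
        if last is None or (r.log2_ratio, r.freq_k27m) != last:
            rank += 1
            last = (r.log2_ratio, r.freq_k27m)
        r.rank = rank
    return records


def select_candidates(
    table: list[ExpansionRecord],
    min_log2_ratio: float = 1.0,
    min_freq: float = 1e-4,
    top_n: int = 100,
) -> list[ExpansionRecord]:
    """Thresholded, rank-truncated candidate list.

    Keeps records with ``log2_ratio >= min_log2_ratio`` and
    ``freq_k27m >= min_freq``, in rank order, truncated to ``top_n``. Fully
    parameterized: the screening preference for the greatest ex vivo
    expansion corresponds to the rank order.
    """
    if not (math.isfinite(min_log2_ratio) and math.isfinite(min_freq)):
        raise ParameterError("thresholds must be finite")
    passing = [r for r in table if r.log2_ratio >= min_log2_ratio and r.freq_k27m >= min_freq]
    passing.sort(key=lambda r: r.rank)
    return passing[: top_n if top_n is not None else len(passing)]


@dataclass
class TrackingTable:
    """Per-timepoint frequency of a designated reactive clonotype set."""

    timepoints: list[float]
    totals: list[float]
    per_clonotype: pd.DataFrame  # rows = keys, columns = timepoints

    def to_frame(self) -> pd.DataFrame:
        frame = self.per_clonotype.copy()
        frame.loc["total"] = self.totals
        return frame


def track_clonotypes(
    samples: list[RepertoireSample],
    reactive_keys,
    match_on: str = "nt",
) -> TrackingTable:
    """Track the summed frequency of a reactive clonotype set over time.

    Keys are ``(v_call, j_call, cdr3_nt)`` by default; ``match_on="aa"``
    matches on ``(v_call, j_call, cdr3_aa)`` instead, which pools convergent
    nucleotide variants of one amino-acid clonotype. Clonotypes absent at a
    timepoint contribute 0.
    """
    if not samples:
        raise ParameterError("at least one sample is required")
    if match_on not in {"nt", "aa"}:
        raise ParameterError("match_on must be 'nt' or 'aa'")
    timepoints = [s.timepoint_weeks for s in samples]
    if len(set(timepoints)) != len(timepoints):
        raise AnalysisError("duplicate timepoints in the longitudinal sample list")
    order = sorted(range(len(samples)), key=lambda i: timepoints[i])
    keys = sorted(set(reactive_keys))
    rows = {key: [] for key in keys}
    totals = []
    for i in order:
        sample = samples[i]
        freq = {}
        for c in sample.clonotypes:
            k = c.key if match_on == "nt" else c.aa_key
            freq[k] = freq.get(k, 0.0) + c.frequency
        total = 0.0
        for key in keys:
            f = freq.get(tuple(key), 0.0)
            rows[key].append(f)
            total += f
        totals.append(total)
    sorted_tp = [timepoints[i] for i in order]
    frame = pd.DataFrame(rows, index=sorted_tp).T
    frame.columns = sorted_tp
    return TrackingTable(timepoints=sorted_tp, totals=totals, per_clonotype=frame)
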