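"""Synthetic data with the statistical structure the analysis assumes.

Every pipeline input can be generated here, so each downstream stage is
testable against planted ground truth without any sequencing download:

* bulk TCRβ repertoires across peptide-expansion conditions, with power-law
  clone sizes, planted mutant-peptide responders and planted convergent
  clonotype groups;
* V(D)J junctions recombined from an embedded germline reference with
  explicit D-segment orientation and reading-frame bookkeeping;
* two-population fluorescence mixtures for reporter cocultures;
* allele-determined presenting-line panel reactivity with call noise;
* BCR clonal lineages accumulating somatic hypermutation.

All generators are deterministic given their seed, and the planted truth is
returned beside the data, never inside it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from Bio.Seq import Seq

from .bcr import BcrClone
from .errors import AnalysisError, ParameterError
from .germline import TRBD_SEGMENTS, TRBJ_SEGMENTS, TRBV_SEGMENTS, GermlineSegment
from .hla import LineGenotype, PanelReactivityMatrix
from .io import Clonotype, RepertoireSample, translate_nt
from .reactivity import FlowHistogram

_BASES = np.array(list("ACGT"))

# Synonymous codon families of the standard code, for junction re-encoding.
_SYNONYMS: dict[str, list[str]] = {}
for _b1 in "ACGT":
    for _b2 in "ACGT":
        for _b3 in "ACGT":
            _codon = _b1 + _b2 + _b3
            _aa = str(Seq(_codon).translate())
            _SYNONYMS.setdefault(_aa, []).append(_codon)
CODON_TO_AA = {c: aa for aa, codons in _SYNONYMS.items() for c in codons}


# ---------------------------------------------------------------------------
# V(D)J junction recombination
# ---------------------------------------------------------------------------


@dataclass
class VdjRearrangement:
    """A simulated junction plus the bookkeeping the D-usage oracle needs."""

    clonotype: Clonotype
    d_core: str  # retained D-derived substring, in junction orientation
    d_core_start: int  # 0-based position of the core within the junction
    orientation: str | None
    frame: int | None  # reading frame of the D segment within the CDR3


def recombine_vdj(
    v: GermlineSegment,
    d: GermlineSegment | None,
    j: GermlineSegment,
    orientation: str = "direct",
    frame_offset: int = 0,
    rng_seed: int = 0,
    *,
    d_core_start: int | None = None,
    d_core_len: int | None = None,
    v_trim: int | None = None,
    j_trim: int | None = None,
    n1_len: int | None = None,
    n2_len: int | None = None,
    max_tries: int = 200,
) -> VdjRearrangement:
    """Build one junction: trimmed V end + N + oriented D core + N + trimmed J start.

    The retained D core starts at offset ``d_core_start`` (default: the
    requested ``frame_offset``) within the oriented D sequence, and the first
    untemplated region is padded so that the core is read in reading frame
    ``frame_offset`` of the D segment. The junction length is padded to a
    multiple of 3 and untemplated bases are re-drawn until the translation is
    productive (no stop codon). Without a D segment, orientation and frame
    are ignored and the junction carries no D-derived nucleotides.
    """
    if orientation not in {"direct", "inverted"}:
        raise ParameterError(f"orientation must be direct or inverted, got {orientation!r}")
    if frame_offset not in {0, 1, 2}:
        raise ParameterError("frame_offset must be 0, 1 or 2")
    rng = np.random.default_rng(rng_seed)

    core = ""
    core_start_d = 0
    if d is not None:
        oriented = d.sequence_nt.upper()
        if orientation == "inverted":
            oriented = str(Seq(oriented).reverse_complement())
        core_start_d = frame_offset if d_core_start is None else d_core_start
        remaining = len(oriented) - core_start_d
        length = remaining if d_core_len is None else d_core_len
        if core_start_d < 0 or length < 1 or core_start_d + length > len(oriented):
            raise ParameterError(
                f"requested retained D core [{core_start_d}, {core_start_d + length}) "
                f"exceeds the {len(oriented)} nt segment"
            )
        core = oriented[core_start_d : core_start_d + length]

    v_seq = v.sequence_nt.upper()
    j_seq = j.sequence_nt.upper()
    for attempt in range(max_tries):
        vt = int(rng.integers(0, min(4, len(v_seq) - 3 + 1))) if v_trim is None else v_trim
        jt = int(rng.integers(0, min(4, len(j_seq) - 3 + 1))) if j_trim is None else j_trim
        if not 0 <= vt <= len(v_seq) - 3 or not 0 <= jt <= len(j_seq) - 3:
            raise ParameterError("trim exceeds segment length")
        v_part = v_seq[: len(v_seq) - vt]
        j_part = j_seq[jt:]
        n1 = int(rng.integers(2, 7)) if n1_len is None else n1_len
        if d is not None:
            # pad N1 so the D core lands in reading frame `frame_offset` of D
            n1 += (core_start_d - frame_offset - (len(v_part) + n1)) % 3
        n2 = int(rng.integers(2, 7)) if n2_len is None else n2_len
        total = len(v_part) + n1 + len(core) + n2 + len(j_part)
        n2 += (-total) % 3
        junction = (
            v_part
            + "".join(rng.choice(_BASES, n1))
            + core
            + "".join(rng.choice(_BASES, n2))
            + j_part
        )
        aa = translate_nt(junction)
        if "*" not in aa:
            return VdjRearrangement(
                clonotype=Clonotype(
                    chain="TRB",
                    cdr3_nt=junction,
                    cdr3_aa=aa,
                    v_call=v.name,
                    j_call=j.name,
                    d_call=d.name if d is not None else None,
                ),
                d_core=core,
                d_core_start=len(v_part) + n1 if d is not None else -1,
                orientation=orientation if d is not None else None,
                frame=frame_offset if d is not None else None,
            )
        if n1_len is not None and n2_len is not None and v_trim is not None and j_trim is not None:
            break  # fully pinned layout cannot escape a stop codon by retrying
    raise ParameterError("could not build a productive junction for the requested layout")


def _safe_d_layouts() -> list[tuple[GermlineSegment, str, int]]:
    """(segment, orientation, frame) combinations whose full-length core is stop-free."""
    layouts = []
    for seg in TRBD_SEGMENTS:
        seq = seg.sequence_nt.upper()
        for orientation, oriented in (("direct", seq), ("inverted", str(Seq(seq).reverse_complement()))):
            for frame in range(3):
                if "*" not in translate_nt(oriented[frame:]):
                    layouts.append((seg, orientation, frame))
    return layouts


# ---------------------------------------------------------------------------
# Peptide-expansion study
# ---------------------------------------------------------------------------


@dataclass
class SimConfig:
    """Study-generator settings.

    Baseline clone sizes follow a discrete power law (Zipf-like,
    ``p_i ∝ i**-abundance_exponent``); peptide-driven expansion multiplies
    the frequency of planted responders by ``expansion_fold`` before
    renormalization; the control conditions carry multiplicative log-normal
    frequency noise of standard deviation ``noise_sd`` (natural-log scale).
    ``depth`` is the number of sequenced templates per sample.
    """

    n_clonotypes: int = 1000
    abundance_exponent: float = 1.2
    n_responders: int = 20
    expansion_fold: float = 10.0
    n_convergent_groups: int = 2
    convergent_group_size: int = 3
    dual_alpha_rate: float = 0.1
    noise_sd: float = 0.3
    depth: int = 100_000
    seed: int = 0

    def __post_init__(self):
        if self.n_clonotypes < 1:
            raise ParameterError("n_clonotypes must be positive")
        if self.abundance_exponent <= 1.0:
            raise ParameterError("abundance_exponent must exceed 1")
        if not 0 <= self.n_responders <= self.n_clonotypes:
            raise ParameterError("n_responders must be between 0 and n_clonotypes")
        if self.expansion_fold < 1.0:
            raise ParameterError("expansion_fold must be >= 1")
        if self.n_convergent_groups < 0 or (self.n_convergent_groups and self.convergent_group_size < 2):
            raise ParameterError("convergent groups need size >= 2")
        if not 0.0 <= self.dual_alpha_rate <= 1.0:
            raise ParameterError("dual_alpha_rate must be in [0, 1]")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be non-negative")
        if self.depth < 1:
            raise ParameterError("depth must be positive")


@dataclass
class StudyTruth:
    """Planted labels, keyed by (v_call, j_call, cdr3_nt)."""

    responder_keys: set
    convergent_groups: list[set]
    base_frequencies: dict


@dataclass
class StudySim:
    samples: dict[str, RepertoireSample]
    truth: StudyTruth
    config: SimConfig


def _synonymous_variants(junction: str, n_variants: int, rng: np.random.Generator) -> list[str]:
    """Distinct synonymous re-encodings of a junction, varied at central codons."""
    codons = [junction[i : i + 3] for i in range(0, len(junction), 3)]
    n_codons = len(codons)
    window = [
        i
        for i in range(max(1, n_codons // 3), max(1, n_codons // 3) + max(1, n_codons - 2 * (n_codons // 3)))
        if i < n_codons - 1 and len(_SYNONYMS[CODON_TO_AA[codons[i]]]) > 1
    ] or [i for i in range(1, n_codons - 1) if len(_SYNONYMS[CODON_TO_AA[codons[i]]]) > 1]
    if not window:
        raise AnalysisError("junction has no degenerate codon to re-encode")
    variants: set[str] = set()
    for _ in range(200 * n_variants):
        if len(variants) == n_variants:
            break
        new = list(codons)
        for i in rng.choice(window, size=min(len(window), int(rng.integers(1, 3))), replace=False):
            options = [c for c in _SYNONYMS[CODON_TO_AA[codons[i]]] if c != codons[i]]
            new[i] = options[int(rng.integers(len(options)))]
        candidate = "".join(new)
        if candidate != junction:
            variants.add(candidate)
    if len(variants) < n_variants:
        raise AnalysisError("junction degeneracy insufficient for the requested variant count")
    return sorted(variants)


def simulate_study(config: SimConfig) -> StudySim:
    """Simulate one subject's four-condition expansion study with truth labels.

    Returns baseline, mutant-peptide-expanded, wild-type-peptide-expanded and
    unstimulated samples, all multinomially sequenced at ``config.depth``.
    Responders are expanded only under the mutant peptide; the control
    conditions see only log-normal noise. Convergent groups are planted by
    synonymously re-encoding a clonotype's junction, so group members share
    amino-acid sequence and V/J genes while differing in nucleotides.
    """
    rng = np.random.default_rng(config.seed)
    layouts = _safe_d_layouts()

    clones: list[Clonotype] = []
    seen_nt: set = set()
    seen_aa: set = set()
    while len(clones) < config.n_clonotypes:
        v = TRBV_SEGMENTS[int(rng.integers(len(TRBV_SEGMENTS)))]
        j = TRBJ_SEGMENTS[int(rng.integers(len(TRBJ_SEGMENTS)))]
        if rng.random() < 0.9:
            d, orientation, frame = layouts[int(rng.integers(len(layouts)))]
        else:
            d, orientation, frame = None, "direct", 0
        try:
            rearr = recombine_vdj(v, d, j, orientation, frame, rng_seed=int(rng.integers(2**31)))
        except ParameterError:
            continue
        c = rearr.clonotype
        if c.key in seen_nt or c.aa_key in seen_aa:
            continue  # keep planted convergence the only convergence
        seen_nt.add(c.key)
        seen_aa.add(c.aa_key)
        clones.append(c)

    freqs = np.arange(1, config.n_clonotypes + 1, dtype=float) ** (-config.abundance_exponent)
    responder_idx = set(
        int(i) for i in rng.choice(config.n_clonotypes, size=config.n_responders, replace=False)
    )

    # plant convergent groups on well-sampled, non-responder clones
    convergent_groups: list[set] = []
    eligible = [i for i in range(min(60, config.n_clonotypes)) if i not in responder_idx]
    seeds = list(rng.choice(eligible, size=min(config.n_convergent_groups, len(eligible)), replace=False))
    extra_clones: list[Clonotype] = []
    extra_freqs: list[float] = []
    for seed_idx in seeds:
        seed_clone = clones[int(seed_idx)]
        group = {seed_clone.key}
        for variant_nt in _synonymous_variants(seed_clone.cdr3_nt, config.convergent_group_size - 1, rng):
            variant = Clonotype(
                chain="TRB",
                cdr3_nt=variant_nt,
                cdr3_aa=seed_clone.cdr3_aa,
                v_call=seed_clone.v_call,
                j_call=seed_clone.j_call,
                d_call=seed_clone.d_call,
            )
            if variant.key in seen_nt:
                raise AnalysisError("synonymous variant collided with an existing clonotype")
            seen_nt.add(variant.key)
            extra_clones.append(variant)
            extra_freqs.append(freqs[int(seed_idx)])
            group.add(variant.key)
        convergent_groups.append(group)

    clones = clones + extra_clones
    freqs = np.concatenate([freqs, np.array(extra_freqs, dtype=float)])
    freqs = freqs / freqs.sum()
    responder_keys = {clones[i].key for i in responder_idx}

    fold = np.ones(len(clones))
    for i in responder_idx:
        fold[i] = config.expansion_fold

    def noisy(base: np.ndarray) -> np.ndarray:
        if config.noise_sd == 0:
            return base
        return base * rng.lognormal(0.0, config.noise_sd, size=len(base))

    condition_freqs = {
        "baseline": freqs,
        "k27m_expanded": freqs * fold,
        "wt_expanded": noisy(freqs),
        "unstimulated": noisy(freqs),
    }
    samples = {}
    for condition, weights in condition_freqs.items():
        p = weights / weights.sum()
        counts = rng.multinomial(config.depth, p)
        observed = []
        for clone, count in zip(clones, counts):
            if count == 0:
                continue
            observed.append(
                Clonotype(
                    chain=clone.chain,
                    cdr3_nt=clone.cdr3_nt,
                    cdr3_aa=clone.cdr3_aa,
                    v_call=clone.v_call,
                    j_call=clone.j_call,
                    d_call=clone.d_call,
                    count=int(count),
                    frequency=count / config.depth,
                    read_support=int(count),
                    umi_support=int(count),
                )
            )
        samples[condition] = RepertoireSample(
            sample_id=f"sim_{condition}",
            subject="SIM01",
            timepoint_weeks=4.0,
            condition=condition,
            compartment="PBMC",
            cell_fraction="CD4",
            clonotypes=observed,
        )
    truth = StudyTruth(
        responder_keys=responder_keys,
        convergent_groups=convergent_groups,
        base_frequencies={c.key: float(f) for c, f in zip(clones, freqs)},
    )
    return StudySim(samples=samples, truth=truth, config=config)


# ---------------------------------------------------------------------------
# Flow-cytometry mixtures
# ---------------------------------------------------------------------------


@dataclass
class FlowSim:
    test: FlowHistogram
    control: FlowHistogram
    true_positive_fraction: float


FLOW_BIN_EDGES = np.linspace(0.0, 5.0, 1025)  # 1024 bins on log10 fluorescence


def simulate_flow(
    reactive: bool,
    n_events: int,
    shift: float = 1.5,
    seed: int = 0,
    positive_fraction: float = 0.5,
    background_mean: float = 1.6,
    background_sd: float = 0.3,
) -> FlowSim:
    """Two-population fluorescence mixture for one coculture well.

    Events live on a log10 fluorescence scale and are binned into 1024 fixed
    bins (cytometer convention). The control well is pure log-normal
    background; when ``reactive``, a fraction ``positive_fraction`` of test
    events is shifted up by ``shift`` decades. The planted positive fraction
    is recorded in the result.
    """
    if n_events < 1:
        raise ParameterError("n_events must be positive")
    if not 0.0 <= positive_fraction <= 1.0:
        raise ParameterError("positive_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    control = rng.normal(background_mean, background_sd, n_events)
    n_pos = int(round(positive_fraction * n_events)) if reactive else 0
    test = np.concatenate(
        [
            rng.normal(background_mean, background_sd, n_events - n_pos),
            rng.normal(background_mean + shift, background_sd, n_pos),
        ]
    )
    lo, hi = FLOW_BIN_EDGES[0], FLOW_BIN_EDGES[-1]
    control = np.clip(control, lo, hi - 1e-9)
    test = np.clip(test, lo, hi - 1e-9)
    return FlowSim(
        test=FlowHistogram.from_events(test, FLOW_BIN_EDGES, channel="GFP", label="test"),
        control=FlowHistogram.from_events(control, FLOW_BIN_EDGES, channel="GFP", label="control"),
        true_positive_fraction=n_pos / n_events,
    )


# ---------------------------------------------------------------------------
# Presenting-line panel
# ---------------------------------------------------------------------------


@dataclass
class PanelSim:
    matrix: PanelReactivityMatrix
    truth_calls: dict[str, bool]  # line_id -> noise-free reactivity
    flipped_lines: list[str]


def simulate_panel(
    restricting_allele: str,
    genotypes: list[LineGenotype],
    cross_reactive=(),
    noise_rate: float = 0.0,
    seed: int = 0,
    tcr_id: str = "TCR1",
) -> PanelSim:
    """Single-TCR reactivity row over a genotyped presenting-line panel.

    A line is truly reactive iff it carries the restricting allele or any
    cross-reactive allele; each call is flipped with probability
    ``noise_rate``, and percent values are drawn consistently with the final
    call (reactive wells high, background wells low). If the restricting
    allele is absent from every line the matrix is all-negative and a warning
    is issued.
    """
    if not 0.0 <= noise_rate <= 1.0:
        raise ParameterError("noise_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    cross = set(cross_reactive)
    present = any(restricting_allele in g.alleles for g in genotypes)
    if not present:
        warnings.warn(f"restricting allele {restricting_allele} absent from all panel lines", stacklevel=2)
    values, calls, flipped = [], [], []
    truth = {}
    for g in genotypes:
        true_call = present and (restricting_allele in g.alleles or bool(cross & g.alleles))
        truth[g.line_id] = true_call
        call = true_call
        if present and rng.random() < noise_rate:
            call = not call
            flipped.append(g.line_id)
        values.append(rng.uniform(25.0, 60.0) if call else rng.uniform(0.0, 2.0))
        calls.append(call)
    matrix = PanelReactivityMatrix(
        tcr_ids=[tcr_id],
        line_ids=[g.line_id for g in genotypes],
        values=np.array([values]),
        calls=np.array([calls]),
    )
    return PanelSim(matrix=matrix, truth_calls=truth, flipped_lines=flipped)


def random_panel_genotypes(
    autologous_alleles,
    n_lines: int,
    carriage_prob: float = 0.35,
    rng: np.random.Generator | None = None,
    require_unique_patterns: bool = True,
    max_tries: int = 200,
) -> list[LineGenotype]:
    """Random partially-matched panel: each line carries each allele independently.

    Optionally redraws until every allele's carrier pattern is unique and
    non-empty (the identifiable regime for deconvolution).
    """
    rng = np.random.default_rng() if rng is None else rng
    alleles = sorted(set(autologous_alleles))
    for _ in range(max_tries):
        carriage = rng.random((n_lines, len(alleles))) < carriage_prob
        patterns = [tuple(carriage[:, k]) for k in range(len(alleles))]
        if not require_unique_patterns or (
            len(set(patterns)) == len(alleles) and all(any(p) for p in patterns)
        ):
            return [
                LineGenotype(f"LCL{i + 1}", {alleles[k] for k in range(len(alleles)) if carriage[i, k]})
                for i in range(n_lines)
            ]
    raise AnalysisError("could not draw a panel with unique carrier patterns")


# ---------------------------------------------------------------------------
# BCR lineages
# ---------------------------------------------------------------------------


@dataclass
class BcrLineageSim:
    clones: list[BcrClone]
    germline_heavy_nt: str
    germline_light_nt: str
    true_shm_heavy: list[int]
    true_shm_light: list[int]


_IGHV_NAMES = ["IGHV1-69*01", "IGHV3-23*01", "IGHV4-34*01", "IGHV3-7*01", "IGHV1-2*01"]
_IGHJ_NAMES = ["IGHJ4*01", "IGHJ6*01", "IGHJ3*01"]
_ISOTYPE_CHOICES = ["IGG1", "IGA1", "IGM", "IGG3"]
_ISOTYPE_PROBS = [0.55, 0.2, 0.15, 0.1]


def _random_coding(n_codons: int, rng: np.random.Generator) -> str:
    codons = [c for c in CODON_TO_AA if CODON_TO_AA[c] != "*"]
    return "".join(codons[int(rng.integers(len(codons)))] for _ in range(n_codons))


def _mutate(seq: str, shm_rate: float, rng: np.random.Generator) -> tuple[str, int]:
    arr = np.array(list(seq))
    mask = rng.random(len(arr)) < shm_rate
    for pos in np.flatnonzero(mask):
        options = [b for b in "ACGT" if b != arr[pos]]
        arr[pos] = options[int(rng.integers(3))]
    return "".join(arr), int(mask.sum())


def simulate_bcr_lineage(
    n_members: int,
    shm_rate: float,
    seed: int = 0,
    heavy_len: int = 350,
    light_len: int = 330,
    junction_aa_len: int = 20,
    light_junction_aa_len: int = 10,
    v_call: str | None = None,
    j_call: str | None = None,
) -> BcrLineageSim:
    """One clonal lineage: members derive from a naive ancestor by independent
    point mutations at per-base probability ``shm_rate``; class-switched
    isotype labels are assigned per member and true SHM counts recorded.
    """
    if n_members < 1:
        raise ParameterError("n_members must be >= 1")
    if not 0.0 <= shm_rate < 1.0:
        raise ParameterError("shm_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    v_name = v_call or _IGHV_NAMES[int(rng.integers(len(_IGHV_NAMES)))]
    j_name = j_call or _IGHJ_NAMES[int(rng.integers(len(_IGHJ_NAMES)))]
    lv_name, lj_name = "IGKV1-39*01", "IGKJ1*01"

    heavy_codons = heavy_len // 3
    germ_heavy = _random_coding(heavy_codons, rng)
    h_start = 3 * (heavy_codons - junction_aa_len - 5)
    h_end = h_start + 3 * junction_aa_len
    light_codons = light_len // 3
    germ_light = _random_coding(light_codons, rng)
    l_start = 3 * (light_codons - light_junction_aa_len - 5)
    l_end = l_start + 3 * light_junction_aa_len

    clones, shm_h, shm_l = [], [], []
    for i in range(n_members):
        obs_h, n_h = _mutate(germ_heavy, shm_rate, rng)
        obs_l, n_l = _mutate(germ_light, shm_rate, rng)
        isotype = str(rng.choice(_ISOTYPE_CHOICES, p=_ISOTYPE_PROBS))
        clones.append(
            BcrClone(
                cell_id=f"B{i + 1}",
                heavy=Clonotype(
                    chain="IGH",
                    cdr3_nt=obs_h[h_start:h_end],
                    cdr3_aa=translate_nt(obs_h[h_start:h_end]),
                    v_call=v_name,
                    j_call=j_name,
                    count=1,
                ),
                light=Clonotype(
                    chain="IGK",
                    cdr3_nt=obs_l[l_start:l_end],
                    cdr3_aa=translate_nt(obs_l[l_start:l_end]),
                    v_call=lv_name,
                    j_call=lj_name,
                    count=1,
                ),
                isotype=isotype,
                shm_heavy=n_h,
                shm_light=n_l,
                heavy_seq_nt=obs_h,
                light_seq_nt=obs_l,
            )
        )
        shm_h.append(n_h)
        shm_l.append(n_l)
    return BcrLineageSim(
        clones=clones,
        germline_heavy_nt=germ_heavy,
        germline_light_nt=germ_light,
        true_shm_heavy=shm_h,
        true_shm_light=shm_l,
    )


def simulate_bcr_repertoire(
    lineage_sizes: list[int],
    shm_rate: float,
    seed: int = 0,
) -> tuple[list[BcrClone], list[int]]:
    """Several independent lineages pooled; returns (clones, lineage labels).

    Lineage ancestors are drawn independently with varying V/J genes and
    junction lengths; ancestors that would collide with an existing lineage's
    (V, J, junction length) bucket at high amino-acid identity are redrawn so
    that the planted partition is unambiguous.
    """
    rng = np.random.default_rng(seed)
    clones: list[BcrClone] = []
    labels: list[int] = []
    signatures: list[tuple[str, str, int, str]] = []
    for label, size in enumerate(lineage_sizes):
        for _ in range(100):
            sim = simulate_bcr_lineage(
                size,
                shm_rate,
                seed=int(rng.integers(2**31)),
                junction_aa_len=int(rng.integers(14, 23)),
            )
            v = sim.clones[0].heavy.v_call
            j = sim.clones[0].heavy.j_call
            germ_cdr3 = sim.clones[0].heavy.cdr3_aa
            clash = any(
                v == sv and j == sj and len(germ_cdr3) == slen
                and sum(a == b for a, b in zip(germ_cdr3, scdr3)) / slen > 0.6
                for sv, sj, slen, scdr3 in signatures
            )
            if not clash:
                signatures.append((v, j, len(germ_cdr3), germ_cdr3))
                break
        else:
            raise AnalysisError("could not draw a non-colliding lineage ancestor")
        for clone in sim.clones:
            clone.cell_id = f"L{label + 1}_{clone.cell_id}"
        clones.extend(sim.clones)
        labels.extend([label] * size)
    return clones, labels
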