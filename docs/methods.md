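# Methods

This note records the models, defaults and numerical choices behind each
stage of the pipeline, what the synthetic-data generator does and does not
emulate, and the known limitations.

## Repertoire I/O

Bulk repertoires are carried as AIRR-C Rearrangement TSVs with mandatory
columns `junction`, `junction_aa`, `v_call`, `j_call`, `duplicate_count`
(optional: `locus`, `d_call`, `consensus_count`, `umi_count`, `productive`,
`frequency`). Counts are authoritative: frequencies are recomputed as
count / Σcount on read, so a returned sample always sums to 1 ± 1e-9.
Duplicate clonotype keys (V gene, J gene, junction) within one file are
merged by summing counts — they are read as sequencing replicates of one
rearrangement. Rows failing validation (non-DNA junctions, negative counts,
amino-acid junctions inconsistent with the standard-code translation of an
in-frame nucleotide junction) are dropped and counted in `sample.qc`, never
silently kept. Non-productive rearrangements are excluded from frequencies
by default (`keep_nonproductive=True` retains them); public repertoire
pipelines differ on this point and the choice is therefore exposed.

Paired-chain input uses the 10x filtered-contig CSV dialect. Cells with one
β and one or two α chains become `PairedTcr` objects — dual-α cells are one
biological clone whose two α chains are screened separately downstream.
β-only, α-only and ambiguous (>1β or >2α) clonotypes are excluded with
counts reported. Clone ids follow the P/C convention: origin letter
(P = expanded PBMC, C = CSF) plus frequency rank, rank 1 being the most
frequent.

## Synthetic-data generator

The generator's defaults define the study conditions every statistical test
runs under.

**Repertoire study** (`simulate_study`): baseline clone frequencies follow a
discrete power law, `p_i ∝ i^−a` with `a = 1.2` — close to the Zipf-like
rank–frequency laws reported for human TCR repertoires — over
`n_clonotypes = 1000` clones, sequenced multinomially at `depth = 10^5`
templates per sample. `n_responders = 20` randomly chosen clones have their
frequency multiplied by `expansion_fold = 10` in the mutant-peptide condition
(then renormalized); the wild-type-expanded and unstimulated controls carry
only multiplicative log-normal noise (`noise_sd = 0.3` on the natural-log
scale). Junctions are recombined from a small embedded germline set: the 3'
ends of six TRBV genes, the 5' starts of five TRBJ genes, and the
full-length IMGT TRBD1\*01 / TRBD2\*01 sequences (the two D sequences are
exact IMGT alleles because the orientation/frame analysis depends on their
nucleotide content; the V/J ends are representative junction-proximal
fragments). Convergent groups (default 2 groups of 3) are planted by
synonymously re-encoding a well-sampled clonotype's junction at central
codons, so members share amino-acid sequence and V/J genes but differ in
nucleotides; clone generation rejects accidental amino-acid collisions so
the planted groups are the only convergence present. Truth labels
(responder keys, convergent group keys, generating frequencies) are returned
beside the samples and never written into the data tables.

What this generator does *not* emulate: sequencing error, PCR amplification
bias, contamination between samples, or repertoire drift between visits.
Tests passing on it show the analysis recovers planted structure under
sampling and abundance noise, not that it is robust to artifact nucleotide
variants — which is precisely why the convergence detector's support filters
exist and default to ≥2 reads and ≥2 UMIs.

**Flow mixtures** (`simulate_flow`): events live on a log10 fluorescence
scale, background N(1.6, 0.3), binned into 1024 fixed bins over [0, 5]
(cytometer convention). A reactive well shifts a fraction π (default 0.5) of
events up by `shift` decades (default 1.5). The generator records the
planted π.

**Panel reactivity** (`simulate_panel`): a line is truly reactive iff it
carries the restricting allele or a designated cross-reactive allele; each
call flips with probability `noise_rate`; percent values are drawn
consistently with the final call (25–60% for positive wells, 0–2% for
background). `random_panel_genotypes` draws each autologous allele per line
independently (carriage probability 0.35) and redraws until every allele's
carrier pattern is unique and non-empty — the identifiable regime.

**BCR lineages** (`simulate_bcr_lineage`): members derive from one random
naive ancestor (350 nt heavy, 330 nt light V-region; heavy junction 20
amino acids by default) by independent per-base substitutions at `shm_rate`;
SHM is uniform along the sequence (no hotspot model). True per-member
mutation counts are recorded; because mutated positions are drawn as a mask,
the Hamming distance to germline equals the truth exactly.

## Expansion screening

`log2_ratio = log2((f_mut + ε)/(f_wt + ε))` over the union of clonotype
keys; the default pseudocount ε is one template of the shallower sample,
making an absent clonotype indistinguishable from a single-template one.
Frequencies, not counts, enter the ratio (depth-invariant). Selection
defaults: `min_log2_ratio = 1` (two-fold specific expansion),
`min_freq = 1e-4` (≥10 templates at the default depth, suppressing
rare-clone ratio noise), `top_n = 100` (the scale of a cloning/screening
campaign). Tracking matches on nucleotide keys by default; amino-acid
matching is opt-in and pools convergent variants of one clonotype.

## Convergence detection

Groups form on identical CDR3 amino-acid sequence — plus V and J gene
(allele calls truncated to gene level, allele miscalls being common) for
bulk data, or the amino-acid CDR3s of both chains for paired data — with
members below 2 reads or 2 UMIs excluded first and identical-nucleotide
entries collapsed. The divergence-location score reports the fraction of
divergent positions inside the central window of the junction: genuine
convergent recombination diverges at the V(D)J junction, sequencing
artifacts do not respect it.

## TRBD orientation/frame analysis

The D locus contributes such short cores that orientation and frame are
enumerable: 6 translations per segment (direct and inverted × 3 frames),
translation truncated at the first stop codon. With the IMGT \*01 alleles
exactly one of the 12 combinations encodes glutamine (TRBD1, direct,
frame 1 → GQG). Junction annotation uses the longest exact substring match
against each oriented segment (`min_match = 5`; mismatch-tolerant alignment
would inflate false assignments on 12–16 nt segments); the frame is where
the junction's codon boundaries fall within the D segment,
`(d_offset − junction_offset) mod 3`, which is invariant to how far an
accidental match extends. Ties break toward the longer match, direct over
inverted, TRBD1 over TRBD2.

Enrichment uses two-sided Fisher's exact tests (sum of all tables with
probability ≤ observed — the standard convention; sidedness is a choice and
is documented here). The odds ratio applies the Haldane 0.5 correction when
any cell is zero. "Central" residue positivity means occurrence within the
middle third of the CDR3 (window fraction configurable).

## Reactivity scoring

Overton percent positive is computed on per-bin frequencies normalized to
each histogram's own event total — depth-invariant — with no rebinning:
mismatched bin edges are an error. Raw per-bin subtraction carries a
positive null bias of order √(occupied bins / events) (≈5–7% at 2×10^4
events over 1024 bins); an optional odd moving-average window suppresses it
(≈1% at window 51) and is off by default, the original method being
raw-bin. The demo pipeline scores with window 51 for this reason.

Calling defaults `min_gfp = 3%`, `min_ha = 20%`, `max_wt_gfp = 2%` are
estimates chosen so that the weakest accepted activity on record (3.1% GFP /
24.9% HA with no wild-type signal) passes while wild-type cross-reactive
TCRs fail regardless of mutant signal; they are configurable and should be
re-derived per assay.

4PL fits run on the log-concentration scale with multi-start initialization
(4 EC50 starts spanning the dose range × 2 Hill starts) under
`scipy.optimize.least_squares`; a response flat to within 0.1% of its
magnitude, or a fitted amplitude below 2% of the observed range, returns a
failure flag instead of an EC50. Competition fits are the same model with a
descending response; the IC50 is the inflection concentration.

## HLA restriction

Locus assignment: the parental line must be reactive and exactly one
knockout (DRA, DQA or DPA) must abrogate reactivity; anything else is
unresolved with a diagnostic. A DQA knockout removes both DQ heterodimers,
so DQA1 versus DQB1 restriction cannot be separated at this step; the panel
step reports β-chain alleles and the α-chain ambiguity stands.

Allele deconvolution prefers, in order: (1) an autologous allele at the
locus whose carrier lines are exactly the reactive lines (unique →
`exact`, several — e.g. alleles co-occurring on one haplotype → all
returned, `ambiguous`); (2) alleles carried only by reactive lines, taking
the widest coverage and explaining remaining reactive lines by a minimal
set of cross-reactive panel alleles (exhaustive set cover when the locus
allele universe has ≤12 alleles, greedy otherwise); (3) with call noise,
the allele(s) minimizing the number of lines whose call contradicts the
carrier pattern, those lines flagged and confidence `inconsistent`. Alleles
are matched at two-field resolution; closely related alleles are distinct.
Panel calls default to ≥10% HA-positive (configurable; no published
threshold exists).

Population coverage treats genes independently under Hardy–Weinberg:
carrier probability `1 − (1 − Σf)²` per gene over the union of usable
alleles, combined as `1 − Π(1 − carrier)`. Haplotype linkage (e.g. DRB1 and
DQB1 alleles co-segregating) is deliberately not modeled; users with
haplotype tables should pool linked alleles into one pseudo-gene before
calling, otherwise coverage across linked loci is overestimated.

## BCR analysis

Lineages are heavy-chain defined — same V and J gene, equal junction
length, CDR3 amino-acid identity ≥ 0.85, single linkage — with light chains
as a veto when both members carry one (different light V/J genes or
junction lengths block a link). SHM is a Hamming count against a
caller-supplied gapless germline (N positions excluded); there is no
internal aligner, so inputs must be pre-aligned, as the simulator's outputs
are. Clonality is the top-N lineage fraction, counting cells.

## Problem sizes and determinism

The test suite and `scripts/acceptance.py` use the default study conditions
above: 10^5-template repertoires over ~1000 clones, 5×10^4-event flow
mixtures, 500 replicate 20-line panels at 5% call noise, 2000-replicate
Fisher null calibration at n = 500 per arm, exhaustive Fisher-versus-
enumeration comparison over all 2×2 tables with row margins ≤ 30 (evaluated
once per symmetry orbit), 200-replicate 4PL recovery at 5% multiplicative
noise, and 20-replicate BCR lineage recovery. Everything is seeded; the
acceptance script derives all randomness from its `--seed`.

## Known limitations

* Recovery of a clonal lineage *intact* at identity 0.85 is stochastic: a
  member whose CDR3 happens to accumulate enough amino-acid changes falls
  below the single-linkage threshold (measured intact fraction ≈0.7–0.9 per
  10-member lineage at `shm_rate = 0.02` across junction lengths 14–22 aa).
  This mirrors real clonal-grouping behavior at fixed identity cutoffs.
* The expansion screen's null behavior (fold 1) leaves candidate selection
  at the false-positive rate of the thresholds (~5% of sufficiently
  abundant clones), so recall and false-positive rate coincide — candidate
  lists from a null experiment are noise, by design detectable via the
  planted-truth report.
* Fisher's exact test is conservative on small tables; the null calibration
  at n = 500 per arm sits near the nominal 5% precisely because the margins
  are large. Small-margin enrichment tests should be read as conservative.
* D-segment annotation cannot assign a frame to junctions whose retained
  core is shorter than `min_match`, and an N-region coincidentally matching
  a D segment for ≥5 nt produces a spurious assignment (~1 in 4^5 per
  offset); both behaviors are inherent to exact-match annotation of short
  cores.
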