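# Methods

`effectome` implements a multi-omics calling procedure for rhizobial type
III secretion effectors (T3Es): genes whose promoters carry a tts-box (the
binding motif of the TtsI activator), whose expression is TtsI-dependent
and flavonoid-induced, and whose protein products appear in culture
supernatant only when the type III secretion system (T3SS) is intact. This
note documents the models, the parameters that matter, the synthetic-data
generator, and the numerical and design choices.

## Motif scanning and transcriptional units

Genes are grouped into transcriptional units by a linear scan over
coordinate-sorted genes: a unit breaks at a strand change or when the
intergenic gap exceeds `max_gap` (default 200 bp, a common prokaryotic
operon heuristic). The unit lead is the most 5′ member on the unit strand.
Promoter windows are the `window` bp (default 600, a typical upstream
regulatory span in bacteria) immediately 5′ of the lead gene's start
codon; minus-strand promoters are reverse-complemented, coordinates are
kept in plus-strand space, and windows truncate (never pad) at contig
ends.

The scanner supports an IUPAC consensus with a mismatch budget and a
log-odds PWM with a score threshold, on both strands. An `N` (or any
ambiguity code) in the *genome* never matches a consensus position —
conservative hit calling. Hits are assigned to the unit whose promoter
window contains them; with `bidirectional` on (the default), a hit is
also assigned to a divergently transcribed unit whose lead start codon
lies within `window` bp on the opposite strand. This captures the
configuration in which a single intergenic tts-box drives transcription
in both orientations (as observed for the rhcC1 / nopB-operon pair).

The packaged default motif (`data/tts_box_consensus.txt`,
`TCGTCARCTTTTCG`, ≤2 mismatches) is an approximate conserved core shipped
for convenience; analyses of real genomes should substitute the consensus
or PWM from the primary literature on TtsI binding sites. Every test in
this repository uses synthetic motifs, so no result here depends on the
shipped string.

Symbiotic-island membership uses the gene midpoint against BED intervals
(0-based half-open; conversion to the internal 1-based inclusive GFF3
convention is centralized in `io_utils`). The midpoint rule gives an
unambiguous call for boundary-straddling genes.

## Differential expression

The design crosses strain (WT vs *ttsI* mutant) with inducer (genistein vs
DMSO), two biological replicates each. Two contrasts classify every gene:
TtsI dependence (WT+genistein over mutant+genistein) and genistein
induction (WT+genistein over WT+DMSO). A gene is called when its fold
change is ≥ `fc_min` (default 2, with positive sign) and its BH-adjusted
p-value is < `p_max` (default 0.01; a `use_adjusted=False` switch gives
raw-p thresholds). `near_miss` marks genes clearing one cutoff but not the
other in a contrast.

The test is a transparent negative-binomial Wald test:

* **Size factors** — median-of-ratios: for sample *j*, the median over
  all-positive genes of count<sub>gj</sub> / geomean<sub>g</sub>.
* **Dispersion** — per-gene method of moments on normalized counts,
  α<sub>c</sub> = (s²<sub>c</sub> − m̄<sub>c</sub>) / m̄²<sub>c</sub>
  within each condition (each condition's own mean, so a true
  between-condition effect cannot inflate the estimate), df-weighted
  across conditions and floored at 10⁻⁸. With only 4 residual degrees of
  freedom this raw estimate is far too noisy to support a calibrated Wald
  test, so the test path moderates it toward the across-gene mean with
  `prior_df = 30` pseudo-degrees of freedom — a scalar analogue of the
  variance moderation universally used for few-replicate designs. The
  pure per-gene estimator remains available (`prior_df = 0`).
* **Wald statistic** — log2FC = log2(m₁/m₂) on per-condition means of
  normalized counts, with zero or near-zero means floored at a 0.5
  pseudocount; SE from the NB delta method,
  var(log m) ≈ (1/m + α)/n per condition. p-values are two-sided from a
  Student-t reference at residual + prior degrees of freedom rather than
  the normal: at 2+2 replicates the normal reference is markedly
  anti-conservative (empirically ~5× the nominal 1 % type-I error on null
  NB data), while the t reference keeps the type-I error at 0.4–1.2 % and
  the null p-value distribution uniform. The two references coincide as
  df grows.
* **Multiplicity** — Benjamini–Hochberg over all tested genes
  (statsmodels).

## Comparative secretome

Peptide identifications per LC-MS run pass a target-decoy FDR filter: the
score cutoff is the smallest observed score *s* with
#decoys≥s / #targets≥s ≤ `fdr_max` (default 0.01); decoys are then
discarded. A protein is detected in a run when ≥ `min_unique` (default 2)
distinct peptide sequences map to it uniquely — peptides shared between
proteins never count. Strain-level presence uses the `any` rule by default
(detected in ≥1 of the runs; `majority` available), matching
presence/absence conventions in shotgun proteomics.

The comparative rule: a protein is candidate-secreted iff present in the
supernatant of WT or the TtsI over-expressor and absent from both T3SS
deletion strains. This is a hard set-theoretic rule — any detection in a
T3SS-mutant supernatant disqualifies, with no statistical leniency.
Candidates are then filtered by localization class (membrane, cytosolic
and classically secreted proteins excluded; unknown and
predicted-effector retained) and, for the survivors, by symbiotic-island
membership of the encoding gene (`require_island`, default on).
Localization is an input annotation; the package does not predict it.
Matches to a user-supplied OMV (outer-membrane-vesicle) background list
are annotated, never excluded, since OMV lysis explains cytosolic and
membrane proteins in supernatants without bearing on T3SS dependence.
T3SS machinery proteins are reported separately: a machinery protein with
the candidate pattern is a `needle_component` (e.g. the NopA pilin), one
present in mutant supernatants is `secreted_t3ss_independent` (the NopX
translocon case), and one never detected is `not_secreted` (the NopB
case).

## Evidence integration and tiers

Each locus accumulates boolean evidence on three axes: motif/regulation
(tts-box or TtsI dependence), secretion, and prior knowledge (in-silico
prediction or homology to a known effector). Tiers, in precedence order:

1. `CONFIRMED_ALL_METHODS` — tts-box ∧ TtsI-regulated ∧ T3SS-secreted.
   Homology is corroborating, not required.
2. `PREDICTION_REJECTED` — a prior prediction with neither regulation nor
   secretion support. A near-miss regulation call blocks rejection: a
   gene just under the significance or fold-change cutoff has weak
   experimental support and stays a candidate.
3. `CANDIDATE_MULTI` — at least two axes (not confirmed/rejected).
4. `CANDIDATE_SINGLE` — exactly one axis.
5. `NOT_EFFECTOR` — no evidence, or TtsI dependence alone for a gene
   outside the symbiotic island (housekeeping regulon members such as
   flagellar or metabolic genes; retained in the report, not tiered as
   candidates).

Adding a motif, regulation or secretion flag never demotes a tier
(property-tested). Adding a *prior-prediction* flag can: a motif-only
locus becomes a rejected prediction, because rejection is precisely the
state of an in-silico claim that the experimental assays failed to
support. The rule "at least two axes" rather than "exactly two" for
`CANDIDATE_MULTI` is deliberate: a prior prediction with a tts-box that
is secreted but not regulated carries three axes yet is not confirmed.

## Synthetic data

The generator produces the inputs the stages assume, all randomness
flowing from one seed (identical configs are byte-identical):

* **Genome** — sequentially packed non-overlapping genes (300–1200 bp,
  gaps 60–250 bp) on random strands on one contig; a contiguous island
  covering `island_span` (default 0.25) of the genome; `n_planted_effectors`
  (default 10 of 200 genes) chosen inside the island, forced to lead
  their transcriptional units, each with one concrete realization of the
  IUPAC motif written into its promoter window on its own strand.
* **Counts** — NB with gene base means log-uniform on [20, 2000] (spanning
  low and high expressors), one shared simulation dispersion (default
  0.1; the estimator still fits per gene), per-sample library factors
  log-uniform on [0.5, 2], and the planted effect — mean × 2^`planted_log2fc`
  (default 3.0) — confined to WT+genistein. Two replicates per condition.
* **Peptides** — three runs per strain across the four secretome strains.
  Planted effectors yield their peptides (4 per protein, ~N(60, 8)
  scores) in every secretion-competent-strain run and never in ΔT3SS
  runs; OMV background (15 % of genes, membrane/cytosolic), lysis
  background (10 %, cytosolic) and classical secretion (5 %) appear in
  all strains at a per-run presence rate of 0.8 (replicate-level
  detection variability is unreported in real data and is a free
  parameter here); decoys are generated 1:1 with scores ~N(25, 8), a
  minimal two-Gaussian model sufficient to exercise target-decoy FDR.

What the generator does **not** emulate: read-level noise and mapping
artifacts, dispersion trends with expression, correlated peptide
detectability (ionization efficiency, protein length), razor peptides,
chimeric/fragmented CDSs, and multi-contig genomes. Passing tests
therefore demonstrate the correctness and calibration of the decision
rules under the assumed statistical structure, not performance on raw
instrument output.

## Fixture tables

Small per-locus tables encode a published worked example of this analysis
(27 prior predictions with regulation statuses, 18 machinery genes, a
563-protein secretome universe whose comparative rule yields 212
candidates and — after the 51 membrane / 58 cytosolic / 25 classical
exclusions, the island filter on 62 unknown-localization proteins and the
needle separation — 18 effector candidates, a 36-locus evidence matrix
with 13 confirmed loci, and a 61-gene regulon with 12 members outside the
island). Loci not individually named in the source text are labelled
`unspecified_*` and are synthetic placeholders; fixture coordinates are
synthetic layouts constructed so the geometric filters reproduce the
recorded memberships. Tests assert totals and named loci only.

## Problem sizes and runtime

The test-suite and the acceptance script use deliberately small instances:
60–80-gene genomes with 4–6 planted effectors for end-to-end runs, 2000
genes for null calibration, 500 for effect recovery, 10 seeds for
FDR/recall averages. These sizes give stable statistics in seconds; all
operations are linear or near-linear in genes × samples and scale to
bacterial-genome-sized inputs unchanged.

## Known limitations

* The NB test has no GLM: it handles one-factor contrasts between
  condition pairs, which is exactly the 2×2 design here, but not
  covariates or interactions.
* Dispersion moderation uses a scalar target, not a mean-dispersion
  trend; strongly expression-dependent dispersion would be mis-moderated.
* Protein inference stops at unique-peptide counting; no parsimony or
  razor-peptide assignment.
* The island filter assumes a meaningful island annotation; for organisms
  without one, `require_island=False` disables it.
* Tier assignment treats evidence as boolean; effect sizes and detection
  strength do not influence tiers beyond the upstream cutoffs.
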