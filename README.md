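# effectome

Multi-omics identification of rhizobial **type III secretion effectors**
(T3Es). Many bradyrhizobia nodulate legumes through a type III secretion
system (T3SS) that injects effector proteins into host cells; cataloguing
a strain's effectors ("the effectome") requires combining several partial
lines of evidence, none sufficient alone:

* a **tts-box** promoter motif, the binding site of TtsI — the
  flavonoid-induced master regulator of the T3SS regulon;
* **TtsI-dependent, genistein-induced transcription**, from an RNA-seq
  comparison of wild type vs a *ttsI* mutant with and without inducer;
* **T3SS-dependent secretion**, from comparative shotgun proteomics of
  culture supernatants: present for wild type and a TtsI over-expressor,
  absent for T3SS deletion mutants;
* prior **in-silico predictions** and homology to known effectors.

This package implements the full decision chain as a tested library with
a CLI: strand-aware tts-box scanning over transcriptional units, a
negative-binomial Wald test for the 2×2 induction design, target-decoy
peptide FDR and two-unique-peptide protein validation feeding the
comparative secretion rule with localization / OMV-background / island
filters, and a per-locus evidence matrix with effector confidence tiers.
A synthetic-data generator produces genomes, count matrices and peptide
tables with planted ground truth, so every rule is exercised end to end.

## The statistics at the core

For gene *g* with normalized condition means m₁, m₂ and moderated NB
dispersion α̂:

    log2FC = log2(m1 / m2)
    SE     = sqrt((1/m1 + α̂)/n1 + (1/m2 + α̂)/n2) / ln 2
    W      = log2FC / SE  ~  t(df_resid + df_prior)   under H0

with median-of-ratios size factors, per-gene within-condition moment
dispersion moderated toward the across-gene mean, and Benjamini–Hochberg
multiplicity control. A gene is TtsI-dependent when fold change ≥ 2 and
adjusted p < 0.01 against the *ttsI* mutant, genistein-induced by the same
thresholds against the uninduced control.

For the secretome, the score cutoff *s* is the smallest observed score
with #decoys≥s / #targets≥s ≤ 1 %, proteins need ≥2 uniquely mapping
peptides per run, and

    candidate  ⇔  present(WT ∪ OETtsI)  ∧  absent(ΔT3SS)  ∧  absent(ΔT3SS-OETtsI)

followed by localization and symbiotic-island filtering. Tier
`CONFIRMED_ALL_METHODS` requires motif ∧ regulation ∧ secretion; see
`docs/methods.md` for the complete tier logic.

## Worked example

Run the whole pipeline on a synthetic dataset with 80 genes, 6 planted
effectors and a fixed seed:

```bash
effectome run --simulate --seed 7 --outdir demo_out
```

or in Python:

```python
from effectome.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(simulate=True, seed=7, outdir="demo_out",
                     sim={"n_genes": 80, "n_planted_effectors": 6})
result = run_pipeline(cfg)
print(result.summary["report"])
```

which prints:

```
Effector evidence report
========================
loci considered: 80

   CONFIRMED_ALL_METHODS: 6
         CANDIDATE_MULTI: 0
        CANDIDATE_SINGLE: 7
     PREDICTION_REJECTED: 0
            NOT_EFFECTOR: 67

                   prior: 0
       transcriptome_new: 0
            proteome_new: 6
                   other: 74

confirmed by all methods:
  gene0031
  gene0040
  gene0042
  gene0045
  gene0046
  gene0047
```

All six planted effectors reach the confirmed tier: each carries its
planted tts-box, is called TtsI-dependent and genistein-induced by the NB
test, and passes the comparative secretion rule. The seven
`CANDIDATE_SINGLE` loci carry motif evidence only — genes sharing a
transcriptional unit with a planted tts-box plus members of one unit with
a chance motif match — with neither regulation nor secretion support:
exactly the false-positive surface that combining omics layers is
designed to cut down.
`demo_out/` contains every intermediate table (motif hits, contrast
statistics, detection matrix, secretome calls, evidence matrix, tiers)
as provenance-stamped TSVs.

Stage-level subcommands (`effectome simulate / scan / de / secretome /
integrate / fixtures`) expose the same steps on user-supplied files; see
`--help` of each.

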