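"""Synthetic inputs with the statistical structure the pipeline assumes.

The generator emulates the study design the analysis stages expect:

* a single-contig bacterial genome with non-overlapping CDSs, a contiguous
  symbiotic island, and a planted TtsI regulon — effector genes inside the
  island with a concrete tts-box realization written into their promoter
  window on the correct strand;
* a four-condition (strain x inducer) RNA-seq count matrix, negative
  binomial with gene-specific base means, a common simulation dispersion,
  per-sample library-size factors, and the planted effect (mean multiplied
  by 2**planted_log2fc) confined to WT + genistein;
* per-run peptide tables for the four secretome strains, with T3SS-
  dependent effector peptides restricted to secretion-competent strains,
  OMV/lysis/classical-secretion background appearing everywhere, and decoy
  peptides drawn from a null score distribution.

All randomness flows from ``SimulationConfig.seed``; identical configs give
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from .genome_annotate import GeneModel, IslandDefinition, IUPAC, reverse_complement
from .io_utils import (gff_interval_to_bed, write_bed, write_fasta, write_gff3,
                       write_tsv)
from .secretome import STRAINS, T3SS_POSITIVE

BASES = "ACGT"
AMINO = "ACDEFGHILMNPQSTVWY"  # K/R reserved for tryptic C-termini


@dataclass
class SimulationConfig:
    seed: int = 0
    n_genes: int = 200
    island_span: float = 0.25
    n_planted_effectors: int = 10
    motif_consensus: str = "TCGTCARCTTTTCG"
    promoter_window: int = 600
    nb_mean_log_range: tuple[float, float] = (math.log(20.0), math.log(2000.0))
    nb_dispersion: float = 0.1
    planted_log2fc: float = 3.0
    n_replicates_rna: int = 2
    n_runs_proteome_per_strain: int = 3
    background_rates: dict = field(default_factory=lambda: {
        "omv_fraction": 0.15, "lysis_fraction": 0.10})
    decoy_ratio: float = 1.0
    # peptide-score model: targets and decoys are both Gaussian; the decoy
    # distribution doubles as the null for spurious identifications
    target_score_mean: float = 60.0
    decoy_score_mean: float = 25.0
    score_sd: float = 8.0
    peptides_per_protein: int = 4
    background_run_presence: float = 0.8
    classical_fraction: float = 0.05

    def validate(self) -> None:
        if not 0.0 <= self.island_span <= 1.0:
            raise ValueError("island_span must be in [0, 1]")
        for key, val in self.background_rates.items():
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"background rate {key} must be in [0, 1]")
        if not 0.0 <= self.classical_fraction <= 1.0:
            raise ValueError("classical_fraction must be in [0, 1]")
        if self.n_planted_effectors > self.n_genes * self.island_span * 0.5:
            raise ValueError(
                "too many planted effectors for the island: need "
                "n_planted_effectors <= n_genes * island_span * 0.5")
        if self.decoy_ratio <= 0:
            raise ValueError("decoy_ratio must be positive")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        bad = set(self.motif_consensus.upper()) - set(IUPAC)
        if bad:
            raise ValueError(f"motif consensus has non-IUPAC codes {bad}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["nb_mean_log_range"] = [float(x) for x in self.nb_mean_log_range]
        return d


@dataclass
class SyntheticGenome:
    contig: str
    sequence: str
    genes: list[GeneModel]
    island: IslandDefinition
    truth: pd.DataFrame              # one row per gene (GroundTruth)
    planted_motifs: pd.DataFrame     # gene_id, start, end, strand, realized


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def _realize_consensus(consensus: str, rng: np.random.Generator) -> str:
    return "".join(rng.choice(sorted(IUPAC[c])) for c in consensus.upper())


def simulate_genome(cfg: SimulationConfig) -> SyntheticGenome:
    """Lay out genes sequentially, pick an island block, plant effectors.

    Planted effector genes sit inside the island, are forced to be unit
    leads (their 5' intergenic gap exceeds the default operon max_gap), and
    carry one concrete tts-box realization in their promoter window on
    their own strand. Raises if the requested genes cannot be packed.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    contig = "chr"
    motif_len = len(cfg.motif_consensus)

    lengths = rng.integers(300, 1200, cfg.n_genes)
    strands = rng.choice(["+", "-"], cfg.n_genes)
    base_gaps = rng.integers(60, 250, cfg.n_genes)

    # provisional layout to locate the island block
    starts = np.empty(cfg.n_genes, dtype=int)
    pos = 1
    for i in range(cfg.n_genes):
        pos += int(base_gaps[i])
        starts[i] = pos
        pos += int(lengths[i])
    genome_len_est = pos + 300

    island_len = int(round(cfg.island_span * genome_len_est))
    island_lo = (genome_len_est - island_len) // 2
    island_hi = island_lo + island_len
    mids = starts + lengths // 2
    island_gene_idx = np.flatnonzero((mids >= island_lo) & (mids < island_hi))
    if len(island_gene_idx) < cfg.n_planted_effectors:
        raise ValueError(
            f"island holds only {len(island_gene_idx)} genes; cannot plant "
            f"{cfg.n_planted_effectors} effectors (genome too small)")
    planted_idx = set(rng.choice(island_gene_idx, cfg.n_planted_effectors,
                                 replace=False).tolist())

    # final layout: widen the 5'-side gap of planted genes so each one
    # leads its own transcriptional unit and has room for the motif
    lead_gap = 350 + rng.integers(0, 150, cfg.n_genes)
    gaps = base_gaps.copy()
    for i in range(cfg.n_genes):
        before = i in planted_idx and strands[i] == "+"
        after = (i - 1) in planted_idx and strands[i - 1] == "-"
        if before and after:
            # motifs on both sides of this gap must not collide
            gaps[i] = lead_gap[i] + 400
        elif before or after:
            gaps[i] = lead_gap[i]
    starts = np.empty(cfg.n_genes, dtype=int)
    pos = 1
    for i in range(cfg.n_genes):
        pos += int(gaps[i])
        starts[i] = pos
        pos += int(lengths[i])
    tail_gap = 350 if (cfg.n_genes - 1) in planted_idx and strands[-1] == "-" \
        else 200
    genome_len = pos + tail_gap

    seq = rng.choice(list(BASES), genome_len)
    # island interval re-derived on the final layout
    island_len = int(round(cfg.island_span * genome_len))
    island_lo = (genome_len - island_len) // 2
    island_hi = island_lo + island_len
    mids = starts + lengths // 2
    in_island = (mids >= island_lo) & (mids < island_hi)
    for i in planted_idx:
        if not in_island[i]:
            # layout shifted the gene out of the recomputed island; widen
            # the island to keep construction guarantees intact
            island_lo = min(island_lo, int(starts[i]) - 1)
            island_hi = max(island_hi, int(starts[i] + lengths[i]))
    in_island = (mids >= island_lo) & (mids < island_hi)

    planted_rows = []
    for i in sorted(planted_idx):
        realized = _realize_consensus(cfg.motif_consensus, rng)
        gstart, gend = int(starts[i]), int(starts[i] + lengths[i] - 1)
        offset = int(rng.integers(20, 300 - motif_len))  # within the lead gap
        if strands[i] == "+":
            mstart = gstart - offset - motif_len        # plus-strand coords
            written = realized
        else:
            mstart = gend + offset + 1
            written = reverse_complement(realized)
        mend = mstart + motif_len - 1
        seq[mstart - 1:mend] = list(written)
        planted_rows.append({"gene_id": f"gene{i + 1:04d}", "start": mstart,
                             "end": mend, "strand": strands[i],
                             "realized": realized})

    genes = []
    for i in range(cfg.n_genes):
        gid = f"gene{i + 1:04d}"
        locus_class = "effector_planted" if i in planted_idx else "other"
        genes.append(GeneModel(
            gene_id=gid, contig=contig, start=int(starts[i]),
            end=int(starts[i] + lengths[i] - 1), strand=str(strands[i]),
            product="planted effector" if i in planted_idx else "hypothetical protein",
            locus_class=locus_class))

    truth = _ground_truth(cfg, genes, planted_idx, in_island, rng)
    island = IslandDefinition([(contig, int(island_lo), int(island_hi))])
    return SyntheticGenome(contig=contig, sequence="".join(seq), genes=genes,
                           island=island, truth=truth,
                           planted_motifs=pd.DataFrame(
                               planted_rows,
                               columns=["gene_id", "start", "end", "strand",
                                        "realized"]))


def _ground_truth(cfg: SimulationConfig, genes: list[GeneModel],
                  planted_idx: set[int], in_island: np.ndarray,
                  rng: np.random.Generator) -> pd.DataFrame:
    """One GroundTruth row per simulated gene (a partition of the genome)."""
    n = len(genes)
    omv = cfg.background_rates.get("omv_fraction", 0.0)
    lysis = cfg.background_rates.get("lysis_fraction", 0.0)
    rows = []
    draws = rng.random(n)
    for i, g in enumerate(genes):
        planted = i in planted_idx
        if planted:
            loc, background = "unknown", "none"
        elif draws[i] < omv:
            loc, background = ("membrane" if rng.random() < 0.5 else "cytosolic"), "omv"
        elif draws[i] < omv + lysis:
            loc, background = "cytosolic", "lysis"
        elif draws[i] < omv + lysis + cfg.classical_fraction:
            loc, background = "secreted_classical", "classical"
        else:
            loc, background = "unknown", "none"
        rows.append({
            "gene_id": g.gene_id,
            "has_tts_box": planted,
            "ttsI_regulated": planted,
            "genistein_induced": planted,
            "secreted_t3ss": planted,
            "localization_class": loc,
            "in_island": bool(in_island[i]),
            "background": background,
        })
    return pd.DataFrame(rows).set_index("gene_id")


def write_genome(genome: SyntheticGenome, outdir: str | Path,
                 cfg: SimulationConfig) -> dict[str, Path]:
    """Write GFF3 + FASTA + island BED + ground truth + manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    feats = []
    for g in genome.genes:
        feats.append({"contig": g.contig, "type": "gene", "start": g.start,
                      "end": g.end, "strand": g.strand,
                      "attributes": {"ID": g.gene_id, "product": g.product,
                                     "locus_class": g.locus_class}})
    paths = {
        "gff3": write_gff3(feats, outdir / "genome.gff3"),
        "fasta": write_fasta({genome.contig: genome.sequence},
                             outdir / "genome.fasta"),
        "island_bed": write_bed(genome.island.intervals, outdir / "island.bed",
                                names=["symbiotic_island"]
                                * len(genome.island.intervals)),
        "truth": write_tsv(genome.truth.reset_index(),
                           outdir / "ground_truth.tsv",
                           config=cfg.to_dict(), seed=cfg.seed),
    }
    manifest = {"seed": cfg.seed, "config": cfg.to_dict()}
    mpath = outdir / "manifest.yaml"
    mpath.write_text(yaml.safe_dump(manifest, sort_keys=True))
    paths["manifest"] = mpath
    return paths


# ---------------------------------------------------------------------------
# RNA-seq counts
# ---------------------------------------------------------------------------

RNA_CONDITIONS = [("WT", "genistein"), ("WT", "DMSO"),
                  ("ttsI_mutant", "genistein"), ("ttsI_mutant", "DMSO")]


def simulate_counts(cfg: SimulationConfig, truth: pd.DataFrame,
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """NB count matrix + sample design for the 2x2 induction experiment.

    Genes flagged both ttsI_regulated and genistein_induced get their mean
    multiplied by 2**planted_log2fc in WT+genistein samples only. Library
    sizes vary via per-sample factors drawn log-uniform in [0.5, 2].
    """
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    genes = truth.index.to_list()
    n_genes = len(genes)
    samples, cond_of = [], []
    for strain, inducer in RNA_CONDITIONS:
        for rep in range(1, cfg.n_replicates_rna + 1):
            samples.append(f"{strain}_{inducer}_r{rep}")
            cond_of.append((strain, inducer))
    n_samp = len(samples)

    lo, hi = cfg.nb_mean_log_range
    base = np.exp(rng.uniform(lo, hi, n_genes))
    sf = np.exp(rng.uniform(np.log(0.5), np.log(2.0), n_samp))
    induced = (truth["ttsI_regulated"] & truth["genistein_induced"]).values
    fold = 2.0 ** cfg.planted_log2fc

    mu = base[:, None] * sf[None, :]
    is_wt_gen = np.array([c == ("WT", "genistein") for c in cond_of])
    mu[np.ix_(induced, is_wt_gen)] *= fold

    alpha = cfg.nb_dispersion
    if alpha < 1e-10:
        counts = rng.poisson(mu)
    else:
        r = 1.0 / alpha
        counts = rng.negative_binomial(r, r / (r + mu))
    counts_df = pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"),
                             columns=samples)
    design = pd.DataFrame({
        "sample_id": samples,
        "strain": [c[0] for c in cond_of],
        "inducer": [c[1] for c in cond_of],
        "replicate": [int(s.rsplit("_r", 1)[1]) for s in samples],
    })
    return counts_df, design


# ---------------------------------------------------------------------------
# proteome peptide tables
# ---------------------------------------------------------------------------

def _peptide_seq(rng: np.random.Generator, used: set[str]) -> str:
    while True:
        n = int(rng.integers(8, 16))
        pep = "".join(rng.choice(list(AMINO), n - 1)) + rng.choice(["K", "R"])
        if pep not in used:
            used.add(pep)
            return pep


def simulate_proteome(cfg: SimulationConfig, truth: pd.DataFrame,
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-run peptide identification tables + run design.

    Effector proteins (secreted_t3ss) appear with all their peptides in
    every run of the secretion-competent strains (WT, OETtsI) and never in
    the T3SS-deletion strains. OMV/lysis/classical background proteins
    appear in runs of all four strains at the configured presence rate.
    Decoys are generated at ``decoy_ratio`` times the target row count,
    with scores from the null (decoy) distribution. A small fraction of
    background peptides is shared between two proteins to exercise
    unique-peptide counting downstream.
    """
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    runs, strain_of = [], []
    for strain in STRAINS:
        for rep in range(1, cfg.n_runs_proteome_per_strain + 1):
            runs.append(f"{strain}_run{rep}")
            strain_of.append(strain)
    run_design = pd.DataFrame({"run_id": runs, "strain": strain_of,
                               "replicate": [int(r.rsplit("run", 1)[1])
                                             for r in runs]})

    effectors = truth.index[truth["secreted_t3ss"]].to_list()
    background = truth.index[truth["background"] != "none"].to_list()

    used: set[str] = set()
    peptides_of: dict[str, list[str]] = {}
    for pid in effectors + background:
        peptides_of[pid] = [_peptide_seq(rng, used)
                            for _ in range(cfg.peptides_per_protein)]
    # share one peptide between consecutive background-protein pairs
    shared_map: dict[str, str] = {}
    for a, b in zip(background[::2], background[1::2]):
        pep = _peptide_seq(rng, used)
        shared_map[pep] = f"{a};{b}"

    rows = []

    def emit(run_id, pid_field, pep, is_decoy, mean):
        rows.append({"run_id": run_id, "peptide": pep, "proteins": pid_field,
                     "score": float(rng.normal(mean, cfg.score_sd)),
                     "is_decoy": is_decoy})

    for run_id, strain in zip(runs, strain_of):
        functional = strain in T3SS_POSITIVE
        if functional:
            for pid in effectors:
                for pep in peptides_of[pid]:
                    emit(run_id, pid, pep, False, cfg.target_score_mean)
        for pid in background:
            if rng.random() < cfg.background_run_presence:
                for pep in peptides_of[pid]:
                    emit(run_id, pid, pep, False, cfg.target_score_mean)
        for pep, pair in shared_map.items():
            if rng.random() < cfg.background_run_presence:
                emit(run_id, pair, pep, False, cfg.target_score_mean)

    n_targets = len(rows)
    n_decoys = int(round(cfg.decoy_ratio * n_targets))
    for i in range(n_decoys):
        run_id = runs[int(rng.integers(0, len(runs)))]
        pep = _peptide_seq(rng, used)
        emit(run_id, f"DECOY_{i + 1:05d}", pep, True, cfg.decoy_score_mean)

    peptides = pd.DataFrame(rows, columns=["run_id", "peptide", "proteins",
                                           "score", "is_decoy"])
    return peptides, run_design


def write_omics(counts: pd.DataFrame, design: pd.DataFrame,
                peptides: pd.DataFrame, run_design: pd.DataFrame,
                truth: pd.DataFrame, outdir: str | Path,
                cfg: SimulationConfig) -> dict[str, Path]:
    outdir = Path(outdir)
    c, s = cfg.to_dict(), cfg.seed
    loc = truth.reset_index()[["gene_id", "localization_class", "in_island"]] \
        .rename(columns={"gene_id": "protein_id"})
    omv = truth.reset_index().loc[truth.reset_index()["background"] == "omv",
                                  ["gene_id"]].rename(columns={"gene_id": "protein_id"})
    return {
        "counts": write_tsv(counts.reset_index(), outdir / "counts.tsv",
                            config=c, seed=s),
        "design": write_tsv(design, outdir / "sample_design.tsv", config=c, seed=s),
        "peptides": write_tsv(peptides, outdir / "peptides.tsv", config=c, seed=s),
        "run_design": write_tsv(run_design, outdir / "run_design.tsv",
                                config=c, seed=s),
        "localization": write_tsv(loc, outdir / "localization.tsv",
                                  config=c, seed=s),
        "omv_reference": write_tsv(omv, outdir / "omv_reference.tsv",
                                   config=c, seed=s),
    }
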