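"""Top-level pipeline driver: scan -> de -> secretome -> integrate.

The driver runs either on user-supplied files (GFF3/FASTA/BED genome,
counts + design TSVs, peptide + run-design TSVs, localization and optional
OMV/prior/homology tables) or on a self-contained synthetic dataset from
:mod:`effectome.synthetic_data`. Every output table carries a provenance
comment (tool version, config hash, seed) and is byte-deterministic for a
fixed configuration.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import evidence as ev
from . import genome_annotate as ga
from . import secretome as sec
from . import synthetic_data as sd
from . import transcriptome_de as de
from .io_utils import read_tsv, write_gff3, write_tsv


@dataclass
class PipelineConfig:
    """All stage parameters plus input/output paths.

    Unknown keys in a config file are rejected; every parameter below is
    the documented default of its stage.
    """

    seed: int = 0
    simulate: bool = False
    outdir: str = "effectome_out"

    # genome_annotate
    window: int = 600
    max_gap: int = 200
    max_mismatch: int | None = None      # None -> motif file default
    motif_consensus: str | None = None   # None -> packaged consensus
    bidirectional: bool = True

    # transcriptome_de
    fc_min: float = 2.0
    p_max: float = 0.01
    use_adjusted_p: bool = True

    # secretome
    fdr_max: float = 0.01
    min_unique: int = 2
    detection_rule: str = "any"
    require_island: bool = True

    # synthetic generator overrides (used when simulate=True)
    sim: dict = field(default_factory=dict)

    # user-data input paths (used when simulate=False)
    gff3: str | None = None
    fasta: str | None = None
    island_bed: str | None = None
    counts: str | None = None
    sample_design: str | None = None
    peptides: str | None = None
    run_design: str | None = None
    localization: str | None = None
    omv_reference: str | None = None
    priors: str | None = None
    homology: str | None = None
    id_map: str | None = None

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


class StageError(RuntimeError):
    def __init__(self, stage: str, original: Exception):
        super().__init__(f"[{stage}] {original}")
        self.stage = stage
        self.original = original


@dataclass
class PipelineResult:
    genes: list
    units: list
    hits: list
    motif_flags: pd.Series
    island_flags: pd.Series
    ttsI_contrast: pd.DataFrame
    genistein_contrast: pd.DataFrame
    regulation: pd.DataFrame
    detection: sec.DetectionMatrix
    secretome_calls: pd.DataFrame
    records: pd.DataFrame
    tiers: pd.Series
    summary: dict
    outputs: dict


def _simulate_inputs(cfg: PipelineConfig, outdir: Path):
    sim_cfg = sd.SimulationConfig(seed=cfg.seed, **cfg.sim)
    genome = sd.simulate_genome(sim_cfg)
    counts, design = sd.simulate_counts(sim_cfg, genome.truth)
    peptides, run_design = sd.simulate_proteome(sim_cfg, genome.truth)
    sd.write_genome(genome, outdir / "inputs", sim_cfg)
    sd.write_omics(counts, design, peptides, run_design, genome.truth,
                   outdir / "inputs", sim_cfg)
    localization = genome.truth.reset_index()[
        ["gene_id", "localization_class"]].rename(
        columns={"gene_id": "protein_id"})
    omv = genome.truth.reset_index()
    omv = omv.loc[omv["background"] == "omv", ["gene_id"]].rename(
        columns={"gene_id": "protein_id"})
    return (genome.genes, {genome.contig: genome.sequence}, genome.island,
            counts, design, peptides, run_design, localization,
            omv["protein_id"], None, None, {}, genome)


def _load_inputs(cfg: PipelineConfig):
    for name in ("gff3", "fasta", "island_bed", "counts", "sample_design",
                 "peptides", "run_design"):
        path = getattr(cfg, name)
        if path is None or not Path(path).exists():
            raise FileNotFoundError(
                f"required input {name!r} missing"
                + (f" (path {path})" if path else " (no path configured)"))
    genes, seqs = ga.load_annotation(cfg.gff3, cfg.fasta)
    island = ga.IslandDefinition.from_bed(cfg.island_bed)
    counts = read_tsv(cfg.counts).set_index("gene_id")
    design = read_tsv(cfg.sample_design,
                      schema=["sample_id", "strain", "inducer"])
    peptides = read_tsv(cfg.peptides, schema=sec.PEPTIDE_COLUMNS)
    run_design = read_tsv(cfg.run_design, schema=["run_id", "strain"])
    localization = (read_tsv(cfg.localization,
                             schema=["protein_id", "localization_class"])
                    if cfg.localization else
                    pd.DataFrame(columns=["protein_id", "localization_class"]))
    omv = (read_tsv(cfg.omv_reference)["protein_id"]
           if cfg.omv_reference and Path(cfg.omv_reference).exists() else None)
    priors = read_tsv(cfg.priors) if cfg.priors else None
    homology = read_tsv(cfg.homology) if cfg.homology else None
    id_map = {}
    if cfg.id_map:
        m = read_tsv(cfg.id_map, schema=["protein_id", "locus_id"])
        id_map = dict(zip(m["protein_id"].astype(str), m["locus_id"].astype(str)))
    return (genes, seqs, island, counts, design, peptides, run_design,
            localization, omv, priors, homology, id_map, None)


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Execute all stages in order, writing outputs under ``cfg.outdir``."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    # provenance hashes only the analysis parameters, not file locations,
    # so identical analyses are byte-identical wherever they are written
    path_keys = {"outdir", "gff3", "fasta", "island_bed", "counts",
                 "sample_design", "peptides", "run_design", "localization",
                 "omv_reference", "priors", "homology", "id_map"}
    conf = {k: v for k, v in cfg.to_dict().items() if k not in path_keys}
    seed = cfg.seed
    outputs: dict[str, Path] = {}

    try:
        if cfg.simulate:
            (genes, seqs, island, counts, design, peptides, run_design,
             localization, omv, priors, homology, id_map, genome) = \
                _simulate_inputs(cfg, outdir)
        else:
            (genes, seqs, island, counts, design, peptides, run_design,
             localization, omv, priors, homology, id_map, genome) = \
                _load_inputs(cfg)
    except Exception as exc:
        raise StageError("inputs", exc) from exc

    # ---- scan ------------------------------------------------------------
    try:
        if cfg.motif_consensus is not None:
            motif = ga.MotifModel(consensus=cfg.motif_consensus,
                                  max_mismatch=cfg.max_mismatch or 0)
        else:
            motif = ga.load_default_motif()
            if cfg.max_mismatch is not None:
                motif.max_mismatch = cfg.max_mismatch
        units = ga.group_units(genes, max_gap=cfg.max_gap)
        gene_by_id = {g.gene_id: g for g in genes}
        lead_genes = {u.lead_gene_id: gene_by_id[u.lead_gene_id] for u in units}
        promoters, all_hits = [], []
        for u in units:
            prom = ga.extract_promoter(u, gene_by_id[u.lead_gene_id], seqs,
                                       window=cfg.window)
            promoters.append(prom)
            all_hits.extend(ga.lift_hits(ga.scan_motif(prom.sequence, motif,
                                                       contig=prom.contig),
                                         prom))
        # de-duplicate hits found via overlapping promoter windows
        all_hits = list({(h.contig, h.start, h.end, h.strand): h
                         for h in all_hits}.values())
        all_hits.sort(key=lambda h: (h.contig, h.start, h.strand))
        hits = ga.assign_hits(all_hits, promoters, units, lead_genes,
                              window=cfg.window,
                              bidirectional=cfg.bidirectional)
        unit_with_box = {uid for h in hits for uid in h.promoter_of}
        motif_flags = pd.Series(
            {g.gene_id: any(u.unit_id in unit_with_box and g.gene_id in u.gene_ids
                            for u in units) for g in genes}, name="has_tts_box")
        island_flags = pd.Series({g.gene_id: ga.in_island(g, island)
                                  for g in genes}, name="in_island")
        outputs["hits_tsv"] = write_tsv(ga.hits_to_frame(hits),
                                        outdir / "tts_box_hits.tsv",
                                        config=conf, seed=seed)
        outputs["hits_gff3"] = write_gff3(
            ga.hits_to_gff3_features(hits, motif.name),
            outdir / "tts_box_hits.gff3")
        units_df = pd.DataFrame([{
            "unit_id": u.unit_id, "contig": u.contig, "start": u.start,
            "end": u.end, "strand": u.strand, "lead_gene": u.lead_gene_id,
            "genes": ";".join(u.gene_ids)} for u in units])
        outputs["units"] = write_tsv(units_df, outdir / "units.tsv",
                                     config=conf, seed=seed)
    except Exception as exc:
        raise StageError("scan", exc) from exc

    # ---- de ----------------------------------------------------------------
    try:
        ttsI_contrast = de.nb_wald_test(
            counts, design, de.Contrast(("WT", "genistein"),
                                        ("ttsI_mutant", "genistein")))
        gen_contrast = de.nb_wald_test(
            counts, design, de.Contrast(("WT", "genistein"), ("WT", "DMSO")))
        regulation = de.classify_regulation(
            ttsI_contrast, gen_contrast, fc_min=cfg.fc_min, p_max=cfg.p_max,
            use_adjusted=cfg.use_adjusted_p)
        outputs["ttsI_contrast"] = write_tsv(
            ttsI_contrast.reset_index(), outdir / "contrast_ttsI.tsv",
            config=conf, seed=seed)
        outputs["genistein_contrast"] = write_tsv(
            gen_contrast.reset_index(), outdir / "contrast_genistein.tsv",
            config=conf, seed=seed)
        outputs["regulation"] = write_tsv(
            regulation.reset_index(), outdir / "regulation_calls.tsv",
            config=conf, seed=seed)
    except Exception as exc:
        raise StageError("de", exc) from exc

    # ---- secretome ---------------------------------------------------------
    try:
        fdr = sec.peptide_fdr_filter(peptides, fdr_max=cfg.fdr_max)
        detections = sec.call_proteins(fdr.retained, min_unique=cfg.min_unique)
        matrix = sec.build_detection_matrix(detections, run_design,
                                            rule=cfg.detection_rule)
        calls = sec.candidate_rule(matrix)
        ann = localization.copy()
        prot_island = island_flags.reindex(ann["protein_id"].map(
            lambda p: id_map.get(str(p), str(p))))
        ann["in_island"] = prot_island.fillna(False).values
        calls = sec.localization_filter(calls, ann,
                                        require_island=cfg.require_island)
        calls = sec.omv_flag(calls, omv)
        machinery = [g.gene_id for g in genes if g.locus_class == "t3ss_machinery"]
        calls = sec.needle_annotation(calls, machinery)
        outputs["detection_matrix"] = write_tsv(
            matrix.presence.reset_index(), outdir / "detection_matrix.tsv",
            config=conf, seed=seed)
        outputs["venn"] = write_tsv(sec.venn_summary(matrix),
                                    outdir / "venn_summary.tsv",
                                    config=conf, seed=seed)
        outputs["secretome_calls"] = write_tsv(
            calls.reset_index(), outdir / "secretome_calls.tsv",
            config=conf, seed=seed)
    except Exception as exc:
        raise StageError("secretome", exc) from exc

    # ---- integrate ---------------------------------------------------------
    try:
        records, unmapped = ev.build_evidence(
            motif_loci=motif_flags, regulation=regulation,
            secretome_calls=calls, priors=priors, homology=homology,
            island_membership=island_flags, id_map=id_map)
        tiers = ev.classify_tiers(records)
        summary = ev.summarize(records, tiers)
        outputs["evidence"] = write_tsv(records.reset_index(),
                                        outdir / "evidence_matrix.tsv",
                                        config=conf, seed=seed)
        outputs["tiers"] = write_tsv(
            summary["matrix"].reset_index().rename(columns={"index": "locus_id"}),
            outdir / "tiers.tsv", config=conf, seed=seed)
        report_path = outdir / "report.txt"
        report_path.write_text(summary["report"])
        outputs["report"] = report_path
        if unmapped:
            unmapped_path = outdir / "unmapped_proteins.txt"
            unmapped_path.write_text("\n".join(unmapped) + "\n")
            outputs["unmapped"] = unmapped_path
    except Exception as exc:
        raise StageError("integrate", exc) from exc

    cfg.to_yaml(outdir / "run_config.yaml")
    return PipelineResult(
        genes=genes, units=units, hits=hits, motif_flags=motif_flags,
        island_flags=island_flags, ttsI_contrast=ttsI_contrast,
        genistein_contrast=gen_contrast, regulation=regulation,
        detection=matrix, secretome_calls=calls, records=records,
        tiers=tiers, summary=summary, outputs=outputs)
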