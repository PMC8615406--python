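"""Genome annotation, transcriptional-unit grouping and tts-box scanning.

The tts-box is the promoter motif bound by TtsI, the transcriptional
activator of the rhizobial type III secretion system (T3SS). Scanning the
promoter regions of transcriptional units for this motif is the in-silico
leg of effector prediction; this module provides the strand-aware scan,
unit grouping by intergenic distance, and symbiotic-island membership.

Coordinates are 1-based inclusive (GFF3 convention) everywhere except at
the BED boundary for island files, where :mod:`effectome.io_utils` converts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO

from .io_utils import bed_interval_to_gff, read_bed

# IUPAC nucleotide codes -> the set of concrete bases they admit.
IUPAC = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"G", "C"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"},
    "H": {"A", "C", "T"}, "V": {"A", "C", "G"},
    "N": {"A", "C", "G", "T"},
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneModel:
    """One annotated CDS; start/end 1-based inclusive, start <= end."""

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str
    product: str = ""
    locus_class: str = "other"  # effector_predicted | t3ss_machinery | nod | other

    def __post_init__(self):
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"gene {self.gene_id}: invalid interval [{self.start}, {self.end}]")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class TranscriptionalUnit:
    """Co-directional run of genes with small intergenic gaps (operon proxy)."""

    unit_id: str
    gene_ids: list[str]       # ordered 5'->3' on the unit strand
    strand: str
    lead_gene_id: str
    contig: str
    start: int                # plus-strand extent of the whole unit
    end: int


@dataclass
class MotifModel:
    """A consensus (IUPAC + max mismatches) or PWM (log-odds + threshold) motif."""

    name: str = "tts_box"
    consensus: str | None = None
    max_mismatch: int = 0
    pwm: np.ndarray | None = None     # shape (L, 4), columns A C G T
    threshold: float | None = None

    def __post_init__(self):
        if self.consensus is not None:
            bad = set(self.consensus.upper()) - set(IUPAC)
            if bad:
                raise ValueError(f"consensus contains non-IUPAC codes {bad}")
            if self.max_mismatch >= len(self.consensus):
                raise ValueError("max_mismatch must be < motif length")
        elif self.pwm is not None:
            self.pwm = np.asarray(self.pwm, dtype=float)
            if self.pwm.ndim != 2 or self.pwm.shape[1] != 4:
                raise ValueError("PWM must have shape (length, 4)")
            if self.threshold is None:
                raise ValueError("PWM mode requires a score threshold")
        else:
            raise ValueError("motif needs either a consensus or a PWM")

    def __len__(self) -> int:
        return len(self.consensus) if self.consensus is not None else self.pwm.shape[0]


@dataclass(frozen=True)
class TtsBoxHit:
    """A motif match; start/end 1-based inclusive on the scanned sequence
    (or in genomic plus-strand space once lifted)."""

    contig: str
    start: int
    end: int
    strand: str
    mismatches: int | None = None
    score: float | None = None
    promoter_of: tuple[str, ...] = ()
    orientation: str = ""     # forward | reverse, relative to assigned unit


@dataclass
class IslandDefinition:
    """Symbiotic-island intervals, 0-based half-open (BED convention)."""

    intervals: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self):
        self.intervals = self._merge(self.intervals)

    @staticmethod
    def _merge(ivs):
        out: list[tuple[str, int, int]] = []
        for contig, s, e in sorted(ivs):
            if out and out[-1][0] == contig and s <= out[-1][2]:
                out[-1] = (contig, out[-1][1], max(out[-1][2], e))
            else:
                out.append((contig, s, e))
        return out

    @classmethod
    def from_bed(cls, path: str | Path) -> "IslandDefinition":
        return cls(read_bed(path))

    def contains_point(self, contig: str, pos_1based: int) -> bool:
        p0 = pos_1based - 1
        return any(c == contig and s <= p0 < e for c, s, e in self.intervals)


# ---------------------------------------------------------------------------
# annotation loading
# ---------------------------------------------------------------------------

def load_annotation(gff3_path: str | Path, fasta_path: str | Path,
                    ) -> tuple[list[GeneModel], dict[str, str]]:
    """Parse a GFF3 + FASTA pair into gene models and contig sequences.

    Genes are returned sorted by (contig, start). A gene extending beyond
    its contig, referencing a missing contig, or lacking a strand is a hard
    error naming the gene.
    """
    seqs = {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(fasta_path), "fasta")}
    db = gffutils.create_db(str(gff3_path), dbfn=":memory:",
                            merge_strategy="create_unique", keep_order=True)
    genes: list[GeneModel] = []
    for feat in db.all_features():
        if feat.featuretype not in {"gene", "CDS"}:
            continue
        gid = feat.attributes.get("ID", [feat.id])[0]
        if feat.featuretype == "CDS" and any(
                g.gene_id == gid for g in genes):
            continue  # CDS child of an already-loaded gene feature
        if feat.strand not in {"+", "-"}:
            raise ValueError(f"gene {gid}: missing or invalid strand {feat.strand!r}")
        if feat.seqid not in seqs:
            raise ValueError(f"gene {gid}: contig {feat.seqid!r} absent from FASTA")
        if feat.end > len(seqs[feat.seqid]) or feat.start < 1:
            raise ValueError(
                f"gene {gid}: interval [{feat.start}, {feat.end}] outside "
                f"contig {feat.seqid} (length {len(seqs[feat.seqid])})")
        attrs = feat.attributes
        genes.append(GeneModel(
            gene_id=gid, contig=feat.seqid, start=feat.start, end=feat.end,
            strand=feat.strand,
            product=attrs.get("product", [""])[0],
            locus_class=attrs.get("locus_class", ["other"])[0],
        ))
    genes.sort(key=lambda g: (g.contig, g.start, g.gene_id))
    return genes, seqs


def genes_to_frame(genes: Iterable[GeneModel]) -> pd.DataFrame:
    return pd.DataFrame([vars(g) for g in genes])


# ---------------------------------------------------------------------------
# transcriptional-unit grouping
# ---------------------------------------------------------------------------

def group_units(genes: Sequence[GeneModel], max_gap: int = 200,
                require_same_strand: bool = True) -> list[TranscriptionalUnit]:
    """Group coordinate-sorted genes into transcriptional units.

    A unit breaks at a strand change (when ``require_same_strand``) or when
    the intergenic gap exceeds ``max_gap`` bp. Every gene lands in exactly
    one unit; the lead gene is the most 5' member on the unit strand.
    """
    genes = sorted(genes, key=lambda g: (g.contig, g.start, g.gene_id))
    units: list[TranscriptionalUnit] = []
    block: list[GeneModel] = []

    def flush():
        if not block:
            return
        strand = block[0].strand
        ordered = block if strand == "+" else list(reversed(block))
        units.append(TranscriptionalUnit(
            unit_id=f"TU{len(units) + 1:04d}",
            gene_ids=[g.gene_id for g in ordered],
            strand=strand,
            lead_gene_id=ordered[0].gene_id,
            contig=block[0].contig,
            start=min(g.start for g in block),
            end=max(g.end for g in block),
        ))
        block.clear()

    for g in genes:
        if block:
            prev = block[-1]
            gap = g.start - prev.end - 1
            breaks = (g.contig != prev.contig or gap > max_gap
                      or (require_same_strand and g.strand != prev.strand))
            if breaks:
                flush()
        block.append(g)
    flush()
    return units


# ---------------------------------------------------------------------------
# promoter extraction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PromoterWindow:
    """Extracted promoter sequence with its plus-strand genomic coordinates."""

    unit_id: str
    contig: str
    start: int     # 1-based inclusive, plus-strand space
    end: int
    strand: str    # unit strand; for '-' the sequence is the revcomp slice
    sequence: str


def extract_promoter(unit: TranscriptionalUnit, lead_gene: GeneModel,
                     seqs: Mapping[str, str], window: int = 600,
                     ) -> PromoterWindow:
    """Return the ``window`` bp immediately 5' of the lead gene's start codon.

    For a minus-strand unit the returned sequence is the reverse complement
    of the plus-strand genomic slice; recorded coordinates stay in
    plus-strand space. Windows truncate (never pad) at contig ends.
    """
    if window <= 0:
        raise ValueError("promoter window must be positive")
    contig_seq = seqs[unit.contig]
    if unit.strand == "+":
        end = lead_gene.start - 1
        start = max(1, end - window + 1)
    else:
        start = lead_gene.end + 1
        end = min(len(contig_seq), start + window - 1)
    if end < start:  # lead gene flush against the contig edge
        seq = ""
        start, end = lead_gene.start, lead_gene.start - 1
    else:
        seq = contig_seq[start - 1:end]
        if unit.strand == "-":
            seq = reverse_complement(seq)
    return PromoterWindow(unit_id=unit.unit_id, contig=unit.contig,
                          start=start, end=end, strand=unit.strand,
                          sequence=seq)


# ---------------------------------------------------------------------------
# motif scanning
# ---------------------------------------------------------------------------

def _consensus_hits(seq: str, consensus: str, max_mismatch: int, strand: str,
                    contig: str) -> list[TtsBoxHit]:
    L, m = len(seq), len(consensus)
    out = []
    sets = [IUPAC[c] for c in consensus.upper()]
    for off in range(L - m + 1):
        mm = 0
        for j in range(m):
            base = seq[off + j]
            # an N (or any ambiguity) in the scanned sequence never matches
            if base not in "ACGT" or base not in sets[j]:
                mm += 1
                if mm > max_mismatch:
                    break
        if mm <= max_mismatch:
            out.append(TtsBoxHit(contig=contig, start=off + 1, end=off + m,
                                 strand=strand, mismatches=mm))
    return out


def _pwm_score_hits(seq: str, pwm: np.ndarray, threshold: float, strand: str,
                    contig: str) -> list[TtsBoxHit]:
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    L, m = len(seq), pwm.shape[0]
    out = []
    for off in range(L - m + 1):
        window = seq[off:off + m]
        if any(b not in idx for b in window):
            continue
        score = float(sum(pwm[j, idx[window[j]]] for j in range(m)))
        if score >= threshold:
            out.append(TtsBoxHit(contig=contig, start=off + 1, end=off + m,
                                 strand=strand, score=score))
    return out


def scan_motif(sequence: str, motif: MotifModel, contig: str = "seq",
               ) -> list[TtsBoxHit]:
    """Scan both strands of ``sequence`` for the motif.

    Consensus mode reports every offset with IUPAC-aware Hamming distance
    <= ``max_mismatch``; PWM mode every offset with summed log-odds >=
    ``threshold``. Minus-strand hits are reported in the coordinates of the
    scanned sequence (their plus-strand footprint). Hits are sorted by
    position, '+' before '-' at ties. A motif longer than the sequence
    yields an empty list.
    """
    seq = sequence.upper()
    m = len(motif)
    if m > len(seq):
        return []
    if motif.consensus is not None:
        fwd = _consensus_hits(seq, motif.consensus, motif.max_mismatch, "+", contig)
        rev = _consensus_hits(seq, reverse_complement(motif.consensus),
                              motif.max_mismatch, "-", contig)
    else:
        rc_pwm = motif.pwm[::-1, ::-1]  # reverse positions, complement columns
        fwd = _pwm_score_hits(seq, motif.pwm, motif.threshold, "+", contig)
        rev = _pwm_score_hits(seq, rc_pwm, motif.threshold, "-", contig)
    return sorted(fwd + rev, key=lambda h: (h.start, h.strand))


def lift_hits(hits: Sequence[TtsBoxHit], promoter: PromoterWindow,
              ) -> list[TtsBoxHit]:
    """Map promoter-local hit coordinates into genomic plus-strand space."""
    out = []
    plen = promoter.end - promoter.start + 1
    for h in hits:
        if promoter.strand == "+":
            gs = promoter.start + h.start - 1
            ge = promoter.start + h.end - 1
            strand = h.strand
        else:
            # promoter sequence was revcomp'ed: mirror the coordinates
            gs = promoter.start + (plen - h.end)
            ge = promoter.start + (plen - h.start)
            strand = "+" if h.strand == "-" else "-"
        out.append(TtsBoxHit(contig=promoter.contig, start=gs, end=ge,
                             strand=strand, mismatches=h.mismatches,
                             score=h.score))
    return out


# ---------------------------------------------------------------------------
# hit -> unit assignment
# ---------------------------------------------------------------------------

def assign_hits(hits: Sequence[TtsBoxHit],
                promoters: Sequence[PromoterWindow],
                units: Sequence[TranscriptionalUnit],
                lead_genes: Mapping[str, GeneModel],
                window: int = 600,
                bidirectional: bool = False) -> list[TtsBoxHit]:
    """Assign genomic-space hits to the units whose promoter contains them.

    With ``bidirectional=True`` a hit is additionally assigned to a
    divergently transcribed unit whose lead-gene start codon lies within
    ``window`` bp on the opposite strand — the configuration in which one
    tts-box in a shared intergenic region drives transcription both ways.
    """
    unit_by_id = {u.unit_id: u for u in units}
    out = []
    for h in hits:
        assigned: list[str] = []
        orientation = ""
        for p in promoters:
            if p.contig == h.contig and p.start <= h.start and h.end <= p.end:
                u = unit_by_id[p.unit_id]
                assigned.append(p.unit_id)
                orientation = "forward" if h.strand == u.strand else "reverse"
        if bidirectional and assigned:
            mid = (h.start + h.end) // 2
            for u in units:
                if u.unit_id in assigned or u.contig != h.contig:
                    continue
                lead = lead_genes[u.lead_gene_id]
                # divergent neighbor: its transcription start within `window`
                # of the hit, pointing away on the opposite strand
                tss = lead.start if u.strand == "+" else lead.end
                if abs(tss - mid) <= window and u.strand != unit_by_id[assigned[0]].strand:
                    assigned.append(u.unit_id)
        out.append(TtsBoxHit(contig=h.contig, start=h.start, end=h.end,
                             strand=h.strand, mismatches=h.mismatches,
                             score=h.score, promoter_of=tuple(assigned),
                             orientation=orientation))
    return out


# ---------------------------------------------------------------------------
# island membership
# ---------------------------------------------------------------------------

def in_island(gene: GeneModel, island: IslandDefinition) -> bool:
    """True iff the gene midpoint lies inside any island interval.

    The midpoint rule gives an unambiguous answer for boundary-straddling
    genes.
    """
    return island.contains_point(gene.contig, gene.midpoint)


def hits_to_frame(hits: Sequence[TtsBoxHit]) -> pd.DataFrame:
    rows = []
    for h in hits:
        rows.append({
            "contig": h.contig, "start": h.start, "end": h.end,
            "strand": h.strand,
            "mismatches": h.mismatches if h.mismatches is not None else "",
            "score": h.score if h.score is not None else "",
            "promoter_of": ";".join(h.promoter_of),
            "orientation": h.orientation,
        })
    return pd.DataFrame(rows, columns=["contig", "start", "end", "strand",
                                       "mismatches", "score", "promoter_of",
                                       "orientation"])


def hits_to_gff3_features(hits: Sequence[TtsBoxHit], motif_name: str = "tts_box",
                          ) -> list[dict]:
    feats = []
    for i, h in enumerate(hits, 1):
        feats.append({
            "contig": h.contig, "type": "TF_binding_site",
            "start": h.start, "end": h.end, "strand": h.strand,
            "score": h.mismatches if h.mismatches is not None else h.score,
            "attributes": {"ID": f"{motif_name}_{i:04d}",
                           "Name": motif_name,
                           "promoter_of": ",".join(h.promoter_of) or "NA"},
        })
    return feats


def load_default_motif() -> MotifModel:
    """The packaged tts-box consensus (see ``data/tts_box_consensus.txt``).

    The shipped string is an approximate conserved core; for analyses of
    real genomes supply the consensus or PWM from the primary literature
    on TtsI binding sites.
    """
    path = Path(__file__).parent / "data" / "tts_box_consensus.txt"
    consensus = None
    max_mm = 2
    for ln in path.read_text().splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        if ln.startswith("max_mismatch"):
            max_mm = int(ln.split("=")[1])
        else:
            consensus = ln
    return MotifModel(name="tts_box", consensus=consensus, max_mismatch=max_mm)
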