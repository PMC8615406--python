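"""Unit grouping, promoter arithmetic, motif scanning and island logic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from effectome import genome_annotate as ga
from effectome import synthetic_data as sd
from effectome.io_utils import write_fasta, write_gff3

BASES = "ACGT"


def make_gene(gid, start, end, strand="+", contig="chr"):
    return ga.GeneModel(gene_id=gid, contig=contig, start=start, end=end,
                        strand=strand)


# ---------------------------------------------------------------------------
# annotation loading
# ---------------------------------------------------------------------------

class TestLoadAnnotation:
    def test_three_gene_toy_roundtrip(self, tmp_path):
        feats = [
            {"contig": "c1", "type": "gene", "start": 10, "end": 100,
             "strand": "+", "attributes": {"ID": "g1"}},
            {"contig": "c1", "type": "gene", "start": 200, "end": 300,
             "strand": "-", "attributes": {"ID": "g2"}},
            {"contig": "c1", "type": "gene", "start": 400, "end": 450,
             "strand": "+", "attributes": {"ID": "g3"}},
        ]
        write_gff3(feats, tmp_path / "t.gff3")
        write_fasta({"c1": "A" * 500}, tmp_path / "t.fasta")
        genes, seqs = ga.load_annotation(tmp_path / "t.gff3", tmp_path / "t.fasta")
        assert [g.gene_id for g in genes] == ["g1", "g2", "g3"]
        assert genes[1].strand == "-"
        assert len(seqs["c1"]) == 500

    def test_gene_beyond_contig_is_named_in_error(self, tmp_path):
        feats = [{"contig": "c1", "type": "gene", "start": 10, "end": 9000,
                  "strand": "+", "attributes": {"ID": "runaway"}}]
        write_gff3(feats, tmp_path / "t.gff3")
        write_fasta({"c1": "A" * 500}, tmp_path / "t.fasta")
        with pytest.raises(ValueError, match="runaway"):
            ga.load_annotation(tmp_path / "t.gff3", tmp_path / "t.fasta")

    def test_simulated_genome_roundtrips(self, tmp_path, small_cfg, small_genome):
        sd.write_genome(small_genome, tmp_path, small_cfg)
        genes, seqs = ga.load_annotation(tmp_path / "genome.gff3",
                                         tmp_path / "genome.fasta")
        assert len(genes) == len(small_genome.genes)
        for loaded, orig in zip(genes, small_genome.genes):
            assert (loaded.gene_id, loaded.start, loaded.end, loaded.strand) \
                == (orig.gene_id, orig.start, orig.end, orig.strand)
        assert seqs[small_genome.contig] == small_genome.sequence


# ---------------------------------------------------------------------------
# unit grouping
# ---------------------------------------------------------------------------

def oracle_group(genes, max_gap, require_same_strand=True):
    """O(n^2) pairwise-merge reference: repeatedly merge adjacent compatible
    genes until no merge applies."""
    groups = [[g] for g in sorted(genes, key=lambda g: (g.contig, g.start))]
    changed = True
    while changed:
        changed = False
        for i in range(len(groups) - 1):
            a, b = groups[i], groups[i + 1]
            gap = b[0].start - max(g.end for g in a) - 1
            same_contig = a[0].contig == b[0].contig
            strand_ok = (not require_same_strand
                         or a[0].strand == b[0].strand)
            if same_contig and strand_ok and gap <= max_gap:
                groups[i] = a + b
                del groups[i + 1]
                changed = True
                break
    return [frozenset(g.gene_id for g in grp) for grp in groups]


class TestGroupUnits:
    def test_small_gap_merges(self):
        genes = [make_gene("a", 100, 400), make_gene("b", 451, 800)]
        units = ga.group_units(genes, max_gap=200)
        assert len(units) == 1
        assert units[0].gene_ids == ["a", "b"]

    def test_strand_flip_always_breaks(self):
        genes = [make_gene("a", 100, 400), make_gene("b", 410, 800, strand="-")]
        assert len(ga.group_units(genes, max_gap=1000)) == 2

    def test_minus_strand_lead_is_most_5prime(self):
        genes = [make_gene("a", 100, 400, strand="-"),
                 make_gene("b", 450, 800, strand="-")]
        unit = ga.group_units(genes, max_gap=200)[0]
        assert unit.lead_gene_id == "b"
        assert unit.gene_ids == ["b", "a"]

    def test_partition_and_oracle_on_random_layouts(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 30))
            pos = 1
            genes = []
            for i in range(n):
                pos += int(rng.integers(1, 400))
                length = int(rng.integers(50, 600))
                genes.append(make_gene(f"g{i}", pos, pos + length,
                                       strand=str(rng.choice(["+", "-"]))))
                pos += length
            max_gap = int(rng.integers(10, 400))
            units = ga.group_units(genes, max_gap=max_gap)
            # partition invariant
            members = [gid for u in units for gid in u.gene_ids]
            assert sorted(members) == sorted(g.gene_id for g in genes)
            # oracle equivalence
            got = [frozenset(u.gene_ids) for u in units]
            assert got == oracle_group(genes, max_gap)


# ---------------------------------------------------------------------------
# promoter extraction
# ---------------------------------------------------------------------------

class TestExtractPromoter:
    def setup_method(self):
        rng = np.random.default_rng(5)
        self.seq = "".join(rng.choice(list(BASES), 2000))

    def _unit(self, gene):
        return ga.TranscriptionalUnit(unit_id="U1", gene_ids=[gene.gene_id],
                                      strand=gene.strand,
                                      lead_gene_id=gene.gene_id,
                                      contig="chr", start=gene.start,
                                      end=gene.end)

    def test_plus_strand_window_coordinates(self):
        g = make_gene("g", 1001, 1500)
        p = ga.extract_promoter(self._unit(g), g, {"chr": self.seq}, window=200)
        assert (p.start, p.end) == (801, 1000)
        assert p.sequence == self.seq[800:1000]

    def test_minus_strand_window_is_revcomp(self):
        g = make_gene("g", 101, 500, strand="-")
        p = ga.extract_promoter(self._unit(g), g, {"chr": self.seq}, window=200)
        assert (p.start, p.end) == (501, 700)
        assert p.sequence == ga.reverse_complement(self.seq[500:700])

    def test_truncates_at_contig_start(self):
        g = make_gene("g", 51, 400)
        p = ga.extract_promoter(self._unit(g), g, {"chr": self.seq}, window=200)
        assert (p.start, p.end) == (1, 50)
        assert len(p.sequence) == 50

    def test_nonpositive_window_rejected(self):
        g = make_gene("g", 1001, 1500)
        with pytest.raises(ValueError):
            ga.extract_promoter(self._unit(g), g, {"chr": self.seq}, window=0)


# ---------------------------------------------------------------------------
# motif scanning
# ---------------------------------------------------------------------------

def brute_force_scan(seq, consensus, max_mismatch):
    """Explicit loop over all offsets and both strands."""
    hits = []
    for strand, cons in (("+", consensus),
                         ("-", ga.reverse_complement(consensus))):
        for off in range(len(seq) - len(cons) + 1):
            mm = sum(1 for j, c in enumerate(cons)
                     if seq[off + j] not in "ACGT"
                     or seq[off + j] not in ga.IUPAC[c])
            if mm <= max_mismatch:
                hits.append((off + 1, off + len(cons), strand, mm))
    return sorted(hits, key=lambda h: (h[0], h[2]))


class TestScanMotif:
    def test_exact_single_hit(self, rng):
        motif = ga.MotifModel(consensus="TTGACATT", max_mismatch=0)
        bg = "".join(rng.choice(list("AC"), 200))  # no T/G runs -> no chance hit
        seq = bg[:90] + "TTGACATT" + bg[90:]
        hits = ga.scan_motif(seq, motif)
        fwd = [h for h in hits if h.strand == "+"]
        assert len(fwd) == 1 and fwd[0].start == 91 and fwd[0].mismatches == 0

    def test_mismatch_threshold_is_sharp(self):
        seq = "CCCCCTTGACAATCCCCC"  # consensus with one substitution at the end
        one = ga.scan_motif(seq, ga.MotifModel(consensus="TTGACAAG",
                                               max_mismatch=1))
        assert [(h.start, h.mismatches) for h in one if h.strand == "+"] \
            == [(6, 1)]
        zero = ga.scan_motif(seq, ga.MotifModel(consensus="TTGACAAG",
                                                max_mismatch=0))
        assert [h for h in zero if h.strand == "+"] == []

    def test_n_in_sequence_never_matches(self):
        motif = ga.MotifModel(consensus="ANT", max_mismatch=0)
        # N in consensus matches anything, N in sequence matches nothing
        assert len([h for h in ga.scan_motif("AGT", motif) if h.strand == "+"]) == 1
        assert [h for h in ga.scan_motif("ANT", motif) if h.strand == "+"] == []

    def test_motif_longer_than_sequence_is_empty(self):
        assert ga.scan_motif("ACG", ga.MotifModel(consensus="ACGTACGT")) == []

    def test_agrees_with_brute_force_on_random_sequences(self, rng):
        for _ in range(60):
            n = int(rng.integers(30, 500))
            seq = "".join(rng.choice(list(BASES), n))
            cons = "".join(rng.choice(list("ACGTRYN"), int(rng.integers(4, 10))))
            mm = int(rng.integers(0, len(cons)))
            got = [(h.start, h.end, h.strand, h.mismatches)
                   for h in ga.scan_motif(seq, ga.MotifModel(consensus=cons,
                                                             max_mismatch=mm))]
            assert got == brute_force_scan(seq, cons, mm)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(seq=st.text(alphabet="ACGT", min_size=10, max_size=80),
           cons=st.text(alphabet="ACGT", min_size=3, max_size=6),
           mm=st.integers(min_value=0, max_value=2))
    def test_strand_symmetry(self, seq, cons, mm):
        """Scanning the reverse complement mirrors hit coordinates."""
        motif = ga.MotifModel(consensus=cons, max_mismatch=mm)
        fwd = ga.scan_motif(seq, motif)
        rev = ga.scan_motif(ga.reverse_complement(seq), motif)
        L = len(seq)
        mirrored = sorted((L - h.end + 1, L - h.start + 1,
                           "+" if h.strand == "-" else "-", h.mismatches)
                          for h in rev)
        assert mirrored == sorted((h.start, h.end, h.strand, h.mismatches)
                                  for h in fwd)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seq=st.text(alphabet="ACGT", min_size=20, max_size=100),
           cons=st.text(alphabet="ACGT", min_size=4, max_size=7),
           mm=st.integers(min_value=0, max_value=3))
    def test_mismatch_monotonicity(self, seq, cons, mm):
        """Raising max_mismatch never removes a hit."""
        lo = ga.scan_motif(seq, ga.MotifModel(consensus=cons, max_mismatch=mm))
        hi = ga.scan_motif(seq, ga.MotifModel(consensus=cons,
                                              max_mismatch=min(mm + 1,
                                                               len(cons) - 1)))
        lo_keys = {(h.start, h.strand) for h in lo}
        hi_keys = {(h.start, h.strand) for h in hi}
        assert lo_keys <= hi_keys

    def test_pwm_mode_matches_consensus_at_strict_threshold(self, rng):
        cons = "TTGACA"
        pwm = np.full((6, 4), -10.0)
        idx = {"A": 0, "C": 1, "G": 2, "T": 3}
        for j, c in enumerate(cons):
            pwm[j, idx[c]] = 1.0
        motif = ga.MotifModel(name="custom", consensus=None, pwm=pwm,
                              threshold=6.0)
        seq = "".join(rng.choice(list(BASES), 300)) + cons
        hits = ga.scan_motif(seq, motif)
        exact = ga.scan_motif(seq, ga.MotifModel(consensus=cons, max_mismatch=0))
        assert {(h.start, h.strand) for h in hits} \
            == {(h.start, h.strand) for h in exact}


# ---------------------------------------------------------------------------
# hit assignment
# ---------------------------------------------------------------------------

class TestAssignHits:
    def _layout(self):
        # divergent pair: gA on '-' [100,400], gB on '+' [1001,1500],
        # shared intergenic region 401..1000
        gA = make_gene("gA", 100, 400, strand="-")
        gB = make_gene("gB", 1001, 1500, strand="+")
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list(BASES), 2000))
        units = ga.group_units([gA, gB], max_gap=200)
        by_id = {"gA": gA, "gB": gB}
        proms = [ga.extract_promoter(u, by_id[u.lead_gene_id], {"chr": seq},
                                     window=600) for u in units]
        return gA, gB, units, proms, by_id

    def test_hit_in_single_promoter(self):
        gA, gB, units, proms, by_id = self._layout()
        uB = next(u for u in units if "gB" in u.gene_ids)
        hit = ga.TtsBoxHit(contig="chr", start=900, end=913, strand="+")
        out = ga.assign_hits([hit], proms, units, by_id, window=600,
                             bidirectional=False)
        assert uB.unit_id in out[0].promoter_of

    def test_bidirectional_assigns_divergent_unit(self):
        gA, gB, units, proms, by_id = self._layout()
        hit = ga.TtsBoxHit(contig="chr", start=700, end=713, strand="+")
        single = ga.assign_hits([hit], proms, units, by_id, window=600,
                                bidirectional=False)
        both = ga.assign_hits([hit], proms, units, by_id, window=600,
                              bidirectional=True)
        assert len(single[0].promoter_of) >= 1
        assert len(both[0].promoter_of) == 2

    def test_no_divergent_neighbor_single_assignment(self):
        g = make_gene("g", 1001, 1500)
        rng = np.random.default_rng(4)
        seq = "".join(rng.choice(list(BASES), 2000))
        units = ga.group_units([g], max_gap=200)
        proms = [ga.extract_promoter(units[0], g, {"chr": seq}, window=600)]
        hit = ga.TtsBoxHit(contig="chr", start=900, end=913, strand="+")
        out = ga.assign_hits([hit], proms, units, {"g": g}, window=600,
                             bidirectional=True)
        assert out[0].promoter_of == (units[0].unit_id,)


# ---------------------------------------------------------------------------
# island membership
# ---------------------------------------------------------------------------

class TestInIsland:
    island = ga.IslandDefinition([("chr", 0, 1000)])

    def test_inside(self):
        assert ga.in_island(make_gene("g", 100, 200), self.island)

    def test_outside(self):
        assert not ga.in_island(make_gene("g", 5000, 5600), self.island)

    def test_midpoint_rule_for_straddler(self):
        # midpoint (900+1300)//2 = 1100 -> outside [0, 1000)
        assert not ga.in_island(make_gene("g", 900, 1300), self.island)
        # midpoint (800+1100)//2 = 950 -> inside
        assert ga.in_island(make_gene("g", 800, 1100), self.island)

    def test_overlapping_intervals_merge(self):
        isl = ga.IslandDefinition([("chr", 0, 500), ("chr", 400, 1000)])
        assert isl.intervals == [("chr", 0, 1000)]


# ---------------------------------------------------------------------------
# simulator round-trip of planted motifs
# ---------------------------------------------------------------------------

def test_planted_motifs_are_recovered_at_planted_coordinates(small_cfg,
                                                             small_genome):
    """Extracting promoters and re-scanning finds every planted tts-box at
    the coordinates recorded in the ground truth."""
    motif = ga.MotifModel(consensus=small_cfg.motif_consensus, max_mismatch=0)
    genes = small_genome.genes
    by_id = {g.gene_id: g for g in genes}
    units = ga.group_units(genes, max_gap=200)
    seqs = {small_genome.contig: small_genome.sequence}
    found = set()
    for u in units:
        prom = ga.extract_promoter(u, by_id[u.lead_gene_id], seqs,
                                   window=small_cfg.promoter_window)
        for h in ga.lift_hits(ga.scan_motif(prom.sequence, motif,
                                            contig=prom.contig), prom):
            found.add((h.start, h.end))
    for _, row in small_genome.planted_motifs.iterrows():
        assert (row["start"], row["end"]) in found
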