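"""Annotation parsing, canonical-transcript choice, introns and windows."""

import numpy as np
import pytest

from mintron.annotation import (
    AnnotationError,
    GeneModel,
    GenomeSequence,
    derive_introns,
    extract_splice_windows,
    parse_annotation,
    select_canonical_transcript,
)
from mintron.pwm import N_BPS_WINDOWS

from conftest import make_genome, make_transcript


def write_toy_inputs(tmp_path, gtf_text, fasta_seqs):
    gtf = tmp_path / "a.gtf"
    gtf.write_text(gtf_text)
    fa = tmp_path / "g.fa"
    fa.write_text("".join(f">{c}\n{s}\n" for c, s in fasta_seqs.items()))
    return str(gtf), str(fa)


TOY_GTF = """\
chr1\tx\tgene\t1\t500\t.\t+\t.\tgene_id "G1"; gene_biotype "protein_coding";
chr1\tx\ttranscript\t1\t500\t.\t+\t.\tgene_id "G1"; transcript_id "T1";
chr1\tx\texon\t1\t100\t.\t+\t.\tgene_id "G1"; transcript_id "T1";
chr1\tx\texon\t201\t300\t.\t+\t.\tgene_id "G1"; transcript_id "T1";
chr1\tx\texon\t401\t500\t.\t+\t.\tgene_id "G1"; transcript_id "T1";
chr1\tx\ttranscript\t1\t300\t.\t+\t.\tgene_id "G1"; transcript_id "T2";
chr1\tx\texon\t1\t100\t.\t+\t.\tgene_id "G1"; transcript_id "T2";
chr1\tx\texon\t201\t300\t.\t+\t.\tgene_id "G1"; transcript_id "T2";
"""


class TestParse:
    def test_toy_gtf(self, tmp_path):
        gtf, fa = write_toy_inputs(tmp_path, TOY_GTF, {"chr1": "A" * 600})
        genes, genome = parse_annotation(gtf, fa)
        assert len(genes) == 1
        (gene,) = genes
        assert gene.gene_type == "protein_coding"
        assert {t.transcript_id for t in gene.transcripts} == {"T1", "T2"}
        t1 = next(t for t in gene.transcripts if t.transcript_id == "T1")
        assert t1.exons == [(0, 100), (200, 300), (400, 500)]

    def test_exon_on_missing_chromosome(self, tmp_path):
        gtf, fa = write_toy_inputs(
            tmp_path,
            'chr9\tx\texon\t1\t10\t.\t+\t.\tgene_id "G"; transcript_id "T";\n',
            {"chr1": "ACGT"},
        )
        with pytest.raises(AnnotationError, match="chr9"):
            parse_annotation(gtf, fa)

    def test_empty_gtf(self, tmp_path):
        gtf, fa = write_toy_inputs(tmp_path, "# header only\n", {"chr1": "ACGT"})
        genes, _ = parse_annotation(gtf, fa)
        assert genes == []

    def test_malformed_line_names_lineno(self, tmp_path):
        gtf, fa = write_toy_inputs(tmp_path, "chr1\tonly\tthree\n", {"chr1": "ACGT"})
        with pytest.raises(AnnotationError, match=":1"):
            parse_annotation(gtf, fa)


class TestCanonical:
    def _gene(self, *txs):
        return GeneModel("G", "protein_coding", "chr1", "+", list(txs))

    def test_ccds_beats_longer_untagged_cds(self):
        ccds = make_transcript(
            [(0, 100), (200, 500)], transcript_id="Tc", cds_span=(0, 400), tags={"CCDS"}
        )
        longer = make_transcript(
            [(0, 700)], transcript_id="Tu", cds_span=(0, 700)
        )
        assert ccds.cds_length < longer.cds_length
        assert select_canonical_transcript(self._gene(ccds, longer)) is ccds

    def test_no_cds_falls_back_to_longest_exonic(self):
        short = make_transcript([(0, 100)], transcript_id="Ta")
        long = make_transcript([(0, 100), (200, 400)], transcript_id="Tb")
        assert select_canonical_transcript(self._gene(short, long)) is long

    def test_tie_breaks_to_smaller_id(self):
        a = make_transcript([(0, 300)], transcript_id="T1", cds_span=(0, 300))
        b = make_transcript([(0, 300)], transcript_id="T2", cds_span=(0, 300))
        assert select_canonical_transcript(self._gene(b, a)) is a

    def test_havana_tag_beats_untagged(self):
        hav = make_transcript(
            [(0, 90)], transcript_id="Th", cds_span=(0, 90), tags={"ensembl_havana"}
        )
        untagged = make_transcript([(0, 300)], transcript_id="Tu", cds_span=(0, 300))
        assert select_canonical_transcript(self._gene(untagged, hav)) is hav


class TestDeriveIntrons:
    def test_plus_strand_counts_and_ordinals(self):
        genome = make_genome()
        tx = make_transcript([(100, 200), (300, 400), (500, 600)])
        introns = derive_introns(tx, genome)
        assert [(i.ordinal, i.start, i.end) for i in introns] == [
            (1, 200, 300), (2, 400, 500)
        ]
        assert all(i.length == 100 for i in introns)

    def test_minus_strand_dinucleotides_reverse_complemented(self):
        seq = list("A" * 1000)
        # genomic forward intron [200,300) reads CT...AC -> revcomp GT...AG
        seq[200:202] = list("CT")
        seq[298:300] = list("AC")
        genome = GenomeSequence({"chr1": "".join(seq)})
        tx = make_transcript([(100, 200), (300, 400)], strand="-")
        (intron,) = derive_introns(tx, genome)
        assert intron.terminal_dinucleotides == ("GT", "AG")
        assert intron.ordinal == 1

    def test_single_exon_gives_no_introns(self):
        assert derive_introns(make_transcript([(0, 100)]), make_genome()) == []

    def test_abutting_exons_error(self):
        tx = make_transcript([(0, 100), (100, 200)])
        with pytest.raises(AnnotationError, match="abutting"):
            derive_introns(tx, make_genome())


class TestSpliceWindows:
    def test_full_length_intron_has_29_bps_windows(self):
        genome = make_genome(seed=3)
        tx = make_transcript([(100, 200), (300, 400)])  # 100-nt intron
        (intron,) = derive_introns(tx, genome)
        w = extract_splice_windows(intron, genome)
        assert len(w.bps_windows) == N_BPS_WINDOWS == 29
        assert len(w.donor12) == 12 and len(w.acceptor14) == 14
        assert not w.flags

    def test_donor_window_is_direct_slice(self):
        seq = list("T" * 1000)
        seq[197:200] = list("CAG")
        seq[200:209] = list("GTATCCTTT")
        genome = GenomeSequence({"chr1": "".join(seq)})
        tx = make_transcript([(100, 200), (300, 400)])
        (intron,) = derive_introns(tx, genome)
        w = extract_splice_windows(intron, genome)
        assert w.donor12 == "CAGGTATCCTTT"
        # intron's first dinucleotide sits at donor positions 4-5
        assert w.donor12[3:5] == "GT"
        # intron's last dinucleotide sits at acceptor positions 12-13
        assert w.acceptor14[11:13] == intron.terminal_dinucleotides[1]

    @pytest.mark.parametrize("length,expected", [(35, 35 - 9 - 12 + 1), (100, 29), (45, 25)])
    def test_short_intron_window_count_matches_brute_slicer(self, length, expected):
        # independent oracle: usable region = min(40, length-9), windows of 12, step 1
        usable = min(40, length - 9)
        brute = max(0, usable - 12 + 1)
        assert brute == expected
        genome = make_genome(seed=5)
        tx = make_transcript([(100, 200), (200 + length, 300 + length)])
        (intron,) = derive_introns(tx, genome)
        w = extract_splice_windows(intron, genome)
        assert len(w.bps_windows) == brute
        if length < 40 + 9:
            assert "short_bps_region" in w.flags

    def test_strand_mirror_produces_identical_windows(self):
        rng = np.random.default_rng(9)
        fwd = "".join(rng.choice(list("ACGT"), size=600))
        rc = fwd.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        genome = GenomeSequence({"f": fwd, "r": rc})
        tx_f = make_transcript([(100, 200), (300, 400)], chrom="f")
        L = 600
        tx_r = make_transcript(
            [(L - 400, L - 300), (L - 200, L - 100)], strand="-", chrom="r"
        )
        (i_f,) = derive_introns(tx_f, genome)
        (i_r,) = derive_introns(tx_r, genome)
        w_f = extract_splice_windows(i_f, genome)
        w_r = extract_splice_windows(i_r, genome)
        assert w_f.donor12 == w_r.donor12
        assert w_f.acceptor14 == w_r.acceptor14
        assert w_f.bps_windows == w_r.bps_windows

    def test_boundary_intron_flagged(self):
        genome = GenomeSequence({"chr1": "A" * 220})
        tx = make_transcript([(0, 2), (210, 215)])
        (intron,) = derive_introns(tx, genome)
        w = extract_splice_windows(intron, genome)
        assert "donor_out_of_bounds" in w.flags


def test_exon_intron_roundtrip_on_simulated_genome(sim):
    """Concatenating exon and intron slices reproduces the gene's span."""
    gene = sim.genes[0]
    tx = gene.transcripts[0]
    chrom = tx.chrom
    lo, hi = tx.span
    pieces = []
    bounds = sorted(tx.exons)
    cursor = lo
    for s, e in bounds:
        if s > cursor:
            pieces.append(sim.genome.fetch(chrom, cursor, s))  # intron
        pieces.append(sim.genome.fetch(chrom, s, e))
        cursor = e
    assert "".join(pieces) == sim.genome.fetch(chrom, lo, hi)
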