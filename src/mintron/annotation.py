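"""Gene-annotation catalog: genes, canonical transcripts, introns, splice windows.

External files use GTF coordinates (1-based, inclusive).  Internally all
intervals are 0-based half-open; the parser and the TSV writers are the only
places offsets change.

The canonical transcript of a gene is chosen by a priority ladder: among
CCDS-tagged coding transcripts the longest CDS; else among Ensembl/Havana
merged coding transcripts the longest CDS; else any coding transcript with
the longest CDS; else the longest transcript by summed exon length.  Ties
break to the lexicographically smallest transcript id.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq

from .pwm import ACCEPTOR_WIDTH, BPS_REGION, BPS_WIDTH, DONOR_WIDTH

#: introns shorter than this are flagged unscorable for BPS/acceptor purposes
MIN_SCORABLE_INTRON_LENGTH = 30

INTRON_CONTEXTS = (
    "flanked_by_two_major",
    "first_or_last",
    "adjacent_to_minor",
    "only_intron",
)


class AnnotationError(ValueError):
    """Malformed annotation input."""


@dataclass
class TranscriptModel:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    exons: list[tuple[int, int]] = field(default_factory=list)  # 0-based half-open
    cds_span: tuple[int, int] | None = None
    tags: set[str] = field(default_factory=set)

    def finalize(self) -> None:
        self.exons.sort()
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise AnnotationError(
                    f"transcript {self.transcript_id}: overlapping exons "
                    f"({s1 + 1}-{e1}, {s2 + 1}-{e2})"
                )

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def cds_length(self) -> int:
        """Total exonic nt inside the CDS span (0 when non-coding)."""
        if self.cds_span is None:
            return 0
        cs, ce = self.cds_span
        return sum(max(0, min(e, ce) - max(s, cs)) for s, e in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


@dataclass
class GeneModel:
    gene_id: str
    gene_type: str  # protein_coding / pseudogene / lincRNA / other
    chrom: str
    strand: str
    transcripts: list[TranscriptModel] = field(default_factory=list)


@dataclass
class IntronRecord:
    intron_id: str
    gene_id: str
    transcript_id: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    strand: str
    ordinal: int  # 1-based, 5'->3' in transcript orientation
    n_introns: int  # total introns in the transcript
    terminal_dinucleotides: tuple[str, str] = ("NN", "NN")
    context: str | None = None  # set after classification
    flags: set[str] = field(default_factory=set)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SpliceSiteWindows:
    donor12: str
    acceptor14: str
    bps_windows: list[str]
    flags: set[str] = field(default_factory=set)


def _norm_gene_type(biotype: str) -> str:
    if biotype == "protein_coding":
        return "protein_coding"
    if "pseudogene" in biotype:
        return "pseudogene"
    if biotype in ("lincRNA", "lncRNA"):
        return "lincRNA"
    return "other"


def _parse_attributes(attr_field: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in attr_field.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if " " not in chunk:
            continue
        key, _, value = chunk.partition(" ")
        attrs.setdefault(key, value.strip().strip('"'))
        if key == "tag":  # tags repeat; collect them all
            attrs.setdefault("_tags", "")
            attrs["_tags"] += "," + value.strip().strip('"')
    return attrs


class GenomeSequence:
    """Uppercased chromosome sequences with slicing in 0-based half-open coords."""

    def __init__(self, records: Mapping[str, str]):
        self._seqs = {name: seq.upper() for name, seq in records.items()}

    @classmethod
    def from_fasta(cls, path: str) -> "GenomeSequence":
        return cls(
            {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}
        )

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self._seqs:
            raise AnnotationError(f"chromosome {chrom!r} absent from genome")
        if start < 0 or end > len(self._seqs[chrom]):
            raise AnnotationError(
                f"interval {chrom}:{start}-{end} outside sequence bounds"
            )
        return self._seqs[chrom][start:end]


def parse_annotation(gtf_path: str, fasta_path: str) -> tuple[list[GeneModel], GenomeSequence]:
    """Parse an Ensembl-dialect GTF plus its genome FASTA.

    Returns genes (with transcripts and exons in genomic order) and the
    sequence provider.  Exon records referencing a chromosome missing from
    the FASTA raise, naming the chromosome.
    """
    genome = GenomeSequence.from_fasta(fasta_path)
    genes: dict[str, GeneModel] = {}
    transcripts: dict[str, TranscriptModel] = {}

    with open(gtf_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise AnnotationError(
                    f"{gtf_path}:{lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom, source, feature, start_s, end_s, _score, strand, _frame, attr = fields
            try:
                start0, end0 = int(start_s) - 1, int(end_s)
            except ValueError as exc:
                raise AnnotationError(f"{gtf_path}:{lineno}: bad coordinates") from exc
            if feature not in ("gene", "transcript", "exon", "CDS"):
                continue
            attrs = _parse_attributes(attr)
            gene_id = attrs.get("gene_id")
            if gene_id is None:
                raise AnnotationError(f"{gtf_path}:{lineno}: missing gene_id")

            if feature == "gene":
                biotype = attrs.get("gene_biotype", attrs.get("gene_type", ""))
                genes.setdefault(
                    gene_id,
                    GeneModel(gene_id, _norm_gene_type(biotype), chrom, strand),
                )
                continue

            tx_id = attrs.get("transcript_id")
            if tx_id is None:
                raise AnnotationError(f"{gtf_path}:{lineno}: missing transcript_id")
            if gene_id not in genes:
                biotype = attrs.get("gene_biotype", attrs.get("gene_type", ""))
                genes[gene_id] = GeneModel(
                    gene_id, _norm_gene_type(biotype), chrom, strand
                )
            if tx_id not in transcripts:
                tx = TranscriptModel(tx_id, gene_id, chrom, strand)
                transcripts[tx_id] = tx
                genes[gene_id].transcripts.append(tx)
            tx = transcripts[tx_id]

            if "ccds_id" in attrs:
                tx.tags.add("CCDS")
            if source == "ensembl_havana" or "basic" in attrs.get("_tags", ""):
                tx.tags.add("ensembl_havana")

            if feature == "exon":
                if chrom not in genome:
                    raise AnnotationError(
                        f"{gtf_path}:{lineno}: exon of {tx_id} on chromosome "
                        f"{chrom!r} absent from FASTA"
                    )
                tx.exons.append((start0, end0))
            elif feature == "CDS":
                if tx.cds_span is None:
                    tx.cds_span = (start0, end0)
                else:
                    cs, ce = tx.cds_span
                    tx.cds_span = (min(cs, start0), max(ce, end0))

    for tx in transcripts.values():
        tx.finalize()
    return list(genes.values()), genome


def select_canonical_transcript(gene: GeneModel) -> TranscriptModel:
    """CCDS > Ensembl/Havana > any coding (longest CDS) > longest transcript."""
    if not gene.transcripts:
        raise AnnotationError(f"gene {gene.gene_id} has no transcripts")
    coding = [t for t in gene.transcripts if t.cds_length > 0]

    def _longest_cds(cands: list[TranscriptModel]) -> TranscriptModel:
        return min(cands, key=lambda t: (-t.cds_length, t.transcript_id))

    for tag in ("CCDS", "ensembl_havana"):
        tagged = [t for t in coding if tag in t.tags]
        if tagged:
            return _longest_cds(tagged)
    if coding:
        return _longest_cds(coding)
    return min(
        gene.transcripts, key=lambda t: (-t.exonic_length, t.transcript_id)
    )


def derive_introns(
    transcript: TranscriptModel, genome: GenomeSequence
) -> list[IntronRecord]:
    """One intron per adjacent exon pair, ordered 5'->3' in transcript orientation.

    Terminal dinucleotides are reported in transcript orientation (donor pair
    first); minus-strand introns are reverse-complemented.
    """
    exons = transcript.exons
    if len(exons) < 2:
        return []
    genomic: list[tuple[int, int]] = []
    for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
        if s2 == e1:
            raise AnnotationError(
                f"transcript {transcript.transcript_id}: abutting exons at {e1}"
            )
        genomic.append((e1, s2))
    n = len(genomic)
    minus = transcript.strand == "-"
    ordered = genomic[::-1] if minus else genomic
    records = []
    for ordinal, (istart, iend) in enumerate(ordered, start=1):
        seq = genome.fetch(transcript.chrom, istart, iend)
        if minus:
            seq = str(Seq(seq).reverse_complement())
        records.append(
            IntronRecord(
                intron_id=f"{transcript.transcript_id}.i{ordinal}",
                gene_id=transcript.gene_id,
                transcript_id=transcript.transcript_id,
                chrom=transcript.chrom,
                start=istart,
                end=iend,
                strand=transcript.strand,
                ordinal=ordinal,
                n_introns=n,
                terminal_dinucleotides=(seq[:2], seq[-2:]),
            )
        )
    return records


def extract_splice_windows(
    intron: IntronRecord,
    genome: GenomeSequence,
    min_scorable_length: int = MIN_SCORABLE_INTRON_LENGTH,
) -> SpliceSiteWindows:
    """Donor (-3..+9), acceptor (-13..+1) and branch-point windows of an intron.

    Branch-point windows slide one nt at a time over intronic positions
    -40..-1 upstream of the 3'SS; introns with fewer than 40 intronic nt
    available yield fewer windows and are flagged ``short_bps_region``.
    Introns running off the chromosome end, or shorter than
    `min_scorable_length`, are flagged.
    """
    flags: set[str] = set()
    chrom_len = genome.length(intron.chrom)
    minus = intron.strand == "-"

    def _fetch_oriented(start: int, end: int) -> str | None:
        if start < 0 or end > chrom_len:
            return None
        seq = genome.fetch(intron.chrom, start, end)
        return str(Seq(seq).reverse_complement()) if minus else seq

    length = intron.length
    if length < min_scorable_length:
        flags.add("short_intron")

    # donor: 3 exonic + 9 intronic nt at the 5'SS (transcript orientation)
    if minus:
        donor = _fetch_oriented(intron.end - 9, intron.end + 3)
        acceptor = _fetch_oriented(intron.start - 1, intron.start + 13)
    else:
        donor = _fetch_oriented(intron.start - 3, intron.start + 9)
        acceptor = _fetch_oriented(intron.end - 13, intron.end + 1)
    if donor is None or len(donor) != DONOR_WIDTH:
        flags.add("donor_out_of_bounds")
        donor = ""
    if acceptor is None or len(acceptor) != ACCEPTOR_WIDTH:
        flags.add("acceptor_out_of_bounds")
        acceptor = ""
    if donor and "N" in donor:
        flags.add("assembly_gap")
    if acceptor and "N" in acceptor:
        flags.add("assembly_gap")

    # branch-point scan region: intronic -40..-1, not crossing the donor's
    # 9 intronic nt for very short introns
    region_len = min(BPS_REGION, max(0, length - 9))
    if region_len < BPS_REGION:
        flags.add("short_bps_region")
    bps_windows: list[str] = []
    if region_len >= BPS_WIDTH:
        if minus:
            region = _fetch_oriented(intron.start, intron.start + region_len)
        else:
            region = _fetch_oriented(intron.end - region_len, intron.end)
        if region is None:
            flags.add("bps_out_of_bounds")
        else:
            bps_windows = [
                region[i : i + BPS_WIDTH]
                for i in range(region_len - BPS_WIDTH + 1)
            ]
    return SpliceSiteWindows(donor or "", acceptor or "", bps_windows, flags)


def intron_catalog_frame(introns: Iterable[IntronRecord]):
    """Intron catalog as a DataFrame with GTF-convention coordinates."""
    import pandas as pd

    rows = []
    for it in introns:
        rows.append(
            {
                "intron_id": it.intron_id,
                "gene_id": it.gene_id,
                "transcript_id": it.transcript_id,
                "chrom": it.chrom,
                "start": it.start + 1,  # back to 1-based inclusive
                "end": it.end,
                "strand": it.strand,
                "ordinal": it.ordinal,
                "dinucleotides": "-".join(it.terminal_dinucleotides),
                "length": it.length,
            }
        )
    return pd.DataFrame(rows)
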