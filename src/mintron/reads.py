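"""Aligned-read containers shared by the retention and AS quantifiers.

Reads come either from a SAM/BAM file (parsed with pysam; `N` CIGAR
operations become inter-block gaps) or from the simulator's tab-separated
read table.  Both are normalised to :class:`AlignedRead`: a read id, a
chromosome, an ordered list of aligned blocks in 0-based half-open genomic
coordinates, and a uniqueness flag (SAM: MAPQ>0 and no ``NH`` tag > 1).

The read-table format is one row per read::

    read_id  chrom  blocks  unique
    r1       chr1   100-175,300-325  1

with blocks comma-separated ``start-end`` pairs (0-based half-open).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

import pysam

READS_TSV_COLUMNS = ("read_id", "chrom", "blocks", "unique")


@dataclass
class AlignedRead:
    read_id: str
    chrom: str
    blocks: list[tuple[int, int]]  # ordered, 0-based half-open
    unique: bool = True

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]

    @property
    def gaps(self) -> list[tuple[int, int]]:
        """Skipped (intronic) intervals between consecutive blocks."""
        return [
            (e1, s2) for (_, e1), (s2, _) in zip(self.blocks, self.blocks[1:])
        ]


def format_blocks(blocks: Iterable[tuple[int, int]]) -> str:
    return ",".join(f"{s}-{e}" for s, e in blocks)


def parse_blocks(text: str) -> list[tuple[int, int]]:
    blocks = []
    for chunk in text.split(","):
        s, _, e = chunk.partition("-")
        blocks.append((int(s), int(e)))
    return blocks


def write_reads_tsv(reads: Iterable[AlignedRead], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(READS_TSV_COLUMNS) + "\n")
        for r in reads:
            fh.write(
                f"{r.read_id}\t{r.chrom}\t{format_blocks(r.blocks)}\t"
                f"{1 if r.unique else 0}\n"
            )


def read_reads_tsv(path: str) -> Iterator[AlignedRead]:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != READS_TSV_COLUMNS:
            raise ValueError(f"{path}: unexpected read-table header {header}")
        for line in fh:
            read_id, chrom, blocks, unique = line.rstrip("\n").split("\t")
            yield AlignedRead(read_id, chrom, parse_blocks(blocks), unique == "1")


def read_sam(path: str) -> Iterator[AlignedRead]:
    """Iterate gapped alignments of a SAM/BAM file as AlignedReads."""
    with pysam.AlignmentFile(path, check_sq=False) as af:
        for aln in af:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            blocks = _merge_adjacent(aln.get_blocks())
            if not blocks:
                continue
            nh = aln.get_tag("NH") if aln.has_tag("NH") else 1
            unique = nh == 1 and aln.mapping_quality > 0
            yield AlignedRead(aln.query_name, aln.reference_name, blocks, unique)


def _merge_adjacent(blocks: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge blocks split by insertions/deletions, keep true N-gap splits.

    pysam's get_blocks() splits on D as well; treating small deletions as
    contiguity keeps boundary-read logic about splicing, not indels.
    """
    merged: list[tuple[int, int]] = []
    for s, e in blocks:
        if merged and s - merged[-1][1] <= 3:  # <=3 nt gap: indel, not intron
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


def load_reads(path: str) -> list[AlignedRead]:
    """Load reads from a .sam/.bam file or a simulator read table."""
    if path.endswith((".sam", ".bam")):
        return list(read_sam(path))
    return list(read_reads_tsv(path))
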