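"""Alternative-splicing categorization around minor introns.

Uniquely mapped spliced reads at a minor-intron locus are binned into nine
categories relative to the canonical exon chain:

* CAT1 — canonical exon-exon junction across the minor intron (the
  constitutive denominator contributor, never reported as an AS event);
* CAT2 — both flanking exons skipped;
* CAT3 — upstream flanking exon skipped;
* CAT4 — downstream flanking exon skipped;
* CAT5-CAT8 — cryptic splice-site usage, generated as side x location
  (5'/3' x exonic/intronic).  CAT5: cryptic 5'SS inside the upstream exon
  (exon truncation); CAT6: cryptic 5'SS inside the minor intron; CAT7:
  cryptic 3'SS inside the downstream exon; CAT8: cryptic 3'SS inside the
  minor intron (downstream-exon extension).  The side/location -> category
  mapping is a module-level table so alternative figure readings are a
  config change;
* CAT9 — junction end strictly inside the minor intron with the other end
  reaching a flanking exon (cryptic-exon support); a read can support CAT9
  together with an intronic cryptic-SS class.

Cryptic splice sites must lie more than 2 nt from the canonical site; a
first pass requires the other junction end to sit exactly on a canonical
splice site, and a second pass rescues reads that share an established
cryptic coordinate without being canonically anchored on the other side.

Each AS event (category + junction coordinates) is quantified as an MSI:
the percentage of the locus's distinct spliced reads supporting it.  A
tissue-level event is accepted when the replicate-mean MSI exceeds 10% and
the replicate-mean supporting reads exceed 1 per 3 million uniquely mapped
reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .annotation import TranscriptModel
from .reads import AlignedRead

MIN_OVERHANG = 2  # junction reads with 1-nt overhangs are excluded
CRYPTIC_MIN_DISTANCE = 2  # strict: cryptic site must be > 2 nt from canonical
AS_MSI_THRESHOLD = 10.0  # strict: mean MSI must exceed 10%
AS_DEPTH_NORM = 3_000_000  # > 1 supporting read per 3M uniquely mapped reads

#: (side, location) -> category number for the four cryptic classes
CRYPTIC_CATEGORY_MAP: dict[tuple[str, str], int] = {
    ("5prime", "exonic"): 5,
    ("5prime", "intronic"): 6,
    ("3prime", "exonic"): 7,
    ("3prime", "intronic"): 8,
}

CATEGORIES = tuple(f"CAT{i}" for i in range(1, 10))


@dataclass(frozen=True)
class JunctionRead:
    read_id: str
    donor_pos: int  # oriented coordinate of the junction's 5' end
    acceptor_pos: int  # oriented coordinate of the junction's 3' end
    left_overhang: int
    right_overhang: int
    unique: bool = True


@dataclass
class MinorIntronLocus:
    """A minor intron with its flanking exon model, in oriented coordinates.

    Oriented coordinates increase 5'->3' along the transcript: genomic
    positions on the plus strand, negated genomic positions on the minus
    strand.  All intervals are half-open.
    """

    intron_id: str
    chrom: str
    strand: str
    upstream_exon: tuple[int, int]  # U1, immediately 5' of the intron
    minor_intron: tuple[int, int]
    downstream_exon: tuple[int, int]  # D1
    upstream_neighbor: tuple[int, int] | None = None  # U2
    downstream_neighbor: tuple[int, int] | None = None  # D2

    @property
    def canonical_donor(self) -> int:
        return self.minor_intron[0]

    @property
    def canonical_acceptor(self) -> int:
        return self.minor_intron[1]

    @classmethod
    def from_transcript(
        cls, transcript: TranscriptModel, intron_ordinal: int, intron_id: str = ""
    ) -> "MinorIntronLocus":
        """Build the locus around the transcript's `intron_ordinal`-th intron
        (1-based, transcript orientation)."""
        exons = transcript.exons
        n_introns = len(exons) - 1
        if not 1 <= intron_ordinal <= n_introns:
            raise ValueError(f"intron ordinal {intron_ordinal} out of range")
        minus = transcript.strand == "-"
        # genomic index of the intron: transcript ordinal k maps to genomic
        # gap index k-1 on '+', n_introns-k on '-'
        gi = (n_introns - intron_ordinal) if minus else (intron_ordinal - 1)

        def orient(iv: tuple[int, int]) -> tuple[int, int]:
            return (-iv[1], -iv[0]) if minus else iv

        u1, d1 = (gi + 1, gi) if minus else (gi, gi + 1)
        u2 = u1 + (1 if minus else -1)
        d2 = d1 + (-1 if minus else 1)
        return cls(
            intron_id=intron_id or f"{transcript.transcript_id}.i{intron_ordinal}",
            chrom=transcript.chrom,
            strand=transcript.strand,
            upstream_exon=orient(exons[u1]),
            minor_intron=orient((exons[gi][1], exons[gi + 1][0])),
            downstream_exon=orient(exons[d1]),
            upstream_neighbor=orient(exons[u2]) if 0 <= u2 < len(exons) else None,
            downstream_neighbor=orient(exons[d2]) if 0 <= d2 < len(exons) else None,
        )

    def orient_position(self, genomic_pos: int) -> int:
        return -genomic_pos if self.strand == "-" else genomic_pos

    @property
    def window(self) -> tuple[int, int]:
        """Interrogation window: neighboring exons through the minor intron."""
        lo = (self.upstream_neighbor or self.upstream_exon)[0]
        hi = (self.downstream_neighbor or self.downstream_exon)[1]
        return lo, hi


def collect_spliced_reads(
    reads: Iterable[AlignedRead], locus: MinorIntronLocus
) -> list[JunctionRead]:
    """Junction reads at the locus: unique, overhangs >= 2, inside the window.

    Multi-gap reads contribute one JunctionRead per gap; each qualifying gap
    must touch the minor-intron neighborhood (upstream exon start through
    downstream exon end).
    """
    lo, hi = locus.window
    core_lo = locus.upstream_exon[0]
    core_hi = locus.downstream_exon[1]
    out: list[JunctionRead] = []
    for read in reads:
        if not read.unique or read.chrom != locus.chrom:
            continue
        blocks = read.blocks
        for k, (gstart, gend) in enumerate(read.gaps):
            left = blocks[k][1] - blocks[k][0]
            right = blocks[k + 1][1] - blocks[k + 1][0]
            if min(left, right) < MIN_OVERHANG:
                continue
            d, a = sorted(
                (locus.orient_position(gstart), locus.orient_position(gend))
            )
            if a < lo or d > hi:  # junction entirely outside the window
                continue
            if a < core_lo or d > core_hi:  # does not touch the neighborhood
                continue
            if locus.strand == "-":
                left, right = right, left
            out.append(JunctionRead(read.read_id, d, a, left, right, read.unique))
    return out


def detect_cryptic_junctions(
    junctions: Sequence[JunctionRead], locus: MinorIntronLocus
) -> dict[tuple[str, int], int]:
    """Two-pass cryptic splice-site detection.

    Pass 1 keeps junction coordinates with one end exactly on a canonical
    splice site of the minor intron and the other more than 2 nt from its
    canonical counterpart.  Pass 2 pools additional reads sharing a pass-1
    cryptic coordinate even without canonical anchoring of the other end.
    Returns ``{(side, cryptic_coordinate): pooled read count}`` with side
    "5prime" (donor moved) or "3prime" (acceptor moved).
    """
    cd, ca = locus.canonical_donor, locus.canonical_acceptor
    sites: dict[tuple[str, int], int] = {}
    for j in junctions:
        if j.acceptor_pos == ca and abs(j.donor_pos - cd) > CRYPTIC_MIN_DISTANCE:
            sites[("5prime", j.donor_pos)] = 0
        if j.donor_pos == cd and abs(j.acceptor_pos - ca) > CRYPTIC_MIN_DISTANCE:
            sites[("3prime", j.acceptor_pos)] = 0
    for j in junctions:  # pass 2: pooled support including rescued reads
        for side, coord in list(sites):
            pos = j.donor_pos if side == "5prime" else j.acceptor_pos
            if pos == coord:
                sites[(side, coord)] += 1
    return sites


def _inside(pos: int, interval: tuple[int, int], strict: bool = True) -> bool:
    s, e = interval
    return s < pos < e if strict else s <= pos <= e


def bin_junction(
    j: JunctionRead,
    locus: MinorIntronLocus,
    cryptic_sites: Mapping[tuple[str, int], int] | None = None,
    category_map: Mapping[tuple[str, str], int] = CRYPTIC_CATEGORY_MAP,
) -> set[str]:
    """Category set supported by one junction; empty set means unassigned."""
    cats: set[int] = set()
    d, a = j.donor_pos, j.acceptor_pos
    u1, m, d1 = locus.upstream_exon, locus.minor_intron, locus.downstream_exon
    cd, ca = m

    if (d, a) == (cd, ca):
        return {"CAT1"}

    skips_u1 = d <= u1[0] and a >= u1[1]
    skips_d1 = d <= d1[0] and a >= d1[1]
    if skips_u1 and skips_d1:
        cats.add(2)
    elif skips_u1:
        cats.add(3)
    elif skips_d1:
        cats.add(4)

    # cryptic splice-site classes; pass-2 rescue via the cryptic-site table
    def _established(side: str, pos: int) -> bool:
        return cryptic_sites is None or (side, pos) in cryptic_sites

    if abs(d - cd) > CRYPTIC_MIN_DISTANCE and _established("5prime", d):
        if a == ca or _inside(a, d1, strict=False):
            if _inside(d, u1, strict=True):
                cats.add(category_map[("5prime", "exonic")])
            elif _inside(d, m, strict=True):
                cats.add(category_map[("5prime", "intronic")])
    if abs(a - ca) > CRYPTIC_MIN_DISTANCE and _established("3prime", a):
        if d == cd or _inside(d, u1, strict=False):
            if _inside(a, d1, strict=True):
                cats.add(category_map[("3prime", "exonic")])
            elif _inside(a, m, strict=True):
                cats.add(category_map[("3prime", "intronic")])

    # cryptic-exon support: a junction end strictly inside the minor intron
    if _inside(d, m, strict=True) or _inside(a, m, strict=True):
        cats.add(9)
    return {f"CAT{c}" for c in cats}


@dataclass
class AsEventRecord:
    intron_id: str
    sample_id: str
    category: str
    junction_coords: tuple[int, int]
    read_count: int
    msi: float
    passed_filters: bool = False
    reasons: list[str] = field(default_factory=list)


def quantify_as_events(
    junctions: Sequence[JunctionRead],
    locus: MinorIntronLocus,
    sample_id: str = "",
    library_unique_reads: int | None = None,
) -> list[AsEventRecord]:
    """Per-sample MSI for every observed (category, junction) AS event.

    The denominator is the number of distinct spliced reads collected at the
    locus; a multi-junction read counts once.  CAT1 support is recorded (it
    is the constitutive reference) but never reported as an AS event.
    """
    denominator = len({j.read_id for j in junctions})
    if denominator == 0:
        return []
    cryptic = detect_cryptic_junctions(junctions, locus)
    support: dict[tuple[str, tuple[int, int]], set[str]] = {}
    for j in junctions:
        for cat in bin_junction(j, locus, cryptic):
            key = (cat, (j.donor_pos, j.acceptor_pos))
            support.setdefault(key, set()).add(j.read_id)
    records = []
    for (cat, coords), read_ids in sorted(support.items()):
        if cat == "CAT1":
            continue
        count = len(read_ids)
        records.append(
            AsEventRecord(
                intron_id=locus.intron_id,
                sample_id=sample_id,
                category=cat,
                junction_coords=coords,
                read_count=count,
                msi=100.0 * count / denominator,
            )
        )
    if library_unique_reads is not None:
        for rec in records:
            _apply_depth_filter(rec, library_unique_reads)
    return records


def _apply_depth_filter(rec: AsEventRecord, library_unique_reads: int) -> None:
    normalized = rec.read_count * AS_DEPTH_NORM / library_unique_reads
    if normalized <= 1:
        rec.reasons.append("depth")


def accept_tissue_events(
    replicate_events: Mapping[str, Sequence[AsEventRecord]],
    library_sizes: Mapping[str, int],
) -> list[dict[str, object]]:
    """Tissue-level AS calls: mean MSI > 10% and mean normalized reads > 1.

    `replicate_events` maps sample_id -> that replicate's AsEventRecords
    (all replicates of one tissue); events are matched across replicates by
    (intron, category, coords), with replicates lacking the event counted
    as zeros.
    """
    n_reps = len(replicate_events)
    if n_reps == 0:
        raise ValueError("need >=1 replicate")
    keys: set[tuple[str, str, tuple[int, int]]] = set()
    for events in replicate_events.values():
        keys |= {(e.intron_id, e.category, e.junction_coords) for e in events}
    out = []
    for key in sorted(keys):
        intron_id, category, coords = key
        msis, norm_reads = [], []
        for sample_id, events in replicate_events.items():
            match = [
                e
                for e in events
                if (e.intron_id, e.category, e.junction_coords) == key
            ]
            msis.append(match[0].msi if match else 0.0)
            count = match[0].read_count if match else 0
            norm_reads.append(count * AS_DEPTH_NORM / library_sizes[sample_id])
        mean_msi = sum(msis) / n_reps
        mean_norm = sum(norm_reads) / n_reps
        reasons = []
        if mean_msi <= AS_MSI_THRESHOLD:
            reasons.append("msi")
        if mean_norm <= 1:
            reasons.append("depth")
        out.append(
            {
                "intron_id": intron_id,
                "category": category,
                "junction_coords": coords,
                "mean_msi": mean_msi,
                "mean_normalized_reads": mean_norm,
                "accepted": not reasons,
                "reasons": reasons,
            }
        )
    return out


ISOFORM_CATEGORIES = (
    "constitutive",
    "truncated_before",
    "terminal_exon_within",
    "AS_across",
)


def bin_annotated_isoforms(
    transcripts: Sequence[TranscriptModel], minor_intron: tuple[int, int], strand: str
) -> dict[str, str]:
    """Bin each annotated transcript of a gene relative to the minor intron.

    Categories, tested in order: supports constitutive splicing of the minor
    intron (adjacent exons abut it exactly); truncated before the intron;
    first/last exon within the intron; alternative splicing across it.
    `minor_intron` is genomic half-open.
    """
    ms, me = minor_intron
    out: dict[str, str] = {}
    for tx in transcripts:
        exons = tx.exons
        gaps = [(e1, s2) for (_, e1), (s2, _) in zip(exons, exons[1:])]
        if (ms, me) in gaps:
            out[tx.transcript_id] = "constitutive"
            continue
        span = (exons[0][0], exons[-1][1])
        before = span[1] <= ms if strand == "+" else span[0] >= me
        if before:
            out[tx.transcript_id] = "truncated_before"
            continue
        terminal = exons[-1] if strand == "+" else exons[0]
        first = exons[0] if strand == "+" else exons[-1]
        if any(ms <= ex[0] and ex[1] <= me for ex in (terminal, first)):
            out[tx.transcript_id] = "terminal_exon_within"
            continue
        out[tx.transcript_id] = "AS_across"
    return out


def as_events_frame(records: Iterable[AsEventRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "intron_id": r.intron_id,
                "sample_id": r.sample_id,
                "category": r.category,
                "donor": r.junction_coords[0],
                "acceptor": r.junction_coords[1],
                "reads": r.read_count,
                "msi": round(r.msi, 4),
                "passed_filters": r.passed_filters,
                "reasons": ",".join(r.reasons),
            }
        )
    return pd.DataFrame(rows)
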