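"""Transcript editing and protein / NMD / NSD fate prediction.

An accepted AS event is applied to the canonical transcript's exon chain
(one event at a time), the edited transcript is translated in silico from
the annotated start codon, and the position of the first in-frame stop
decides the fate:

* no stop before the transcript end — non-stop decay (NSD; the poly(A)
  signal is approximated by the annotated transcript end);
* stop more than 50 nt upstream of the final exon-exon junction —
  nonsense-mediated decay (NMD);
* otherwise protein, classified as truncated / extended / unchanged by
  comparing the new ORF length with the canonical one.

Events that pass the read filter only as a sum over multiple distinct
junction coordinates, none passing individually, are excluded from fate
prediction.

All coordinates here are "oriented": increasing 5'->3' along the transcript
(genomic on the plus strand, negated on the minus strand), half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from Bio.Seq import Seq

from .altsplice import AS_DEPTH_NORM, AS_MSI_THRESHOLD, MinorIntronLocus
from .annotation import GenomeSequence, TranscriptModel

NMD_DISTANCE = 50  # nt upstream of the last exon-exon junction

STOP_CODONS = {"TAA", "TAG", "TGA"}


def oriented_exons(transcript: TranscriptModel) -> list[tuple[int, int]]:
    """Exon chain in oriented coordinates, 5'->3'."""
    if transcript.strand == "-":
        return [(-e, -s) for s, e in reversed(transcript.exons)]
    return list(transcript.exons)


def oriented_fetch(
    genome: GenomeSequence, chrom: str, strand: str, interval: tuple[int, int]
) -> str:
    s, e = interval
    if strand == "-":
        seq = genome.fetch(chrom, -e, -s)
        return str(Seq(seq).reverse_complement())
    return genome.fetch(chrom, s, e)


def oriented_start_codon(transcript: TranscriptModel) -> int | None:
    """Oriented coordinate of the first base of the annotated start codon."""
    if transcript.cds_span is None:
        return None
    cs, ce = transcript.cds_span
    return cs if transcript.strand == "+" else -ce


@dataclass
class SpliceEvent:
    """One alternative-splicing event in locus-oriented coordinates."""

    kind: str  # 'retention', 'CAT2'..'CAT9'
    junction: tuple[int, int] | None = None  # cryptic donor/acceptor (CAT5-8)
    cryptic_exon: tuple[int, int] | None = None  # inserted exon (CAT9)


@dataclass
class ModifiedTranscript:
    source_transcript_id: str
    applied_event: SpliceEvent
    chrom: str
    strand: str
    exon_chain: list[tuple[int, int]]  # oriented, ordered
    annotated_start: int | None  # transcript coordinate, None when start lost
    canonical_orf_length: int | None = None

    @property
    def junction_positions(self) -> list[int]:
        """Transcript coordinates of every exon-exon junction."""
        out, t = [], 0
        for s, e in self.exon_chain[:-1]:
            t += e - s
            out.append(t)
        return out

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exon_chain)


@dataclass
class FatePrediction:
    fate: str  # 'protein', 'NMD', 'NSD' or 'start_lost'
    protein_change: str  # 'truncated', 'extended', 'unchanged', 'n/a'
    new_stop_position: int | None  # transcript coord of the stop codon start


class EventExcludedError(ValueError):
    """Event not applicable to fate prediction (multi-coordinate aggregate)."""


def _transcript_coord(chain: Sequence[tuple[int, int]], oriented_base: int) -> int | None:
    t = 0
    for s, e in chain:
        if s <= oriented_base < e:
            return t + (oriented_base - s)
        t += e - s
    return None


def apply_as_event(
    canonical: TranscriptModel,
    locus: MinorIntronLocus,
    event: SpliceEvent,
) -> ModifiedTranscript:
    """Edit the canonical exon chain according to one AS event.

    Retention merges the minor intron into its flanking exons; skipping
    removes flanking exon(s); a cryptic splice site moves the corresponding
    exon boundary to the event's junction coordinate; a cryptic exon is
    inserted inside the minor intron.
    """
    chain = oriented_exons(canonical)
    u1, m, d1 = locus.upstream_exon, locus.minor_intron, locus.downstream_exon
    try:
        iu, idn = chain.index(u1), chain.index(d1)
    except ValueError as exc:
        raise ValueError("locus exons not found in canonical transcript") from exc

    new_chain = list(chain)
    kind = event.kind
    if kind in ("CAT1", "constitutive"):
        pass
    elif kind == "retention":
        new_chain[iu : idn + 1] = [(u1[0], d1[1])]
    elif kind == "CAT2":
        del new_chain[iu : idn + 1]
    elif kind == "CAT3":
        del new_chain[iu]
    elif kind == "CAT4":
        del new_chain[idn]
    elif kind in ("CAT5", "CAT6"):
        if event.junction is None:
            raise ValueError(f"{kind} needs a junction coordinate")
        new_chain[iu] = (u1[0], event.junction[0])
    elif kind in ("CAT7", "CAT8"):
        if event.junction is None:
            raise ValueError(f"{kind} needs a junction coordinate")
        new_chain[idn] = (event.junction[1], d1[1])
    elif kind == "CAT9":
        if event.cryptic_exon is None:
            raise ValueError("CAT9 needs the cryptic exon interval")
        es, ee = event.cryptic_exon
        if not (m[0] < es < ee < m[1]):
            raise ValueError("cryptic exon must lie inside the minor intron")
        new_chain.insert(idn, (es, ee))
    else:
        raise ValueError(f"unknown event kind {kind!r}")

    start_base = oriented_start_codon(canonical)
    tstart = _transcript_coord(new_chain, start_base) if start_base is not None else None
    return ModifiedTranscript(
        source_transcript_id=canonical.transcript_id,
        applied_event=event,
        chrom=canonical.chrom,
        strand=canonical.strand,
        exon_chain=new_chain,
        annotated_start=tstart,
    )


def _chain_sequence(
    genome: GenomeSequence, chrom: str, strand: str, chain: Sequence[tuple[int, int]]
) -> str:
    return "".join(oriented_fetch(genome, chrom, strand, iv) for iv in chain)


def _first_stop(seq: str, start: int) -> int | None:
    """Transcript coordinate of the first in-frame stop codon at/after start."""
    for pos in range(start, len(seq) - 2, 3):
        if seq[pos : pos + 3] in STOP_CODONS:
            return pos
    return None


def predict_fate(mt: ModifiedTranscript, genome: GenomeSequence) -> FatePrediction:
    """Translate the edited transcript and call protein / NMD / NSD."""
    if mt.annotated_start is None:
        return FatePrediction("start_lost", "n/a", None)
    seq = _chain_sequence(genome, mt.chrom, mt.strand, mt.exon_chain)
    stop = _first_stop(seq, mt.annotated_start)
    if stop is None:
        return FatePrediction("NSD", "n/a", None)
    junctions = mt.junction_positions
    if junctions and junctions[-1] - (stop + 3) > NMD_DISTANCE:
        return FatePrediction("NMD", "n/a", stop)
    new_orf = stop + 3 - mt.annotated_start
    change = "unchanged"
    if mt.canonical_orf_length is not None:
        if new_orf < mt.canonical_orf_length:
            change = "truncated"
        elif new_orf > mt.canonical_orf_length:
            change = "extended"
    return FatePrediction("protein", change, stop)


def predict_event_fate(
    canonical: TranscriptModel,
    locus: MinorIntronLocus,
    event: SpliceEvent,
    genome: GenomeSequence,
) -> FatePrediction:
    """Apply one event and predict its fate, filling the canonical ORF length."""
    mt = apply_as_event(canonical, locus, event)
    chain = oriented_exons(canonical)
    start_base = oriented_start_codon(canonical)
    if start_base is not None:
        tstart = _transcript_coord(chain, start_base)
        if tstart is not None:
            seq = _chain_sequence(genome, canonical.chrom, canonical.strand, chain)
            stop = _first_stop(seq, tstart)
            if stop is not None:
                mt.canonical_orf_length = stop + 3 - tstart
    return predict_fate(mt, genome)


def variant_protein(
    mt: ModifiedTranscript, genome: GenomeSequence
) -> str | None:
    """Predicted protein sequence of the edited transcript (None if no ORF)."""
    if mt.annotated_start is None:
        return None
    seq = _chain_sequence(genome, mt.chrom, mt.strand, mt.exon_chain)
    coding = seq[mt.annotated_start :]
    coding = coding[: len(coding) - len(coding) % 3]
    protein = str(Seq(coding).translate(to_stop=True))
    return protein


def exclude_multi_coordinate_events(
    tissue_events: Sequence[Mapping[str, object]],
) -> tuple[list[Mapping[str, object]], list[dict[str, object]]]:
    """Split tissue-level AS calls into fate-predictable and excluded events.

    An (intron, category) whose pooled support across distinct junction
    coordinates passes the MSI and depth filters while no single coordinate
    passes on its own is excluded from ORF analysis.
    """
    kept: list[Mapping[str, object]] = []
    excluded: list[dict[str, object]] = []
    by_cat: dict[tuple[str, str], list[Mapping[str, object]]] = {}
    for ev in tissue_events:
        by_cat.setdefault((str(ev["intron_id"]), str(ev["category"])), []).append(ev)
    for (intron_id, category), events in sorted(by_cat.items()):
        singles = [e for e in events if e["accepted"]]
        if singles:
            kept.extend(singles)
            continue
        pooled_msi = sum(float(e["mean_msi"]) for e in events)
        pooled_norm = sum(float(e["mean_normalized_reads"]) for e in events)
        if pooled_msi > AS_MSI_THRESHOLD and pooled_norm > 1 and len(events) > 1:
            excluded.append(
                {
                    "intron_id": intron_id,
                    "category": category,
                    "reason": "multi_coordinate_aggregate",
                    "n_coordinates": len(events),
                }
            )
    return kept, excluded
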