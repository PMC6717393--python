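"""Event application, in-silico translation and NMD/NSD fate rules."""

import numpy as np
import pytest

from mintron.altsplice import MinorIntronLocus
from mintron.annotation import GenomeSequence
from mintron.orf import (
    SpliceEvent,
    apply_as_event,
    exclude_multi_coordinate_events,
    predict_event_fate,
    predict_fate,
    variant_protein,
)

from conftest import make_transcript


def coding_toy(seed=0, n_exons=5, exon_len=60, intron_len=120, stop_exon_offset=30):
    """A clean coding transcript: Ala codons everywhere, ATG at tpos 10,
    a single TAA near the end of the last exon."""
    rng = np.random.default_rng(seed)
    total = 400 + n_exons * (exon_len + intron_len)
    seq = list("".join(rng.choice(list("ACGT"), size=total)))
    exons = [(200 + i * (exon_len + intron_len), 200 + i * (exon_len + intron_len) + exon_len)
             for i in range(n_exons)]
    for s, e in exons:
        for g in range(s, e, 3):
            seq[g : g + 3] = list("GCT")
    seq[exons[0][0] + 10 : exons[0][0] + 13] = list("ATG")
    tpos_start = 10
    stop_tpos = (n_exons - 1) * exon_len + stop_exon_offset
    stop_tpos += (3 - (stop_tpos - tpos_start) % 3) % 3
    stop_g = exons[-1][0] + (stop_tpos - (n_exons - 1) * exon_len)
    seq[stop_g : stop_g + 3] = list("TAA")
    tx = make_transcript(exons, cds_span=(exons[0][0] + 10, stop_g + 3))
    return tx, seq


class TestApplyEvent:
    def test_cat3_removes_one_exon(self):
        tx, seq = coding_toy()
        locus = MinorIntronLocus.from_transcript(tx, 3, "m")
        mt = apply_as_event(tx, locus, SpliceEvent("CAT3"))
        assert len(mt.exon_chain) == 4
        assert locus.upstream_exon not in mt.exon_chain

    def test_cat9_inserts_72nt_exon(self):
        tx, seq = coding_toy()
        locus = MinorIntronLocus.from_transcript(tx, 3, "m")
        ms, me = locus.minor_intron
        mt = apply_as_event(tx, locus, SpliceEvent("CAT9", cryptic_exon=(ms + 10, ms + 82)))
        assert len(mt.exon_chain) == 6
        assert (ms + 10, ms + 82) in mt.exon_chain
        assert mt.length == sum(e - s for s, e in tx.exons) + 72

    def test_junction_positions_strictly_increasing(self):
        tx, _ = coding_toy()
        locus = MinorIntronLocus.from_transcript(tx, 3, "m")
        for kind in ("CAT1", "retention", "CAT2", "CAT3", "CAT4"):
            mt = apply_as_event(tx, locus, SpliceEvent(kind))
            jp = mt.junction_positions
            assert jp == sorted(jp)
            assert len(jp) == len(mt.exon_chain) - 1

    def test_cryptic_event_needs_junction(self):
        tx, _ = coding_toy()
        locus = MinorIntronLocus.from_transcript(tx, 3, "m")
        with pytest.raises(ValueError, match="junction"):
            apply_as_event(tx, locus, SpliceEvent("CAT6"))

    def test_start_lost_flagged(self):
        tx, seq = coding_toy()
        locus = MinorIntronLocus.from_transcript(tx, 1, "m")  # first intron
        # CAT3 on the first intron removes exon 1 and with it the start codon
        mt = apply_as_event(tx, locus, SpliceEvent("CAT3"))
        genome = GenomeSequence({"chr1": "".join(seq)})
        fate = predict_fate(mt, genome)
        assert fate.fate == "start_lost"


class TestFateRules:
    def test_cat1_identity_is_unchanged_protein(self):
        tx, seq = coding_toy()
        genome = GenomeSequence({"chr1": "".join(seq)})
        locus = MinorIntronLocus.from_transcript(tx, 3, "m")
        fate = predict_event_fate(tx, locus, SpliceEvent("CAT1"), genome)
        assert (fate.fate, fate.protein_change) == ("protein", "unchanged")

    def test_premature_stop_far_upstream_of_last_junction_is_nmd(self):
        tx, seq = coding_toy()
        locus = MinorIntronLocus.from_transcript(tx, 3, "m")
        ms, me = locus.minor_intron
        # cassette starting with an in-frame TAA, >50 nt upstream of the
        # final junction
        es = ms + 10 + ((3 - ((180 - 10 + 10) % 3)) % 3)
        seq2 = list(seq)
        seq2[es : es + 3] = list("TAA")
        genome = GenomeSequence({"chr1": "".join(seq2)})
        fate = predict_event_fate(
            tx, locus, SpliceEvent("CAT9", cryptic_exon=(es, es + 72)), genome
        )
        assert fate.fate == "NMD"

    def test_no_stop_before_transcript_end_is_nsd(self):
        tx, seq = coding_toy()
        genome = GenomeSequence({"chr1": "".join(seq)})
        # removing the stop-carrying last exon leaves no in-frame stop
        locus = MinorIntronLocus.from_transcript(tx, 4, "m")
        fate = predict_event_fate(tx, locus, SpliceEvent("CAT4"), genome)
        assert fate.fate == "NSD"

    def test_stop_downstream_of_annotated_is_extension(self):
        tx, seq = coding_toy()
        locus = MinorIntronLocus.from_transcript(tx, 3, "m")
        ms, _ = locus.minor_intron
        es = ms + 10 + ((3 - ((180 - 10 + 10) % 3)) % 3)
        seq2 = list(seq)
        for g in range(es, es + 72, 3):
            seq2[g : g + 3] = list("GCT")
        genome = GenomeSequence({"chr1": "".join(seq2)})
        fate = predict_event_fate(
            tx, locus, SpliceEvent("CAT9", cryptic_exon=(es, es + 72)), genome
        )
        assert (fate.fate, fate.protein_change) == ("protein", "extended")
        mt = apply_as_event(tx, locus, SpliceEvent("CAT9", cryptic_exon=(es, es + 72)))
        prot = variant_protein(mt, genome)
        assert prot is not None and len(prot) == (fate.new_stop_position - mt.annotated_start) // 3

    def test_inserting_3n_stopfree_block_never_triggers_decay(self):
        """Frame logic: in-frame stop-free cassettes keep the protein fate
        when the canonical stop stays downstream of the last junction zone."""
        tx, seq = coding_toy(stop_exon_offset=6)
        locus = MinorIntronLocus.from_transcript(tx, 3, "m")
        ms, _ = locus.minor_intron
        genome_base = list(seq)
        for length in (12, 36, 72):
            es = ms + 10 + ((3 - ((180 - 10 + 10) % 3)) % 3)
            seq2 = list(genome_base)
            for g in range(es, es + length, 3):
                seq2[g : g + 3] = list("GCT")
            genome = GenomeSequence({"chr1": "".join(seq2)})
            fate = predict_event_fate(
                tx, locus, SpliceEvent("CAT9", cryptic_exon=(es, es + length)), genome
            )
            assert fate.fate == "protein"

    def test_fate_panel_is_exact(self):
        from mintron.validation import orf_fate_panel

        n_ok, n_total = orf_fate_panel()
        assert n_ok == n_total


class TestMultiCoordinateExclusion:
    def _call(self, intron, cat, coords, msi, norm, accepted):
        return {
            "intron_id": intron,
            "category": cat,
            "junction_coords": coords,
            "mean_msi": msi,
            "mean_normalized_reads": norm,
            "accepted": accepted,
            "reasons": [] if accepted else ["msi"],
        }

    def test_aggregate_without_single_pass_excluded(self):
        calls = [
            self._call("i1", "CAT6", (10, 50), 6.0, 0.8, False),
            self._call("i1", "CAT6", (12, 50), 5.0, 0.7, False),
            self._call("i1", "CAT6", (15, 50), 4.0, 0.6, False),
        ]
        kept, excluded = exclude_multi_coordinate_events(calls)
        assert kept == []
        assert excluded[0]["reason"] == "multi_coordinate_aggregate"
        assert excluded[0]["n_coordinates"] == 3

    def test_single_passing_coordinate_kept(self):
        calls = [
            self._call("i1", "CAT6", (10, 50), 20.0, 2.0, True),
            self._call("i1", "CAT6", (12, 50), 3.0, 0.2, False),
        ]
        kept, excluded = exclude_multi_coordinate_events(calls)
        assert len(kept) == 1 and kept[0]["accepted"]
        assert excluded == []
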