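"""MSI computation, evidence counting, filters and flanking bins."""

import pytest
from hypothesis import given, settings, strategies as st

from mintron.annotation import IntronRecord
from mintron.reads import AlignedRead
from mintron.retention import (
    IntronEvidence,
    MsiRecord,
    compute_msi,
    compute_msi_pooled,
    count_intron_evidence,
    evaluate_replicate,
    filter_retention,
    flanking_bin,
)


def evidence(b5=0, b3=0, s=0, cov=1.0, intron="i1", sample="s1"):
    return IntronEvidence(intron, sample, b5, b3, s, cov, 1_000_000)


def toy_intron(start=1000, length=100, strand="+"):
    return IntronRecord("i1", "g1", "t1", "c", start, start + length, strand, 1, 2)


class TestComputeMsi:
    @pytest.mark.parametrize(
        "b5,b3,s,expected",
        [
            (0, 0, 10, 0.0),
            (5, 5, 0, 100.0),
            (6, 3, 6, 100 * 0.5 * (6 / 12 + 3 / 9)),  # 41.67
            (10, 10, 10, 50.0),
        ],
    )
    def test_values(self, b5, b3, s, expected):
        assert compute_msi(evidence(b5, b3, s)) == pytest.approx(expected, abs=0.01)

    def test_no_reads_undefined(self):
        assert compute_msi(evidence(0, 0, 0)) is None
        rec = evaluate_replicate(evidence(0, 0, 0))
        assert not rec.passed_filters and "no_reads" in rec.reasons

    def test_pooled_variant(self):
        assert compute_msi_pooled(evidence(5, 5, 0)) == 100.0
        assert compute_msi_pooled(evidence(0, 0, 10)) == 0.0

    @settings(deadline=None, max_examples=100)
    @given(
        st.integers(0, 50), st.integers(0, 50), st.integers(0, 50)
    )
    def test_monotone_in_evidence(self, b5, b3, s):
        base = compute_msi(evidence(b5, b3, s))
        if base is None:
            return
        up_boundary = compute_msi(evidence(b5 + 1, b3, s))
        up_spliced = compute_msi(evidence(b5, b3, s + 1))
        assert up_boundary >= base - 1e-9
        assert up_spliced <= base + 1e-9

    def test_bounds(self):
        for b5, b3, s in [(1, 0, 0), (0, 1, 5), (3, 7, 2)]:
            msi = compute_msi(evidence(b5, b3, s))
            assert 0.0 <= msi <= 100.0


class TestCounting:
    def test_spliced_exact_gap_only(self):
        intron = toy_intron()
        gs, ge = intron.start, intron.end
        reads = [
            AlignedRead("sp", "c", [(gs - 40, gs), (ge, ge + 40)]),  # exact
            AlignedRead("near", "c", [(gs - 40, gs + 1), (ge, ge + 40)]),  # off gap
        ]
        ev = count_intron_evidence(reads, intron)
        assert ev.spliced_reads == 1
        assert ev.boundary_reads_5 == 0 and ev.boundary_reads_3 == 0

    def test_anchor_rule_excludes_short_overhang(self):
        intron = toy_intron()
        gs = intron.start
        reads = [
            AlignedRead("short", "c", [(gs - 40, gs + 2)]),  # 2 nt on intron side
            AlignedRead("ok", "c", [(gs - 3, gs + 3)]),
        ]
        ev = count_intron_evidence(reads, intron, anchor=3)
        assert ev.boundary_reads_5 == 1

    def test_minus_strand_swaps_boundaries(self):
        intron = toy_intron(strand="-")
        gs, ge = intron.start, intron.end
        reads = [AlignedRead("b", "c", [(ge - 10, ge + 10)])]  # genomic right = 5'SS
        ev = count_intron_evidence(reads, intron)
        assert (ev.boundary_reads_5, ev.boundary_reads_3) == (1, 0)

    def test_nonunique_ignored(self):
        intron = toy_intron()
        gs, ge = intron.start, intron.end
        reads = [AlignedRead("m", "c", [(gs - 40, gs), (ge, ge + 40)], unique=False)]
        ev = count_intron_evidence(reads, intron)
        assert ev.spliced_reads == 0

    def test_coverage_fraction(self):
        intron = toy_intron(length=100)
        gs = intron.start
        reads = [AlignedRead("c1", "c", [(gs, gs + 50)])]
        ev = count_intron_evidence(reads, intron)
        assert ev.covered_fraction == pytest.approx(0.5)

    def test_generator_bookkeeping_is_recovered(self, sim):
        """Counted evidence equals the generator's truth table exactly."""
        from mintron.simulate import SimConfig, simulate_reads

        cfg = SimConfig(seed=11, tissues=("thymus",), replicates=1)
        rd = simulate_reads(sim, cfg)
        sample = "thymus_r1"
        reads = rd.samples[sample]
        truth = sim.intron_truth.set_index("intron_id")
        checked = 0
        for row in rd.retention_truth.itertuples():
            t = truth.loc[row.intron_id]
            intron = IntronRecord(
                row.intron_id, t.gene_id, t.transcript_id, t.chrom,
                int(t.start), int(t.end), t.strand, int(t.ordinal), int(t.n_introns),
            )
            ev = count_intron_evidence(reads, intron, sample)
            assert (ev.boundary_reads_5, ev.boundary_reads_3, ev.spliced_reads) == (
                row.b5, row.b3, row.spliced,
            )
            if row.b5 + row.b3 > 0:
                assert ev.covered_fraction > 0.95
            checked += 1
        assert checked > 5


class TestFilters:
    def test_boundary_total_must_exceed_four(self):
        rec = evaluate_replicate(evidence(2, 2, 10))
        assert not rec.passed_filters and "boundary_reads" in rec.reasons
        rec5 = evaluate_replicate(evidence(3, 2, 10))
        assert rec5.passed_filters

    def test_each_splice_site_needs_a_read(self):
        rec = evaluate_replicate(evidence(6, 0, 10))
        assert "splice_site_support" in rec.reasons

    def test_coverage_must_exceed_95(self):
        rec = evaluate_replicate(evidence(4, 4, 10, cov=0.90))
        assert rec.reasons == ["coverage"]

    def test_retained_calls_require_all_replicates_in_mouse_mode(self):
        def rec(sample, tissue, ok):
            ev = evidence(4, 4, 10) if ok else evidence(1, 1, 10)
            ev.sample_id = sample
            return evaluate_replicate(ev, tissue)

        records = [
            rec("t1", "thymus", True), rec("t2", "thymus", True), rec("t3", "thymus", True),
            rec("l1", "liver", True), rec("l2", "liver", False), rec("l3", "liver", True),
        ]
        calls = filter_retention(records, mode="mouse")
        assert calls["i1"]["retained_tissues"] == ["thymus"]
        assert calls["i1"]["retention_class"] == "all_replicates"

    def test_human_mode_needs_three_of_many(self):
        def rec(sample, ok):
            ev = evidence(4, 4, 10) if ok else evidence(1, 1, 10)
            ev.sample_id = sample
            return evaluate_replicate(ev, "heart")

        records = [rec(f"h{k}", k < 3) for k in range(5)]  # 3 of 5 pass
        calls = filter_retention(records, mode="human")
        assert calls["i1"]["retained_tissues"] == ["heart"]
        assert filter_retention(records, mode="mouse")["i1"]["retained_tissues"] == []

    def test_some_replicates_class(self):
        def rec(sample, ok):
            ev = evidence(4, 4, 10) if ok else evidence(1, 1, 10)
            ev.sample_id = sample
            return evaluate_replicate(ev, "lung")

        records = [rec("a", True), rec("b", False), rec("c", False)]
        calls = filter_retention(records)
        assert calls["i1"]["retention_class"] == "some_replicates"

    def test_filter_conservativeness_audit(self):
        """Every retained call has b5>=1, b3>=1, b5+b3>=5, coverage>0.95."""
        records = []
        for k, (b5, b3, s, cov) in enumerate(
            [(3, 2, 10, 1.0), (4, 4, 0, 0.99), (1, 4, 3, 0.97)]
        ):
            ev = evidence(b5, b3, s, cov)
            ev.sample_id = f"r{k}"
            records.append(evaluate_replicate(ev, "kidney"))
        calls = filter_retention(records)
        if "kidney" in calls["i1"]["retained_tissues"]:
            for rec in records:
                e = rec.evidence
                assert e.boundary_reads_5 >= 1 and e.boundary_reads_3 >= 1
                assert e.boundary_reads_5 + e.boundary_reads_3 >= 5
                assert e.covered_fraction > 0.95


class TestFlankingBins:
    @pytest.mark.parametrize(
        "minor,up,down,expected",
        [
            (True, False, False, "I"),
            (True, True, False, "II"),
            (True, False, True, "II"),
            (True, True, True, "III"),
            (False, False, False, "IV"),
            (False, True, False, "V"),
            (False, True, True, "VI"),
        ],
    )
    def test_enumeration(self, minor, up, down, expected):
        assert flanking_bin(minor, up, down) == expected
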