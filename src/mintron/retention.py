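"""Intron-retention quantification as a mis-splicing index (MSI).

For each intron and sample we count

* boundary reads: contiguously aligned reads crossing the exon-intron
  junction with at least `anchor` nt on each side (default 3), separately at
  the 5'SS (b5) and 3'SS (b3);
* spliced reads: uniquely mapped reads whose alignment gap equals the intron
  exactly (s);
* coverage: the fraction of intron bases covered by >=1 aligned read base.

The MSI is the mean of the two per-boundary retention ratios,

    MSI = 100 * 1/2 * ( b5/(b5+s) + b3/(b3+s) )

An intron is called retained in a tissue when every qualifying replicate
passes all evidence filters: total boundary reads b5+b3 > 4, at least one
boundary read at each splice site, and intron coverage > 95%.  Mouse-style
analysis demands a pass in all replicates; human-style in at least three.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .annotation import IntronRecord
from .reads import AlignedRead

DEFAULT_ANCHOR = 3
MIN_BOUNDARY_READS_TOTAL = 4  # strict: must exceed
MIN_COVERAGE = 0.95  # strict: must exceed
HUMAN_MIN_REPLICATES = 3


@dataclass
class IntronEvidence:
    intron_id: str
    sample_id: str
    boundary_reads_5: int = 0
    boundary_reads_3: int = 0
    spliced_reads: int = 0
    covered_fraction: float = 0.0
    library_unique_reads: int = 0


@dataclass
class MsiRecord:
    intron_id: str
    sample_id: str
    msi: float | None  # None when undefined (no reads)
    passed_filters: bool
    reasons: list[str] = field(default_factory=list)
    replicate_group: str = ""
    evidence: IntronEvidence | None = None


def count_intron_evidence(
    reads: Iterable[AlignedRead],
    intron: IntronRecord,
    sample_id: str = "",
    anchor: int = DEFAULT_ANCHOR,
    library_unique_reads: int = 0,
) -> IntronEvidence:
    """Count boundary/spliced/coverage evidence for one intron.

    Only uniquely mapped reads contribute.  A boundary read must be aligned
    contiguously across the junction with >= `anchor` nt on both sides; a
    spliced read must have a gap with exactly the intron's coordinates.
    """
    istart, iend = intron.start, intron.end
    b5 = b3 = s = 0
    covered = [False] * intron.length
    for read in reads:
        if not read.unique or read.chrom != intron.chrom:
            continue
        if read.end <= istart or read.start >= iend:
            if (istart, iend) not in read.gaps:
                continue
        for bs, be in read.blocks:
            # contiguous span across a junction
            if bs <= istart - anchor and be >= istart + anchor:
                b5 += 1
            if bs <= iend - anchor and be >= iend + anchor:
                b3 += 1
            os_, oe = max(bs, istart), min(be, iend)
            for pos in range(os_, oe):
                covered[pos - istart] = True
        if (istart, iend) in read.gaps:
            s += 1
    # transcript orientation: on the minus strand the genomic-left junction
    # is the 3'SS
    if intron.strand == "-":
        b5, b3 = b3, b5
    return IntronEvidence(
        intron_id=intron.intron_id,
        sample_id=sample_id,
        boundary_reads_5=b5,
        boundary_reads_3=b3,
        spliced_reads=s,
        covered_fraction=sum(covered) / len(covered) if covered else 0.0,
        library_unique_reads=library_unique_reads,
    )


def compute_msi(evidence: IntronEvidence) -> float | None:
    """Mean-of-boundaries mis-splicing index in percent; None when no reads."""
    b5, b3, s = (
        evidence.boundary_reads_5,
        evidence.boundary_reads_3,
        evidence.spliced_reads,
    )
    if b5 + b3 + s == 0:
        return None
    terms = []
    for b in (b5, b3):
        if b + s > 0:
            terms.append(b / (b + s))
    if not terms:
        return None
    return 100.0 * sum(terms) / 2.0


def compute_msi_pooled(evidence: IntronEvidence) -> float | None:
    """Alternative pooled-boundary MSI: 100*(b5+b3)/(b5+b3+2s)."""
    b5, b3, s = (
        evidence.boundary_reads_5,
        evidence.boundary_reads_3,
        evidence.spliced_reads,
    )
    denom = b5 + b3 + 2 * s
    if denom == 0:
        return None
    return 100.0 * (b5 + b3) / denom


def evaluate_replicate(evidence: IntronEvidence, replicate_group: str = "") -> MsiRecord:
    """Per-replicate MSI plus the evidence filters with reason codes."""
    reasons = []
    if evidence.boundary_reads_5 + evidence.boundary_reads_3 + evidence.spliced_reads == 0:
        reasons.append("no_reads")
    if evidence.boundary_reads_5 + evidence.boundary_reads_3 <= MIN_BOUNDARY_READS_TOTAL:
        reasons.append("boundary_reads")
    if evidence.boundary_reads_5 < 1 or evidence.boundary_reads_3 < 1:
        reasons.append("splice_site_support")
    if evidence.covered_fraction <= MIN_COVERAGE:
        reasons.append("coverage")
    return MsiRecord(
        intron_id=evidence.intron_id,
        sample_id=evidence.sample_id,
        msi=compute_msi(evidence),
        passed_filters=not reasons,
        reasons=reasons,
        replicate_group=replicate_group,
        evidence=evidence,
    )


def filter_retention(
    records: Sequence[MsiRecord], mode: str = "mouse"
) -> dict[str, dict[str, object]]:
    """Tissue-level retained-intron calls from per-replicate records.

    Groups by (intron, replicate_group).  In "mouse" mode an intron is
    retained in a tissue when all replicates pass; in "human" mode when at
    least three do (all, for tissues with fewer replicates).  Returns, per
    intron: retained tissues, per-tissue replicate pass counts and the
    three-way retention class (retained in all replicates of >=1 tissue /
    only ever in 1-2 replicates / in none).
    """
    if mode not in ("mouse", "human"):
        raise ValueError("mode must be 'mouse' or 'human'")
    by_intron: dict[str, dict[str, list[MsiRecord]]] = {}
    for rec in records:
        by_intron.setdefault(rec.intron_id, {}).setdefault(
            rec.replicate_group, []
        ).append(rec)
    out: dict[str, dict[str, object]] = {}
    for intron_id, tissues in by_intron.items():
        retained_in: list[str] = []
        pass_counts: dict[str, tuple[int, int]] = {}
        for tissue, recs in tissues.items():
            n_pass = sum(r.passed_filters for r in recs)
            pass_counts[tissue] = (n_pass, len(recs))
            if mode == "mouse":
                ok = n_pass == len(recs) and n_pass > 0
            else:
                need = min(HUMAN_MIN_REPLICATES, len(recs))
                ok = n_pass >= need and n_pass > 0
            if ok:
                retained_in.append(tissue)
        max_pass = max((n for n, _ in pass_counts.values()), default=0)
        if retained_in:
            retention_class = "all_replicates"
        elif max_pass > 0:
            retention_class = "some_replicates"
        else:
            retention_class = "none"
        out[intron_id] = {
            "retained_tissues": sorted(retained_in),
            "pass_counts": pass_counts,
            "retention_class": retention_class,
        }
    return out


FLANKING_BINS = ("I", "II", "III", "IV", "V", "VI")


def flanking_bin(
    minor_retained: bool, upstream_major_retained: bool, downstream_major_retained: bool
) -> str:
    """Joint minor/flanking-major retention bin (I..VI).

    I: minor only; II: minor + one major; III: minor + both majors;
    IV: none; V: one major only; VI: both majors only.
    """
    n_major = int(upstream_major_retained) + int(downstream_major_retained)
    if minor_retained:
        return {0: "I", 1: "II", 2: "III"}[n_major]
    return {0: "IV", 1: "V", 2: "VI"}[n_major]


def msi_group_tests(
    length_by_class: Mapping[str, Sequence[float]] | None = None,
    msi_by_group: Mapping[str, Sequence[float]] | None = None,
    as_vs_nonas_lengths: tuple[Sequence[float], Sequence[float]] | None = None,
) -> dict[str, object]:
    """The three group comparisons of the retention/AS analyses.

    * intron length across retention classes: Kruskal-Wallis + Dunn post-hoc;
    * per-intron MSI across tissues, or minor vs flanking majors: one-way
      ANOVA + Tukey HSD;
    * alternatively- vs constitutively-spliced intron length: Mann-Whitney U.

    Pass any subset; results are keyed by comparison name.
    """
    from .stats import anova_tukey, kruskal_dunn, mann_whitney

    out: dict[str, object] = {}
    if length_by_class is not None:
        out["length_by_retention_class"] = kruskal_dunn(length_by_class)
    if msi_by_group is not None:
        out["msi_across_groups"] = anova_tukey(msi_by_group)
    if as_vs_nonas_lengths is not None:
        out["as_vs_nonas_length"] = mann_whitney(*as_vs_nonas_lengths)
    return out


def msi_frame(records: Iterable[MsiRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        ev = r.evidence
        rows.append(
            {
                "intron_id": r.intron_id,
                "sample_id": r.sample_id,
                "tissue": r.replicate_group,
                "msi": round(r.msi, 4) if r.msi is not None else "",
                "boundary_reads_5": ev.boundary_reads_5 if ev else "",
                "boundary_reads_3": ev.boundary_reads_3 if ev else "",
                "spliced_reads": ev.spliced_reads if ev else "",
                "covered_fraction": round(ev.covered_fraction, 4) if ev else "",
                "passed_filters": r.passed_filters,
                "reasons": ",".join(r.reasons),
            }
        )
    return pd.DataFrame(rows)


def retention_calls_frame(calls: Mapping[str, dict[str, object]]) -> pd.DataFrame:
    rows = []
    for intron_id, info in calls.items():
        rows.append(
            {
                "intron_id": intron_id,
                "retained_tissues": ",".join(info["retained_tissues"]),
                "retention_class": info["retention_class"],
            }
        )
    return pd.DataFrame(rows)
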