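"""Minor-intron calling from rescaled splice-site scores.

An intron is called minor when any of four criteria holds (evaluated in
order; the first that fires is reported):

1. the AT-AC minor 5'SS score is over 50 and at least 10 points above every
   other 5'SS score;
2. the GT-AG minor 5'SS score is over 50, at least 25 points above the GT-AG
   major 5'SS score and at least 10 above the two remaining 5'SS scores;
3. the GT-AG minor 5'SS score is over 50, at least 10 points above every
   other 5'SS score, and the best branch-point score is over 65;
4. the sum of the minor 5'SS, branch-point and minor 3'SS scores is over 150.

Criterion 4 uses the larger of the two minor 5'SS scores and the minor 3'SS
matrix of the matching subtype.  Margins are non-strict (>= 10 passes);
"over" thresholds are strict (> 50).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .annotation import (
    GeneModel,
    GenomeSequence,
    IntronRecord,
    derive_introns,
    extract_splice_windows,
    select_canonical_transcript,
)
from .pwm import (
    ACCEPTOR_WIDTH,
    DONOR_WIDTH,
    AmbiguousWindowError,
    PwmSet,
    best_bps_score,
    score_window,
)

CRITERION_MINOR_5SS_OVER = 50.0
CRITERION_MARGIN_OTHER = 10.0
CRITERION_MARGIN_MAJOR_GTAG = 25.0
CRITERION_BPS_OVER = 65.0
CRITERION_SUM_OVER = 150.0


@dataclass
class IntronScores:
    """Rescaled 0-100 scores of one intron against the PWM set."""

    x_5ss: dict[str, float]  # keyed by the four 5'SS PWM names
    x_3ss: dict[str, float] = field(default_factory=dict)  # minor 3'SS PWMs
    x_bps: float | None = None
    bps_window_index: int | None = None
    bps_ppm_variant: str | None = None
    raw: dict[str, float] = field(default_factory=dict)  # audit trail


@dataclass
class Classification:
    call: str  # "minor" or "major"
    criterion: int | None  # 1..4, None when major
    subtype: str  # "AT-AC", "GT-AG", "other"


def score_intron(
    intron: IntronRecord, genome: GenomeSequence, pwms: PwmSet
) -> IntronScores | None:
    """Score the donor/acceptor/branch-point windows of one intron.

    Returns None when the donor window is unavailable (flagged introns at
    sequence boundaries): without all four 5'SS scores no criterion applies.
    """
    windows = extract_splice_windows(intron, genome)
    intron.flags |= windows.flags
    if len(windows.donor12) != DONOR_WIDTH:
        return None
    x_5ss: dict[str, float] = {}
    raw: dict[str, float] = {}
    try:
        for name in (
            "minor_5ss_ATAC",
            "minor_5ss_GTAG",
            "major_5ss_GTAG",
            "major_5ss_GCAG",
        ):
            x_5ss[name] = score_window(windows.donor12, pwms[name])
    except AmbiguousWindowError:
        intron.flags.add("unscorable_donor")
        return None
    x_3ss: dict[str, float] = {}
    if len(windows.acceptor14) == ACCEPTOR_WIDTH:
        for name in ("minor_3ss_ATAC", "minor_3ss_GTAG"):
            try:
                x_3ss[name] = score_window(windows.acceptor14, pwms[name])
            except AmbiguousWindowError:
                intron.flags.add("unscorable_acceptor")
    bps = best_bps_score(windows.bps_windows, pwms["bps_A9"], pwms["bps_A10"])
    scores = IntronScores(x_5ss=x_5ss, x_3ss=x_3ss, raw=raw)
    if bps is not None:
        scores.x_bps, scores.bps_window_index, scores.bps_ppm_variant = bps
    return scores


def classify_intron(scores: IntronScores) -> Classification:
    """Apply the four minor-intron criteria to a score vector."""
    x = scores.x_5ss
    atac = x["minor_5ss_ATAC"]
    mgtag = x["minor_5ss_GTAG"]
    maj_gt = x["major_5ss_GTAG"]
    maj_gc = x["major_5ss_GCAG"]
    bps = scores.x_bps

    # criterion 1: AT-AC 5'SS dominates
    if atac > CRITERION_MINOR_5SS_OVER and all(
        atac - other >= CRITERION_MARGIN_OTHER for other in (mgtag, maj_gt, maj_gc)
    ):
        return Classification("minor", 1, _winning_subtype(scores))
    # criterion 2: minor GT-AG dominates, wide margin over major GT-AG
    if (
        mgtag > CRITERION_MINOR_5SS_OVER
        and mgtag - maj_gt >= CRITERION_MARGIN_MAJOR_GTAG
        and mgtag - atac >= CRITERION_MARGIN_OTHER
        and mgtag - maj_gc >= CRITERION_MARGIN_OTHER
    ):
        return Classification("minor", 2, _winning_subtype(scores))
    # criterion 3: minor GT-AG dominates and the branch point is strong
    if (
        mgtag > CRITERION_MINOR_5SS_OVER
        and all(
            mgtag - other >= CRITERION_MARGIN_OTHER
            for other in (atac, maj_gt, maj_gc)
        )
        and bps is not None
        and bps > CRITERION_BPS_OVER
    ):
        return Classification("minor", 3, _winning_subtype(scores))
    # criterion 4: combined 5'SS + BPS + 3'SS strength
    x5, variant = max((atac, "ATAC"), (mgtag, "GTAG"))
    x3 = scores.x_3ss.get(f"minor_3ss_{variant}")
    if bps is not None and x3 is not None and x5 + bps + x3 > CRITERION_SUM_OVER:
        return Classification("minor", 4, _winning_subtype(scores))
    return Classification("major", None, _winning_subtype(scores))


def _winning_subtype(scores: IntronScores) -> str:
    # subtype from the score vector alone is provisional; the terminal
    # dinucleotide subtype (below) is what catalogs report
    return "AT-AC" if scores.x_5ss["minor_5ss_ATAC"] >= scores.x_5ss["minor_5ss_GTAG"] else "GT-AG"


def subtype_terminal_dinucleotide(intron: IntronRecord) -> str:
    first, last = (d.upper() for d in intron.terminal_dinucleotides)
    if (first, last) == ("GT", "AG"):
        return "GT-AG"
    if (first, last) == ("AT", "AC"):
        return "AT-AC"
    return "other"


def assign_context(
    introns: Sequence[IntronRecord], calls: Sequence[Classification]
) -> None:
    """Set the positional context of each minor intron of one transcript.

    Precedence: only_intron > first_or_last > adjacent_to_minor >
    flanked_by_two_major.
    """
    if len(introns) != len(calls):
        raise ValueError("introns and calls must align")
    minor = [c.call == "minor" for c in calls]
    n = len(introns)
    for i, intron in enumerate(introns):
        if not minor[i]:
            intron.context = None
            continue
        if n == 1:
            intron.context = "only_intron"
        elif i == 0 or i == n - 1:
            intron.context = "first_or_last"
        elif minor[i - 1] or minor[i + 1]:
            intron.context = "adjacent_to_minor"
        else:
            intron.context = "flanked_by_two_major"


@dataclass
class ClassifiedIntron:
    intron: IntronRecord
    scores: IntronScores | None
    classification: Classification


def classify_annotation(
    genes: Iterable[GeneModel], genome: GenomeSequence, pwms: PwmSet
) -> list[ClassifiedIntron]:
    """Classify every intron of every gene's canonical transcript."""
    out: list[ClassifiedIntron] = []
    for gene in genes:
        if not gene.transcripts:
            continue
        tx = select_canonical_transcript(gene)
        introns = derive_introns(tx, genome)
        results = []
        for intron in introns:
            scores = score_intron(intron, genome, pwms)
            if scores is None:
                cls = Classification("major", None, subtype_terminal_dinucleotide(intron))
            else:
                cls = classify_intron(scores)
                cls.subtype = subtype_terminal_dinucleotide(intron)
            results.append(Classification(cls.call, cls.criterion, cls.subtype))
            out.append(ClassifiedIntron(intron, scores, results[-1]))
        assign_context(introns, results)
    return out


def classification_frame(classified: Sequence[ClassifiedIntron]) -> pd.DataFrame:
    """Classification table: one row per intron, 1-based coordinates."""
    rows = []
    for ci in classified:
        it, sc, cl = ci.intron, ci.scores, ci.classification
        row = {
            "intron_id": it.intron_id,
            "gene_id": it.gene_id,
            "transcript_id": it.transcript_id,
            "chrom": it.chrom,
            "start": it.start + 1,
            "end": it.end,
            "strand": it.strand,
            "ordinal": it.ordinal,
            "length": it.length,
            "dinucleotides": "-".join(it.terminal_dinucleotides),
            "call": cl.call,
            "criterion": cl.criterion if cl.criterion is not None else "none",
            "subtype": cl.subtype,
            "context": it.context or "",
            "flags": ",".join(sorted(it.flags)),
        }
        if sc is not None:
            row.update(
                {
                    "x_minor_5ss_ATAC": round(sc.x_5ss["minor_5ss_ATAC"], 3),
                    "x_minor_5ss_GTAG": round(sc.x_5ss["minor_5ss_GTAG"], 3),
                    "x_major_5ss_GTAG": round(sc.x_5ss["major_5ss_GTAG"], 3),
                    "x_major_5ss_GCAG": round(sc.x_5ss["major_5ss_GCAG"], 3),
                    "x_minor_3ss_ATAC": round(sc.x_3ss.get("minor_3ss_ATAC", float("nan")), 3),
                    "x_minor_3ss_GTAG": round(sc.x_3ss.get("minor_3ss_GTAG", float("nan")), 3),
                    "x_bps": round(sc.x_bps, 3) if sc.x_bps is not None else "",
                    "bps_window": sc.bps_window_index or "",
                    "bps_variant": sc.bps_ppm_variant or "",
                }
            )
        rows.append(row)
    return pd.DataFrame(rows)


def minor_intron_catalog(classified: Sequence[ClassifiedIntron]) -> pd.DataFrame:
    frame = classification_frame(classified)
    if frame.empty:
        return frame
    return frame[frame["call"] == "minor"].reset_index(drop=True)


def compare_with_prior_list(
    minor: pd.DataFrame, prior: pd.DataFrame, slack: int = 0
) -> dict[str, int]:
    """Coordinate intersection with a prior minor-intron list.

    `prior` needs chrom/start/end columns (1-based inclusive).  With the
    default slack of 0 only exact coordinate matches count as shared.
    """
    def _key(df: pd.DataFrame) -> set[tuple[str, int, int]]:
        return {
            (str(r.chrom), int(r.start), int(r.end)) for r in df.itertuples()
        }

    ours, theirs = _key(minor), _key(prior)
    if slack > 0:
        shared = {
            k
            for k in ours
            if any(
                k[0] == p[0] and abs(k[1] - p[1]) <= slack and abs(k[2] - p[2]) <= slack
                for p in theirs
            )
        }
    else:
        shared = ours & theirs
    return {
        "shared": len(shared),
        "novel": len(ours - shared),
        "missed_prior": len(theirs) - len(shared) if slack == 0 else sum(
            1
            for p in theirs
            if not any(
                p[0] == k[0] and abs(p[1] - k[1]) <= slack and abs(p[2] - k[2]) <= slack
                for k in ours
            )
        ),
    }
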