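"""End-to-end pipeline over a run directory.

Expects the simulator's layout (or equivalently named real inputs):
``genome.fa``, ``annotation.gtf``, ``ppms.txt``, ``reads/<sample>.tsv|.sam``,
``library_sizes.tsv``, ``tpm.tsv``, ``samples.tsv``.  Stages write TSV/JSON
reports into an output directory; each stage is callable on its own.
"""

from __future__ import annotations

import json
import os
from bisect import bisect_left
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .altsplice import (
    MinorIntronLocus,
    accept_tissue_events,
    as_events_frame,
    collect_spliced_reads,
    quantify_as_events,
)
from .annotation import GenomeSequence, IntronRecord, parse_annotation
from .classify import (
    ClassifiedIntron,
    classification_frame,
    classify_annotation,
    minor_intron_catalog,
)
from .orf import (
    SpliceEvent,
    apply_as_event,
    exclude_multi_coordinate_events,
    predict_fate,
    variant_protein,
)
from .pwm import PwmSet
from .reads import AlignedRead, load_reads
from .retention import (
    count_intron_evidence,
    evaluate_replicate,
    filter_retention,
    flanking_bin,
    msi_frame,
    retention_calls_frame,
)


class ReadIndex:
    """Coarse positional index of reads of one sample, per chromosome."""

    def __init__(self, reads: Sequence[AlignedRead]):
        self._by_chrom: dict[str, tuple[list[int], list[AlignedRead]]] = {}
        buckets: dict[str, list[AlignedRead]] = {}
        for r in reads:
            buckets.setdefault(r.chrom, []).append(r)
        for chrom, rs in buckets.items():
            rs.sort(key=lambda r: r.start)
            self._by_chrom[chrom] = ([r.start for r in rs], rs)
        self.n_reads = len(reads)
        self._max_span = max((r.end - r.start for r in reads), default=0)

    def overlapping(self, chrom: str, start: int, end: int) -> list[AlignedRead]:
        if chrom not in self._by_chrom:
            return []
        starts, rs = self._by_chrom[chrom]
        lo = bisect_left(starts, start - self._max_span)
        hi = bisect_left(starts, end)
        return [r for r in rs[lo:hi] if r.end > start]


def _sample_tissue(sample: str) -> str:
    # simulator convention: <tissue>_r<replicate>
    return sample.rsplit("_r", 1)[0]


@dataclass
class PipelineRun:
    genes: list
    genome: GenomeSequence
    classified: list[ClassifiedIntron]
    minor_catalog: pd.DataFrame


def classify_stage(run_dir: str, out_dir: str) -> PipelineRun:
    genes, genome = parse_annotation(
        os.path.join(run_dir, "annotation.gtf"), os.path.join(run_dir, "genome.fa")
    )
    pwms = PwmSet.from_file(os.path.join(run_dir, "ppms.txt"))
    classified = classify_annotation(genes, genome, pwms)
    os.makedirs(out_dir, exist_ok=True)
    frame = classification_frame(classified)
    frame.to_csv(os.path.join(out_dir, "classification.tsv"), sep="\t", index=False)
    minor = minor_intron_catalog(classified)
    minor.to_csv(os.path.join(out_dir, "minor_introns.tsv"), sep="\t", index=False)
    from .cli import export_catalog

    export_catalog(minor, out_dir)
    return PipelineRun(genes, genome, classified, minor)


def _load_samples(run_dir: str) -> dict[str, ReadIndex]:
    reads_dir = os.path.join(run_dir, "reads")
    samples: dict[str, ReadIndex] = {}
    for name in sorted(os.listdir(reads_dir)):
        if name.endswith((".tsv", ".sam", ".bam")):
            sample = name.rsplit(".", 1)[0]
            if sample in samples:
                continue
            samples[sample] = ReadIndex(load_reads(os.path.join(reads_dir, name)))
    return samples


def retention_stage(
    run_dir: str, out_dir: str, run: PipelineRun, mode: str = "mouse"
) -> dict[str, object]:
    """Per-sample MSI, tissue retention calls, and minor/flanking bins."""
    samples = _load_samples(run_dir)
    records = []
    introns = [ci.intron for ci in run.classified]
    for sample, index in samples.items():
        tissue = _sample_tissue(sample)
        for intron in introns:
            cand = index.overlapping(intron.chrom, intron.start - 200, intron.end + 200)
            ev = count_intron_evidence(
                cand, intron, sample, library_unique_reads=index.n_reads
            )
            records.append(evaluate_replicate(ev, tissue))
    calls = filter_retention(records, mode=mode)
    os.makedirs(out_dir, exist_ok=True)
    msi_frame(records).to_csv(os.path.join(out_dir, "msi.tsv"), sep="\t", index=False)
    retention_calls_frame(calls).to_csv(
        os.path.join(out_dir, "retention_calls.tsv"), sep="\t", index=False
    )

    # per-tissue joint minor/flanking-major bins for minors flanked by two majors
    tissues = sorted({_sample_tissue(s) for s in samples})
    per_tissue_pass: dict[str, set[str]] = {t: set() for t in tissues}
    by_key: dict[tuple[str, str], list] = {}
    for rec in records:
        by_key.setdefault((rec.intron_id, rec.replicate_group), []).append(rec)
    for (intron_id, tissue), recs in by_key.items():
        n_pass = sum(r.passed_filters for r in recs)
        ok = n_pass == len(recs) if mode == "mouse" else n_pass >= min(3, len(recs))
        if ok and n_pass > 0:
            per_tissue_pass[tissue].add(intron_id)
    intron_by_id = {i.intron_id: i for i in introns}
    bin_rows = []
    for ci in run.classified:
        it = ci.intron
        if ci.classification.call != "minor" or it.context != "flanked_by_two_major":
            continue
        up_id = f"{it.transcript_id}.i{it.ordinal - 1}"
        down_id = f"{it.transcript_id}.i{it.ordinal + 1}"
        if up_id not in intron_by_id or down_id not in intron_by_id:
            continue
        for tissue in tissues:
            bin_rows.append(
                {
                    "intron_id": it.intron_id,
                    "tissue": tissue,
                    "bin": flanking_bin(
                        it.intron_id in per_tissue_pass[tissue],
                        up_id in per_tissue_pass[tissue],
                        down_id in per_tissue_pass[tissue],
                    ),
                }
            )
    pd.DataFrame(bin_rows).to_csv(
        os.path.join(out_dir, "flanking_bins.tsv"), sep="\t", index=False
    )
    return {"calls": calls, "records": records, "bins": bin_rows}


def _minor_loci(run: PipelineRun) -> list[tuple[MinorIntronLocus, IntronRecord]]:
    tx_by_id = {
        t.transcript_id: t for g in run.genes for t in g.transcripts
    }
    loci = []
    for ci in run.classified:
        if ci.classification.call != "minor":
            continue
        it = ci.intron
        tx = tx_by_id[it.transcript_id]
        loci.append((MinorIntronLocus.from_transcript(tx, it.ordinal, it.intron_id), it))
    return loci


def altsplice_stage(
    run_dir: str, out_dir: str, run: PipelineRun
) -> dict[str, object]:
    """Per-sample AS events at every minor-intron locus + tissue-level calls."""
    samples = _load_samples(run_dir)
    loci = _minor_loci(run)
    all_events = []
    per_tissue: dict[str, dict[str, list]] = {}
    library_sizes = {s: idx.n_reads for s, idx in samples.items()}
    for sample, index in samples.items():
        tissue = _sample_tissue(sample)
        events = []
        for locus, it in loci:
            window = 2000
            cand = index.overlapping(it.chrom, it.start - window, it.end + window)
            junctions = collect_spliced_reads(cand, locus)
            events.extend(
                quantify_as_events(junctions, locus, sample, library_sizes[sample])
            )
        all_events.extend(events)
        per_tissue.setdefault(tissue, {})[sample] = events
    tissue_calls = []
    for tissue, reps in per_tissue.items():
        for call in accept_tissue_events(reps, library_sizes):
            call["tissue"] = tissue
            tissue_calls.append(call)
    os.makedirs(out_dir, exist_ok=True)
    as_events_frame(all_events).to_csv(
        os.path.join(out_dir, "as_events.tsv"), sep="\t", index=False
    )
    pd.DataFrame(
        [
            {
                "intron_id": c["intron_id"],
                "tissue": c["tissue"],
                "category": c["category"],
                "donor": c["junction_coords"][0],
                "acceptor": c["junction_coords"][1],
                "mean_msi": round(float(c["mean_msi"]), 4),
                "mean_normalized_reads": round(float(c["mean_normalized_reads"]), 4),
                "accepted": c["accepted"],
                "reasons": ",".join(c["reasons"]),
            }
            for c in tissue_calls
        ]
    ).to_csv(os.path.join(out_dir, "as_tissue_calls.tsv"), sep="\t", index=False)
    return {"events": all_events, "tissue_calls": tissue_calls, "loci": loci}


def _event_from_call(
    call: Mapping[str, object], locus: MinorIntronLocus, accepted_calls: Sequence[Mapping[str, object]]
) -> SpliceEvent | None:
    category = str(call["category"])
    coords = call["junction_coords"]
    if category in ("CAT2", "CAT3", "CAT4"):
        return SpliceEvent(category)
    if category in ("CAT5", "CAT6", "CAT7", "CAT8"):
        return SpliceEvent(category, junction=tuple(coords))
    if category == "CAT9":
        # pair intron-internal junction ends into a cryptic exon
        cd, ca = locus.minor_intron
        ends = []
        for other in accepted_calls:
            if other["intron_id"] != call["intron_id"] or other["category"] != "CAT9":
                continue
            d, a = other["junction_coords"]
            if cd < a < ca:
                ends.append(("start", a))
            if cd < d < ca:
                ends.append(("end", d))
        starts = sorted(p for kind, p in ends if kind == "start")
        stops = sorted(p for kind, p in ends if kind == "end")
        for s in starts:
            for e in stops:
                if s < e:
                    return SpliceEvent(category, cryptic_exon=(s, e))
        return None
    return None


def orf_stage(out_dir: str, run: PipelineRun, as_result: Mapping[str, object]) -> pd.DataFrame:
    """Fate prediction for accepted tissue-level AS events."""
    tissue_calls = list(as_result["tissue_calls"])
    loci = {locus.intron_id: locus for locus, _ in as_result["loci"]}
    tx_by_id = {t.transcript_id: t for g in run.genes for t in g.transcripts}
    intron_by_id = {ci.intron.intron_id: ci.intron for ci in run.classified}
    kept, excluded = exclude_multi_coordinate_events(
        [c for c in tissue_calls]
    )
    rows = []
    proteins = []
    seen: set[tuple[str, str, tuple[int, int]]] = set()
    for call in kept:
        key = (str(call["intron_id"]), str(call["category"]), tuple(call["junction_coords"]))
        if key in seen:
            continue
        seen.add(key)
        intron = intron_by_id[str(call["intron_id"])]
        locus = loci[str(call["intron_id"])]
        tx = tx_by_id[intron.transcript_id]
        if tx.cds_span is None:
            rows.append(
                {
                    "gene_id": intron.gene_id,
                    "intron_id": intron.intron_id,
                    "category": call["category"],
                    "fate": "non_coding",
                    "protein_change": "n/a",
                    "new_stop": "",
                }
            )
            continue
        event = _event_from_call(call, locus, [c for c in kept])
        if event is None:
            rows.append(
                {
                    "gene_id": intron.gene_id,
                    "intron_id": intron.intron_id,
                    "category": call["category"],
                    "fate": "unresolved_geometry",
                    "protein_change": "n/a",
                    "new_stop": "",
                }
            )
            continue
        mt = apply_as_event(tx, locus, event)
        fate = predict_fate(mt, run.genome)
        rows.append(
            {
                "gene_id": intron.gene_id,
                "intron_id": intron.intron_id,
                "category": call["category"],
                "fate": fate.fate,
                "protein_change": fate.protein_change,
                "new_stop": fate.new_stop_position if fate.new_stop_position is not None else "",
            }
        )
        if fate.fate == "protein":
            prot = variant_protein(mt, run.genome)
            if prot:
                proteins.append((f"{intron.intron_id}.{call['category']}", prot))
    frame = pd.DataFrame(rows)
    os.makedirs(out_dir, exist_ok=True)
    frame.to_csv(os.path.join(out_dir, "orf_fate.tsv"), sep="\t", index=False)
    summary = (
        frame["fate"].value_counts().rename_axis("fate").reset_index(name="n")
        if not frame.empty
        else pd.DataFrame(columns=["fate", "n"])
    )
    summary.to_csv(os.path.join(out_dir, "orf_fate_summary.tsv"), sep="\t", index=False)
    with open(os.path.join(out_dir, "orf_excluded.json"), "w") as fh:
        json.dump(excluded, fh, indent=1)
    with open(os.path.join(out_dir, "variant_proteins.fa"), "w") as fh:
        for name, prot in proteins:
            fh.write(f">{name}\n{prot}\n")
    return frame


def signature_stage(
    run_dir: str, out_dir: str, n_bootstrap: int = 500, seed: int = 0
) -> dict[str, object]:
    from .signatures import (
        ExpressionMatrix,
        all_pairwise_de,
        compute_signatures,
    )

    expr = ExpressionMatrix.from_files(
        os.path.join(run_dir, "tpm.tsv"), os.path.join(run_dir, "samples.tsv")
    )
    pairwise = all_pairwise_de(expr, n_bootstrap=n_bootstrap, seed=seed)
    results = compute_signatures(pairwise, expr.tissues)
    os.makedirs(out_dir, exist_ok=True)
    summary = {
        t: {"up": sorted(r.up_signature), "down": sorted(r.down_signature)}
        for t, r in results.items()
    }
    with open(os.path.join(out_dir, "signatures.json"), "w") as fh:
        json.dump(summary, fh, indent=1)
    return {"results": results, "summary": summary}


def run_all(
    run_dir: str, out_dir: str, mode: str = "mouse", seed: int = 0
) -> dict[str, object]:
    """Execute classify -> retention -> altsplice -> orf-fate -> signature."""
    run = classify_stage(run_dir, out_dir)
    retention = retention_stage(run_dir, out_dir, run, mode=mode)
    as_result = altsplice_stage(run_dir, out_dir, run)
    fates = orf_stage(out_dir, run, as_result)
    signatures = (
        signature_stage(run_dir, out_dir, seed=seed)
        if os.path.exists(os.path.join(run_dir, "tpm.tsv"))
        else None
    )
    return {
        "classify": run,
        "retention": retention,
        "altsplice": as_result,
        "orf": fates,
        "signatures": signatures,
    }
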