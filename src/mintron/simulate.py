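"""Seeded synthetic genomes, reads and expression matrices with ground truth.

The generator emulates the statistical structure the analysis modules
expect, so every pipeline stage is testable without downloads:

* splice-site position probability matrices with a tunable per-position
  information content (consensus sequences differ between minor and major
  matrices at the canonical positions);
* a toy genome + annotation whose genes carry one-to-three minor introns
  among major introns, with splice sites sampled from the corresponding
  PPMs, both strands represented, and a pseudogene / lincRNA fraction;
* junction/boundary reads drawn binomially around planted per-intron
  retention MSIs and per-category AS MSIs, with per-sample library sizes;
* replicate TPM matrices with planted tissue-enriched signature genes.

Everything is driven by one integer seed through ``numpy.random.default_rng``
and each output is accompanied by a truth table.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneModel, GenomeSequence, TranscriptModel
from .pwm import BASES, Ppm
from .reads import AlignedRead, write_reads_tsv

_REVCOMP = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_REVCOMP)[::-1]


# ---------------------------------------------------------------------------
# PPM simulation
# ---------------------------------------------------------------------------

#: consensus sequences of the simulated matrices; canonical positions
#: (terminal dinucleotides, branch adenosine) are held near-certain
_PPM_CONSENSUS: dict[str, tuple[str, tuple[int, ...]]] = {
    # 5'SS: 3 exonic + 9 intronic (-3..+9); fixed: intron positions +1,+2
    "minor_5ss_ATAC": ("AAGATATCCTTT", (3, 4)),
    "minor_5ss_GTAG": ("AAGGTATCCTTT", (3, 4)),
    "major_5ss_GTAG": ("CAGGTAAGTATT", (3, 4)),
    "major_5ss_GCAG": ("CAGGCAAGTATT", (3, 4)),
    # 3'SS: 13 intronic + 1 exonic (-13..+1); fixed: intron positions -2,-1
    "minor_3ss_ATAC": ("TTTTCCTTTTCACG", (11, 12)),
    "minor_3ss_GTAG": ("TTTTCCTTTTCAGG", (11, 12)),
    # branch-point windows, 12 nt, adenosine at the 9th / 10th position
    "bps_A9": ("TTTCCTTAACTC", (8,)),
    "bps_A10": ("TTTTCCTTAACT", (9,)),
    # used only to embed realistic major acceptors in simulated sequence
    "major_3ss_GTAG": ("TCTCTCTCTCCAGG", (11, 12)),
}


def _consensus_prob(information_content: float) -> float:
    """Consensus-base probability giving the requested bits/position."""
    from scipy.optimize import brentq

    if not 0 < information_content <= 2:
        raise ValueError("information_content must be in (0, 2]")
    if information_content == 2:
        return 1.0

    def ic(p: float) -> float:
        q = (1 - p) / 3
        h = -(p * np.log2(p) + (3 * q * np.log2(q) if q > 0 else 0.0))
        return 2 - h - information_content

    return float(brentq(ic, 0.2501, 1 - 1e-9))


def simulate_ppms(
    seed: int = 0, information_content: float = 1.8
) -> dict[str, Ppm]:
    """The full named PPM set at a given per-position information content."""
    p = _consensus_prob(information_content)
    ppms: dict[str, Ppm] = {}
    for name, (consensus, fixed) in _PPM_CONSENSUS.items():
        width = len(consensus)
        matrix = np.full((4, width), 0.0)
        for j, base in enumerate(consensus):
            pj = max(p, 0.97) if j in fixed else p
            for i, b in enumerate(BASES):
                matrix[i, j] = pj if b == base else (1 - pj) / 3
        ppms[name] = Ppm(name=name, matrix=matrix)
    return ppms


# ---------------------------------------------------------------------------
# Genome + annotation simulation
# ---------------------------------------------------------------------------


@dataclass
class SimConfig:
    seed: int = 0
    # genome / annotation
    n_genes: int = 50
    mig_fraction: float = 0.2
    exons_per_gene: tuple[int, int] = (4, 8)
    minor_per_mig_probs: tuple[float, float, float] = (0.90, 0.08, 0.02)
    pseudogene_fraction: float = 0.04
    lincrna_fraction: float = 0.04
    exon_length_meanlog: float = float(np.log(120))
    exon_length_sdlog: float = 0.3
    minor_intron_length_meanlog: float = float(np.log(150))
    major_intron_length_meanlog: float = float(np.log(400))
    intron_length_sdlog: float = 0.4
    min_intron_length: int = 80
    min_exon_length: int = 40
    atac_fraction: float = 0.25  # AT-AC vs GT-AG minor introns
    information_content: float = 1.8
    # reads
    tissues: tuple[str, ...] = ("cortex", "heart", "liver", "testis")
    replicates: int = 3
    junction_depth: int = 100  # junction-spanning read pairs per intron
    read_length: int = 100
    retained_fraction: float = 0.3  # minor introns with planted retention
    retention_msi_values: tuple[float, ...] = (5.0, 20.0, 50.0, 80.0)
    as_event_fraction: float = 0.3  # minor introns with a planted AS event
    as_locus_depth: int = 60
    as_msi_values: tuple[float, ...] = (25.0, 40.0)
    # expression
    tpm_meanlog: float = float(np.log(20))
    tpm_sdlog: float = 1.0
    silent_fraction: float = 0.1
    n_signature_genes_per_tissue: int = 2
    signature_fold: float = 8.0
    noise_sdlog2: float = 0.3


@dataclass
class SimulatedGenome:
    genome: GenomeSequence
    genes: list[GeneModel]
    intron_truth: pd.DataFrame  # one row per intron with planted class
    fasta: dict[str, str]
    gtf_lines: list[str]


def _sample_window(rng: np.random.Generator, ppm: Ppm) -> str:
    cols = ppm.matrix.T
    return "".join(
        BASES[rng.choice(4, p=col / col.sum())] for col in cols
    )


def _lognormal_int(
    rng: np.random.Generator, meanlog: float, sdlog: float, minimum: int
) -> int:
    return max(minimum, int(round(float(rng.lognormal(meanlog, sdlog)))))


def simulate_genome_annotation(
    cfg: SimConfig, ppms: Mapping[str, Ppm] | None = None
) -> SimulatedGenome:
    """A toy genome and annotation with planted minor/major introns."""
    rng = np.random.default_rng(cfg.seed)
    if ppms is None:
        ppms = simulate_ppms(cfg.seed, cfg.information_content)
    chrom = "chrS1"
    chrom_parts: list[str] = []
    cursor = 0
    genes: list[GeneModel] = []
    truth_rows: list[dict[str, object]] = []
    gtf: list[str] = []

    n_mig = max(1, int(round(cfg.n_genes * cfg.mig_fraction)))
    mig_flags = np.zeros(cfg.n_genes, dtype=bool)
    mig_flags[rng.choice(cfg.n_genes, size=n_mig, replace=False)] = True

    for g in range(cfg.n_genes):
        gene_id = f"SIMG{g + 1:04d}"
        tx_id = f"SIMT{g + 1:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        r = rng.random()
        if r < cfg.pseudogene_fraction:
            gene_type = "pseudogene"
        elif r < cfg.pseudogene_fraction + cfg.lincrna_fraction:
            gene_type = "lincRNA"
        else:
            gene_type = "protein_coding"
        n_exons = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
        n_introns = n_exons - 1

        minor_ordinals: set[int] = set()
        if mig_flags[g] and n_introns >= 1:
            n_minor = min(
                n_introns, 1 + int(rng.choice(3, p=cfg.minor_per_mig_probs))
            )
            minor_ordinals = set(
                int(o) + 1
                for o in rng.choice(n_introns, size=n_minor, replace=False)
            )

        exon_lens = [
            _lognormal_int(rng, cfg.exon_length_meanlog, cfg.exon_length_sdlog, cfg.min_exon_length)
            for _ in range(n_exons)
        ]
        intron_meta: list[dict[str, object]] = []
        intron_lens: list[int] = []
        for ordinal in range(1, n_introns + 1):
            is_minor = ordinal in minor_ordinals
            meanlog = (
                cfg.minor_intron_length_meanlog
                if is_minor
                else cfg.major_intron_length_meanlog
            )
            length = _lognormal_int(
                rng, meanlog, cfg.intron_length_sdlog, cfg.min_intron_length
            )
            intron_lens.append(length)
            if is_minor:
                subtype = "AT-AC" if rng.random() < cfg.atac_fraction else "GT-AG"
            else:
                subtype = "GC-AG" if rng.random() < 0.02 else "GT-AG"
            intron_meta.append(
                {"ordinal": ordinal, "minor": is_minor, "subtype": subtype, "length": length}
            )

        # assemble the transcript-oriented pre-mRNA with planted windows
        total_len = sum(exon_lens) + sum(intron_lens)
        seq = list("".join(rng.choice(list(BASES), size=total_len)))
        # transcript-oriented segment boundaries
        bounds: list[tuple[str, int, int]] = []  # (kind, start, end) tx-oriented
        pos = 0
        for i in range(n_exons):
            bounds.append(("exon", pos, pos + exon_lens[i]))
            pos += exon_lens[i]
            if i < n_introns:
                bounds.append(("intron", pos, pos + intron_lens[i]))
                pos += intron_lens[i]

        intron_bounds = [b for b in bounds if b[0] == "intron"]
        for meta, (_, istart, iend) in zip(intron_meta, intron_bounds):
            if meta["minor"]:
                tag = "ATAC" if meta["subtype"] == "AT-AC" else "GTAG"
                donor = _sample_window(rng, ppms[f"minor_5ss_{tag}"])
                acceptor = _sample_window(rng, ppms[f"minor_3ss_{tag}"])
                variant = "bps_A9" if rng.random() < 0.5 else "bps_A10"
                bps = _sample_window(rng, ppms[variant])
                # branch window occupies intronic -25..-14 (upstream of the
                # acceptor's 13 intronic nt)
                seq[iend - 25 : iend - 13] = list(bps)
            else:
                tag = "GCAG" if meta["subtype"] == "GC-AG" else "GTAG"
                donor = _sample_window(rng, ppms[f"major_5ss_{tag}"])
                acceptor = _sample_window(rng, ppms["major_3ss_GTAG"])
            # donor window: 3 exonic + 9 intronic
            seq[istart - 3 : istart + 9] = list(donor)
            # acceptor window: 13 intronic + 1 exonic
            seq[iend - 13 : iend + 1] = list(acceptor)
            meta["terminal"] = (seq[istart] + seq[istart + 1], seq[iend - 2] + seq[iend - 1])

        tx_seq = "".join(seq)
        gene_start = cursor + 100  # spacer between genes
        if strand == "+":
            placed = tx_seq
        else:
            placed = _revcomp(tx_seq)
        chrom_parts.append("N" * (gene_start - cursor) + placed)
        cursor = gene_start + total_len

        # genomic exon coordinates
        exon_coords: list[tuple[int, int]] = []
        for kind, s, e in bounds:
            if kind != "exon":
                continue
            if strand == "+":
                exon_coords.append((gene_start + s, gene_start + e))
            else:
                exon_coords.append(
                    (gene_start + total_len - e, gene_start + total_len - s)
                )
        exon_coords.sort()

        tx = TranscriptModel(tx_id, gene_id, chrom, strand)
        tx.exons = exon_coords
        if gene_type == "protein_coding":
            span = (exon_coords[0][0] + 3, exon_coords[-1][1] - 3)
            tx.cds_span = span
        tx.tags.add("ensembl_havana")
        tx.finalize()
        gene = GeneModel(gene_id, gene_type, chrom, strand, [tx])
        genes.append(gene)

        # truth rows with genomic intron coordinates
        n_min = len(minor_ordinals)
        for meta, (_, istart, iend) in zip(intron_meta, intron_bounds):
            if strand == "+":
                gs, ge = gene_start + istart, gene_start + iend
            else:
                gs, ge = gene_start + total_len - iend, gene_start + total_len - istart
            ordinal = int(meta["ordinal"])
            if meta["minor"]:
                if n_introns == 1:
                    context = "only_intron"
                elif ordinal in (1, n_introns):
                    context = "first_or_last"
                elif (ordinal - 1) in minor_ordinals or (ordinal + 1) in minor_ordinals:
                    context = "adjacent_to_minor"
                else:
                    context = "flanked_by_two_major"
            else:
                context = ""
            truth_rows.append(
                {
                    "intron_id": f"{tx_id}.i{ordinal}",
                    "gene_id": gene_id,
                    "transcript_id": tx_id,
                    "chrom": chrom,
                    "start": gs,
                    "end": ge,
                    "strand": strand,
                    "ordinal": ordinal,
                    "n_introns": n_introns,
                    "minor": bool(meta["minor"]),
                    "subtype": meta["subtype"],
                    "dinucleotides": "-".join(meta["terminal"]),
                    "context": context,
                    "length": int(meta["length"]),
                    "gene_type": gene_type,
                    "n_minor_in_gene": n_min,
                }
            )

        # GTF lines (1-based inclusive)
        biotype = {"pseudogene": "processed_pseudogene", "lincRNA": "lincRNA"}.get(
            gene_type, "protein_coding"
        )
        attrs = f'gene_id "{gene_id}"; gene_biotype "{biotype}";'
        gspan = (exon_coords[0][0] + 1, exon_coords[-1][1])
        gtf.append(
            f"{chrom}\tsim\tgene\t{gspan[0]}\t{gspan[1]}\t.\t{strand}\t.\t{attrs}"
        )
        tattrs = f'{attrs} transcript_id "{tx_id}"; tag "basic";'
        gtf.append(
            f"{chrom}\tsim\ttranscript\t{gspan[0]}\t{gspan[1]}\t.\t{strand}\t.\t{tattrs}"
        )
        for s, e in exon_coords:
            gtf.append(
                f"{chrom}\tsim\texon\t{s + 1}\t{e}\t.\t{strand}\t.\t{tattrs}"
            )
        if tx.cds_span is not None:
            cs, ce = tx.cds_span
            for s, e in exon_coords:
                os_, oe = max(s, cs), min(e, ce)
                if os_ < oe:
                    gtf.append(
                        f"{chrom}\tsim\tCDS\t{os_ + 1}\t{oe}\t.\t{strand}\t0\t{tattrs}"
                    )

    fasta = {chrom: "".join(chrom_parts) + "N" * 50}
    genome = GenomeSequence(fasta)
    return SimulatedGenome(
        genome=genome,
        genes=genes,
        intron_truth=pd.DataFrame(truth_rows),
        fasta=fasta,
        gtf_lines=gtf,
    )


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------


@dataclass
class SimulatedReads:
    samples: dict[str, list[AlignedRead]]  # sample_id -> reads
    library_sizes: dict[str, int]
    retention_truth: pd.DataFrame  # per intron x sample planted MSI + counts
    as_truth: pd.DataFrame  # per planted AS event x sample


def _plan_retention(
    sim: SimulatedGenome, cfg: SimConfig, rng: np.random.Generator
) -> dict[str, float]:
    """Assign a planted retention MSI to a fraction of minor introns."""
    minors = sim.intron_truth[sim.intron_truth["minor"]]
    ids = list(minors["intron_id"])
    rng.shuffle(ids)
    n_ret = int(round(len(ids) * cfg.retained_fraction))
    plan: dict[str, float] = {i: 0.0 for i in ids}
    for k, intron_id in enumerate(ids[:n_ret]):
        plan[intron_id] = float(
            cfg.retention_msi_values[k % len(cfg.retention_msi_values)]
        )
    return plan


def _plan_as_events(
    sim: SimulatedGenome, cfg: SimConfig, rng: np.random.Generator
) -> list[dict[str, object]]:
    """Plant AS events (category + geometry offsets) on minor introns."""
    minors = sim.intron_truth[
        sim.intron_truth["minor"]
        & (sim.intron_truth["ordinal"] > 1)
        & (sim.intron_truth["ordinal"] < sim.intron_truth["n_introns"])
    ]
    ids = list(minors["intron_id"])
    rng.shuffle(ids)
    n_ev = int(round(len(ids) * cfg.as_event_fraction))
    categories = ["CAT2", "CAT3", "CAT4", "CAT5", "CAT6", "CAT7", "CAT8", "CAT9"]
    events = []
    for k, intron_id in enumerate(ids[:n_ev]):
        events.append(
            {
                "intron_id": intron_id,
                "category": categories[k % len(categories)],
                "msi": float(cfg.as_msi_values[k % len(cfg.as_msi_values)]),
            }
        )
    return events


def _locus_for(sim: SimulatedGenome, intron_id: str):
    from .altsplice import MinorIntronLocus

    row = sim.intron_truth.set_index("intron_id").loc[intron_id]
    tx = next(
        t
        for g in sim.genes
        for t in g.transcripts
        if t.transcript_id == row["transcript_id"]
    )
    return MinorIntronLocus.from_transcript(tx, int(row["ordinal"]), intron_id), row


def event_junction(
    locus, category: str, offset: int = 30
) -> tuple[int, int]:
    """Oriented (donor, acceptor) junction coordinates for a planted event."""
    u1, m, d1 = locus.upstream_exon, locus.minor_intron, locus.downstream_exon
    u2, d2 = locus.upstream_neighbor, locus.downstream_neighbor
    cd, ca = m
    if category == "CAT2":
        if u2 is None or d2 is None:
            raise ValueError("CAT2 needs both neighbor exons")
        return (u2[1], d2[0])
    if category == "CAT3":
        if u2 is None:
            raise ValueError("CAT3 needs the upstream neighbor exon")
        return (u2[1], ca)
    if category == "CAT4":
        if d2 is None:
            raise ValueError("CAT4 needs the downstream neighbor exon")
        return (cd, d2[0])
    if category == "CAT5":  # cryptic donor inside the upstream exon
        return (cd - min(offset, (u1[1] - u1[0]) // 2), ca)
    if category == "CAT6":  # cryptic donor inside the minor intron
        return (cd + min(offset, (m[1] - m[0]) // 3), ca)
    if category == "CAT7":  # cryptic acceptor inside the downstream exon
        return (cd, ca + min(offset, (d1[1] - d1[0]) // 2))
    if category == "CAT8":  # cryptic acceptor inside the minor intron
        return (cd, ca - min(offset, (m[1] - m[0]) // 3))
    if category == "CAT9":  # junction onto a cryptic exon inside the intron
        mid = (m[0] + m[1]) // 2
        return (cd, mid)
    raise ValueError(f"no junction geometry for {category}")


def _junction_read(
    read_id: str,
    chrom: str,
    strand: str,
    donor: int,
    acceptor: int,
    overhang: int,
) -> AlignedRead:
    """A spliced read with `overhang` aligned nt on each side of the gap."""
    if strand == "-":
        gs, ge = -acceptor, -donor
    else:
        gs, ge = donor, acceptor
    return AlignedRead(
        read_id, chrom, [(gs - overhang, gs), (ge, ge + overhang)], True
    )


def simulate_reads(
    sim: SimulatedGenome, cfg: SimConfig, seed: int | None = None
) -> SimulatedReads:
    """Draw junction/boundary reads around the planted MSIs for every sample.

    Retention at a planted MSI of p%: spliced reads s ~ Binomial(N, 1-p) and
    per-boundary unspliced reads b5, b3 ~ Binomial(N, p) at junction depth N,
    plus coverage-fill reads strictly inside the intron (so they never count
    as boundary evidence).  An intron carrying a planted AS event instead
    splits its N junction reads binomially between the event junction and the
    canonical junction, so the observed event MSI is Binomial(N, msi/100)/N;
    such introns are not also planted as retained, keeping the two recovery
    experiments separable.
    """
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    retention_plan = _plan_retention(sim, cfg, rng)
    as_plan = _plan_as_events(sim, cfg, rng)
    as_by_intron: dict[str, dict[str, object]] = {
        str(ev["intron_id"]): ev for ev in as_plan
    }
    for intron_id in as_by_intron:
        retention_plan[intron_id] = 0.0
    loci = {
        intron_id: _locus_for(sim, intron_id)[0] for intron_id in as_by_intron
    }

    half = cfg.read_length // 2
    samples: dict[str, list[AlignedRead]] = {}
    library_sizes: dict[str, int] = {}
    ret_rows: list[dict[str, object]] = []
    as_rows: list[dict[str, object]] = []

    truth = sim.intron_truth
    for tissue in cfg.tissues:
        for rep in range(1, cfg.replicates + 1):
            sample = f"{tissue}_r{rep}"
            reads: list[AlignedRead] = []
            rid = 0

            def _emit(blocks: list[tuple[int, int]], chrom: str) -> None:
                nonlocal rid
                rid += 1
                reads.append(AlignedRead(f"{sample}.r{rid}", chrom, blocks, True))

            for row in truth.itertuples():
                intron_id = row.intron_id
                gs, ge = int(row.start), int(row.end)
                N = cfg.junction_depth
                event = as_by_intron.get(intron_id)
                if event is not None:
                    category = str(event["category"])
                    phi = float(event["msi"]) / 100.0
                    k = int(rng.binomial(N, phi))
                    s, b5, b3 = N - k, 0, 0
                    donor, acceptor = event_junction(loci[intron_id], category)
                    for _ in range(k):
                        _emit(
                            _junction_read(
                                "", row.chrom, row.strand, donor, acceptor, half
                            ).blocks,
                            row.chrom,
                        )
                    as_rows.append(
                        {
                            "intron_id": intron_id,
                            "sample_id": sample,
                            "tissue": tissue,
                            "category": category,
                            "planted_msi": float(event["msi"]),
                            "event_reads": k,
                            "locus_depth": N,
                        }
                    )
                else:
                    msi = retention_plan.get(intron_id, 0.0)
                    p = msi / 100.0
                    s = int(rng.binomial(N, 1 - p))
                    b5 = int(rng.binomial(N, p)) if p > 0 else 0
                    b3 = int(rng.binomial(N, p)) if p > 0 else 0
                # spliced reads exactly across the intron
                for _ in range(s):
                    _emit([(gs - half, gs), (ge, ge + half)], row.chrom)
                # boundary reads centered on each junction, in transcript
                # orientation (the 5' junction is genomic-left on '+')
                for _ in range(b5):
                    j = gs if row.strand == "+" else ge
                    _emit([(j - half, j + half)], row.chrom)
                for _ in range(b3):
                    j = ge if row.strand == "+" else gs
                    _emit([(j - half, j + half)], row.chrom)
                # coverage fill strictly inside the intron
                if b5 + b3 > 0:
                    pos = gs
                    while pos < ge:
                        _emit([(pos, min(ge, pos + cfg.read_length))], row.chrom)
                        pos += half
                if bool(row.minor) and event is None:
                    ret_rows.append(
                        {
                            "intron_id": intron_id,
                            "sample_id": sample,
                            "tissue": tissue,
                            "planted_msi": retention_plan.get(intron_id, 0.0),
                            "b5": b5,
                            "b3": b3,
                            "spliced": s,
                        }
                    )
            samples[sample] = reads
            library_sizes[sample] = len(reads)
    return SimulatedReads(
        samples=samples,
        library_sizes=library_sizes,
        retention_truth=pd.DataFrame(ret_rows),
        as_truth=pd.DataFrame(as_rows),
    )


# ---------------------------------------------------------------------------
# Expression simulation
# ---------------------------------------------------------------------------


@dataclass
class SimulatedExpression:
    tpm: pd.DataFrame
    sample_tissue: dict[str, str]
    truth: pd.DataFrame  # gene x tissue planted mean + signature membership


def simulate_expression(
    cfg: SimConfig, gene_ids: Sequence[str] | None = None, seed: int | None = None
) -> SimulatedExpression:
    """Replicate TPM matrices with planted tissue-enriched signature genes."""
    rng = np.random.default_rng(cfg.seed + 2 if seed is None else seed)
    if cfg.replicates < 2:
        raise ValueError("DE-ready designs need >=2 replicates")
    if gene_ids is None:
        gene_ids = [f"SIMG{i + 1:04d}" for i in range(cfg.n_genes)]
    genes = list(gene_ids)
    n = len(genes)
    base = rng.lognormal(cfg.tpm_meanlog, cfg.tpm_sdlog, size=n)
    silent = rng.random(n) < cfg.silent_fraction
    base[silent] = rng.uniform(0.05, 0.5, size=int(silent.sum()))

    # plant signature genes: distinct non-silent genes per tissue
    eligible = [i for i in range(n) if not silent[i]]
    rng.shuffle(eligible)
    signature: dict[str, list[int]] = {}
    k = 0
    for tissue in cfg.tissues:
        picked = eligible[k : k + cfg.n_signature_genes_per_tissue]
        signature[tissue] = picked
        k += len(picked)

    sample_tissue: dict[str, str] = {}
    columns: dict[str, np.ndarray] = {}
    sdlog = cfg.noise_sdlog2 * float(np.log(2))
    for tissue in cfg.tissues:
        means = base.copy()
        means[signature[tissue]] *= cfg.signature_fold
        for rep in range(1, cfg.replicates + 1):
            sample = f"{tissue}_r{rep}"
            sample_tissue[sample] = tissue
            columns[sample] = means * rng.lognormal(0.0, sdlog, size=n)
    tpm = pd.DataFrame(columns, index=genes)

    truth_rows = []
    for i, gene in enumerate(genes):
        for tissue in cfg.tissues:
            mean = base[i] * (cfg.signature_fold if i in signature[tissue] else 1.0)
            truth_rows.append(
                {
                    "gene_id": gene,
                    "tissue": tissue,
                    "planted_mean_tpm": float(mean),
                    "silent": bool(silent[i]),
                    "signature_tissue": tissue if i in signature[tissue] else "",
                }
            )
    return SimulatedExpression(tpm, sample_tissue, pd.DataFrame(truth_rows))


# ---------------------------------------------------------------------------
# Run-directory output
# ---------------------------------------------------------------------------


def write_sam(
    reads: Sequence[AlignedRead], chrom_lengths: Mapping[str, int], path: str
) -> None:
    """Write reads as a valid SAM file with M/N CIGARs."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for chrom, length in chrom_lengths.items():
            fh.write(f"@SQ\tSN:{chrom}\tLN:{length}\n")
        for r in reads:
            cigar = []
            for k, (s, e) in enumerate(r.blocks):
                if k > 0:
                    cigar.append(f"{s - r.blocks[k - 1][1]}N")
                cigar.append(f"{e - s}M")
            seq_len = sum(e - s for s, e in r.blocks)
            mapq = 60 if r.unique else 0
            nh = 1 if r.unique else 2
            fh.write(
                f"{r.read_id}\t0\t{r.chrom}\t{r.start + 1}\t{mapq}\t"
                f"{''.join(cigar)}\t*\t0\t0\t{'A' * seq_len}\t*\tNH:i:{nh}\n"
            )


def write_run(
    run_dir: str,
    cfg: SimConfig,
    sim: SimulatedGenome,
    reads: SimulatedReads | None = None,
    expression: SimulatedExpression | None = None,
    sam: bool = False,
) -> None:
    """Write all simulated artifacts + truth tables under one directory."""
    os.makedirs(run_dir, exist_ok=True)
    with open(os.path.join(run_dir, "genome.fa"), "w") as fh:
        for chrom, seq in sim.fasta.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    with open(os.path.join(run_dir, "annotation.gtf"), "w") as fh:
        fh.write("\n".join(sim.gtf_lines) + "\n")
    from .pwm import write_ppms

    write_ppms(simulate_ppms(cfg.seed, cfg.information_content), os.path.join(run_dir, "ppms.txt"))
    sim.intron_truth.to_csv(
        os.path.join(run_dir, "truth_introns.tsv"), sep="\t", index=False
    )
    with open(os.path.join(run_dir, "config.json"), "w") as fh:
        json.dump(asdict(cfg), fh, indent=1, default=list)
    if reads is not None:
        reads_dir = os.path.join(run_dir, "reads")
        os.makedirs(reads_dir, exist_ok=True)
        chrom_lengths = {c: len(s) for c, s in sim.fasta.items()}
        for sample, rs in reads.samples.items():
            write_reads_tsv(rs, os.path.join(reads_dir, f"{sample}.tsv"))
            if sam:
                write_sam(rs, chrom_lengths, os.path.join(reads_dir, f"{sample}.sam"))
        pd.DataFrame(
            [{"sample": s, "library_unique_reads": n} for s, n in reads.library_sizes.items()]
        ).to_csv(os.path.join(run_dir, "library_sizes.tsv"), sep="\t", index=False)
        reads.retention_truth.to_csv(
            os.path.join(run_dir, "truth_retention.tsv"), sep="\t", index=False
        )
        reads.as_truth.to_csv(
            os.path.join(run_dir, "truth_as_events.tsv"), sep="\t", index=False
        )
    if expression is not None:
        expression.tpm.to_csv(os.path.join(run_dir, "tpm.tsv"), sep="\t")
        pd.DataFrame(
            [
                {"sample": s, "tissue": t}
                for s, t in expression.sample_tissue.items()
            ]
        ).to_csv(os.path.join(run_dir, "samples.tsv"), sep="\t", index=False)
        expression.truth.to_csv(
            os.path.join(run_dir, "truth_expression.tsv"), sep="\t", index=False
        )
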