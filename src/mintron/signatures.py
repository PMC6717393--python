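"""Tissue expression signatures by pairwise-DE intersection.

A gene belongs to a tissue's UpSignature when it is called upregulated
(fold-change > 2, p < 0.01) in that tissue versus *every* other tissue;
DownSignatures are the mirror image.  With T tissues this takes C(T,2)
pairwise comparisons (55 for the paper-scale 11 tissues).

The default differential-expression engine is a seeded replicate bootstrap:
replicates of each tissue are resampled with replacement B times, the
fold-change is the ratio of replicate-mean TPMs (pseudocount 0.1), and the
p-value is the two-sided bootstrap tail probability that the log2
fold-change crosses zero (with an add-one correction so p >= 1/(B+1)).
Externally computed DE tables can be injected instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

FC_THRESHOLD = 2.0  # strict: fold-change must exceed 2 (or fall below 1/2)
P_THRESHOLD = 0.01
TPM_PSEUDOCOUNT = 0.1
EXPRESSION_TPM_THRESHOLD = 1.0
DEFAULT_BOOTSTRAP = 1000


@dataclass
class ExpressionMatrix:
    """TPM matrix (genes x samples) with a sample -> tissue design."""

    tpm: pd.DataFrame
    sample_tissue: dict[str, str]

    def __post_init__(self) -> None:
        if (self.tpm.values < 0).any():
            raise ValueError("TPM values must be non-negative")
        missing = set(self.tpm.columns) - set(self.sample_tissue)
        if missing:
            raise ValueError(f"samples without tissue assignment: {sorted(missing)}")

    @property
    def tissues(self) -> list[str]:
        seen: list[str] = []
        for col in self.tpm.columns:
            t = self.sample_tissue[col]
            if t not in seen:
                seen.append(t)
        return seen

    def samples_of(self, tissue: str) -> list[str]:
        return [c for c in self.tpm.columns if self.sample_tissue[c] == tissue]

    def tissue_matrix(self, tissue: str) -> pd.DataFrame:
        samples = self.samples_of(tissue)
        if not samples:
            raise ValueError(f"tissue {tissue!r} has no samples")
        return self.tpm[samples]

    @classmethod
    def from_files(cls, tpm_path: str, sample_sheet_path: str) -> "ExpressionMatrix":
        """Load a genes-x-samples TPM TSV and a sample/tissue sheet TSV."""
        tpm = pd.read_csv(tpm_path, sep="\t", index_col=0)
        sheet = pd.read_csv(sample_sheet_path, sep="\t")
        if not {"sample", "tissue"} <= set(sheet.columns):
            raise ValueError("sample sheet needs 'sample' and 'tissue' columns")
        return cls(tpm, dict(zip(sheet["sample"].astype(str), sheet["tissue"].astype(str))))


@dataclass
class DeCall:
    gene_id: str
    tissue_a: str
    tissue_b: str
    fold_change: float  # a over b, pseudocounted
    p_value: float
    direction: str  # up_in_a / down_in_a / nonDE


@dataclass
class SignatureResult:
    tissue: str
    up_signature: set[str]
    down_signature: set[str]
    audit: pd.DataFrame = field(default_factory=pd.DataFrame)


def expressed_mig_overlap(
    expr: ExpressionMatrix,
    mig_list: Sequence[str],
    threshold: float = EXPRESSION_TPM_THRESHOLD,
) -> dict[str, object]:
    """Per-tissue expressed-gene sets (mean TPM over replicates > threshold).

    Genes absent from the matrix count as unexpressed.  Returns per-tissue
    sets, the all-tissue intersection and pairwise overlap counts.
    """
    present = [g for g in mig_list if g in expr.tpm.index]
    per_tissue: dict[str, set[str]] = {}
    for tissue in expr.tissues:
        means = expr.tissue_matrix(tissue).loc[present].mean(axis=1)
        per_tissue[tissue] = set(means.index[means > threshold])
    tissues = list(per_tissue)
    intersection = set.intersection(*per_tissue.values()) if per_tissue else set()
    pairwise = {
        (a, b): len(per_tissue[a] & per_tissue[b]) for a, b in combinations(tissues, 2)
    }
    return {
        "per_tissue": per_tissue,
        "intersection": intersection,
        "pairwise_overlap": pairwise,
        "missing_genes": sorted(set(mig_list) - set(present)),
    }


def bootstrap_de(
    expr: ExpressionMatrix,
    tissue_a: str,
    tissue_b: str,
    n_bootstrap: int = DEFAULT_BOOTSTRAP,
    seed: int = 0,
) -> list[DeCall]:
    """Replicate-bootstrap differential expression between two tissues."""
    mat_a = expr.tissue_matrix(tissue_a).to_numpy()
    mat_b = expr.tissue_matrix(tissue_b).to_numpy()
    if mat_a.shape[1] < 2 or mat_b.shape[1] < 2:
        raise ValueError(
            "bootstrap DE needs >=2 replicates per tissue; "
            "inject an external DE table for single-replicate designs"
        )
    rng = np.random.default_rng(seed)
    genes = list(expr.tpm.index)
    mean_a = mat_a.mean(axis=1) + TPM_PSEUDOCOUNT
    mean_b = mat_b.mean(axis=1) + TPM_PSEUDOCOUNT
    fc = mean_a / mean_b

    idx_a = rng.integers(0, mat_a.shape[1], size=(n_bootstrap, mat_a.shape[1]))
    idx_b = rng.integers(0, mat_b.shape[1], size=(n_bootstrap, mat_b.shape[1]))
    boot_a = mat_a[:, idx_a].mean(axis=2) + TPM_PSEUDOCOUNT  # genes x B
    boot_b = mat_b[:, idx_b].mean(axis=2) + TPM_PSEUDOCOUNT
    log_fc = np.log2(boot_a / boot_b)
    n_le = (log_fc <= 0).sum(axis=1)
    n_ge = (log_fc >= 0).sum(axis=1)
    p = 2.0 * (np.minimum(n_le, n_ge) + 1) / (n_bootstrap + 1)
    p = np.minimum(p, 1.0)

    calls = []
    for g, f, pv in zip(genes, fc, p):
        if f > FC_THRESHOLD and pv < P_THRESHOLD:
            direction = "up_in_a"
        elif f < 1.0 / FC_THRESHOLD and pv < P_THRESHOLD:
            direction = "down_in_a"
        else:
            direction = "nonDE"
        calls.append(DeCall(str(g), tissue_a, tissue_b, float(f), float(pv), direction))
    return calls


def de_calls_from_table(
    table: pd.DataFrame, tissue_a: str, tissue_b: str
) -> list[DeCall]:
    """Adapt an external DE table (gene_id, fold_change, p_value columns)."""
    calls = []
    for row in table.itertuples():
        fc, p = float(row.fold_change), float(row.p_value)
        if fc > FC_THRESHOLD and p < P_THRESHOLD:
            direction = "up_in_a"
        elif fc < 1.0 / FC_THRESHOLD and p < P_THRESHOLD:
            direction = "down_in_a"
        else:
            direction = "nonDE"
        calls.append(DeCall(str(row.gene_id), tissue_a, tissue_b, fc, p, direction))
    return calls


def all_pairwise_de(
    expr: ExpressionMatrix,
    n_bootstrap: int = DEFAULT_BOOTSTRAP,
    seed: int = 0,
    engine: Callable[..., list[DeCall]] | None = None,
) -> dict[tuple[str, str], list[DeCall]]:
    """All C(T,2) pairwise comparisons with a per-pair derived seed."""
    tissues = expr.tissues
    out: dict[tuple[str, str], list[DeCall]] = {}
    for k, (a, b) in enumerate(combinations(tissues, 2)):
        if engine is not None:
            out[(a, b)] = engine(expr, a, b)
        else:
            out[(a, b)] = bootstrap_de(
                expr, a, b, n_bootstrap=n_bootstrap, seed=(seed * 100003 + k) % (2**31)
            )
    return out


def compute_signatures(
    pairwise: Mapping[tuple[str, str], list[DeCall]], tissues: Sequence[str]
) -> dict[str, SignatureResult]:
    """Intersect pairwise DE directions into per-tissue Up/DownSignatures."""
    expected = set(combinations(tissues, 2))
    have = set(pairwise)
    missing = expected - have - {(b, a) for a, b in have}
    if missing:
        raise ValueError(f"missing pairwise comparisons: {sorted(missing)}")

    # direction[gene][ (tissue, other) ] -> up/down/nonDE from tissue's view
    direction: dict[str, dict[tuple[str, str], str]] = {}
    for (a, b), calls in pairwise.items():
        for call in calls:
            d = direction.setdefault(call.gene_id, {})
            d[(a, b)] = call.direction
            flipped = {"up_in_a": "down_in_a", "down_in_a": "up_in_a"}.get(
                call.direction, "nonDE"
            )
            d[(b, a)] = flipped

    results: dict[str, SignatureResult] = {}
    for tissue in tissues:
        others = [t for t in tissues if t != tissue]
        up, down = set(), set()
        for gene, dirs in direction.items():
            views = [dirs.get((tissue, other), "nonDE") for other in others]
            if all(v == "up_in_a" for v in views):
                up.add(gene)
            elif all(v == "down_in_a" for v in views):
                down.add(gene)
        audit = pd.DataFrame(
            {
                other: {
                    gene: direction.get(gene, {}).get((tissue, other), "nonDE")
                    for gene in sorted(up | down)
                }
                for other in others
            }
        )
        results[tissue] = SignatureResult(tissue, up, down, audit)

    # a gene cannot be up against all others in two different tissues
    for ta, tb in combinations(tissues, 2):
        overlap = results[ta].up_signature & results[tb].up_signature
        if overlap:
            raise AssertionError(
                f"UpSignatures of {ta} and {tb} overlap: {sorted(overlap)}"
            )
    return results


def n_pairwise_comparisons(n_tissues: int) -> int:
    """Number of pairwise tissue comparisons the signature analysis needs."""
    return n_tissues * (n_tissues - 1) // 2
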