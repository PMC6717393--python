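"""Group-comparison statistics used by the retention and AS analyses.

* K-group length/retention-class comparisons: Kruskal-Wallis rank-sum test
  followed by a Dunn post-hoc with multiplicity control;
* per-intron across-tissue and minor-vs-flanking MSI comparisons: one-way
  ANOVA followed by Tukey's HSD;
* alternatively-spliced vs constitutively spliced intron length: two-group
  Mann-Whitney U.

The Dunn test is the standard rank-based z-statistic with tie correction;
p-values are adjusted with Holm's method by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_stars(p: float) -> str:
    for thr, stars in STAR_THRESHOLDS:
        if p < thr:
            return stars
    return "n.s."


@dataclass
class GroupTestResult:
    test: str
    statistic: float
    p_value: float
    stars: str
    posthoc: "list[PairwiseResult] | None" = None


@dataclass
class PairwiseResult:
    group_a: str
    group_b: str
    statistic: float
    p_value: float
    stars: str


def _check_groups(groups: Mapping[str, Sequence[float]]) -> dict[str, np.ndarray]:
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    for name, arr in arrays.items():
        if arr.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 observations")
    return arrays


def _degenerate(arrays: Mapping[str, np.ndarray]) -> bool:
    pooled = np.concatenate(list(arrays.values()))
    return np.ptp(pooled) == 0


def dunn_posthoc(
    groups: Mapping[str, Sequence[float]], adjust: str = "holm"
) -> list[PairwiseResult]:
    """All-pairs Dunn test on pooled ranks with tie correction."""
    arrays = _check_groups(groups)
    names = list(arrays)
    pooled = np.concatenate([arrays[n] for n in names])
    labels = np.concatenate(
        [np.full(arrays[n].size, i) for i, n in enumerate(names)]
    )
    ranks = sps.rankdata(pooled)
    n = pooled.size
    # tie correction term
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (12 * (n - 1))
    mean_ranks = {i: ranks[labels == i].mean() for i in range(len(names))}
    sizes = {i: int((labels == i).sum()) for i in range(len(names))}
    pairs = list(combinations(range(len(names)), 2))
    zvals, pvals = [], []
    for i, j in pairs:
        se = np.sqrt(
            (n * (n + 1) / 12.0 - tie_term) * (1.0 / sizes[i] + 1.0 / sizes[j])
        )
        z = (mean_ranks[i] - mean_ranks[j]) / se
        zvals.append(z)
        pvals.append(2 * sps.norm.sf(abs(z)))
    if adjust:
        pvals = multipletests(pvals, method=adjust)[1].tolist()
    return [
        PairwiseResult(names[i], names[j], float(z), float(p), significance_stars(p))
        for (i, j), z, p in zip(pairs, zvals, pvals)
    ]


def kruskal_dunn(groups: Mapping[str, Sequence[float]]) -> GroupTestResult:
    """Kruskal-Wallis across groups, Dunn post-hoc on all pairs."""
    arrays = _check_groups(groups)
    if _degenerate(arrays):
        return GroupTestResult("kruskal_wallis", float("nan"), float("nan"), "n.s.")
    h, p = sps.kruskal(*arrays.values())
    return GroupTestResult(
        "kruskal_wallis", float(h), float(p), significance_stars(p), dunn_posthoc(arrays)
    )


def anova_tukey(groups: Mapping[str, Sequence[float]]) -> GroupTestResult:
    """One-way ANOVA across groups, Tukey HSD post-hoc on all pairs."""
    arrays = _check_groups(groups)
    if _degenerate(arrays):
        return GroupTestResult("anova", float("nan"), float("nan"), "n.s.")
    names = list(arrays)
    f, p = sps.f_oneway(*[arrays[n] for n in names])
    hsd = sps.tukey_hsd(*[arrays[n] for n in names])
    posthoc = []
    for i, j in combinations(range(len(names)), 2):
        pij = float(hsd.pvalue[i, j])
        posthoc.append(
            PairwiseResult(
                names[i], names[j], float(hsd.statistic[i, j]), pij,
                significance_stars(pij),
            )
        )
    return GroupTestResult("anova", float(f), float(p), significance_stars(p), posthoc)


def mann_whitney(
    group_a: Sequence[float], group_b: Sequence[float]
) -> GroupTestResult:
    """Two-group Mann-Whitney U (two-sided)."""
    a, b = np.asarray(group_a, float), np.asarray(group_b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >=2 observations per group")
    if np.ptp(np.concatenate([a, b])) == 0:
        return GroupTestResult("mann_whitney", float("nan"), float("nan"), "n.s.")
    u, p = sps.mannwhitneyu(a, b, alternative="two-sided")
    return GroupTestResult("mann_whitney", float(u), float(p), significance_stars(p))
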