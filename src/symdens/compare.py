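"""Nonparametric comparison of fitness across allocation strategies.

Host fitness ``V_H`` and symbiont fitness ``V_S`` from five simulated
cohorts (optimal, imperfect, fixed, proportional, symbiont-optimal) are
compared by a Kruskal-Wallis test followed by pairwise two-sided Wilcoxon
rank-sum (Mann-Whitney) tests; a Holm adjustment of the pairwise p-values
is reported alongside the raw ones.  Strategies are grouped by significance
letters: strategies sharing a letter are not significantly different.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .simulate import CohortResult

__all__ = [
    "KruskalResult",
    "StrategyComparison",
    "kruskal_wallis",
    "pairwise_wilcoxon",
    "compare_strategies",
]


class KruskalResult(NamedTuple):
    H: float
    df: int
    p: float


def kruskal_wallis(groups: Sequence[np.ndarray]) -> KruskalResult:
    """Rank-based H statistic with tie correction, p from chi-squared(k-1).

    Degenerate input (all observations identical) gives H = 0, p = 1.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) == 0 for g in arrays):
        raise ValueError("groups must be non-empty")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return KruskalResult(0.0, len(groups) - 1, 1.0)
    H, p = stats.kruskal(*arrays)
    return KruskalResult(float(H), len(groups) - 1, float(p))


def pairwise_wilcoxon(
    groups: Mapping[str, np.ndarray], adjust: bool = True
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-sided rank-sum p for every unordered pair of groups.

    Returns ``(raw, holm)`` square symmetric DataFrames (diagonal NaN);
    with ``adjust=False`` the second frame is a copy of the first.
    """
    names = list(groups)
    k = len(names)
    raw = pd.DataFrame(np.full((k, k), np.nan), index=names, columns=names)
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    pvals = []
    for i, j in pairs:
        a = np.asarray(groups[names[i]], dtype=float)
        b = np.asarray(groups[names[j]], dtype=float)
        if np.ptp(np.concatenate([a, b])) == 0:
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        pvals.append(p)
        raw.iloc[i, j] = raw.iloc[j, i] = p
    holm = raw.copy()
    if adjust and pvals:
        adjusted = multipletests(pvals, method="holm")[1]
        for (i, j), p in zip(pairs, adjusted):
            holm.iloc[i, j] = holm.iloc[j, i] = float(p)
    return raw, holm


def _letter_groups(names: Sequence[str], ns_matrix: pd.DataFrame, means: Mapping[str, float]) -> dict[str, str]:
    """Compact letter display: letters index the maximal cliques of the
    'not significantly different' graph, ordered by best group mean."""
    g = nx.Graph()
    g.add_nodes_from(names)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if ns_matrix.loc[a, b]:
                g.add_edge(a, b)
    cliques = sorted(
        nx.find_cliques(g), key=lambda c: -max(means[m] for m in c)
    )
    letters: dict[str, list[str]] = {n: [] for n in names}
    for idx, clique in enumerate(cliques):
        letter = chr(ord("a") + idx)
        for member in clique:
            letters[member].append(letter)
    return {n: "".join(sorted(v)) for n, v in letters.items()}


@dataclass
class StrategyComparison:
    """Full comparison of the five strategies for both fitness types."""

    kruskal: dict[str, KruskalResult]
    pairwise_raw: dict[str, pd.DataFrame]
    pairwise_holm: dict[str, pd.DataFrame]
    summary: pd.DataFrame
    alpha: float = 0.05

    def significant_pairs(self, fitness: str, adjusted: bool = True) -> set[frozenset]:
        mat = (self.pairwise_holm if adjusted else self.pairwise_raw)[fitness]
        out = set()
        for a in mat.index:
            for b in mat.columns:
                if a != b and mat.loc[a, b] < self.alpha:
                    out.add(frozenset((a, b)))
        return out


def compare_strategies(
    cohorts: Mapping[str, CohortResult], alpha: float = 0.05
) -> StrategyComparison:
    """Assemble fitness vectors from one cohort per strategy and test them.

    The summary table carries per-strategy mean, SD and significance letter
    (letters computed on the Holm-adjusted pairwise matrix).
    """
    if not cohorts:
        raise ValueError("no cohorts given")
    names = list(cohorts)
    kruskal: dict[str, KruskalResult] = {}
    raw_mats: dict[str, pd.DataFrame] = {}
    holm_mats: dict[str, pd.DataFrame] = {}
    rows = []
    for fitness in ("V_H", "V_S"):
        groups = {name: getattr(c, fitness) for name, c in cohorts.items()}
        kruskal[fitness] = kruskal_wallis(list(groups.values()))
        raw, holm = pairwise_wilcoxon(groups)
        raw_mats[fitness] = raw
        holm_mats[fitness] = holm
        means = {n: float(np.mean(g)) for n, g in groups.items()}
        ns = holm.isna() | (holm >= alpha)
        letters = _letter_groups(names, ns, means)
        for name, g in groups.items():
            rows.append(
                {
                    "strategy": name,
                    "fitness": fitness,
                    "mean": means[name],
                    "sd": float(np.std(g, ddof=1)) if len(g) > 1 else 0.0,
                    "letters": letters[name],
                }
            )
    return StrategyComparison(
        kruskal=kruskal,
        pairwise_raw=raw_mats,
        pairwise_holm=holm_mats,
        summary=pd.DataFrame(rows),
        alpha=alpha,
    )
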