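"""Small-sample statistics used across the selection stages."""

from __future__ import annotations

from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "hypergeometric_overlap",
    "rank_sum_test",
    "mitotic_correlation",
    "adjust_pvalues",
]

EXACT_GROUP_LIMIT = 10  # exact rank-sum enumeration when both groups <= this


def hypergeometric_overlap(regulon_targets: Iterable[str],
                           signature_genes: Iterable[str],
                           universe: Iterable[str]) -> float:
    """Upper-tail hypergeometric probability of an overlap at least as large."""
    universe = set(universe)
    a = set(regulon_targets)
    b = set(signature_genes)
    if not a <= universe or not b <= universe:
        raise ValueError("both gene sets must be subsets of the universe")
    k = len(a & b)
    return float(sps.hypergeom.sf(k - 1, len(universe), len(a), len(b)))


def rank_sum_test(values: Sequence[float], group_labels: Sequence) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact enumeration of the midrank-sum permutation distribution when both
    groups have <= 10 observations; normal approximation with tie and
    continuity correction otherwise.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    levels = pd.unique(labels)
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {len(levels)}")
    x = values[labels == levels[0]]
    y = values[labels == levels[1]]
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    if n1 <= EXACT_GROUP_LIMIT and n2 <= EXACT_GROUP_LIMIT:
        ranks = sps.rankdata(np.concatenate([x, y]))
        w_obs = ranks[:n1].sum()
        mu = n1 * (n1 + n2 + 1) / 2.0
        dev = abs(w_obs - mu)
        hits = total = 0
        for comb in combinations(range(n1 + n2), n1):
            total += 1
            if abs(sum(ranks[i] for i in comb) - mu) >= dev - 1e-9:
                hits += 1
        return hits / total
    return float(sps.mannwhitneyu(x, y, alternative="two-sided",
                                  method="asymptotic").pvalue)


def mitotic_correlation(activity_row: Sequence[float],
                        mitotic_index: Sequence[float]) -> tuple[float, float]:
    """Spearman correlation (midranks for ties) of activity vs mitotic index."""
    a = np.asarray(activity_row, dtype=float)
    m = np.asarray(mitotic_index, dtype=float)
    if a.shape != m.shape or len(a) < 5:
        raise ValueError("need at least 5 paired observations")
    if np.ptp(m) == 0:
        raise ValueError("mitotic index is constant; rho undefined")
    rho, p = sps.spearmanr(a, m)
    return float(rho), float(p)


def adjust_pvalues(pvalues: Sequence[float], method: str = "BH") -> np.ndarray:
    """Multiple-testing adjustment: Benjamini-Hochberg or Bonferroni."""
    p = np.asarray(pvalues, dtype=float)
    if p.size and ((p < 0).any() or (p > 1).any() or not np.isfinite(p).all()):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    if method == "BH":
        return multipletests(p, method="fdr_bh")[1]
    if method == "Bonferroni":
        return np.minimum(p * len(p), 1.0)
    raise ValueError(f"unknown method {method!r}; use 'BH' or 'Bonferroni'")
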