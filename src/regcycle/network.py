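"""ARACNe-style transcriptional-network inference.

Pairwise mutual information between each curated TF and every other gene,
a pooled permutation-null significance threshold, data-processing-inequality
(DPI) pruning of the weakest edge in each triangle, and signed regulon
assembly (mode = sign of the TF-target Pearson correlation).

The MI estimator rank-transforms both vectors to uniform scores and applies
equal-frequency binning with a Miller-Madow bias correction, floored at 0.
Rank transformation makes the estimate invariant to monotone rescaling, which
matters because cohorts arrive on different expression scales.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .containers import GeneExpressionMatrix, TranscriptionalNetwork

__all__ = [
    "estimate_mi",
    "mi_null_threshold",
    "apply_dpi",
    "build_regulons",
    "RegulonInference",
]


def _n_bins(n: int) -> int:
    """Equal-frequency bin count: floor(sqrt(n/5)) clamped to [4, 16]."""
    return int(np.clip(int(np.sqrt(n / 5)), 4, 16))


def _discretize(v: np.ndarray, n_bins: int) -> np.ndarray:
    """Rank-transform then cut into equal-frequency bins."""
    n = len(v)
    ranks = np.empty(n, dtype=np.int64)
    ranks[np.argsort(v, kind="stable")] = np.arange(n)
    return (ranks * n_bins) // n


def _mi_from_bins(bx: np.ndarray, by: np.ndarray, n_bins: int) -> float:
    """Plug-in MI of two binned vectors with Miller-Madow correction (nats)."""
    n = len(bx)
    joint = np.bincount(bx * n_bins + by, minlength=n_bins * n_bins).astype(float)
    nz = joint > 0
    p = joint[nz] / n
    px = joint.reshape(n_bins, n_bins).sum(axis=1) / n
    py = joint.reshape(n_bins, n_bins).sum(axis=0) / n
    outer = np.outer(px, py).ravel()[nz]
    mi = float(np.sum(p * np.log(p / outer)))
    mi -= (int(nz.sum()) - int((px > 0).sum()) - int((py > 0).sum()) + 1) / (2 * n)
    return max(mi, 0.0)


def estimate_mi(x: Sequence[float], y: Sequence[float],
                n_bins: int | None = None) -> float:
    """Mutual information (nats) between two equal-length sample vectors.

    Symmetric in its arguments and nonnegative (the bias correction is floored
    at 0). A constant vector carries no information: MI = 0 with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < 10:
        raise ValueError("need at least 10 paired observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant vector: MI defined as 0", stacklevel=2)
        return 0.0
    bins = n_bins if n_bins is not None else _n_bins(len(x))
    bx, by = _discretize(x, bins), _discretize(y, bins)
    if bx.tobytes() > by.tobytes():  # canonical order: exact symmetry in floats
        bx, by = by, bx
    return _mi_from_bins(bx, by, bins)


def mi_null_threshold(
    expression: GeneExpressionMatrix | pd.DataFrame,
    n_permutations: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    n_bins: int | None = None,
) -> float:
    """(1 - alpha) quantile of MI over sample-label-permuted gene pairs.

    The null pools permuted pairs across genes (one global threshold), the
    usual ARACNe practice.
    """
    if not 0 < alpha <= 1:
        raise ValueError(f"alpha must lie in (0, 1], got {alpha}")
    if n_permutations < 100:
        raise ValueError("need at least 100 permutations")
    data = expression.data if isinstance(expression, GeneExpressionMatrix) else expression
    values = data.to_numpy()
    n_genes, n_samples = values.shape
    bins = n_bins if n_bins is not None else _n_bins(n_samples)
    disc = np.vstack([_discretize(values[i], bins) for i in range(n_genes)])
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for p in range(n_permutations):
        i, j = rng.choice(n_genes, size=2, replace=False)
        null[p] = _mi_from_bins(disc[i], rng.permutation(disc[j]), bins)
    return float(np.quantile(null, 1.0 - alpha))


def apply_dpi(
    edges: Mapping[tuple[str, str], float],
    tolerance: float = 0.1,
) -> dict[tuple[str, str], float]:
    """Data-processing-inequality pruning of a weighted undirected edge set.

    For every triangle, the weakest edge is removed when its MI is below
    ``(1 - tolerance) * min(other two)``. All removals are decided on the
    input graph, making a second application a no-op (idempotence).
    """
    if not 0 <= tolerance <= 1:
        raise ValueError("tolerance must lie in [0, 1]")
    weight: dict[tuple[str, str], float] = {}
    adj: dict[str, set[str]] = defaultdict(set)
    for (a, b), w in edges.items():
        if a == b:
            raise ValueError(f"self-edge {a!r}")
        key = (a, b) if a <= b else (b, a)
        weight[key] = float(w)
        adj[a].add(b)
        adj[b].add(a)

    def _w(u: str, v: str) -> float:
        return weight[(u, v) if u <= v else (v, u)]

    removed: set[tuple[str, str]] = set()
    for a, b in list(weight):
        for c in adj[a] & adj[b]:
            if c <= b:  # visit each triangle a < b < c once
                continue
            trio = [(_w(a, b), (a, b)), (_w(a, c), (a, c)), (_w(b, c), (b, c))]
            trio.sort(key=lambda t: t[0])
            if trio[0][0] < (1.0 - tolerance) * trio[1][0]:
                u, v = trio[0][1]
                removed.add((u, v) if u <= v else (v, u))
    return {pair: w for pair, w in weight.items() if pair not in removed}


def build_regulons(
    expression: GeneExpressionMatrix,
    tf_list: Sequence[str],
    alpha: float = 0.01,
    n_permutations: int = 1000,
    dpi_tolerance: float = 0.1,
    seed: int = 0,
    n_bins: int | None = None,
    include_tf_tf: bool = True,
) -> TranscriptionalNetwork:
    """Infer the full signed TF -> target network from one cohort.

    Regulon targets are genes whose TF-gene MI exceeds the permutation-null
    threshold and survives DPI; the mode is the sign of the TF-target Pearson
    correlation. TFs with empty regulons are retained (see
    :meth:`TranscriptionalNetwork.empty_tfs`).
    """
    data = expression.data
    universe = list(data.index)
    gene_pos = {g: i for i, g in enumerate(universe)}
    tfs = [tf for tf in tf_list if tf in gene_pos]
    if not tfs:
        raise ValueError("no TF from the list is present in the expression matrix")
    tf_set = set(tfs)
    values = data.to_numpy()
    n_samples = values.shape[1]
    bins = n_bins if n_bins is not None else _n_bins(n_samples)
    disc = np.vstack([_discretize(values[i], bins) for i in range(len(universe))])

    threshold = mi_null_threshold(expression, n_permutations=n_permutations,
                                  alpha=alpha, seed=seed, n_bins=bins)

    edges: dict[tuple[str, str], float] = {}
    for tf in tfs:
        ti = gene_pos[tf]
        for gene, gi in gene_pos.items():
            if gene == tf or (gene in tf_set and not include_tf_tf):
                continue
            key = (tf, gene) if tf <= gene else (gene, tf)
            if key in edges:
                continue
            mi = _mi_from_bins(disc[ti], disc[gi], bins)
            if mi >= threshold and mi > 0:
                edges[key] = mi

    pruned = apply_dpi(edges, tolerance=dpi_tolerance)

    rows = []
    for (a, b), w in pruned.items():
        pairs = []
        if a in tf_set:
            pairs.append((a, b))
        if b in tf_set:
            pairs.append((b, a))
        for tf, target in pairs:
            r = np.corrcoef(values[gene_pos[tf]], values[gene_pos[target]])[0, 1]
            mode = -1 if r < 0 else 1
            rows.append((tf, target, mode, w))
    edge_df = pd.DataFrame(rows, columns=["tf", "target", "mode", "weight"])
    edge_df = edge_df.sort_values(["tf", "target"], kind="stable").reset_index(drop=True)
    return TranscriptionalNetwork(
        universe=universe,
        edges=edge_df,
        tfs=tfs,
        parameters={
            "alpha": alpha,
            "n_permutations": n_permutations,
            "dpi_tolerance": dpi_tolerance,
            "mi_threshold": threshold,
            "n_bins": bins,
            "seed": seed,
            "include_tf_tf": include_tf_tf,
        },
    )


class RegulonInference(BaseEstimator):
    """Estimator wrapper around :func:`build_regulons`.

    Parameters
    ----------
    tfs : sequence of str
        Curated TF symbols; those absent from the fitted matrix are dropped.
    alpha : float, default 0.01
        Significance level of the pooled permutation-null MI threshold.
    n_permutations : int, default 1000
        Permuted pairs drawn for the null.
    dpi_tolerance : float, default 0.1
        DPI slack; 0 prunes aggressively, 1 disables pruning.
    n_bins : int or None
        Equal-frequency bin count; None picks floor(sqrt(n/5)) in [4, 16].
    include_tf_tf : bool, default True
        Whether a TF may appear in another TF's regulon.
    random_state : int, default 0

    Attributes
    ----------
    network_ : TranscriptionalNetwork
    threshold_ : float
        The permutation-null MI threshold used.
    """

    def __init__(self, tfs: Sequence[str] = (), alpha: float = 0.01,
                 n_permutations: int = 1000, dpi_tolerance: float = 0.1,
                 n_bins: int | None = None, include_tf_tf: bool = True,
                 random_state: int = 0):
        self.tfs = tfs
        self.alpha = alpha
        self.n_permutations = n_permutations
        self.dpi_tolerance = dpi_tolerance
        self.n_bins = n_bins
        self.include_tf_tf = include_tf_tf
        self.random_state = random_state

    def fit(self, X: GeneExpressionMatrix | pd.DataFrame, y=None) -> "RegulonInference":
        if isinstance(X, pd.DataFrame):
            X = GeneExpressionMatrix(X)
        self.network_ = build_regulons(
            X, list(self.tfs), alpha=self.alpha,
            n_permutations=self.n_permutations,
            dpi_tolerance=self.dpi_tolerance, seed=self.random_state,
            n_bins=self.n_bins, include_tf_tf=self.include_tf_tf,
        )
        self.threshold_ = self.network_.parameters["mi_threshold"]
        return self
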