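"""Consensus clustering of tumors and the cell-cycle group assignment.

Stability-based clustering in the ConsensusClusterPlus style: repeated k-means
on item-resampled (and optionally feature-resampled) data, accumulating the
co-clustering frequency of every co-sampled pair; final labels come from
average-linkage hierarchical clustering of (1 - consensus). The number of
clusters is chosen by the consensus-CDF area criterion: the smallest k whose
area under the consensus CDF is within a small tolerance of the maximum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.cluster import AgglomerativeClustering, KMeans

from .containers import GeneExpressionMatrix

__all__ = [
    "ConsensusClustering",
    "ConsensusResult",
    "consensus_cluster",
    "choose_k",
    "assign_cell_cycle_groups",
    "assign_regulon_clusters",
]

CHOOSE_K_TOLERANCE = 0.02  # CDF areas within 2% of the max count as tied


class ConsensusClustering(BaseEstimator):
    """Consensus k-means clustering of samples.

    Parameters
    ----------
    n_clusters : int, default 2
    n_reps : int, default 1000
        Resampling repetitions.
    item_fraction : float, default 0.9
        Fraction of samples drawn (without replacement) per repetition.
    feature_fraction : float, default 1.0
        Fraction of features drawn per repetition.
    n_init : int, default 10
        k-means restarts per repetition (best inertia kept).
    random_state : int, default 0

    Attributes
    ----------
    consensus_matrix_ : ndarray (n_samples, n_samples)
        Co-clustering frequency among co-sampled pairs; diagonal is 1.
    labels_ : ndarray of int
        Final labels from average-linkage clustering of 1 - consensus.
    cdf_area_ : float
        Area under the empirical CDF of the off-diagonal consensus entries.
    """

    def __init__(self, n_clusters: int = 2, n_reps: int = 1000,
                 item_fraction: float = 0.9, feature_fraction: float = 1.0,
                 n_init: int = 10, random_state: int = 0):
        self.n_clusters = n_clusters
        self.n_reps = n_reps
        self.item_fraction = item_fraction
        self.feature_fraction = feature_fraction
        self.n_init = n_init
        self.random_state = random_state

    def fit(self, X, y=None) -> "ConsensusClustering":
        X = np.asarray(X, dtype=float)
        n, p = X.shape
        if p < 2:
            raise ValueError("need at least 2 features")
        if n < 2 * self.n_clusters:
            raise ValueError(f"need at least {2 * self.n_clusters} samples for "
                             f"k = {self.n_clusters}")
        rng = np.random.default_rng(self.random_state)
        co = np.zeros((n, n))
        counted = np.zeros((n, n))
        n_items = max(self.n_clusters, int(round(self.item_fraction * n)))
        n_feats = max(1, int(round(self.feature_fraction * p)))
        for rep in range(self.n_reps):
            items = np.sort(rng.choice(n, size=n_items, replace=False))
            feats = (np.sort(rng.choice(p, size=n_feats, replace=False))
                     if n_feats < p else slice(None))
            rep_seed = int(rng.integers(0, 2**31 - 1))
            km = KMeans(n_clusters=self.n_clusters, n_init=self.n_init,
                        random_state=rep_seed).fit(X[items][:, feats])
            counted[np.ix_(items, items)] += 1.0
            for c in range(self.n_clusters):
                members = items[km.labels_ == c]
                co[np.ix_(members, members)] += 1.0
        with np.errstate(invalid="ignore"):
            consensus = np.where(counted > 0, co / np.maximum(counted, 1), 0.0)
        consensus = (consensus + consensus.T) / 2.0
        np.fill_diagonal(consensus, 1.0)
        self.consensus_matrix_ = consensus
        agg = AgglomerativeClustering(n_clusters=self.n_clusters,
                                      metric="precomputed", linkage="average")
        self.labels_ = agg.fit_predict(1.0 - consensus)
        self.cdf_area_ = _cdf_area(consensus)
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_


def _cdf_area(consensus: np.ndarray) -> float:
    """Area under the empirical CDF of the off-diagonal consensus entries."""
    v = np.sort(consensus[np.triu_indices_from(consensus, k=1)])
    if v.size == 0:
        return 0.0
    xs = np.concatenate([v, [1.0]])
    cdf = np.arange(1, len(v) + 1) / len(v)
    return float(np.sum(np.diff(xs) * cdf) + v[0] * 0.0)


@dataclass
class ConsensusResult:
    """Consensus clustering evaluated over a range of k."""

    sample_ids: list[str]
    consensus: dict[int, np.ndarray]
    labels: dict[int, np.ndarray]
    cdf_area: dict[int, float]
    chosen_k: int = field(default=0)


def consensus_cluster(
    feature_matrix: pd.DataFrame,
    k_range=(2, 3, 4),
    n_reps: int = 1000,
    item_fraction: float = 0.9,
    feature_fraction: float = 1.0,
    seed: int = 0,
) -> ConsensusResult:
    """Consensus clustering of samples (rows) over a range of cluster counts."""
    k_range = sorted(k_range)
    n = feature_matrix.shape[0]
    if 2 * max(k_range) > n:
        raise ValueError(f"k range {k_range} exceeds the sample count {n}")
    result = ConsensusResult(sample_ids=list(feature_matrix.index),
                             consensus={}, labels={}, cdf_area={})
    for k in k_range:
        model = ConsensusClustering(
            n_clusters=k, n_reps=n_reps, item_fraction=item_fraction,
            feature_fraction=feature_fraction, random_state=seed + k,
        ).fit(feature_matrix.to_numpy())
        result.consensus[k] = model.consensus_matrix_
        result.labels[k] = model.labels_
        result.cdf_area[k] = model.cdf_area_
    result.chosen_k = choose_k(result)
    return result


def consensus_pac(consensus: np.ndarray, lower: float = 0.1,
                  upper: float = 0.9) -> float:
    """Proportion of ambiguous clustering: off-diagonal consensus entries
    strictly between the two cutoffs (0 for a perfectly stable clustering)."""
    v = consensus[np.triu_indices_from(consensus, k=1)]
    if v.size == 0:
        return 0.0
    return float(np.mean((v > lower) & (v < upper)))


def choose_k(result: ConsensusResult, tolerance: float = CHOOSE_K_TOLERANCE) -> int:
    """Cluster count from consensus stability plus the CDF-area criterion.

    The raw area under the consensus CDF grows mechanically with k (it equals
    one minus the mean consensus, dominated by the between-cluster zeros), so
    it cannot be compared across k directly. Candidates are first restricted
    to the k whose proportion of ambiguous clustering (PAC) is within
    ``tolerance`` of the minimum — the stable clusterings — and among those
    the smallest k whose CDF area is within ``tolerance`` of the candidates'
    maximum wins.
    """
    if len(result.consensus) < 2:
        raise ValueError("need at least 2 candidate k values")
    pac = {k: consensus_pac(m) for k, m in result.consensus.items()}
    best_pac = min(pac.values())
    candidates = [k for k in sorted(pac) if pac[k] <= best_pac + tolerance]
    best_area = max(result.cdf_area[k] for k in candidates)
    for k in candidates:
        if result.cdf_area[k] >= (1.0 - tolerance) * best_area:
            return k
    return candidates[-1]  # unreachable


def assign_cell_cycle_groups(
    expression: GeneExpressionMatrix | pd.DataFrame,
    early_genes,
    late_genes,
    seed: int = 0,
    n_reps: int = 1000,
) -> pd.Series:
    """Early/late cell-cycle labels by 2-cluster consensus clustering.

    Samples are clustered on the union of the early and late cell-cycle gene
    lists (gene-wise z-scores, Euclidean k-means); the cluster with the higher
    mean expression of late-list genes is labeled "late".
    """
    data = expression.data if isinstance(expression, GeneExpressionMatrix) else expression
    early = [g for g in early_genes if g in data.index]
    late = [g for g in late_genes if g in data.index]
    if not early or not late:
        raise ValueError("early/late gene lists do not intersect the universe")
    union = list(dict.fromkeys(early + late))
    sub = data.loc[union]
    sd = sub.std(axis=1, ddof=1)
    if (sd == 0).all():
        raise ValueError("no variance across samples; cannot cluster")
    z = sub.sub(sub.mean(axis=1), axis=0).div(sd.replace(0, 1.0), axis=0)
    model = ConsensusClustering(n_clusters=2, n_reps=n_reps,
                                random_state=seed).fit(z.T.to_numpy())
    labels = model.labels_
    late_mean = data.loc[late].mean(axis=0).to_numpy()
    means = [late_mean[labels == c].mean() for c in (0, 1)]
    late_cluster = int(np.argmax(means))
    out = np.where(labels == late_cluster, "late", "early")
    return pd.Series(out, index=data.columns, name="cell_cycle_group")


def assign_regulon_clusters(
    activity: pd.DataFrame,
    directions: pd.Series | None = None,
    seed: int = 0,
    n_reps: int = 1000,
) -> pd.Series:
    """High/Low Cell Cycle labels by 2-cluster consensus on regulon activity.

    The cluster with the higher mean activity of high-CC-direction regulons
    (all regulons if no directions are given) is labeled "high".
    """
    rows = activity.dropna(how="all")
    model = ConsensusClustering(n_clusters=2, n_reps=n_reps,
                                random_state=seed).fit(rows.T.to_numpy())
    labels = model.labels_
    if directions is not None:
        high_rows = [tf for tf in rows.index if directions.get(tf) == "high-CC"]
        score = rows.loc[high_rows].mean(axis=0) if high_rows else rows.mean(axis=0)
    else:
        score = rows.mean(axis=0)
    score = score.to_numpy()
    high_cluster = int(np.argmax([score[labels == c].mean() for c in (0, 1)]))
    out = np.where(labels == high_cluster, "high", "low")
    return pd.Series(out, index=activity.columns, name="regulon_cluster")
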