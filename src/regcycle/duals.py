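"""Dual-regulon analysis: TF pairs acting on shared targets.

A dual regulon is a TF pair whose target sets overlap more than expected
(two-sided Fisher exact test over the expression universe, BH-adjusted).
For each such pair, the "regulon agreement" is the Spearman correlation
between the two TFs' per-target Pearson correlation profiles over the shared
targets: positive agreement means the TFs push shared targets the same way
(co-activation), negative agreement means they oppose each other
(antagonism).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .containers import GeneExpressionMatrix, TranscriptionalNetwork
from .stats import adjust_pvalues

__all__ = [
    "DualRegulonRecord",
    "overlap_test",
    "regulon_agreement",
    "find_duals",
    "agreement_clustering",
]

MIN_SHARED_TARGETS = 10


@dataclass
class DualRegulonRecord:
    """One significant TF pair (tf_a < tf_b lexicographically)."""

    tf_a: str
    tf_b: str
    n_shared: int
    overlap_p: float
    overlap_q: float
    corr_a: np.ndarray  # Pearson r of each shared target with tf_a
    corr_b: np.ndarray
    agreement: float  # Spearman correlation of the two profiles
    direction: str  # co-activating / antagonistic


def overlap_test(regulon_a, regulon_b, universe) -> float:
    """Two-sided Fisher exact p for the overlap of two regulons."""
    universe = set(universe)
    a, b = set(regulon_a), set(regulon_b)
    if not a or not b:
        raise ValueError("regulons must be non-empty")
    if not a <= universe or not b <= universe:
        raise ValueError("regulons must be subsets of the universe")
    n11 = len(a & b)
    n12 = len(a - b)
    n21 = len(b - a)
    n22 = len(universe) - len(a | b)
    return float(sps.fisher_exact([[n11, n12], [n21, n22]],
                                  alternative="two-sided")[1])


def _pearson_profile(values: np.ndarray, tf_row: np.ndarray) -> np.ndarray:
    """Pearson r of each row of ``values`` with ``tf_row``."""
    tf_c = tf_row - tf_row.mean()
    v_c = values - values.mean(axis=1, keepdims=True)
    denom = np.sqrt((v_c ** 2).sum(axis=1) * (tf_c ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (v_c @ tf_c) / denom
    return np.where(np.isfinite(r), r, 0.0)


def regulon_agreement(
    expression: GeneExpressionMatrix | pd.DataFrame,
    tf_a: str,
    tf_b: str,
    shared_targets,
    min_shared: int = MIN_SHARED_TARGETS,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Spearman correlation of the two per-target correlation profiles.

    Returns (agreement, profile_a, profile_b). Raises when fewer than
    ``min_shared`` shared targets are present in the matrix.
    """
    data = expression.data if isinstance(expression, GeneExpressionMatrix) else expression
    targets = [t for t in shared_targets if t in data.index]
    if len(targets) < min_shared:
        raise ValueError(f"only {len(targets)} shared targets present "
                         f"(minimum {min_shared})")
    values = data.loc[targets].to_numpy(dtype=float)
    r_a = _pearson_profile(values, data.loc[tf_a].to_numpy(dtype=float))
    r_b = _pearson_profile(values, data.loc[tf_b].to_numpy(dtype=float))
    if np.ptp(r_a) == 0 and np.ptp(r_b) == 0:
        # identical constant profiles: perfectly concordant by convention
        agreement = 1.0 if np.allclose(r_a, r_b) else 0.0
    elif np.allclose(r_a, r_b):
        agreement = 1.0
    elif np.allclose(r_a, -r_b):
        agreement = -1.0
    else:
        agreement = float(sps.spearmanr(r_a, r_b)[0])
    return agreement, r_a, r_b


def find_duals(
    network: TranscriptionalNetwork,
    expression: GeneExpressionMatrix | pd.DataFrame,
    min_shared: int = MIN_SHARED_TARGETS,
    alpha: float = 0.05,
    tfs: list[str] | None = None,
) -> list[DualRegulonRecord]:
    """All significant dual regulons among the network's TFs.

    Candidate pairs share at least ``min_shared`` targets; overlap p-values
    are BH-adjusted across candidates and pairs with q < alpha are returned,
    each once with tf_a < tf_b.
    """
    data = expression.data if isinstance(expression, GeneExpressionMatrix) else expression
    pool = sorted(tfs if tfs is not None else network.tfs)
    members = {tf: set(network.regulon_members(tf)) for tf in pool}
    universe = set(network.universe)
    candidates = []
    for tf_a, tf_b in combinations(pool, 2):
        shared = members[tf_a] & members[tf_b]
        shared_present = [t for t in shared if t in data.index]
        if len(shared_present) < min_shared:
            continue
        p = overlap_test(members[tf_a], members[tf_b], universe)
        candidates.append((tf_a, tf_b, sorted(shared_present), p))
    if not candidates:
        return []
    qvals = adjust_pvalues([c[3] for c in candidates], "BH")
    records = []
    for (tf_a, tf_b, shared, p), q in zip(candidates, qvals):
        if q >= alpha:
            continue
        agreement, r_a, r_b = regulon_agreement(data, tf_a, tf_b, shared,
                                                min_shared=min_shared)
        records.append(DualRegulonRecord(
            tf_a=tf_a, tf_b=tf_b, n_shared=len(shared), overlap_p=p,
            overlap_q=float(q), corr_a=r_a, corr_b=r_b, agreement=agreement,
            direction="co-activating" if agreement >= 0 else "antagonistic",
        ))
    return records


def agreement_clustering(
    records: list[DualRegulonRecord],
    tfs: list[str],
) -> tuple[pd.Series, pd.DataFrame, bool]:
    """Two-way clustering of TFs by regulon agreement.

    Missing pairwise agreements are imputed at 0 for the clustering only.
    Returns (cluster labels in {0, 1}, agreement matrix, stable flag); the
    forced 2-split is flagged unstable when the mean between-cluster
    agreement is nonnegative (no opposing structure).
    """
    if len(tfs) < 4:
        raise ValueError("need at least 4 TFs with pairwise records")
    matrix = pd.DataFrame(np.nan, index=tfs, columns=tfs, dtype=float)
    np.fill_diagonal(matrix.to_numpy(), 1.0)
    for rec in records:
        if rec.tf_a in matrix.index and rec.tf_b in matrix.index:
            matrix.loc[rec.tf_a, rec.tf_b] = rec.agreement
            matrix.loc[rec.tf_b, rec.tf_a] = rec.agreement
    off_diag = matrix.to_numpy()[~np.eye(len(tfs), dtype=bool)]
    if np.isnan(off_diag).all():
        raise ValueError("no pairwise agreement available for any TF pair")
    filled = matrix.fillna(0.0)
    np.fill_diagonal(filled.to_numpy(), 1.0)
    dist = 1.0 - filled.to_numpy()
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(z, t=2, criterion="maxclust") - 1
    out = pd.Series(labels, index=tfs, name="agreement_cluster")
    between = filled.to_numpy()[np.ix_(labels == 0, labels == 1)]
    stable = bool(between.size and between.mean() < 0)
    return out, matrix, stable
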