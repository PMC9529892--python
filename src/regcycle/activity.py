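"""Per-sample regulon activity as a two-tailed running-sum enrichment score.

Each sample gets a *signature*: its expression z-scored gene-wise against the
cohort. A gene set's enrichment score (ES) in a sample is the signed maximum
deviation of a weighted running sum over genes ranked by decreasing signature
value: hits increment by normalized weight |z|**exponent (exponent 0 gives
the classic unweighted statistic), misses decrement by 1/(N - k). ES lies in
[-1, 1]. A regulon's two-tailed activity is ES(positive-mode targets) minus
ES(negative-mode targets), lying in [-2, 2]: positive scores mean the regulon
pushes its targets in the inferred directions in that sample.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import ActivityMatrix, GeneExpressionMatrix, TranscriptionalNetwork

__all__ = [
    "sample_signature",
    "signature_matrix",
    "enrichment_score",
    "regulon_activity",
    "signature_activity",
    "enrichment_score_difference",
    "RegulonActivity",
]


def signature_matrix(expression: GeneExpressionMatrix | pd.DataFrame) -> pd.DataFrame:
    """Gene-wise cohort z-scores (zero-variance genes get 0 everywhere)."""
    data = expression.data if isinstance(expression, GeneExpressionMatrix) else expression
    if data.shape[1] < 3:
        raise ValueError("signature standardization needs at least 3 samples")
    values = data.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (values - mean) / sd
    z[np.broadcast_to(sd == 0, z.shape)] = 0.0
    return pd.DataFrame(z, index=data.index, columns=data.columns)


def sample_signature(expression: GeneExpressionMatrix | pd.DataFrame,
                     sample: str) -> pd.Series:
    """One sample's signature: (x - cohort mean) / cohort sd per gene."""
    data = expression.data if isinstance(expression, GeneExpressionMatrix) else expression
    if sample not in data.columns:
        raise KeyError(f"sample {sample!r} not in matrix")
    return signature_matrix(data)[sample]


# ---------------------------------------------------------------------------
# vectorized running-sum core


def _sort_orders(Z: np.ndarray, genes: Sequence[str]) -> np.ndarray:
    """Per-sample gene ordering: decreasing signature, ties by gene symbol."""
    gene_rank = np.empty(len(genes), dtype=np.int64)
    gene_rank[np.argsort(np.asarray(genes, dtype=object))] = np.arange(len(genes))
    order = np.empty(Z.shape, dtype=np.int64)
    for s in range(Z.shape[1]):
        order[:, s] = np.lexsort((gene_rank, -Z[:, s]))
    return order


def _batch_es(Z: np.ndarray, order: np.ndarray, member: np.ndarray,
              exponent: float, sorted_absZ: np.ndarray | None = None) -> np.ndarray:
    """ES of one gene set for every sample (column) at once."""
    n_genes, n_samples = Z.shape
    k = int(member.sum())
    if k == 0 or k == n_genes:
        raise ValueError("gene set must be a proper nonempty subset of the universe")
    hit = member[order]  # (n_genes, n_samples) in ranked order
    if exponent == 0:
        w = hit.astype(float)
    else:
        if sorted_absZ is None:
            sorted_absZ = np.abs(np.take_along_axis(Z, order, axis=0)) ** exponent
        w = sorted_absZ * hit
    wsum = w.sum(axis=0)
    flat = wsum == 0  # degenerate weighting (e.g. all-zero signature)
    if flat.any() and exponent != 0:
        w[:, flat] = hit[:, flat].astype(float)
        wsum = np.where(flat, float(k), wsum)
    p_hit = np.cumsum(w, axis=0) / wsum
    p_miss = np.cumsum(~hit, axis=0) / float(n_genes - k)
    dev = p_hit - p_miss
    max_dev = dev.max(axis=0)
    min_dev = dev.min(axis=0)
    # signed maximum deviation; an exact magnitude tie resolves positive
    es = np.where(max_dev + min_dev >= -1e-9, max_dev, min_dev)
    # a constant signature ranks genes arbitrarily and carries no signal
    constant = np.ptp(Z, axis=0) == 0
    es[constant] = 0.0
    return es


def enrichment_score(signature: pd.Series, gene_set: Iterable[str],
                     weight_exponent: float = 1.0) -> float:
    """Running-sum enrichment score of one gene set in one sample signature."""
    gene_set = set(gene_set)
    universe = set(signature.index)
    inter = gene_set & universe
    if not inter:
        raise ValueError(f"gene set has empty intersection with the universe "
                         f"(set of {len(gene_set)} genes)")
    if len(inter) == len(universe):
        raise ValueError("gene set covers the whole universe; ES undefined")
    Z = signature.to_numpy(dtype=float)[:, None]
    order = _sort_orders(Z, list(signature.index))
    member = signature.index.isin(inter)
    return float(_batch_es(Z, order, member, weight_exponent)[0])


# ---------------------------------------------------------------------------
# regulon / set activity


def regulon_activity(
    network: TranscriptionalNetwork,
    expression: GeneExpressionMatrix | pd.DataFrame,
    weight_exponent: float = 1.0,
    min_per_side: int = 5,
) -> ActivityMatrix:
    """Two-tailed enrichment score of every regulon in every sample.

    Targets are split by mode; the score is ES(positive set) - ES(negative
    set) in [-2, 2]. Regulons with fewer than ``min_per_side`` targets on
    either side fall back to a one-tailed ES of all targets signed by the
    majority mode (a tie keeps the two-tailed difference, preserving the
    mode-negation antisymmetry). Regulons with no targets in the matrix get a
    row of NaN with a warning.
    """
    data = expression.data if isinstance(expression, GeneExpressionMatrix) else expression
    missing = set(network.universe) - set(data.index)
    if missing:
        warnings.warn(f"{len(missing)} network genes absent from the expression "
                      "matrix; regulons are intersected", stacklevel=2)
    Zdf = signature_matrix(data)
    Z = Zdf.to_numpy()
    genes = list(Zdf.index)
    index = pd.Index(genes)
    order = _sort_orders(Z, genes)
    sorted_absZ = (np.abs(np.take_along_axis(Z, order, axis=0)) ** weight_exponent
                   if weight_exponent != 0 else None)

    scores = np.full((len(network.tfs), Z.shape[1]), np.nan)
    for i, tf in enumerate(network.tfs):
        members = network.regulon_members(tf)
        pos = [t for t, m in members.items() if m > 0 and t in Zdf.index]
        neg = [t for t, m in members.items() if m < 0 and t in Zdf.index]
        if not pos and not neg:
            warnings.warn(f"regulon {tf!r} has no targets in the matrix; "
                          "scores set to NaN", stacklevel=2)
            continue

        def es(targets: list[str]) -> np.ndarray:
            return _batch_es(Z, order, index.isin(targets), weight_exponent,
                             sorted_absZ)

        if pos and neg and (min(len(pos), len(neg)) >= min_per_side
                            or len(pos) == len(neg)):
            scores[i] = es(pos) - es(neg)
        else:
            majority = 1 if len(pos) > len(neg) else -1
            scores[i] = majority * es(pos + neg)
    out = pd.DataFrame(scores, index=pd.Index(network.tfs, name="regulon"),
                       columns=Zdf.columns)
    return ActivityMatrix(out, kind="two-tailed-regulon")


def signature_activity(
    expression: GeneExpressionMatrix | pd.DataFrame,
    gene_sets: dict[str, Iterable[str]],
    weight_exponent: float = 1.0,
) -> ActivityMatrix:
    """One-tailed per-sample enrichment of arbitrary named gene sets."""
    data = expression.data if isinstance(expression, GeneExpressionMatrix) else expression
    Zdf = signature_matrix(data)
    Z = Zdf.to_numpy()
    index = pd.Index(Zdf.index)
    order = _sort_orders(Z, list(Zdf.index))
    sorted_absZ = (np.abs(np.take_along_axis(Z, order, axis=0)) ** weight_exponent
                   if weight_exponent != 0 else None)
    rows = {}
    for name, members in gene_sets.items():
        inter = set(members) & set(Zdf.index)
        if not inter:
            raise ValueError(f"gene set {name!r} has empty intersection with "
                             "the expression universe")
        rows[name] = _batch_es(Z, order, index.isin(inter), weight_exponent,
                               sorted_absZ)
    out = pd.DataFrame(rows, index=Zdf.columns).T
    return ActivityMatrix(out, kind="single-set")


def enrichment_score_difference(activity_row: pd.Series,
                                group_labels: pd.Series) -> float:
    """Median activity in the late group minus median in the early group."""
    labels = group_labels.reindex(activity_row.index)
    late = activity_row[labels == "late"]
    early = activity_row[labels == "early"]
    if late.empty or early.empty:
        raise ValueError("both early and late groups must be non-empty")
    return float(late.median() - early.median())


class RegulonActivity(BaseEstimator, TransformerMixin):
    """Transformer computing regulon activity from a frozen network.

    Parameters
    ----------
    network : TranscriptionalNetwork
    weight_exponent : float, default 1.0
    min_per_side : int, default 5

    After :meth:`fit` (which only validates), :meth:`transform` maps a genes x
    samples expression matrix to a regulons x samples activity frame.
    """

    def __init__(self, network: TranscriptionalNetwork | None = None,
                 weight_exponent: float = 1.0, min_per_side: int = 5):
        self.network = network
        self.weight_exponent = weight_exponent
        self.min_per_side = min_per_side

    def fit(self, X=None, y=None) -> "RegulonActivity":
        if self.network is None:
            raise ValueError("a network is required")
        self.regulon_names_ = list(self.network.tfs)
        return self

    def transform(self, X: GeneExpressionMatrix | pd.DataFrame) -> pd.DataFrame:
        return regulon_activity(self.network, X,
                                weight_exponent=self.weight_exponent,
                                min_per_side=self.min_per_side).data
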