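"""Cross-cohort normalization and stage-group comparison of regulon activity.

A second cohort of raw counts is brought onto the inference cohort's scale by
upper-quartile normalization, a one-factor unwanted-variation correction
anchored on housekeeping genes (RUV with k = 1), and TPM conversion. The
frozen network is then projected onto the new cohort and per-regulon activity
compared between stage groups (noninvasive vs invasive) with Bonferroni
control.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator, TransformerMixin

from .activity import regulon_activity
from .containers import ActivityMatrix, GeneExpressionMatrix, TranscriptionalNetwork
from .stats import adjust_pvalues

__all__ = [
    "upper_quartile_normalize",
    "remove_unwanted_variation",
    "counts_to_tpm",
    "project_regulon_activity",
    "compare_stage_groups",
    "UpperQuartileNormalizer",
    "RUVNormalizer",
]


def _as_df(expression) -> pd.DataFrame:
    return (expression.data if isinstance(expression, GeneExpressionMatrix)
            else expression)


def upper_quartile_normalize(counts) -> pd.DataFrame:
    """Scale each sample so its upper quartile of nonzero counts equals the
    across-sample mean upper quartile."""
    data = _as_df(counts)
    values = data.to_numpy(dtype=float)
    uq = np.empty(values.shape[1])
    for j in range(values.shape[1]):
        nz = values[:, j][values[:, j] > 0]
        if nz.size == 0:
            raise ValueError(f"sample {data.columns[j]!r} has all-zero counts")
        uq[j] = np.quantile(nz, 0.75)
    scale = uq.mean() / uq
    return pd.DataFrame(values * scale[None, :], index=data.index,
                        columns=data.columns)


def remove_unwanted_variation(counts, housekeeping_genes, k: int = 1,
                              pseudocount: float = 1.0) -> pd.DataFrame:
    """One-factor unwanted-variation correction anchored on housekeeping genes.

    The factor is the first right-singular direction (per-sample loadings) of
    the row-centered log(count + 1) housekeeping submatrix; each gene's log
    expression is regressed on it and the fitted component subtracted, then
    exponentiated back to the count scale. ``k = 0`` is an identity
    passthrough.
    """
    data = _as_df(counts)
    if k == 0:
        return data.copy()
    if k != 1:
        raise ValueError("only k = 0 or k = 1 is supported")
    hk = [g for g in housekeeping_genes if g in data.index]
    if len(hk) < 3:
        raise ValueError(f"only {len(hk)} housekeeping genes present (need >= 3)")
    log = np.log(data.to_numpy(dtype=float) + pseudocount)
    hk_idx = data.index.get_indexer(hk)
    sub = log[hk_idx]
    sub_centered = sub - sub.mean(axis=1, keepdims=True)
    # loadings: first right-singular vector of the centered hk submatrix
    _, _, vt = np.linalg.svd(sub_centered, full_matrices=False)
    w = vt[0]  # per-sample loadings, unit norm
    w_centered = w - w.mean()
    denom = float(w_centered @ w_centered)
    log_centered = log - log.mean(axis=1, keepdims=True)
    beta = log_centered @ w_centered / denom  # per-gene slope
    corrected_log = log - np.outer(beta, w_centered)
    corrected = np.exp(corrected_log) - pseudocount
    return pd.DataFrame(np.clip(corrected, 0.0, None), index=data.index,
                        columns=data.columns)


def counts_to_tpm(counts, gene_lengths: pd.Series) -> pd.DataFrame:
    """Length-normalized transcripts per million; columns sum to 1e6."""
    data = _as_df(counts)
    missing = [g for g in data.index if g not in gene_lengths.index]
    if missing:
        raise ValueError(f"missing gene length for {missing[0]!r} "
                         f"({len(missing)} genes total)")
    lengths = gene_lengths.reindex(data.index).to_numpy(dtype=float)
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    rate = data.to_numpy(dtype=float) / lengths[:, None]
    tpm = rate / rate.sum(axis=0, keepdims=True) * 1e6
    return pd.DataFrame(tpm, index=data.index, columns=data.columns)


def project_regulon_activity(
    network: TranscriptionalNetwork,
    expression,
    weight_exponent: float = 1.0,
    min_per_side: int = 5,
    coverage_floor: float = 0.8,
) -> tuple[ActivityMatrix, dict[str, float]]:
    """Score the frozen regulons on a new cohort.

    Target sets and modes stay exactly as inferred; signatures and scores are
    computed on the new cohort. Regulons with less than ``coverage_floor`` of
    their targets present are flagged (scores NaN). Returns the activity
    matrix and the per-regulon target coverage.
    """
    data = _as_df(expression)
    present = set(data.index)
    coverage = {}
    for tf in network.tfs:
        members = network.regulon_members(tf)
        coverage[tf] = (sum(t in present for t in members) / len(members)
                        if members else 0.0)
    if all(c < coverage_floor for c in coverage.values()):
        raise ValueError("every regulon falls below the coverage floor on the "
                         "new cohort")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        act = regulon_activity(network, data, weight_exponent=weight_exponent,
                               min_per_side=min_per_side)
    out = act.data.copy()
    flagged = [tf for tf, c in coverage.items() if c < coverage_floor]
    if flagged:
        warnings.warn(f"{len(flagged)} regulon(s) below {coverage_floor:.0%} "
                      f"target coverage flagged: {flagged[:5]}", stacklevel=2)
        out.loc[flagged] = np.nan
    return ActivityMatrix(out, kind="two-tailed-regulon"), coverage


def compare_stage_groups(
    activity: ActivityMatrix | pd.DataFrame,
    stage_labels: pd.Series,
    invasive_classes: tuple[str, ...] = ("MIBC", "LP-invasive"),
    directions: pd.Series | None = None,
    correction: str = "Bonferroni",
) -> pd.DataFrame:
    """Per-regulon rank-sum comparison of activity between stage groups.

    ``median_difference`` is median(invasive) - median(noninvasive). When the
    regulon's recorded cell-cycle direction is supplied, ``consistent`` flags
    whether the sign of the median difference matches it (high-CC regulons
    are expected to gain activity in invasive disease).
    """
    data = activity.data if isinstance(activity, ActivityMatrix) else activity
    labels = stage_labels.reindex(data.columns)
    invasive = labels.isin(invasive_classes).to_numpy()
    nipuc = (labels == "NIPUC").to_numpy()
    if invasive.sum() == 0 or nipuc.sum() == 0:
        raise ValueError("both stage groups must be non-empty")
    records = []
    for tf in data.index:
        row = data.loc[tf].to_numpy(dtype=float)
        if np.isnan(row).all():
            records.append((tf, np.nan, np.nan))
            continue
        diff = float(np.nanmedian(row[invasive]) - np.nanmedian(row[nipuc]))
        p = float(sps.mannwhitneyu(row[invasive], row[nipuc],
                                   alternative="two-sided",
                                   method="asymptotic").pvalue)
        records.append((tf, diff, p))
    out = pd.DataFrame(records, columns=["tf", "median_difference", "p"])
    out = out.set_index("tf")
    tested = out["p"].notna()
    adj = np.full(len(out), np.nan)
    adj[tested.to_numpy()] = adjust_pvalues(out.loc[tested, "p"], correction)
    out["p_adjusted"] = adj
    out["significant"] = out["p_adjusted"] < 0.05
    if directions is not None:
        expected = directions.reindex(out.index).map({"high-CC": 1.0, "low-CC": -1.0})
        out["consistent"] = np.sign(out["median_difference"]) == expected
    return out


class UpperQuartileNormalizer(BaseEstimator, TransformerMixin):
    """Transformer form of :func:`upper_quartile_normalize` (stateless)."""

    def fit(self, X, y=None):
        return self

    def transform(self, X) -> pd.DataFrame:
        return upper_quartile_normalize(X)


class RUVNormalizer(BaseEstimator, TransformerMixin):
    """Transformer form of :func:`remove_unwanted_variation`.

    Parameters
    ----------
    housekeeping_genes : sequence of str
    k : int, default 1
        0 = passthrough, 1 = one-factor correction.
    """

    def __init__(self, housekeeping_genes=(), k: int = 1):
        self.housekeeping_genes = housekeeping_genes
        self.k = k

    def fit(self, X, y=None):
        return self

    def transform(self, X) -> pd.DataFrame:
        return remove_unwanted_variation(X, list(self.housekeeping_genes), k=self.k)
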