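"""Two-layer, two-cohort selection of cell-cycle-associated regulons.

Stage 1 (inference cohort): a regulon survives when its target set overlaps
the early-vs-late differential expression signature (hypergeometric test) AND
its activity differs between the early and late groups (rank-sum), both at
FDR q below the cutoff. Stage 2 (validation cohort with mitotic index): a
survivor is selected when its activity again separates the groups AND
correlates with mitotic index (Spearman), both at FDR q below the cutoff,
with concordant direction: the sign of rho must match the sign of the
enrichment score difference (median late minus median early).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .activity import regulon_activity
from .containers import GeneExpressionMatrix, TranscriptionalNetwork
from .stats import adjust_pvalues, hypergeometric_overlap, mitotic_correlation

__all__ = ["differential_signature", "two_layer_selection"]


def differential_signature(
    expression: GeneExpressionMatrix | pd.DataFrame,
    groups: pd.Series,
    q_cutoff: float = 0.01,
) -> list[str]:
    """Genes differing between early and late groups at BH q < cutoff.

    Gene-wise two-sided rank-sum (normal approximation with tie correction),
    BH-adjusted across all genes.
    """
    data = expression.data if isinstance(expression, GeneExpressionMatrix) else expression
    labels = groups.reindex(data.columns)
    early = data.columns[(labels == "early").to_numpy()]
    late = data.columns[(labels == "late").to_numpy()]
    if len(early) == 0 or len(late) == 0:
        raise ValueError("both early and late groups must be non-empty")
    x = data[late].to_numpy()
    y = data[early].to_numpy()
    p = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                         axis=1).pvalue
    q = adjust_pvalues(p, "BH")
    return [g for g, qi in zip(data.index, q) if qi < q_cutoff]


def two_layer_selection(
    network: TranscriptionalNetwork,
    expression_a: GeneExpressionMatrix | pd.DataFrame,
    groups_a: pd.Series,
    expression_b: GeneExpressionMatrix | pd.DataFrame,
    groups_b: pd.Series,
    mitotic_index: pd.Series | None = None,
    q_cutoff: float = 0.05,
    signature_q: float = 0.01,
    weight_exponent: float = 1.0,
    min_per_side: int = 5,
) -> pd.DataFrame:
    """Run the two-layer, two-cohort regulon selection.

    Returns one row per TF with the layer p/q values, the Spearman rho against
    mitotic index, the enrichment score difference and direction (computed on
    the validation cohort), and the final ``selected`` flag. A missing mitotic
    index skips the correlation layer (flagged in ``mitotic_tested``) and
    selection then requires only the remaining tests.
    """
    data_a = (expression_a.data if isinstance(expression_a, GeneExpressionMatrix)
              else expression_a)
    data_b = (expression_b.data if isinstance(expression_b, GeneExpressionMatrix)
              else expression_b)
    act_a = regulon_activity(network, data_a, weight_exponent=weight_exponent,
                             min_per_side=min_per_side).data
    act_b = regulon_activity(network, data_b, weight_exponent=weight_exponent,
                             min_per_side=min_per_side).data

    sig_genes = differential_signature(data_a, groups_a, q_cutoff=signature_q)
    universe = set(data_a.index)

    labels_a = groups_a.reindex(act_a.columns)
    mask_early_a = (labels_a == "early").to_numpy()
    mask_late_a = (labels_a == "late").to_numpy()
    labels_b = groups_b.reindex(act_b.columns)
    mask_early_b = (labels_b == "early").to_numpy()
    mask_late_b = (labels_b == "late").to_numpy()

    tfs = list(network.tfs)
    rows: dict[str, dict] = {tf: {} for tf in tfs}
    testable = []
    for tf in tfs:
        targets = [t for t in network.regulon_members(tf) if t in universe]
        row_a = act_a.loc[tf].to_numpy()
        if not targets or np.isnan(row_a).all():
            rows[tf]["testable"] = False
            continue
        rows[tf]["testable"] = True
        rows[tf]["overlap_p"] = hypergeometric_overlap(targets, sig_genes, universe)
        rows[tf]["group_a_p"] = float(sps.mannwhitneyu(
            row_a[mask_late_a], row_a[mask_early_a], alternative="two-sided",
            method="asymptotic").pvalue)
        testable.append(tf)

    overlap_q = adjust_pvalues([rows[tf]["overlap_p"] for tf in testable], "BH")
    group_a_q = adjust_pvalues([rows[tf]["group_a_p"] for tf in testable], "BH")
    for tf, oq, gq in zip(testable, overlap_q, group_a_q):
        rows[tf]["overlap_q"] = oq
        rows[tf]["group_a_q"] = gq
        rows[tf]["stage1_pass"] = bool(oq < q_cutoff and gq < q_cutoff)

    survivors = [tf for tf in testable if rows[tf]["stage1_pass"]]
    mito = None
    if mitotic_index is not None:
        mito = mitotic_index.reindex(act_b.columns).to_numpy(dtype=float)

    for tf in survivors:
        row_b = act_b.loc[tf].to_numpy()
        rows[tf]["group_b_p"] = float(sps.mannwhitneyu(
            row_b[mask_late_b], row_b[mask_early_b], alternative="two-sided",
            method="asymptotic").pvalue)
        rows[tf]["es_difference"] = float(
            np.median(row_b[mask_late_b]) - np.median(row_b[mask_early_b]))
        if mito is not None:
            rho, p = mitotic_correlation(row_b, mito)
            rows[tf]["rho"] = rho
            rows[tf]["rho_p"] = p

    group_b_q = adjust_pvalues([rows[tf]["group_b_p"] for tf in survivors], "BH")
    for tf, q in zip(survivors, group_b_q):
        rows[tf]["group_b_q"] = q
    if mito is not None:
        rho_q = adjust_pvalues([rows[tf]["rho_p"] for tf in survivors], "BH")
        for tf, q in zip(survivors, rho_q):
            rows[tf]["rho_q"] = q

    records = []
    for tf in tfs:
        r = rows[tf]
        selected = False
        concordant = np.nan
        direction = ""
        if r.get("stage1_pass"):
            des = r["es_difference"]
            direction = "high-CC" if des > 0 else "low-CC"
            stage2 = r["group_b_q"] < q_cutoff
            if mito is not None:
                concordant = bool(np.sign(r["rho"]) == np.sign(des))
                stage2 = stage2 and r["rho_q"] < q_cutoff and concordant
            selected = bool(stage2)
        records.append({
            "tf": tf,
            "testable": r.get("testable", False),
            "overlap_p": r.get("overlap_p", np.nan),
            "overlap_q": r.get("overlap_q", np.nan),
            "group_a_p": r.get("group_a_p", np.nan),
            "group_a_q": r.get("group_a_q", np.nan),
            "stage1_pass": bool(r.get("stage1_pass", False)),
            "group_b_p": r.get("group_b_p", np.nan),
            "group_b_q": r.get("group_b_q", np.nan),
            "rho": r.get("rho", np.nan),
            "rho_p": r.get("rho_p", np.nan),
            "rho_q": r.get("rho_q", np.nan),
            "mitotic_tested": mito is not None and r.get("stage1_pass", False),
            "es_difference": r.get("es_difference", np.nan),
            "direction": direction,
            "concordant": concordant,
            "selected": selected,
        })
    return pd.DataFrame.from_records(records, index="tf")
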