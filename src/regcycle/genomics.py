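"""Mutation filtering, tumor mutational burden, copy-number thresholding and
the chromosomal-instability statistic.

Mutation calls survive filtering when depth > 50, variant allele fraction
> 5% and alt reads > 10 (all strict — boundary values fail). TMB is the count
of surviving calls. Copy-number segment means (log-ratio, 0 = neutral) are
thresholded into five levels: > 1.05 high gain (2), > 0.1 gain (1),
< -0.75 homozygous loss (-2), < -0.1 loss (-1), else neutral (0); the four
cutoffs can be re-calibrated against a reference cohort by quantile matching.
Chromosomal instability (CIN) is the mean over chromosomes of the mean
absolute segment mean within each chromosome, unweighted by segment length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import MutationCallSet, SegmentProfile

__all__ = [
    "CnThresholds",
    "DEFAULT_THRESHOLDS",
    "filter_mutations",
    "tumor_mutational_burden",
    "calibrate_thresholds",
    "threshold_segments",
    "chromosomal_instability",
    "assign_gene_calls",
    "genomic_summary",
]

MIN_DEPTH = 50
MIN_ALT_READS = 10
MIN_VAF = 0.05


@dataclass(frozen=True)
class CnThresholds:
    """Five-level copy-number cutoffs on the segment-mean log-ratio scale."""

    gain: float = 0.1
    high_gain: float = 1.05
    loss: float = -0.1
    homozygous_loss: float = -0.75

    def __post_init__(self) -> None:
        if not self.homozygous_loss < self.loss < self.gain < self.high_gain:
            raise ValueError(
                "thresholds must satisfy homozygous_loss < loss < gain < high_gain"
            )
        if not self.loss < 0 < self.gain:
            # a shifted study distribution can push the neutral band off zero;
            # legal but worth flagging since 0 is the copy-neutral log-ratio
            warnings.warn("neutral band does not bracket 0 (loss < 0 < gain "
                          "violated)", stacklevel=3)


DEFAULT_THRESHOLDS = CnThresholds()


def filter_mutations(callset: MutationCallSet) -> MutationCallSet:
    """Keep calls with depth > 50, VAF > 5% and alt reads > 10 (strict)."""
    calls = callset.calls
    keep = ((calls["depth"] > MIN_DEPTH)
            & (calls["vaf"] > MIN_VAF)
            & (calls["alt_reads"] > MIN_ALT_READS))
    return MutationCallSet(sample_id=callset.sample_id,
                           calls=calls[keep].reset_index(drop=True))


def tumor_mutational_burden(callset: MutationCallSet) -> int:
    """Total number of mutations after filtering."""
    return int(len(filter_mutations(callset).calls))


def threshold_segments(profile: SegmentProfile,
                       thresholds: CnThresholds = DEFAULT_THRESHOLDS) -> np.ndarray:
    """Five-level call per segment: -2, -1, 0, 1 or 2 (strict inequalities)."""
    means = profile.segments["segment_mean"].to_numpy(dtype=float)
    calls = np.zeros(len(means), dtype=int)
    calls[means > thresholds.gain] = 1
    calls[means > thresholds.high_gain] = 2
    calls[means < thresholds.loss] = -1
    calls[means < thresholds.homozygous_loss] = -2
    return calls


_BOUNDARIES = (  # (lower level, upper level, CnThresholds field, default)
    (-2, -1, "homozygous_loss"),
    (-1, 0, "loss"),
    (0, 1, "gain"),
    (1, 2, "high_gain"),
)


def calibrate_thresholds(
    reference_values,
    reference_calls,
    study_values,
    defaults: CnThresholds = DEFAULT_THRESHOLDS,
) -> CnThresholds:
    """Quantile-match copy-number cutoffs from a thresholded reference cohort.

    For each boundary between adjacent call levels, the continuous value at
    which the reference call level changes is located, its empirical quantile
    in the reference distribution computed, and that quantile mapped onto the
    study cohort's continuous distribution. A boundary whose levels are
    absent from the reference falls back to the default with a warning.
    """
    ref_v = np.asarray(reference_values, dtype=float)
    ref_c = np.asarray(reference_calls, dtype=int)
    study = np.asarray(study_values, dtype=float)
    if ref_v.shape != ref_c.shape:
        raise ValueError("reference values and calls must align")
    out = {}
    for lo, hi, name in _BOUNDARIES:
        side_lo = ref_v[ref_c == lo]
        side_hi = ref_v[ref_c == hi]
        if len(side_lo) == 0 or len(side_hi) == 0:
            warnings.warn(f"reference lacks a call level at the {name} boundary; "
                          "falling back to the default cutoff", stacklevel=2)
            out[name] = getattr(defaults, name)
            continue
        # reference calls are monotone in the continuous value, so the level
        # change sits between the adjacent extremes
        cut = (side_lo.max() + side_hi.min()) / 2.0
        quantile = float(np.mean(ref_v < cut))
        out[name] = float(np.quantile(study, quantile))
    return CnThresholds(**out)


def chromosomal_instability(profile: SegmentProfile) -> float:
    """Mean over chromosomes of the mean |segment mean| within each chromosome."""
    segs = profile.segments
    if segs.empty:
        raise ValueError(f"sample {profile.sample_id!r}: empty segment profile")
    per_chrom = segs.groupby("chromosome", sort=False)["segment_mean"] \
                    .apply(lambda v: float(np.abs(v.to_numpy()).mean()))
    return float(per_chrom.mean())


def assign_gene_calls(
    profile: SegmentProfile,
    gene_map: pd.DataFrame,
    thresholds: CnThresholds = DEFAULT_THRESHOLDS,
) -> pd.Series:
    """Per-gene five-level call from the segment containing the gene midpoint.

    ``gene_map`` needs columns gene, chromosome, start, end. A gene spanning a
    breakpoint takes the call of the segment with the larger overlap; genes
    with no overlapping segment get a missing value.
    """
    calls = threshold_segments(profile, thresholds)
    segs = profile.segments
    out = {}
    for _, row in gene_map.iterrows():
        sub = segs[segs["chromosome"] == row["chromosome"]]
        if sub.empty:
            out[row["gene"]] = np.nan
            continue
        mid = (row["start"] + row["end"]) / 2.0
        hit = sub[(sub["start"] <= mid) & (mid <= sub["end"])]
        if len(hit) == 1:
            out[row["gene"]] = calls[hit.index[0]]
            continue
        overlap = (np.minimum(sub["end"], row["end"])
                   - np.maximum(sub["start"], row["start"])).clip(lower=0)
        if overlap.max() <= 0:
            out[row["gene"]] = np.nan
        else:
            out[row["gene"]] = calls[overlap.idxmax()]
    return pd.Series(out, name=profile.sample_id)


def genomic_summary(
    profiles: list[SegmentProfile],
    callsets: list[MutationCallSet],
    thresholds: CnThresholds = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Per-sample TMB and CIN table."""
    tmb = {cs.sample_id: tumor_mutational_burden(cs) for cs in callsets}
    cin = {p.sample_id: chromosomal_instability(p) for p in profiles}
    samples = sorted(set(tmb) | set(cin))
    return pd.DataFrame({
        "tmb": pd.Series(tmb).reindex(samples),
        "cin": pd.Series(cin).reindex(samples),
    }, index=pd.Index(samples, name="sample"))
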