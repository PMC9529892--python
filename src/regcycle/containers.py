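"""Validated in-memory containers shared by every pipeline stage.

All tabular payloads are pandas objects; the wrappers add the invariants the
pipeline relies on (unique identifiers, finite values, consistent shapes) and
fail loudly at construction time rather than deep inside an analysis stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

EXPRESSION_SCALES = ("log-normalized", "raw-counts")
CELL_CYCLE_GROUPS = ("early", "late", "unassigned")
REGULON_CLUSTERS = ("high", "low", "unassigned")
STAGE_CLASSES = ("NIPUC", "LP-invasive", "MIBC", "unknown")


def _check_unique(labels: Sequence[str], what: str) -> None:
    seen = pd.Index(labels)
    if seen.has_duplicates:
        dups = seen[seen.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what}: {dups[:5]}")


@dataclass
class GeneExpressionMatrix:
    """Genes x samples expression matrix with a declared measurement scale.

    Parameters
    ----------
    data : DataFrame
        Rows are gene symbols, columns are sample identifiers.
    scale : str
        Either ``"log-normalized"`` (values may be negative) or
        ``"raw-counts"`` (values must be nonnegative).
    """

    data: pd.DataFrame
    scale: str = "log-normalized"

    def __post_init__(self) -> None:
        if self.scale not in EXPRESSION_SCALES:
            raise ValueError(f"scale must be one of {EXPRESSION_SCALES}, got {self.scale!r}")
        _check_unique(self.data.index, "gene identifiers")
        _check_unique(self.data.columns, "sample identifiers")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("expression values must be numeric")
        if not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite expression value at gene {self.data.index[bad[0]]!r}, "
                f"sample {self.data.columns[bad[1]]!r}"
            )
        if self.scale == "raw-counts" and (values < 0).any():
            raise ValueError("raw-counts matrix contains negative values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass
class GeneSetCollection:
    """Named gene sets (cell-cycle early/late lists, EMT, pluripotency, ...)."""

    sets: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            self.sets[name] = frozenset(members)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)


@dataclass
class PhenotypeTable:
    """Per-sample phenotype annotations.

    ``data`` is indexed by sample id and may carry any subset of the columns
    ``mitotic_index`` (nonnegative integer count per 10 high-power fields),
    ``cell_cycle_group`` (early/late/unassigned), ``regulon_cluster``
    (high/low/unassigned) and ``stage_class`` (NIPUC/LP-invasive/MIBC/unknown).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample identifiers")
        if "mitotic_index" in self.data.columns:
            mi = self.data["mitotic_index"].dropna()
            arr = mi.to_numpy()
            if len(arr) and (np.any(arr < 0) or np.any(arr != np.floor(arr))):
                raise ValueError("mitotic_index must be a nonnegative integer count")
        for col, allowed in (
            ("cell_cycle_group", CELL_CYCLE_GROUPS),
            ("regulon_cluster", REGULON_CLUSTERS),
            ("stage_class", STAGE_CLASSES),
        ):
            if col in self.data.columns:
                bad = set(self.data[col].dropna()) - set(allowed)
                if bad:
                    raise ValueError(f"invalid {col} values: {sorted(bad)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)


@dataclass
class SegmentProfile:
    """Copy-number segments of one sample (log-ratio means; 0 = neutral).

    ``segments`` columns: chromosome, start, end, segment_mean.
    """

    sample_id: str
    segments: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"chromosome", "start", "end", "segment_mean"}
        missing = required - set(self.segments.columns)
        if missing:
            raise ValueError(f"segment table missing columns: {sorted(missing)}")
        if (self.segments["start"].to_numpy() >= self.segments["end"].to_numpy()).any():
            raise ValueError(f"sample {self.sample_id!r}: segment with start >= end")
        if not np.isfinite(self.segments["segment_mean"].to_numpy()).all():
            raise ValueError(f"sample {self.sample_id!r}: non-finite segment mean")


@dataclass
class MutationCallSet:
    """Mutation calls of one sample with depth / alt-read / VAF evidence.

    ``calls`` columns: gene, depth, alt_reads, vaf.
    """

    sample_id: str
    calls: pd.DataFrame
    vaf_tolerance: float = 0.01

    def __post_init__(self) -> None:
        required = {"gene", "depth", "alt_reads", "vaf"}
        missing = required - set(self.calls.columns)
        if missing:
            raise ValueError(f"mutation table missing columns: {sorted(missing)}")
        depth = self.calls["depth"].to_numpy()
        alt = self.calls["alt_reads"].to_numpy()
        vaf = self.calls["vaf"].to_numpy()
        if (alt < 0).any() or (alt > depth).any():
            raise ValueError(f"sample {self.sample_id!r}: alt_reads outside [0, depth]")
        if (vaf < 0).any() or (vaf > 1).any():
            raise ValueError(f"sample {self.sample_id!r}: VAF outside [0, 1]")
        with np.errstate(divide="ignore", invalid="ignore"):
            implied = np.where(depth > 0, alt / np.maximum(depth, 1), 0.0)
        if np.any(np.abs(vaf - implied) > self.vaf_tolerance):
            raise ValueError(f"sample {self.sample_id!r}: VAF inconsistent with alt/depth")


@dataclass
class TranscriptionalNetwork:
    """Inferred TF -> target network: signed, MI-weighted regulons.

    ``edges`` columns: tf, target, mode (+1/-1), weight (MI, > 0).
    ``tfs`` lists every TF evaluated, including those whose regulon came out
    empty (retained but flagged via :meth:`empty_tfs`).
    """

    universe: list[str]
    edges: pd.DataFrame
    tfs: list[str]
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"tf", "target", "mode", "weight"}
        missing = required - set(self.edges.columns)
        if missing:
            raise ValueError(f"edge table missing columns: {sorted(missing)}")
        uni = set(self.universe)
        edge_nodes = set(self.edges["tf"]) | set(self.edges["target"])
        if not edge_nodes <= uni:
            raise ValueError(f"edges reference genes outside the universe: "
                             f"{sorted(edge_nodes - uni)[:5]}")
        if (self.edges["tf"].to_numpy() == self.edges["target"].to_numpy()).any():
            raise ValueError("self-edges are forbidden")
        if not set(np.unique(self.edges["mode"])) <= {-1, 1}:
            raise ValueError("modes must be +1 or -1")
        if len(self.edges) and (self.edges["weight"].to_numpy() <= 0).any():
            raise ValueError("edge weights must be strictly positive")

    def regulon(self, tf: str) -> pd.DataFrame:
        """Target table (target, mode, weight) of one TF."""
        if tf not in set(self.tfs):
            raise KeyError(f"unknown TF {tf!r}")
        return self.edges[self.edges["tf"] == tf].reset_index(drop=True)

    def regulon_members(self, tf: str) -> dict[str, int]:
        """Mapping target -> mode for one TF."""
        sub = self.regulon(tf)
        return dict(zip(sub["target"], sub["mode"].astype(int)))

    def empty_tfs(self) -> list[str]:
        with_targets = set(self.edges["tf"])
        return [tf for tf in self.tfs if tf not in with_targets]

    def n_edges(self) -> int:
        return len(self.edges)


@dataclass
class ActivityMatrix:
    """Regulon (or gene-set) x sample enrichment scores.

    ``kind`` is ``"two-tailed-regulon"`` (scores in [-2, 2]) or
    ``"single-set"`` (scores in [-1, 1]).
    """

    data: pd.DataFrame
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in ("two-tailed-regulon", "single-set"):
            raise ValueError(f"unknown activity kind {self.kind!r}")
        _check_unique(self.data.index, "regulon/set names")
        _check_unique(self.data.columns, "sample identifiers")
        bound = 2.0 if self.kind == "two-tailed-regulon" else 1.0
        values = self.data.to_numpy()
        finite = values[np.isfinite(values)]
        if len(finite) and np.abs(finite).max() > bound + 1e-9:
            raise ValueError(f"{self.kind} scores exceed [-{bound}, {bound}]")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)
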