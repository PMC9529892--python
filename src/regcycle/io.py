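"""Readers and writers for the plain-text formats the pipeline touches.

Expression: TSV, genes x samples. Gene sets: GMT. Copy-number segments: SEG.
Mutations: MAF-like TSV (sample, gene, depth, alt_reads, vaf). Phenotype: TSV
keyed by sample. Network: TSV edge list plus a JSON parameter sidecar.

Every reader rejects malformed input with an error that names the offending
location; values are never silently coerced.
"""

from __future__ import annotations

import json
import os
from typing import Iterable

import numpy as np
import pandas as pd

from .containers import (
    GeneExpressionMatrix,
    GeneSetCollection,
    MutationCallSet,
    PhenotypeTable,
    SegmentProfile,
    TranscriptionalNetwork,
)

NETWORK_SCHEMA_VERSION = 1


# ---------------------------------------------------------------------------
# expression


def read_expression(path: str, scale: str = "log-normalized") -> GeneExpressionMatrix:
    """Read a genes x samples TSV (first column = gene symbol, header row).

    Duplicate gene rows are collapsed by keeping the row with the highest mean
    value. Non-numeric cells and duplicate sample headers are errors.
    """
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
    samples = header[1:]
    if len(set(samples)) != len(samples):
        dups = sorted({s for s in samples if samples.count(s) > 1})
        raise ValueError(f"{path}: duplicate sample header(s) {dups}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.columns = samples
    df.index = df.index.astype(str).str.strip()
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any() or df[col].isna().any():
            row = df.index[(bad | df[col].isna()).to_numpy()][0]
            raise ValueError(f"{path}: non-numeric value at gene {row!r}, sample {col!r}")
        values[:, j] = converted.to_numpy()
    out = pd.DataFrame(values, index=df.index, columns=df.columns)
    if out.index.has_duplicates:
        # keep the duplicate row with the highest mean expression
        means = out.mean(axis=1).to_numpy()
        order = np.lexsort((-means, out.index.to_numpy()))
        out = out.iloc[order]
        out = out[~out.index.duplicated(keep="first")]
        # restore first-occurrence order of the original file
        first = pd.Index(dict.fromkeys(df.index))
        out = out.loc[first]
    return GeneExpressionMatrix(out, scale=scale)


def write_expression(matrix: GeneExpressionMatrix, path: str) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="gene")


# ---------------------------------------------------------------------------
# gene sets (GMT)


def read_gmt(path: str) -> GeneSetCollection:
    """Read a GMT file: name, description, then member genes, tab-separated."""
    sets: dict[str, frozenset[str]] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name = fields[0].strip()
            members = {g.strip() for g in fields[2:] if g.strip()}
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            sets[name] = frozenset(members)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str, description: str = "na") -> None:
    with open(path, "w") as handle:
        for name in collection.names():
            members = sorted(collection[name])
            handle.write("\t".join([name, description, *members]) + "\n")


# ---------------------------------------------------------------------------
# copy-number segments (SEG)


def read_seg(path: str) -> list[SegmentProfile]:
    """Read a SEG file into one profile per sample.

    Required columns (case-insensitive): Sample, Chromosome, Start, End,
    Segment_Mean. Chromosome labels are preserved verbatim; coordinates are
    1-based inclusive labels and never used arithmetically.
    """
    df = pd.read_csv(path, sep="\t")
    colmap = {c.lower(): c for c in df.columns}
    required = {"sample": "sample_id", "chromosome": "chromosome", "start": "start",
                "end": "end", "segment_mean": "segment_mean"}
    missing = [k for k in required if k not in colmap]
    if missing:
        raise ValueError(f"{path}: missing SEG column(s) {missing}")
    df = df.rename(columns={colmap[k]: v for k, v in required.items()})
    bad = df.index[df["start"].to_numpy() >= df["end"].to_numpy()]
    if len(bad):
        raise ValueError(f"{path}: row {bad[0] + 2}: Start >= End")
    profiles = []
    for sample, sub in df.groupby("sample_id", sort=False):
        profiles.append(SegmentProfile(
            sample_id=str(sample),
            segments=sub[["chromosome", "start", "end", "segment_mean"]]
            .reset_index(drop=True),
        ))
    return profiles


def write_seg(profiles: Iterable[SegmentProfile], path: str) -> None:
    rows = []
    for prof in profiles:
        sub = prof.segments.copy()
        sub.insert(0, "Sample", prof.sample_id)
        rows.append(sub)
    out = pd.concat(rows, ignore_index=True)
    out.columns = ["Sample", "Chromosome", "Start", "End", "Segment_Mean"]
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# mutation calls


def read_mutations(path: str) -> list[MutationCallSet]:
    """Read a MAF-like TSV requiring columns sample, gene, depth, alt_reads, vaf."""
    df = pd.read_csv(path, sep="\t")
    required = ["sample", "gene", "depth", "alt_reads", "vaf"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mutation column(s) {missing}")
    out = []
    for sample, sub in df.groupby("sample", sort=False):
        out.append(MutationCallSet(
            sample_id=str(sample),
            calls=sub[["gene", "depth", "alt_reads", "vaf"]].reset_index(drop=True),
        ))
    return out


def write_mutations(callsets: Iterable[MutationCallSet], path: str) -> None:
    rows = []
    for cs in callsets:
        sub = cs.calls.copy()
        sub.insert(0, "sample", cs.sample_id)
        rows.append(sub)
    pd.concat(rows, ignore_index=True).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# phenotype


def read_phenotype(path: str) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return PhenotypeTable(df)


def write_phenotype(table: PhenotypeTable, path: str) -> None:
    table.data.to_csv(path, sep="\t", index_label="sample")


# ---------------------------------------------------------------------------
# network (edge-list TSV + JSON sidecar)


def _sidecar_path(path: str) -> str:
    return os.path.splitext(path)[0] + ".params.json"


def write_network(network: TranscriptionalNetwork, path: str) -> None:
    """Write the edge list as TSV and parameters/universe as a JSON sidecar."""
    edges = network.edges.copy()
    edges["weight"] = edges["weight"].map(lambda v: float(v).hex())
    edges.to_csv(path, sep="\t", index=False)
    sidecar = {
        "schema_version": NETWORK_SCHEMA_VERSION,
        "universe": list(network.universe),
        "tfs": list(network.tfs),
        "parameters": network.parameters,
    }
    with open(_sidecar_path(path), "w") as handle:
        json.dump(sidecar, handle, indent=1)


def read_network(path: str) -> TranscriptionalNetwork:
    with open(_sidecar_path(path)) as handle:
        sidecar = json.load(handle)
    version = sidecar.get("schema_version")
    if version != NETWORK_SCHEMA_VERSION:
        raise ValueError(f"{path}: unsupported network schema version {version!r}")
    edges = pd.read_csv(path, sep="\t", dtype={"tf": str, "target": str})
    if len(edges):
        edges["weight"] = edges["weight"].map(float.fromhex)
        edges["mode"] = edges["mode"].astype(int)
    else:
        edges = pd.DataFrame(columns=["tf", "target", "mode", "weight"])
    return TranscriptionalNetwork(
        universe=list(sidecar["universe"]),
        edges=edges,
        tfs=list(sidecar["tfs"]),
        parameters=sidecar["parameters"],
    )


# ---------------------------------------------------------------------------
# misc small formats


def read_tf_list(path: str) -> list[str]:
    """Plain text, one TF symbol per line; blank lines ignored."""
    with open(path) as handle:
        tfs = [line.strip() for line in handle if line.strip()]
    if len(set(tfs)) != len(tfs):
        raise ValueError(f"{path}: duplicate TF symbols")
    return tfs


def write_activity(activity, path: str) -> None:
    activity.data.to_csv(path, sep="\t", index_label="regulon")
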