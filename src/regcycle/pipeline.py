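"""End-to-end orchestration: simulate -> infer -> activity -> grouping ->
selection -> High/Low clustering -> duals -> genomics -> cross-cohort.

A single YAML config drives every stage; one master seed deterministically
derives per-stage seeds, every intermediate artifact is written in the
package's text formats, and a JSON manifest records parameters, seeds and a
content hash per output so identical config + seed reproduces identical
hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
import warnings
from dataclasses import asdict, dataclass, field, fields

import numpy as np
import pandas as pd
import yaml

from . import io as rcio
from .activity import regulon_activity
from .cluster import assign_cell_cycle_groups, assign_regulon_clusters
from .containers import GeneExpressionMatrix, GeneSetCollection, PhenotypeTable
from .crosscohort import (
    compare_stage_groups,
    counts_to_tpm,
    project_regulon_activity,
    remove_unwanted_variation,
    upper_quartile_normalize,
)
from .duals import agreement_clustering, find_duals
from .genomics import DEFAULT_THRESHOLDS, genomic_summary
from .network import build_regulons
from .selection import two_layer_selection
from .simulate import SimulationConfig, simulate_cohort, simulate_mutations, \
    simulate_segments, simulate_stage_cohort
from .stats import rank_sum_test

logger = logging.getLogger("regcycle")

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (see ``load_config`` for YAML)."""

    output_dir: str = "regcycle_out"
    seed: int = 0
    simulate: dict = field(default_factory=dict)
    network: dict = field(default_factory=dict)
    activity: dict = field(default_factory=dict)
    clustering: dict = field(default_factory=dict)
    selection: dict = field(default_factory=dict)
    duals: dict = field(default_factory=dict)
    genomics: dict = field(default_factory=dict)
    cross_cohort: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.simulate.setdefault("enabled", True)
        self.duals.setdefault("enabled", True)
        self.genomics.setdefault("enabled", True)
        self.cross_cohort.setdefault("enabled", True)
        if not self.simulate["enabled"]:
            required = ["expr_a", "pheno_a", "expr_b", "pheno_b", "tfs", "cc_sets"]
            missing = [k for k in required if k not in self.inputs]
            if missing:
                raise ValueError(f"simulate disabled but inputs missing: {missing}")
            for key, path in self.inputs.items():
                if not os.path.exists(path):
                    raise FileNotFoundError(f"input {key!r}: {path} does not exist")


def load_config(path: str) -> PipelineConfig:
    with open(path) as handle:
        raw = yaml.safe_load(handle) or {}
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**raw)


def _stage_seed(master: int, index: int) -> int:
    return int(np.random.default_rng([int(master), index]).integers(0, 2**31 - 1))


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns (and writes) the manifest."""
    out = config.output_dir
    os.makedirs(out, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}}

    def record(stage: str, files: list[str], params: dict, t0: float) -> None:
        manifest["stages"][stage] = {
            "params": params,
            "outputs": {os.path.basename(f): _sha256(f) for f in files},
            "seconds": round(time.time() - t0, 3),
        }
        logger.info("stage %s done in %.1fs", stage, time.time() - t0)

    # ---------------------------------------------------------------- simulate
    t0 = time.time()
    if config.simulate["enabled"]:
        sim = {k: v for k, v in config.simulate.items()
               if k not in ("enabled", "n_samples_b", "stage_cohort")}
        sim_cfg = SimulationConfig(**sim, seed=_stage_seed(config.seed, 0))
        expr_a, pheno_a, truth_a = simulate_cohort(sim_cfg)
        cfg_b = SimulationConfig(**{**asdict(sim_cfg),
                                    "n_samples": config.simulate.get(
                                        "n_samples_b", sim_cfg.n_samples),
                                    "seed": _stage_seed(config.seed, 1)})
        expr_b, pheno_b, truth_b = simulate_cohort(cfg_b)
        segments = simulate_segments(cfg_b, pheno_b)
        mutations, _ = simulate_mutations(cfg_b, pheno_b)
        stage_opts = config.simulate.get("stage_cohort", {})
        cfg_c = SimulationConfig(**{**asdict(sim_cfg),
                                    "seed": _stage_seed(config.seed, 2)})
        counts_c, pheno_c, _ = simulate_stage_cohort(
            cfg_c,
            n_nipuc=stage_opts.get("n_nipuc", 60),
            n_invasive=stage_opts.get("n_invasive", 60),
            stage_shift=stage_opts.get("stage_shift", 2.0),
        )
        tf_names = [tf for tf in truth_a.tf_programs]
        cc_sets = GeneSetCollection({
            "cell_cycle_early": frozenset(truth_a.early_genes),
            "cell_cycle_late": frozenset(truth_a.late_genes),
        })
        rng_len = np.random.default_rng([config.seed, 5])
        lengths = pd.Series(
            rng_len.integers(500, 5000, size=len(counts_c.data.index)).astype(float),
            index=counts_c.data.index, name="length")
        housekeeping = [g for g in expr_a.gene_ids if g.startswith("NULL")][:11]

        paths = {
            "expr_a": f"{out}/expr_a.tsv", "expr_b": f"{out}/expr_b.tsv",
            "pheno_a": f"{out}/pheno_a.tsv", "pheno_b": f"{out}/pheno_b.tsv",
            "counts_c": f"{out}/counts_c.tsv", "pheno_c": f"{out}/pheno_c.tsv",
            "seg": f"{out}/segments.seg", "mutations": f"{out}/mutations.tsv",
            "cc_sets": f"{out}/cc_sets.gmt", "tfs": f"{out}/tfs.txt",
            "lengths": f"{out}/lengths.tsv", "housekeeping": f"{out}/housekeeping.txt",
            "truth": f"{out}/truth.json",
        }
        rcio.write_expression(expr_a, paths["expr_a"])
        rcio.write_expression(expr_b, paths["expr_b"])
        rcio.write_phenotype(pheno_a, paths["pheno_a"])
        rcio.write_phenotype(pheno_b, paths["pheno_b"])
        rcio.write_expression(counts_c, paths["counts_c"])
        rcio.write_phenotype(pheno_c, paths["pheno_c"])
        rcio.write_seg(segments, paths["seg"])
        rcio.write_mutations(mutations, paths["mutations"])
        rcio.write_gmt(cc_sets, paths["cc_sets"])
        with open(paths["tfs"], "w") as handle:
            handle.write("\n".join(tf_names) + "\n")
        lengths.to_csv(paths["lengths"], sep="\t", header=True, index_label="gene")
        with open(paths["housekeeping"], "w") as handle:
            handle.write("\n".join(housekeeping) + "\n")
        with open(paths["truth"], "w") as handle:
            json.dump(truth_a.to_jsonable(), handle, sort_keys=True)
        record("simulate", list(paths.values()), asdict(sim_cfg), t0)
    else:
        paths = dict(config.inputs)
        expr_a = rcio.read_expression(paths["expr_a"])
        pheno_a = rcio.read_phenotype(paths["pheno_a"])
        expr_b = rcio.read_expression(paths["expr_b"])
        pheno_b = rcio.read_phenotype(paths["pheno_b"])
        tf_names = rcio.read_tf_list(paths["tfs"])
        cc_sets = rcio.read_gmt(paths["cc_sets"])
        segments = rcio.read_seg(paths["seg"]) if "seg" in paths else []
        mutations = (rcio.read_mutations(paths["mutations"])
                     if "mutations" in paths else [])
        counts_c = (rcio.read_expression(paths["counts_c"], scale="raw-counts")
                    if "counts_c" in paths else None)
        pheno_c = (rcio.read_phenotype(paths["pheno_c"])
                   if "pheno_c" in paths else None)
        lengths = (pd.read_csv(paths["lengths"], sep="\t", index_col=0)["length"]
                   if "lengths" in paths else None)
        housekeeping = (rcio.read_tf_list(paths["housekeeping"])
                        if "housekeeping" in paths else [])

    # ----------------------------------------------------------------- network
    t0 = time.time()
    net_params = dict(alpha=config.network.get("alpha", 0.01),
                      n_permutations=config.network.get("n_permutations", 1000),
                      dpi_tolerance=config.network.get("dpi_tolerance", 0.1),
                      seed=_stage_seed(config.seed, 10))
    network = build_regulons(expr_a, tf_names, **net_params)
    net_path = f"{out}/network.tsv"
    rcio.write_network(network, net_path)
    record("network", [net_path, f"{out}/network.params.json"], net_params, t0)

    # ---------------------------------------------------------------- activity
    t0 = time.time()
    act_params = dict(weight_exponent=config.activity.get("weight_exponent", 1.0),
                      min_per_side=config.activity.get("min_per_side", 5))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        act_a = regulon_activity(network, expr_a, **act_params)
        act_b = regulon_activity(network, expr_b, **act_params)
    rcio.write_activity(act_a, f"{out}/activity_a.tsv")
    rcio.write_activity(act_b, f"{out}/activity_b.tsv")
    record("activity", [f"{out}/activity_a.tsv", f"{out}/activity_b.tsv"],
           act_params, t0)

    # ------------------------------------------------------------- cc grouping
    t0 = time.time()
    n_reps = config.clustering.get("n_reps", 1000)
    early = cc_sets["cell_cycle_early"]
    late = cc_sets["cell_cycle_late"]
    groups_a = assign_cell_cycle_groups(expr_a, early, late,
                                        seed=_stage_seed(config.seed, 20),
                                        n_reps=n_reps)
    groups_b = assign_cell_cycle_groups(expr_b, early, late,
                                        seed=_stage_seed(config.seed, 21),
                                        n_reps=n_reps)
    groups_a.to_frame().to_csv(f"{out}/groups_a.tsv", sep="\t", index_label="sample")
    groups_b.to_frame().to_csv(f"{out}/groups_b.tsv", sep="\t", index_label="sample")
    record("cell_cycle_groups", [f"{out}/groups_a.tsv", f"{out}/groups_b.tsv"],
           {"n_reps": n_reps}, t0)

    # --------------------------------------------------------------- selection
    t0 = time.time()
    sel_params = dict(q_cutoff=config.selection.get("q_cutoff", 0.05),
                      signature_q=config.selection.get("signature_q", 0.01))
    mito = (pheno_b.data["mitotic_index"]
            if "mitotic_index" in pheno_b.data.columns else None)
    selection = two_layer_selection(network, expr_a, groups_a, expr_b, groups_b,
                                    mitotic_index=mito, **sel_params, **act_params)
    selection.to_csv(f"{out}/selection.tsv", sep="\t")
    record("selection", [f"{out}/selection.tsv"], sel_params, t0)
    selected = list(selection.index[selection["selected"]])

    # ---------------------------------------------------- High/Low clustering
    t0 = time.time()
    cluster_tfs = selected if len(selected) >= 2 else list(
        selection.index[selection["testable"]])
    directions = selection["direction"].replace("", np.nan).dropna()
    clusters_b = assign_regulon_clusters(act_b.data.loc[cluster_tfs], directions,
                                         seed=_stage_seed(config.seed, 30),
                                         n_reps=n_reps)
    clusters_b.to_frame().to_csv(f"{out}/regulon_clusters.tsv", sep="\t",
                                 index_label="sample")
    record("regulon_clusters", [f"{out}/regulon_clusters.tsv"],
           {"n_tfs": len(cluster_tfs)}, t0)

    # ------------------------------------------------------------------- duals
    if config.duals["enabled"]:
        t0 = time.time()
        dual_params = dict(min_shared=config.duals.get("min_shared", 10),
                           alpha=config.duals.get("alpha", 0.05))
        dual_tfs = selected if len(selected) >= 2 else list(network.tfs)
        records_ = find_duals(network, expr_a, tfs=dual_tfs, **dual_params)
        dual_df = pd.DataFrame([{
            "tf_a": r.tf_a, "tf_b": r.tf_b, "n_shared": r.n_shared,
            "overlap_p": r.overlap_p, "overlap_q": r.overlap_q,
            "agreement": r.agreement, "direction": r.direction,
        } for r in records_])
        dual_df.to_csv(f"{out}/duals.tsv", sep="\t", index=False)
        record("duals", [f"{out}/duals.tsv"], dual_params, t0)

    # ---------------------------------------------------------------- genomics
    if config.genomics["enabled"] and segments and mutations:
        t0 = time.time()
        summary = genomic_summary(segments, mutations)
        summary["group"] = clusters_b.reindex(summary.index)
        tested = summary.dropna(subset=["group"])
        comparisons = {}
        for metric in ("tmb", "cin"):
            sub = tested.dropna(subset=[metric])
            if sub["group"].nunique() == 2:
                comparisons[metric] = rank_sum_test(sub[metric].to_numpy(),
                                                    sub["group"].to_numpy())
        summary.to_csv(f"{out}/genomic_summary.tsv", sep="\t")
        with open(f"{out}/genomic_tests.json", "w") as handle:
            json.dump(comparisons, handle, sort_keys=True)
        record("genomics", [f"{out}/genomic_summary.tsv", f"{out}/genomic_tests.json"],
               {"thresholds": asdict(DEFAULT_THRESHOLDS)}, t0)

    # ------------------------------------------------------------ cross-cohort
    if config.cross_cohort["enabled"] and counts_c is not None:
        t0 = time.time()
        norm = upper_quartile_normalize(counts_c)
        if len(housekeeping) >= 3:
            norm = remove_unwanted_variation(norm, housekeeping, k=1)
        tpm = counts_to_tpm(norm, lengths) if lengths is not None else norm
        log_tpm = np.log2(tpm + 1.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            act_c, coverage = project_regulon_activity(network, log_tpm, **act_params)
        stage_cmp = compare_stage_groups(
            act_c, pheno_c.data["stage_class"],
            directions=directions if len(directions) else None)
        stage_cmp.to_csv(f"{out}/cross_cohort.tsv", sep="\t")
        record("cross_cohort", [f"{out}/cross_cohort.tsv"],
               {"n_housekeeping": len(housekeeping)}, t0)

    with open(f"{out}/manifest.json", "w") as handle:
        json.dump(manifest, handle, indent=1, sort_keys=True)
    return manifest
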