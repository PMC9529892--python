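"""Synthetic cohorts with planted regulatory and genomic ground truth.

The generator emulates the statistical structure of a papillary urothelial
carcinoma cohort as the pipeline sees it: a bimodal latent cell-cycle
phenotype, signed TF -> target regulons driven by it (two opposed TF programs
plus inert null TFs), planted co-activating and antagonistic TF pairs with
shared targets, a mitotic-index count whose rate rises with the latent
phenotype, per-chromosome copy-number segment means with group-dependent
dispersion, and mutation calls with realistic depth/VAF spread. Every
generator is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .containers import (
    GeneExpressionMatrix,
    MutationCallSet,
    PhenotypeTable,
    SegmentProfile,
)

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_cohort",
    "simulate_segments",
    "simulate_mutations",
    "simulate_batch_counts",
    "simulate_stage_cohort",
]


@dataclass
class SimulationConfig:
    """Knobs of the planted-truth cohort generator.

    The latent cell-cycle activity is a two-component Gaussian mixture with
    component means +-``group_separation``/2 and unit within-component
    variance; the group label ("late" = high activity) derives from the sign
    of the latent value. TF expression is ``sign * latent`` plus Gaussian
    noise; target expression is ``effect_size * mode * TF`` plus independent
    Gaussian noise, all on the log scale.
    """

    n_samples: int = 300
    n_tfs_high: int = 10
    n_tfs_low: int = 10
    n_tfs_null: int = 0
    n_pos_targets: int = 20
    n_neg_targets: int = 10
    n_null_genes: int = 80
    n_cell_cycle_genes: int = 40  # per early / late list, drawn from targets
    effect_size: float = 1.0
    noise_scale: float = 2.0
    tf_noise_scale: float = 1.7
    group_separation: float = 4.0
    # planted dual pairs
    n_coactivating_pairs: int = 0
    n_antagonistic_pairs: int = 0
    n_shared_targets: int = 15
    # mitotic index (count per 10 high-power fields): Poisson with log link
    mitotic_base_rate: float = 3.0
    mitotic_slope: float = 0.5
    # copy-number segments
    n_chromosomes: int = 22
    segments_per_chromosome: int = 3
    segment_sd_low: float = 0.05
    segment_dispersion_ratio: float = 3.0
    # mutation calls
    mutation_rate_low: float = 20.0
    mutation_rate_ratio: float = 2.0
    mean_depth: float = 150.0
    vaf_alpha: float = 3.0
    vaf_beta: float = 9.0
    fraction_failing: float = 0.0  # per filter clause
    # raw-counts mode
    count_baseline_log2: float = 5.0
    count_dispersion: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        counts = [
            self.n_samples, self.n_pos_targets + self.n_neg_targets,
            self.n_tfs_high + self.n_tfs_low + self.n_tfs_null,
        ]
        if any(c <= 0 for c in counts):
            raise ValueError("sample, TF and per-TF target counts must be positive")
        if self.effect_size < 0 or self.noise_scale <= 0:
            raise ValueError("effect size must be >= 0 and noise scale > 0")
        need_high = 2 * self.n_coactivating_pairs + self.n_antagonistic_pairs
        if need_high > self.n_tfs_high or self.n_antagonistic_pairs > self.n_tfs_low:
            raise ValueError(
                "planted dual pairs exceed the TF namespace: "
                f"need {need_high} high-program and {self.n_antagonistic_pairs} "
                f"low-program TFs, have {self.n_tfs_high}/{self.n_tfs_low}"
            )


@dataclass
class SimulationTruth:
    """Planted ground truth accompanying a simulated cohort."""

    latent: pd.Series
    groups: pd.Series  # "early" / "late", late = latent > 0
    regulons: dict[str, dict[str, int]]  # tf -> {target: mode}
    tf_programs: dict[str, str]  # tf -> high / low / null
    dual_pairs: list[tuple[str, str, str]]  # (tf_a, tf_b, direction)
    early_genes: list[str]
    late_genes: list[str]
    config: SimulationConfig

    def planted_edges(self) -> set[tuple[str, str]]:
        return {(tf, t) for tf, reg in self.regulons.items() for t in reg}

    def edge_modes(self) -> dict[tuple[str, str], int]:
        return {(tf, t): m for tf, reg in self.regulons.items() for t, m in reg.items()}

    def to_jsonable(self) -> dict:
        return {
            "latent": self.latent.to_dict(),
            "groups": self.groups.to_dict(),
            "regulons": self.regulons,
            "tf_programs": self.tf_programs,
            "dual_pairs": [list(p) for p in self.dual_pairs],
            "early_genes": self.early_genes,
            "late_genes": self.late_genes,
            "config": asdict(self.config),
        }


def _latent_and_groups(config: SimulationConfig, rng: np.random.Generator,
                       n: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    n = config.n_samples if n is None else n
    component = rng.integers(0, 2, size=n)
    centers = np.where(component == 1, config.group_separation / 2.0,
                       -config.group_separation / 2.0)
    latent = centers + rng.standard_normal(n)
    groups = np.where(latent > 0, "late", "early")
    return latent, groups


def simulate_cohort(
    config: SimulationConfig,
    scale: str = "log-normalized",
) -> tuple[GeneExpressionMatrix, PhenotypeTable, SimulationTruth]:
    """Draw one cohort: expression, phenotype (mitotic index + group), truth."""
    config.validate()
    rng = np.random.default_rng([int(config.seed), 0])
    samples = [f"S{i:04d}" for i in range(config.n_samples)]
    latent, groups = _latent_and_groups(config, rng)

    tf_names = (
        [f"TFH{i:02d}" for i in range(config.n_tfs_high)]
        + [f"TFL{i:02d}" for i in range(config.n_tfs_low)]
        + [f"TFN{i:02d}" for i in range(config.n_tfs_null)]
    )
    tf_programs = {tf: ("high" if tf.startswith("TFH") else
                        "low" if tf.startswith("TFL") else "null")
                   for tf in tf_names}

    rows: dict[str, np.ndarray] = {}
    n = config.n_samples
    for tf in tf_names:
        sign = {"high": 1.0, "low": -1.0, "null": 0.0}[tf_programs[tf]]
        rows[tf] = sign * latent + config.tf_noise_scale * rng.standard_normal(n)

    regulons: dict[str, dict[str, int]] = {tf: {} for tf in tf_names}
    for tf in tf_names:
        for j in range(config.n_pos_targets + config.n_neg_targets):
            mode = 1 if j < config.n_pos_targets else -1
            target = f"{tf}_t{j:02d}"
            rows[target] = (config.effect_size * mode * rows[tf]
                            + config.noise_scale * rng.standard_normal(n))
            regulons[tf][target] = mode

    # planted dual pairs: co-activating pairs within the high program,
    # antagonistic pairs across programs (high vs low); each pair gets its
    # own block of shared targets with per-target sign mixing.
    dual_pairs: list[tuple[str, str, str]] = []
    high = [tf for tf in tf_names if tf_programs[tf] == "high"]
    low = [tf for tf in tf_names if tf_programs[tf] == "low"]
    pair_specs = []
    for p in range(config.n_coactivating_pairs):
        pair_specs.append((high[2 * p], high[2 * p + 1], "co-activating"))
    for p in range(config.n_antagonistic_pairs):
        pair_specs.append((high[2 * config.n_coactivating_pairs + p], low[p],
                           "antagonistic"))
    for idx, (tf_a, tf_b, direction) in enumerate(pair_specs):
        for j in range(config.n_shared_targets):
            m_a = 1 if j % 2 == 0 else -1  # balanced mixed signs
            m_b = m_a if direction == "co-activating" else -m_a
            target = f"DUAL{idx:02d}_t{j:02d}"
            rows[target] = (config.effect_size
                            * (m_a * rows[tf_a] + m_b * rows[tf_b]) / 2.0
                            + config.noise_scale * rng.standard_normal(n))
            regulons[tf_a][target] = m_a
            regulons[tf_b][target] = m_b
        dual_pairs.append((tf_a, tf_b, direction))

    # the "established cell-cycle gene lists" are themselves network targets:
    # late genes rise with latent activity (+ targets of the high program and
    # - targets of the low program), early genes the mirror image
    late_genes = _cc_list(regulons, tf_programs, +1, config.n_cell_cycle_genes)
    early_genes = _cc_list(regulons, tf_programs, -1, config.n_cell_cycle_genes)

    for i in range(config.n_null_genes):
        rows[f"NULL{i:03d}"] = rng.standard_normal(n)

    expr = pd.DataFrame(rows, index=samples).T
    expr.columns = samples
    if scale == "raw-counts":
        expr = _to_counts(expr, config, rng)
    matrix = GeneExpressionMatrix(expr, scale=scale)

    rate = config.mitotic_base_rate * np.exp(config.mitotic_slope * latent)
    mitotic = rng.poisson(rate)
    pheno = PhenotypeTable(pd.DataFrame(
        {"mitotic_index": mitotic, "cell_cycle_group": groups},
        index=pd.Index(samples, name="sample"),
    ))
    truth = SimulationTruth(
        latent=pd.Series(latent, index=samples),
        groups=pd.Series(groups, index=samples),
        regulons=regulons,
        tf_programs=tf_programs,
        dual_pairs=dual_pairs,
        early_genes=early_genes,
        late_genes=late_genes,
        config=config,
    )
    return matrix, pheno, truth


def _cc_list(regulons: dict[str, dict[str, int]], tf_programs: dict[str, str],
             latent_sign: int, size: int) -> list[str]:
    """Round-robin over TFs: targets whose latent coefficient has the sign."""
    pools = []
    for tf, reg in regulons.items():
        prog = tf_programs[tf]
        if prog == "null":
            continue
        tf_sign = 1 if prog == "high" else -1
        pools.append([t for t, mode in reg.items()
                      if not t.startswith("DUAL") and mode * tf_sign == latent_sign])
    out: list[str] = []
    depth = 0
    while len(out) < size and any(depth < len(p) for p in pools):
        for p in pools:
            if depth < len(p) and len(out) < size:
                out.append(p[depth])
        depth += 1
    return out


def _to_counts(log_expr: pd.DataFrame, config: SimulationConfig,
               rng: np.random.Generator) -> pd.DataFrame:
    """Negative-binomial counts with mean 2**(x + baseline)."""
    mu = np.exp2(log_expr.to_numpy() + config.count_baseline_log2)
    r = config.count_dispersion
    p = r / (r + mu)
    counts = rng.negative_binomial(r, p)
    return pd.DataFrame(counts.astype(float), index=log_expr.index,
                        columns=log_expr.columns)


# ---------------------------------------------------------------------------
# genomic layers


def _group_of(phenotype: PhenotypeTable) -> pd.Series:
    """High/low instability tier per sample from the phenotype labels."""
    df = phenotype.data
    if "regulon_cluster" in df.columns and (df["regulon_cluster"] != "unassigned").any():
        return df["regulon_cluster"].map({"high": "high", "low": "low"})
    if "cell_cycle_group" in df.columns:
        return df["cell_cycle_group"].map({"late": "high", "early": "low"})
    raise ValueError("phenotype carries no group labels")


def simulate_segments(config: SimulationConfig,
                      phenotype: PhenotypeTable) -> list[SegmentProfile]:
    """Zero-centered per-chromosome segment means; the high group gets
    ``segment_dispersion_ratio`` times the low group's standard deviation."""
    config.validate()
    rng = np.random.default_rng([int(config.seed), 1])
    tiers = _group_of(phenotype)
    profiles = []
    seg_len = 1_000_000
    for sample in phenotype.sample_ids:
        sd = config.segment_sd_low
        if tiers.loc[sample] == "high":
            sd *= config.segment_dispersion_ratio
        recs = []
        for c in range(config.n_chromosomes):
            for s in range(config.segments_per_chromosome):
                recs.append((
                    f"chr{c + 1}",
                    s * seg_len + 1,
                    (s + 1) * seg_len,
                    sd * rng.standard_normal(),
                ))
        profiles.append(SegmentProfile(
            sample_id=sample,
            segments=pd.DataFrame(recs, columns=["chromosome", "start", "end",
                                                 "segment_mean"]),
        ))
    return profiles


_FILTER_CLAUSES = ("none", "depth", "alt_reads", "vaf")


def simulate_mutations(
    config: SimulationConfig, phenotype: PhenotypeTable,
) -> tuple[list[MutationCallSet], pd.DataFrame]:
    """Mutation calls with higher per-sample rate in the high group.

    A ``fraction_failing`` of calls is engineered, per clause, to fail one of
    the depth / alt-read / VAF filters. Returns the call sets plus a truth
    table (sample, call, gene, engineered_clause, passes).
    """
    config.validate()
    rng = np.random.default_rng([int(config.seed), 2])
    tiers = _group_of(phenotype)
    gene_pool = [f"GENE{i:03d}" for i in range(50)]
    callsets, truth_rows = [], []
    f = config.fraction_failing
    probs = np.array([max(0.0, 1 - 3 * f), f, f, f])
    probs = probs / probs.sum()
    for sample in phenotype.sample_ids:
        rate = config.mutation_rate_low
        if tiers.loc[sample] == "high":
            rate *= config.mutation_rate_ratio
        n_calls = rng.poisson(rate)
        recs = []
        for i in range(n_calls):
            clause = _FILTER_CLAUSES[rng.choice(4, p=probs)]
            if clause == "none":
                depth = max(int(rng.poisson(config.mean_depth)), 51)
                vaf_true = max(rng.beta(config.vaf_alpha, config.vaf_beta), 0.08)
                alt = int(rng.binomial(depth, vaf_true))
                alt = max(alt, 11, int(np.floor(0.05 * depth)) + 1)
                alt = min(alt, depth)
            elif clause == "depth":
                depth = int(rng.integers(10, 51))
                alt = max(int(round(0.3 * depth)), 1)
            elif clause == "alt_reads":
                depth = max(int(rng.poisson(config.mean_depth)), 150)
                alt = int(rng.integers(1, 11))
            else:  # vaf
                depth = max(int(rng.poisson(2 * config.mean_depth)), 300)
                alt = max(int(np.floor(0.04 * depth)), 11)
            vaf = alt / depth
            gene = gene_pool[rng.integers(0, len(gene_pool))]
            recs.append((gene, depth, alt, vaf))
            passes = depth > 50 and vaf > 0.05 and alt > 10
            truth_rows.append((sample, i, gene, clause, passes))
        calls = pd.DataFrame(recs, columns=["gene", "depth", "alt_reads", "vaf"])
        callsets.append(MutationCallSet(sample_id=sample, calls=calls))
    truth = pd.DataFrame(
        truth_rows, columns=["sample", "call", "gene", "engineered_clause", "passes"])
    return callsets, truth


# ---------------------------------------------------------------------------
# cross-cohort helpers


def simulate_batch_counts(
    n_samples: int = 200,
    n_genes: int = 300,
    n_housekeeping: int = 11,
    batch_effect: float = 1.0,
    noise_sd: float = 0.3,
    baseline_log2: float = 6.0,
    seed: int = 0,
) -> tuple[GeneExpressionMatrix, pd.Series, list[str]]:
    """Counts cohort with an additive log2-scale batch shift on every gene.

    Returns (raw-counts matrix, batch labels in {0, 1}, housekeeping genes).
    """
    rng = np.random.default_rng([int(seed), 3])
    samples = [f"B{i:04d}" for i in range(n_samples)]
    hk = [f"HK{i:02d}" for i in range(n_housekeeping)]
    other = [f"BG{i:03d}" for i in range(n_genes - n_housekeeping)]
    genes = hk + other
    batch = rng.integers(0, 2, size=n_samples)
    base = rng.normal(baseline_log2, 1.0, size=len(genes))
    log2x = (base[:, None] + batch_effect * batch[None, :]
             + noise_sd * rng.standard_normal((len(genes), n_samples)))
    counts = rng.poisson(np.exp2(log2x)).astype(float)
    matrix = GeneExpressionMatrix(
        pd.DataFrame(counts, index=genes, columns=samples), scale="raw-counts")
    return matrix, pd.Series(batch, index=samples, name="batch"), hk


def simulate_stage_cohort(
    config: SimulationConfig,
    n_nipuc: int = 150,
    n_invasive: int = 150,
    stage_shift: float = 2.0,
) -> tuple[GeneExpressionMatrix, PhenotypeTable, SimulationTruth]:
    """Counts cohort mixing noninvasive and invasive samples.

    Invasive samples get their latent cell-cycle activity shifted up by
    ``stage_shift``, emulating the higher cell-cycle tone of invasive disease.
    """
    total = n_nipuc + n_invasive
    cfg = SimulationConfig(**{**asdict(config), "n_samples": total})
    matrix, pheno, truth = simulate_cohort(cfg, scale="log-normalized")
    rng = np.random.default_rng([int(config.seed), 4])
    stage = np.array(["NIPUC"] * n_nipuc + ["MIBC"] * n_invasive)
    rng.shuffle(stage)
    shift = np.where(stage == "MIBC", stage_shift, 0.0)
    # re-apply the latent shift to every latent-driven gene
    expr = matrix.data.copy()
    coef = _latent_coefficients(truth)
    for gene, c in coef.items():
        if c != 0.0:
            expr.loc[gene] = expr.loc[gene].to_numpy() + c * shift
    counts = _to_counts(expr, cfg, rng)
    out = GeneExpressionMatrix(counts, scale="raw-counts")
    pheno_df = pheno.data.copy()
    pheno_df["stage_class"] = stage
    truth.latent = truth.latent + shift
    truth.groups = pd.Series(np.where(truth.latent > 0, "late", "early"),
                             index=truth.latent.index)
    return out, PhenotypeTable(pheno_df), truth


def _latent_coefficients(truth: SimulationTruth) -> dict[str, float]:
    """Expected coefficient of each gene on the latent activity."""
    cfg = truth.config
    coef: dict[str, float] = {}
    sign = {"high": 1.0, "low": -1.0, "null": 0.0}
    for tf, prog in truth.tf_programs.items():
        coef[tf] = sign[prog]
        for target, mode in truth.regulons[tf].items():
            if target.startswith("DUAL"):
                # shared target: average of both parents' contributions
                coef.setdefault(target, 0.0)
                coef[target] += cfg.effect_size * mode * sign[prog] / 2.0
            else:
                coef[target] = cfg.effect_size * mode * sign[prog]
    return coef
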