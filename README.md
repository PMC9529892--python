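# regcycle

Transcriptional-network analysis of cell-cycle dysregulation in noninvasive
papillary urothelial carcinoma (NIPUC), built as a tested, reusable Python
pipeline. Noninvasive bladder tumors with higher cell-cycle activity recur
and progress more often, and that activity is coordinated by a network of
transcription factors (TFs) acting on overlapping target genes. `regcycle`
reconstructs this analysis end-to-end for anyone who wants to apply it to
expression cohorts or study its statistical behavior:

- **Regulon inference** (ARACNe-style): mutual information (MI) between each
  curated TF and every gene, a pooled permutation-null significance
  threshold, data-processing-inequality (DPI) pruning of the weakest edge in
  every triangle, and a signed *regulon* per TF (mode = sign of the
  TF-target Pearson correlation).
- **Regulon activity**: per-sample, two-tailed single-sample gene-set
  enrichment. Each sample's *signature* is its cohort z-scored expression;
  a regulon's activity is ES(positive targets) − ES(negative targets), where
  ES is the signed maximum deviation of the GSEA running sum, so scores lie
  in [−2, 2].
- **Cell-cycle phenotyping**: consensus k-means clustering (90% item
  resampling, Euclidean distance, 1000 repetitions) into early vs late
  cell-cycle groups on cell-cycle gene expression, and High vs Low Cell
  Cycle groups on regulon activity, with a consensus-CDF/PAC choice of k.
- **Two-layer, two-cohort selection** of cell-cycle-associated regulons:
  layer 1 tests target-set overlap with the early/late differential
  signature (hypergeometric) and activity difference between groups
  (Wilcoxon rank-sum); layer 2 revalidates on a second cohort and requires
  Spearman correlation with mitotic index (count of mitotic figures per 10
  high-power fields), all FDR-controlled with concordant directions.
- **Dual regulons**: TF pairs with significantly overlapping targets (Fisher
  exact, BH), their *regulon agreement* — the Spearman correlation between
  the two TFs' per-target correlation profiles — and 2-way clustering of TFs
  into co-activating vs antagonistic programs.
- **Genomic metrics**: mutation-call filtering (depth > 50, VAF > 5%, alt
  reads > 10), tumor mutational burden (TMB), five-level copy-number calls
  (gain > 0.1, high gain > 1.05, loss < −0.1, homozygous loss < −0.75 on the
  log-ratio scale, re-calibratable by quantile matching against a reference
  cohort), and chromosomal instability (CIN = mean over chromosomes of the
  mean |segment mean|).
- **Cross-cohort comparison**: upper-quartile normalization, a one-factor
  unwanted-variation correction anchored on housekeeping genes (RUV, k = 1),
  TPM conversion, projection of the frozen regulons onto the new cohort, and
  Bonferroni-controlled activity comparison between noninvasive and invasive
  stage groups.

Because the study cohorts are controlled-access, the package ships a
first-class synthetic-data module that plants every signal the pipeline is
supposed to find — a bimodal latent cell-cycle phenotype, two opposing TF
programs with signed targets, co-activating and antagonistic TF pairs,
mitotic-index counts, group-dependent copy-number dispersion and mutation
rates — so every stage has a parameter-recovery test with no downloads.

Core stages are scikit-learn-style estimators (`RegulonInference`,
`RegulonActivity`, `ConsensusClustering`, `UpperQuartileNormalizer`,
`RUVNormalizer`) that compose with sklearn pipelines; the module-level
functions are thin wrappers over them.

## Worked example

```python
from regcycle import (build_regulons, regulon_activity,
                      assign_cell_cycle_groups, enrichment_score_difference,
                      mitotic_correlation)
from regcycle.simulate import SimulationConfig, simulate_cohort

cfg = SimulationConfig(n_samples=300, seed=0)   # 20 TFs x 30 signed targets
expr, pheno, truth = simulate_cohort(cfg)

net = build_regulons(expr, list(truth.tf_programs), seed=0)
print(net.n_edges(), round(net.parameters["mi_threshold"], 4))
# 855 0.0405

act = regulon_activity(net, expr)               # regulons x samples, [-2, 2]
groups = assign_cell_cycle_groups(expr, truth.early_genes, truth.late_genes,
                                  seed=0, n_reps=200)
print(round((groups == truth.groups).mean(), 3))
# 0.993

row = act.data.loc["TFH00"]                     # a planted high-CC regulon
print(round(enrichment_score_difference(row, groups), 2))
# 2.31
rho, p = mitotic_correlation(row.to_numpy(),
                             pheno.data["mitotic_index"].to_numpy())
print(round(rho, 3))
# 0.786
```

Reading the numbers: the inferred network has 855 signed TF→target edges
above the permutation-null MI threshold of 0.04 nats (the 600 planted edges
plus TF–TF co-regulation edges). Consensus clustering on the cell-cycle gene
lists reproduces the planted early/late split for 99.3% of samples. The
regulon of `TFH00`, a planted high-cell-cycle TF, has an enrichment score
difference of +2.31 (median activity in late minus early group — strongly
late-shifted) and its activity correlates with the mitotic index at
Spearman ρ = 0.79, exactly the two-layer evidence pattern the selection
stage requires.

The same flow runs from the shell:

```bash
regcycle simulate --n-samples 300 --seed 0 -o cohort/
regcycle infer-network --expr cohort/expression.tsv --tfs tfs.txt -o net.tsv
regcycle activity --network net.tsv --expr cohort/expression.tsv -o act.tsv
regcycle run --config config.yaml        # full pipeline with manifest
```

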