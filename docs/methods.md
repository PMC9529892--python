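# Methods

This note documents the models, estimators, numerical choices and known
limitations of `regcycle`, in the spirit of the methods documentation that
accompanies packages like statsmodels or msprime.

## Regulon inference

**Mutual information estimator.** Both expression vectors are
rank-transformed to uniform scores and cut into `B = floor(sqrt(n/5))`
equal-frequency bins, clamped to [4, 16]; MI is the plug-in estimate on the
joint histogram with a Miller–Madow bias correction, floored at 0 (in nats).
Rank transformation makes the estimate invariant under strictly monotone
rescaling of either vector, which matters because cohorts arrive on
different expression scales (log-FPKM, log-TPM, microarray intensities).
The upper clamp of 16 bins was set from the closed form for the bivariate
Gaussian copula: at 12 bins the exactly discretized MI for ρ = 0.9 is 0.748
nats against the continuous 0.830, leaving too little margin for the
estimator's ±0.1 accuracy contract at n = 5000; at 16 bins the discretized
value is 0.772. Exact float symmetry in the two arguments is guaranteed by
canonicalizing the argument order before summation. A constant vector
carries no information and scores MI = 0 with a warning.

**Significance threshold.** The null pools MI values computed on
sample-label-permuted random gene pairs (a single global threshold, the
usual ARACNe practice) and takes the (1 − α) quantile. The default is
α = 0.01 and 1000 permutations. The pooled null is a *per-pair* test: with
~10⁴ candidate TF–gene pairs a 0.05 threshold admits hundreds of false
edges by construction, so the default is stricter than the per-test
convention — ARACNe implementations with analytic nulls go much further
(p ≈ 10⁻⁷) than an empirical quantile can resolve at practical permutation
counts.

**DPI pruning.** For every triangle of retained edges the weakest edge is
removed when its MI falls below (1 − tolerance) × the smaller of the other
two; removals are decided on the input graph, which makes the operation
idempotent. Default tolerance 0.1, the conventional ARACNe setting. TF–TF
edges are allowed as regulon membership; self-edges are forbidden. Network
bootstrapping (consensus over resampled runs) is not performed.

**Modes.** Each retained TF→target edge gets mode +1 or −1 from the sign of
the TF–target Pearson correlation; a zero correlation (possible only with
degenerate data) maps to +1. TFs whose regulons come out empty are retained
and flagged rather than dropped.

## Regulon activity

A sample's signature is its gene-wise cohort z-score (sample standard
deviation, ddof = 1); zero-variance genes score 0, and a cohort needs at
least 3 samples. The enrichment score of a gene set walks the genes in
decreasing signature order (ties broken by gene symbol for cross-platform
determinism): hits increment the running sum by their normalized weight
|z|^exponent, misses decrement by 1/(N − k), and the ES is the signed
maximum deviation, so ES ∈ [−1, 1]. When the maximum positive and negative
deviations tie in magnitude (to 1e-9) the positive one is reported — without
a fixed rule the sign would depend on floating-point summation order. The
default weight exponent is 1 (signature-weighted hits, the common
GSEA2/ssGSEA practice); exponent 0 gives the classic rank-only statistic
used by the analytic oracle tests. Scores are reported raw, never
z-normalized across samples.

A regulon's two-tailed activity is ES(positive-mode targets) −
ES(negative-mode targets) ∈ [−2, 2]. Regulons with fewer than 5 targets on
either side fall back to a one-tailed ES of all targets signed by the
majority mode; an exact tie in side sizes keeps the two-tailed difference so
that negating every mode always negates the score exactly. The enrichment
score difference of a regulon is the median activity in the late cell-cycle
group minus the median in the early group; as a difference of medians of
[−2, 2] scores it ranges over [−4, 4].

## Consensus clustering and the choice of k

Repetitions subsample 90% of samples (and optionally a fraction of
features), run Euclidean k-means (10 restarts, best inertia, seeded per
repetition), and accumulate co-clustering frequency among co-sampled pairs;
consensus(i, i) ≡ 1. Final labels come from average-linkage hierarchical
clustering of 1 − consensus. The default is 1000 repetitions; tests and the
example pipeline configs use 60–200 repetitions, a problem-size choice that
leaves the consensus estimates amply stable for well-separated groups.

The raw area under the consensus CDF equals 1 − mean(consensus) and
therefore grows mechanically with k (more between-cluster zero pairs): on
perfectly separated two-blob data it measures 0.51/0.63/0.70 for
k = 2/3/4. A "greatest area" rule applied naively would always pick the
largest k. `choose_k` therefore first restricts candidates to the k whose
proportion of ambiguous clustering (PAC: off-diagonal consensus entries in
(0.1, 0.9)) is within 0.02 of the minimum — the stable clusterings — and
then applies the area criterion with a 2% tie tolerance among them, ties
resolving to the smallest k. PAC is the standard quantitative refinement of
the CDF-curve eyeball and reproduces the intended behavior (two blobs → 2,
three blobs → 3) where the raw area cannot.

Early/late cell-cycle groups come from 2-cluster consensus on the union of
the early and late gene lists (gene-wise z-scores); the cluster with higher
mean late-gene expression is "late". High/Low Cell Cycle groups come from
the same procedure on selected-regulon activity, the cluster with higher
mean high-CC regulon activity being "high".

## Two-layer selection

Layer 1 (inference cohort) requires both a hypergeometric overlap between
the regulon's targets and the early/late differential signature and a
rank-sum difference in activity between the groups, each at BH q < 0.05
across TFs. The differential signature is defined as the genes at BH
q < 0.01 by gene-wise rank-sum between the groups — the underlying study
leaves this gene list underspecified, and a rank-based differential set is
self-contained and scale-robust. Layer 2 (validation cohort) requires, among
layer-1 survivors, a rank-sum group difference and a Spearman correlation
with mitotic index, each at BH q < 0.05 (adjusted within survivors), with
concordant direction: sign(ρ) must equal the sign of the enrichment score
difference. A missing mitotic index skips the correlation with an explicit
flag and selection then rests on the remaining tests. Rank-sum p-values use
exact enumeration of the midrank permutation distribution when both groups
have ≤ 10 observations and the tie-corrected normal approximation with
continuity correction otherwise.

## Dual regulons

Candidate pairs share at least 10 targets (Spearman agreement on shorter
profiles is unstable); the overlap is tested two-sided by Fisher's exact
test over the full expression universe and BH-adjusted across candidates.
For a significant pair, each shared target's Pearson correlation with the
two TFs gives two profiles, and the agreement is their Spearman correlation:
exactly +1/−1 for identical/negated profiles by an explicit short-circuit
(sample correlations of identical vectors are exact, so the short-circuit
only removes float noise from the rank correlation). Agreement clustering
builds the symmetric agreement matrix over the chosen TFs, imputes missing
pairs at 0 (for clustering only, never reported as a measurement), and cuts
an average-linkage tree of 1 − agreement into two clusters; the split is
flagged unstable when the mean between-cluster agreement is nonnegative
(no opposing structure to find).

## Genomic metrics

Mutation calls pass filtering only with depth > 50, variant allele fraction
> 0.05 and alt reads > 10 — all strict, so boundary values fail. TMB is the
count of surviving calls. Segment means threshold into five levels at
> 1.05 / > 0.1 / < −0.1 / < −0.75 (strict; boundary values are neutral).
Quantile calibration locates, in a reference cohort with both continuous
values and five-level calls, the midpoint between adjacent call levels,
takes its empirical quantile, and maps that quantile onto the study
cohort's continuous distribution; a missing reference level falls back to
the default cutoff with a warning. Thresholds must be strictly increasing;
a neutral band that does not bracket zero (possible for a shifted study
distribution) warns rather than errors. CIN is the mean over the
chromosomes present of the mean absolute segment mean per chromosome,
unweighted by segment length or probe count (the definition names neither).
Gene-level calls take the segment containing the gene midpoint, or the
larger-overlap segment for genes spanning breakpoints.

## Cross-cohort normalization

Upper-quartile normalization scales each sample so the 75th percentile of
its nonzero counts equals the across-sample mean upper quartile; it is
idempotent to machine precision. The unwanted-variation correction (k = 1)
takes the first right-singular direction of the row-centered
log(count + 1) housekeeping submatrix as per-sample loadings, regresses
every gene's log expression on the centered loadings, subtracts the fitted
component, and exponentiates back (clipped at 0); k = 0 is an identity
passthrough, and at least 3 housekeeping genes must be present. The
housekeeping list is configurable — the synthetic cohorts use planted
latent-independent genes; the 11-gene set used on real cohorts should be
supplied by the user. TPM conversion divides counts by gene length and
rescales columns to 1e6. Projection onto a new cohort freezes target sets
and modes and recomputes signatures on the new cohort; regulons with under
80% target coverage are flagged NaN. Stage-group comparisons are rank-sum
tests Bonferroni-adjusted across regulons, with a direction-consistency
flag against each regulon's recorded high/low-CC direction. A uniform
library-size-like batch shift is removed by upper-quartile scaling alone;
the RUV step addresses batch structure visible in the housekeeping genes
beyond global scaling.

## The synthetic cohort generator

The generator emulates the statistical structure the pipeline consumes,
not bladder-cancer biology. A two-component Gaussian mixture with component
means ±separation/2 (default separation 4) and unit within-component
variance supplies the latent cell-cycle activity; the group label is the
sign of the latent value. TF expression is sign × latent + 1.7 × noise
(sign +1 for the high program, −1 for the low program, 0 for null TFs);
target expression is effect × mode × TF + 2.0 × noise, all Gaussian on the
log scale; a negative-binomial mode (mean 2^(x + 5), dispersion 10)
produces raw counts for the normalization tests. The early/late cell-cycle
gene lists are drawn round-robin from the planted targets whose latent
coefficient has the matching sign — in the modeled study the cell-cycle
genes are themselves regulated by the network, and planting them as
separate latent readouts would create TF–gene dependencies that no
network-based pruning could remove. The TF and target noise scales were set
from the triangle geometry of DPI: a spurious TF→target edge has
correlation r(TF,TF′) × r(TF′,target), and pruning it reliably at 10%
tolerance with n = 300 requires the direct correlation to sit near 0.8 and
the TF–TF correlation near 0.5, with estimator noise small relative to the
margins.

Planted dual pairs add shared targets driven by the average of the two
parents' signed contributions, with per-target signs alternating so the
correlation profiles have the spread the Spearman agreement needs;
co-activating pairs live inside the high program and antagonistic pairs
bridge the two programs, mirroring how opposing regulators share targets.
Mitotic index is Poisson with a log link on latent activity (base rate 3
per 10 high-power fields, slope 0.5) — the simplest count model for a
mitotic-figure count. Segment means are zero-centered Gaussians per
chromosome (22 chromosomes × 3 segments) with standard deviation 0.05,
tripled in the high group; mutation-call counts are Poisson (rate 20,
doubled in the high group) with depths around 150, Beta(3, 9) allele
fractions, and an optional engineered fraction of calls that fail each
filter clause, recorded in the truth table. All generators are pure
functions of (config, seed).

What the generator does **not** emulate — and therefore what passing tests
do not certify about real data: gene-length and GC biases, mutational
signatures, linkage and copy-number coupling to expression, non-Gaussian
expression heavy tails, hierarchical TF→TF regulation, and cohort batch
structure beyond an additive log-scale shift.

## Problem sizes and determinism

The shipped test and pipeline configurations use 90–300 samples, 8–50 TFs,
60–1000 consensus repetitions and 200–2000 MI permutations — sizes at which
every planted-recovery contract holds with margin while a full end-to-end
run stays in the seconds-to-minutes range. One master seed derives
per-stage seeds; all randomness flows through `numpy.random.default_rng`,
and the pipeline manifest records a content hash per output so identical
config + seed reproduces identical hashes.

## Known limitations

- The empirical permutation null cannot resolve the extreme tail thresholds
  analytic ARACNe nulls use; with very large gene universes the pooled
  α = 0.01 default admits a correspondingly larger absolute number of false
  edges.
- Marginal TF–TF dependencies induced by an unobserved common driver are
  genuine mutual information and survive DPI by design; regulon membership
  of co-driven TFs is therefore expected, and planted-edge recovery is
  evaluated over TF→non-TF pairs, the pairs the ground truth specifies.
- The exact rank-sum enumeration switches to the normal approximation above
  group size 10; p-values near the switch boundary are approximation-grade.
- RUV with k = 1 removes one factor; multi-factor unwanted variation is out
  of scope, as is microarray normalization.
- Consensus clustering inherits k-means' spherical-cluster bias; strongly
  elongated expression clusters may fragment.
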