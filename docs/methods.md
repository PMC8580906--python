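# Methods

`omicpred` implements a multi-omics genomic-prediction workflow for inbred
crop panels: relationship kernels from SNPs and omics features, single- and
multi-kernel BLUP, BayesB, multi-trait models across environments, weighted
correlation network modules on metabolites, and a network-guided marker
prioritization that transfers prediction across distantly related
populations. This note records the models, the synthetic study conditions,
the numerical choices, and the limits of what the test suite demonstrates.

## Relationship kernels

The genomic relationship matrix follows VanRaden's first method: dosages
(0/1/2 copies of the alternate allele) are centered by twice the allele
frequency and the cross product is scaled by `2 * sum(p_j (1 - p_j))`, so
the mean diagonal is about `1 + f` for inbreeding level `f` (close to 2 in
a selfing crop). Omics kernels are `W W' / N` over `N` features. The
divisor fixes the scale but not the centering; we column-center and scale
each feature to unit population variance before the product, which makes
the kernel scale-free with diagonal mean exactly 1. A `scale=False` mode
keeps raw values for sensitivity checks, since the raw-vs-scaled choice is
a genuine degree of freedom in this construction. Kernels are stabilized
by adding a small ridge (1e-6, or enough to clear a genuinely negative
eigenvalue) to the diagonal only when the smallest eigenvalue is negative.

Marker QC uses strict inequalities throughout — MAF > 0.02, site
missingness < 0.60, site heterozygosity < 0.10 for markers; call rate
> 0.80 and heterozygosity < 0.10 for lines — with heterozygosity defined
as the fraction of dosage-1 calls among non-missing calls. Missing
dosages are imputed by column means or, when a marker map is available, by
regression on up to eight map-nearest markers of the same chromosome
(exploiting local LD; clipped to [0, 2]). Rogers' distance represents
each genotype by its within-individual allele frequency (0, 0.5, 1) and
takes the root mean square frequency difference over markers; the paperless
corner case of heterozygotes is thereby handled symmetrically. Neighbor
joining delegates to scikit-bio's Saitou–Nei implementation.

## Stage one: augmented-design adjustment

Plot-level records from augmented incomplete block designs are adjusted
with the mixed model

```
value = intercept + check effects (fixed) + block (random) + batch (random,
        optional) + line + residual
```

Replicated check varieties are fixed effects; unreplicated test lines are
random (BLUP mode, the default) or fixed (BLUE mode, refit by GLS at the
REML variance estimates). REML maximizes the profile restricted likelihood
over log variance components with a bounded quasi-Newton search; variances
pinned at the lower bound are reported as zero. Line-mean heritability is
`h2 = s_g / (s_g + s_e / r_bar)` with `r_bar` the harmonic-mean replication
of test lines (1 for fully unreplicated entries); it feeds the accuracy
denominators downstream. A deregression option divides each BLUP by its
reliability `1 - PEV/s_g`.

The fixed/random split of checks and entries is a modeling convention, not
something the adjusted-value consumer can distinguish at desk scale; the
BLUE switch exists to quantify the difference on real data.

## Prediction engines

**Single kernel.** `y = Xb + g + e`, `g ~ N(0, s_g K)`, fitted by the
eigendecomposition trick: after rotating by the eigenvectors of K the
restricted likelihood is a one-dimensional function of the variance ratio
`delta = s_e/s_g`, profiled on a 61-point log grid and refined by bounded
scalar minimization. BLUPs shrink each eigencomponent by
`d_i / (d_i + delta)`.

**Multi-kernel.** `y = Xb + sum_k g_k + e` with one variance per kernel,
fitted by classical EM-REML (the expectation updates keep every component
non-negative and increase the restricted likelihood monotonically;
convergence when the relative change drops below 1e-8 or after 500
iterations). EM is slow near boundaries but deterministic, which the test
suite relies on. A Gibbs backend samples each kernel effect in its
eigenbasis, where the full conditionals are diagonal, and agrees with EM
within sampling error; it exists because the deterministic/stochastic
agreement is itself a useful cross-check. Out-of-sample lines are
predicted by the kernel projection
`ghat_test = sum_k s_k K_k[test,train] V^{-1} (y - Xb)`.

**BayesB.** Per-marker effects with a point mass at zero (prior exclusion
probability `pi = 0.95`) and scaled-inverse-chi-square effect variances
(`nu = 4.2`; the scale solves a prior heritability of 0.5 through
`S = vary * h2 * (nu - 2) / (nu (1 - pi) sum 2 p q)`). Single-site Gibbs
with the standard marginal-likelihood inclusion step; defaults 12000
iterations, 2000 burn-in, thinning 5 (tests and the acceptance script use
shorter chains, which is sufficient for rank statistics and posterior
means at these problem sizes). The inner loop is compiled with numba,
with a pure-NumPy fallback implementing the identical algorithm.

**Multi-trait.** Environments are treated as traits:
`Cov(g) = G0 (x) K`, `Cov(e) = I (x) R0`, with G0 diagonal (D),
unstructured (UN) or first-order factor-analytic (FA1 = lam lam' + Psi),
and R0 D or UN; all six pairings of {D, UN, FA1} x {D, UN} run, covering
every reading of the structure codes. A factor-analytic residual is
rejected. After rotating by the eigenvectors of K, rows are independent
with covariance `d_i G0 + R0`, and EM-REML alternates the E-step (with the
fixed-effect projection correction, so a D–D fit matches per-environment
single-kernel REML to ~1e-5 at tight tolerance) with structure-projected
M-steps; FA1 is projected by alternating rank-1 fits. One environment
reduces to the single-kernel model. FA order is fixed at 1 — three
environments cannot identify more factors.

Masked cells (the CV2 scenario) are handled by EM imputation: missing
entries are filled with the current fitted values between covariance
updates (8 outer rounds). This slightly understates residual variance
relative to a full missing-data E-step because the imputed cells carry no
conditional variance; point predictions, which are what CV2 consumes, are
unaffected to first order, and the covariance-recovery tests use complete
data.

**Two-kernel model.** The prioritized-vs-rest genomic model is the
multi-kernel engine with exactly two genomic kernels; empty marker sets
are rejected.

## Accuracy estimation and comparisons

Two estimators mirror the two study settings. Where omics and phenotypes
were measured on the same plots, micro-environmental covariance inflates
plain correlations, so accuracy is estimated from a bivariate mixed model
of (observed, predicted) over the test lines with the genomic kernel:
accuracy = genetic correlation x sqrt(genetic signal fraction of the
prediction), clamped to [-1, 1], with a logged fallback to the scaled
correlation when the bivariate fit degenerates. Elsewhere accuracy is
`r(yhat, y) / sqrt(h2)`, deliberately unclamped (values above 1 flag an
optimistic h2, which is informative). The h2 in the denominator is the
stage-one line-mean estimate computed once on the full data — a mild,
documented optimism; per-fold recomputation is available by flag.

Paired model comparisons use the Wilcoxon signed-rank test with zero
differences dropped. For up to 25 non-zero differences the null
distribution of the rank sum is computed exactly by dynamic programming
over doubled midranks (exact even under ties, unlike the textbook
enumeration); larger samples use the normal approximation with continuity
and tie corrections. Percent-change summaries report medians (the
single-environment convention) and means (the transfer-experiment
convention) with 0.05/0.01/0.001 stars.

Cross-validation schemes share one master seed that spawns per-repeat
streams; every model sees the identical partition in each repeat
(partition hashes are recorded), which the paired tests require. The CV2
scheme masks the same 20% of lines in each target environment in turn and
builds the metabolite kernel only from the other environments — by
default averaging each line's feature vector across the source
environments (keeps the feature count fixed and is symmetric in the
sources), with a concatenation mode as the alternative. The "G+M" kernel
option in multi-trait fits uses the unweighted mean of the two kernels: a
single-kernel multi-trait engine keeps the EM simple, and the equal-weight
sum is the neutral choice absent variance estimates per kernel.

## Network module detection

Metabolite co-abundance modules follow the weighted-correlation recipe:
unsigned adjacency `|cor|^beta` at soft power 4 (chosen in real analyses
from the scale-free fit chart, which `pick_soft_threshold` reproduces:
binned log p(k) vs log k regression, sign-corrected R^2), topological
overlap, average-linkage clustering of 1 - TOM, and a Dynamic-Hybrid tree
cut re-implemented from its published description. Stage 1 scans merges
bottom-up and accepts minimal branches that are large enough
(minClusterSize 20), internally tight (normalized core scatter of the
lowest minClusterSize-1 merges below the deepSplit preset) and separated
from their surroundings (normalized gap to the branch's attachment merge
above the preset); heights are normalized to the 5th-percentile-to-cut
range with cut height = q5 + 0.99 (max - q5). The deepSplit presets are
maxCoreScatter in {0.64, 0.73, 0.82, 0.91, 0.95} for levels 0-4 with
minGap = 3/4 (1 - maxCoreScatter); level 2 is the default. Stage 2
assigns unlabelled features to the nearest module medoid, ignoring the
dendrogram, when the distance does not exceed that module's own medoid
radius; the rest keep label 0. No reference implementation of the hybrid
cut is available in this environment, so correctness is established by
planted-partition recovery (ARI 1.0 on the generator's module structure at
noise_sd 0.6) and null behavior (pure-noise features stay unassigned in
at least 9 of 10 seeds) rather than output-matching.

Module eigenvectors are the unit-norm first left singular vector of the
standardized member submatrix, sign-aligned to correlate positively with
the members. Enrichment per module is a one-sided Fisher exact test of
the in-module x in-class table with BH adjustment across modules; a
module holding every feature has an undefined odds ratio and p = 1.

## Marker prioritization and the transfer experiment

GWAS is the standard kinship mixed model: variance components estimated
once under the null (P3D) with intercept + 2 genotype PCs, then each
marker tested by GLS in the whitened space (Wald t); markers with
MAF < 0.02 are excluded, and an exact per-marker REML mode exists as a
slow flag. FDR selection is BH with a strict q-value < threshold,
matching the strict "< 0.05" convention used for every other filter. LD
expansion returns the seeds plus every same-chromosome marker with
dosage-correlation r^2 >= 0.1 (the conventional pruning threshold); scope
and window are configurable, monomorphic markers are excluded with a
warning, and the expansion is monotone in the threshold.

The pipeline ties these together: modules -> class enrichment
(Fisher q < 0.05) -> module eigenvectors clustered with the trait
family's PC1 (correlation dissimilarity, average linkage) -> GWAS on the
eigenvector and the trait PC1. A module is prioritized when it is
enriched, is among the trait composite's first merge partners, and has at
least one FDR-significant marker on the trait peak's chromosome
(optionally within a window). Seeds default to the module GWAS hits; a
joint mode adds trait-GWAS hits on the same chromosome, since the original
choice between the two is not determinable. Significant markers plus LD
partners form the prioritized set; the test population then builds
prioritized and rest kernels and runs five-fold CV against GBLUP and
(optionally) BayesB. When no module passes, the pipeline reports "no
prioritization possible" and runs the reference models only.

## Synthetic study conditions

The generator encodes the study structure so every stage is testable
without external data:

* **Two panels** of 368 and 232 lines with 32 shared (defaults; tests use
  scaled-down panels of 120–300 lines), allele frequencies diverging by
  Balding–Nichols drift (`Beta(p(1-F)/F, (1-p)(1-F)/F)`, F = fst, default
  0.15; the calibration tests use 0.3 and recover it by the Hudson
  estimator within ±0.05).
* **LD** by first-order Markov haplotype copying (copy probability
  ld_rho, default 0.6; 0.85 in the transfer experiment so that a
  prioritized QTL region spans a realistic handful of markers). Genomes
  are 7 chromosomes x 300 markers by default, scaled to 3-4 x 100-150 in
  tests — sizes chosen so the full suite runs at desk scale.
* **Inbreeding** 0.95 (selfing crop): a line's two haplotypes are
  identical with that probability, giving GRM diagonals near 2 and
  keeping simulated markers compatible with the heterozygosity filters.
  This field extends the configured study conditions; without it the QC
  stage would discard most simulated markers.
* **Architectures**: fixed per-marker QTL effects plus a standardized
  polygenic background of variance `polygenic_var`. With one environment
  the fixed effects act directly (deterministic signal for GWAS and
  prioritization tests). With several environments, exact
  `Cov(g) = G0 (x) A` is impossible with fixed effects — they would force
  perfect cross-environment QTL correlation — so e independent
  realizations of the architecture (fresh effect draws with per-marker sd
  |effect|) are mixed through the symmetric square root of G0. This gives
  the exact Kronecker covariance at the cost of randomizing per-copy
  effect signs; per-realization genetic correlations fluctuate more for
  oligogenic traits, which the recovery tests average over.
* **Residuals**: when `h2_target` is set, R0's diagonal is rescaled so
  line-level heritability matches the target (correlations preserved).
  The across-environment genetic correlation default of 0.6 is a
  placeholder for moderately consistent multi-location trials, not an
  estimate of any real data; directional tests use 0.8 as the
  strong-borrowing condition and 0 as the null.
* **Features**: planted modules share a latent factor = loading x a
  genetic driver + noise, features = factor + `noise_sd` x noise
  (defaults: loading 0.7, noise_sd 0.6 — strong but not degenerate
  co-abundance). The driver is a QTL dosage (pleiotropy map) or, via
  `module_drivers`, any per-line signal such as a trait's total genetic
  value — the mechanism by which an omics kernel carries information
  beyond the SNPs. Background features are independent noise.
  Annotations enrich chosen modules with a chemical superclass at a 10%
  background rate.
* **Field designs**: blocks with one common check in every block and
  secondary checks in a third of blocks, unreplicated test lines, block /
  batch effects at configurable sd, plot residuals drawn from R0.

What passing tests do and do not show: linear architectures, Gaussian
noise, MCAR missingness and exchangeable environments are exactly the
assumptions of the fitted models, so recovery here demonstrates correct
implementation, not robustness to real-data violations (non-linear
QTL-metabolite maps, batch-confounded designs, informative missingness,
cross-panel feature mismatch). The paper-scale accuracies from the real
oat panels are not reproducible from this package alone.

## Numerical choices and degenerate inputs

* REML convergence: relative log-likelihood change < 1e-8 (500-iteration
  cap; tests needing structural equalities tighten to 1e-12).
* Variance components are floored slightly above zero inside EM to keep
  covariance matrices invertible; stage-one components at the optimizer's
  lower bound report as exact zeros.
* PCA signs follow the largest-magnitude-loading-positive convention;
  eigenvector signs align to member features.
* Wilcoxon with no non-zero differences returns p = 1 with a warning;
  constant predictions make scaled accuracy undefined (missing, with a
  warning); a zero-baseline repeat is excluded from percent change.
* Ties in the tree cut and medoid assignment resolve by first index;
  module labels are renumbered by decreasing size.
* Seeds: every stochastic operation takes an explicit seed; CV spawns
  per-repeat child streams from `numpy.random.SeedSequence` and records
  partition hashes.

## Known limitations

* The Dynamic-Hybrid cut is a faithful-by-behavior re-implementation, not
  an output-identical port; branch-level tie-breaking may differ from the
  reference on pathological dendrograms.
* EM-REML converges slowly when a component sits near zero; the
  max-iteration warning flags fits whose variances may be a few percent
  from the optimum (predictions are far less sensitive).
* The bivariate accuracy model can degenerate on small or noiseless test
  sets; the fallback to scaled correlation is logged.
* Multi-trait EM imputation understates R0 slightly under masking (see
  above).
* BayesB's inclusion probabilities are Monte-Carlo estimates; rank-based
  checks are stable at the default chain lengths, individual
  probabilities less so.
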