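# Methods

`pseudomics` implements the downstream statistics of a single-nucleus
multi-omic case/control study of psychiatric disease: pseudobulk
differential expression (DE) and chromatin-accessibility (DA) testing with
a data-driven covariate model, contrasts between propensity-matched extreme
polygenic-risk-score (PRS) groups, over-representation enrichment, and
multi-omic Spearman correlation networks. This note records the models, the
parameters that matter, the numerical choices, and what the synthetic
cohort does and does not emulate.

## Pseudobulk and QC

Nucleus counts are summed within each cell-type–donor pair (integer
arithmetic; totals are conserved exactly), or per donor across cell types
for the "full" pseudobulk used in covariate screening. RNA nuclei are
dropped when total counts < 500, detected genes < 300, or mitochondrial
fraction ≥ 15%; ATAC nuclei when outside 1,000–100,000 unique fragments or
below TSS enrichment 4. Features detected in fewer than 500 nuclei are
removed. All cutoffs are strict in the stated direction, so a nucleus
sitting exactly on a boundary is kept.

## Gene-activity scores

Accessibility at gene level is summarized from 501-bp peaks as

    score(g, s) = Σ_{p : d(p,g) ≤ 100 kb} exp(−d(p,g) / 5 kb) · count(p, s)

where d is 0 for peaks overlapping the gene body and otherwise the bp gap
to the nearest gene-body edge (intervals are 0-based half-open; two
intervals that abut have d = 0). The window is symmetric and strand is
ignored for the distance. The exponential kernel with a 5-kb decay is a
stipulated, documented choice — toolkits that produce such scores do not
expose a single closed-form model — and the important property, linearity
in peak counts, is tested. Scores are divided by the number of aggregated
cells per sample before testing; a second normalization raises an error.

## Covariate model

Screening runs once on the full pseudobulk (genes with ≥ 10 counts in 90%
of donors): counts are variance-stabilized, PCA is applied, and each
candidate covariate is tested against the first 10 PCs — Pearson
correlation with a t-test for continuous covariates (age, pH, PMI, RIN),
one-way ANOVA of PC scores by level for categoricals (sex, library batch),
the univariate equivalent of a canonical-correlation screen. A covariate is
selected when its minimum p over the 10 PCs is ≤ 0.05; under pure noise the
familywise selection rate is 1 − 0.95^10 ≈ 0.40, and the tests verify this
calibration rather than hide it.

The variance-stabilizing transform is median-of-ratios size factors
(median over all-positive genes of count / geometric mean) followed by
log2(count / sf + 1) — closed-form, rank-preserving within sample, and
exactly testable on hand fixtures. When no gene is positive in every
sample it falls back to total-count factors with a warning.

Missing RIN is imputed to the cohort median. The final model for every
per-gene test is

    ~ variable_of_interest + Sex + Age + pH + RIN + PMI + lib_batch + PC_noise

with continuous covariates centered, sex coded M = 1, batch one-hot with
the reference level dropped. For genetic-risk contrasts lib_batch is
omitted (too few donors per batch to support a categorical term), and the
DA model omits RIN (an RNA-quality covariate).

**PC_noise.** Each feature of the transformed matrix is residualized
against the design including the variable of interest; PC_noise is the
first principal component of the residual matrix, standardized to unit
variance. The residuals are not re-centered before the SVD — the intercept
already gives them zero mean, and any extra centering would break the
exact orthogonality of PC_noise to every design column, which is asserted
at machine precision. One noise PC is estimated, recomputed per
differential-testing dataset.

**Outliers.** Iteratively: PC1 scores of the current samples; remove those
more than 3 sample SDs (ddof = 1) from the score mean; recompute; stop when
nothing is removed or fewer than 3 samples remain. The count strictly
decreases, so termination is structural. Only PCA is recomputed between
rounds, not the transformation.

## Differential testing

**DE (counts).** Per gene, an NB GLM with log link and offset
log(size factor). Dispersion is gene-wise method-of-moments on normalized
counts, (s² − m)/m², floored at 1e-8; no shrinkage across genes — the one
intentional simplification relative to count toolkits, accepted because
validation is by calibration and recovery on synthetic data rather than by
replicating any particular gene list. Coefficients come from IRLS
(vectorized across genes; relative tolerance 1e-8, ≤ 100 iterations, a
1e-10 ridge on the weighted normal equations against degenerate weights,
linear predictors clipped at ±30); the Wald SE is from the expected
information matrix, the reference is normal, log2FC = β/ln 2. All-zero and
non-converged genes are reported with NA statistics. At the dispersion
floor the fit coincides with a Poisson GLM, which is the test oracle.

**DA (gene scores).** OLS on log2(normalized score + 1); the group
coefficient is the log2FC; Wald statistic β/SE with a t reference
(df = n − p), conservative at small n. Residual normality is summarized by
gene-wise Shapiro–Wilk (advisory; never gates results).

**FDR.** Benjamini–Hochberg step-up with enforced monotonicity; NA p-values
pass through and do not count toward m. Genes at FDR ≤ 0.1 are reported as
significant. The pipeline order is fixed: feature filter (counts ≥ 10 in
75% of samples; scores > 0.1 in 75%) → size factors / normalization →
outlier removal → imputation → design with PC_noise → fit → BH. Cell types
with fewer than 6 surviving samples are skipped with a warning.

## Extreme genetic-risk groups

Per trait, the 20 highest- and 20 lowest-PRS donors form candidate pools
(one global PRS-descending ranking, ties broken by donor id, keeps the
pools disjoint). A logistic regression of pool membership on age, pH, PMI
and RIN (standardized; sex excluded because it is matched exactly) gives
propensities; under separation or non-convergence a linear-discriminant
fallback is used with a warning, and scores are clipped to (1e-6, 1−1e-6)
so logit distances stay finite.

Candidates outside the common support of the two propensity distributions
are discarded before pairing. This step matters: with equal-size pools,
plain 1:1 greedy matching pairs every donor, so matching could never
improve covariate balance; discarding the non-overlapping extremes is what
lets the matched subsets be more comparable than the raw pools, and it
reproduces the qualitative behaviour of matched groups shrinking well
below the pool size. Within each sex stratum, high-pool donors are then
processed in descending propensity and greedily take the nearest unmatched
low-pool donor by |logit propensity| distance, without replacement and
without a caliper; unmatched donors are excluded. Matched groups are
equal-sized by construction, every pair shares a sex (asserted on every
run), and a balance table reports pre/post standardized mean differences.

## Enrichment, networks, comparisons

Over-representation uses the exact upper-tail hypergeometric p = P(X ≥ k)
with BH across sets (significance FDR ≤ 0.05). Pathway enrichment takes,
per cell type and direction, the 250 genes with the most significant up-
or down-regulation (ranked by FDR, then |log2FC|, then gene id — fully
deterministic), against the universe of genes tested in that cell type;
directions with < 10 genes are skipped. Motif enrichment contrasts the
peaks in a gene's promoter window — 2 kb upstream to 500 bp downstream of
the TSS, strand-aware, configurable — against all annotated peaks, one
test per motif.

Networks: expression and accessibility features are residualized against
sex, age, RIN, PMI, pH and batch; PRS and status nodes enter uncorrected.
Spearman rho uses average ranks; p from the t approximation with
df = n − 2 (a 10,000-draw permutation oracle backs this in the tests);
edges keep nominal p ≤ 0.05 with weight |rho| and the sign retained.

Cell-type proportions between modalities are compared per cell type with
the two-sided Wilcoxon signed-rank test on donor-paired differences
(zeros dropped — the classic convention; exact null for n ≤ 25, normal
approximation with continuity correction above), BH across cell types,
plus per-donor Pearson correlations of the proportion vectors. Cross-study
effect-size comparison is the Pearson correlation of per-gene log2FCs over
shared genes, per cell-type pair, NA below 3 shared genes.

## Synthetic cohort

The generator emulates the study's data structure so every stage is
testable without restricted human data. Donors draw age ~ N(54.27, 13.64),
PMI ~ N(33.90, 14.82) truncated at 0, pH ~ N(6.60, 0.24), 38% female;
cases (62% of donors) carry schizophrenia/schizoaffective/MDD/bipolar
labels in proportions 38:7:7:5; exactly one donor has missing RIN so the
imputation path always runs; batches are round-robin. PRS is built from a
liability-threshold model (cases' latent liability above the threshold,
controls' below) with a configurable PRS–liability correlation
(default 0.3), standardized — both PRS tails therefore mix cases and
controls, as in real cohorts.

Expression pseudobulk is negative binomial with
log2 mean = gene baseline (U(3,9)) + library offset (evenly spaced over a
4-fold range, shuffled) + status effect + PRS effect (slope lfc/2 per PRS
SD) + one hidden donor factor + batch offsets + small covariate effects;
dispersion defaults to 0.1. Gene scores are log-normal with the same
planted structure, scaled by cell counts so downstream normalization
recovers the per-cell signal. A per-nucleus mode draws gamma-mixed Poisson
nuclei whose donor sums are exactly NB, for QC/aggregation tests. Cell-type
compositions are drawn once per donor and shared between modalities with
modality-specific capture noise, so cross-modality proportion correlations
are realistically high. All truth (effects, loadings, hidden factor
values) is recorded before noise is drawn.

What the generator does not emulate: raw reads and fragments, ambient
contamination, doublets, dropout structure beyond NB sampling, dispersion
trends in expression strength, LD structure behind PRS, or correlated gene
modules (genes are independent given the planted factors). Passing tests
therefore certify the statistics — calibration, recovery, invariants — not
robustness to every artefact of real single-nucleus data.

## Simulation scale and defaults

Calibration suites use 2,000 genes × 40 donors over 20–50 seeds; recovery
uses 200 genes at 20 vs 20 donors with dispersion 0.1 and unit log2FC; the
hidden-factor benchmark plants a design-orthogonal factor at SNR 2 (loading
sqrt(2·(1/μ + α))/ln 2); the matching benchmark confounds PRS with age at
0.03 per year (pool-level age SMD ≈ 1, matched sizes ≈ 11–17); the
end-to-end run is 90 donors × 8 cell types × 1,500 genes with 5,000 peaks,
50 motifs, 30 gene sets. These sizes leave every property overwhelmingly
powered while keeping the full suite around a minute and a half.

## Known limitations

- No dispersion shrinkage: at very small n the NB Wald test relies on the
  MoM estimate and a normal reference; calibration is verified at n = 40
  but will degrade below ~12 samples per group.
- The DA log2FC is the model coefficient on log2(score + 1); near-zero
  scores compress effects toward zero (visible as the small negative bias
  in the recovery benchmark).
- The gene-score kernel is a stand-in for toolkit-internal weighting;
  absolute scores are not comparable to any specific toolkit's, though the
  linear-in-counts property and window semantics are guaranteed.
- Greedy matching is order-dependent by design (deterministic), not
  optimal matching; no caliper is applied beyond common-support
  discarding.
- Covariate screening reports associations; the final model always uses
  the fixed covariate set above, mirroring the analysis it reimplements.
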