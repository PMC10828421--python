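# Methods

This note documents the statistical models implemented in `mgwas`, the
choices made where the design was genuinely open, and what the synthetic
validation does and does not demonstrate.

## Quality control

Variants are kept when minor allele frequency ≥ 1% (computed from mean
dosage; invariant under REF/ALT swap), exact-test Hardy–Weinberg p > 10⁻⁶,
and call rate > 98%. The HWE test is the exact conditional test: it
conditions on the observed allele counts and sums the probabilities of every
heterozygote count whose conditional probability does not exceed that of the
observed count. No mid-p adjustment is applied. Because this null
distribution is discrete, the resulting p-values are conservative and not
exactly uniform under HWE (a noticeable point mass sits at p = 1); the test
suite therefore checks tail calibration of the exact test and checks
uniformity on the asymptotic chi-square analogue. Missing dosages are
mean-imputed per variant after QC. Microbial features are kept when
prevalence and mean relative abundance *strictly* exceed 10% and 10⁻⁴
(strict because the canonical boundary case — a feature present in 141 of
1401 samples, 10.06% — is kept).

## Diversity and ordination

Shannon entropy is reported in nats and Simpson as 1 − Σp², the defaults of
vegan's `diversity`. β-diversity is Bray–Curtis on relative abundances, raw
(not square-root transformed). PCoA Gower-centres G = −½·J·D²·J and
eigendecomposes; axes are eigenvectors scaled by √eigenvalue, negative
eigenvalues are reported but neither corrected (no Lingoes/Cailliez) nor
included in total inertia. Axis signs are fixed so the largest-magnitude
score on each axis is positive, for reproducibility. Host PCA standardizes
each variant as (g − 2p̂)/√(2p̂(1−p̂)) and takes left singular vectors scaled
by singular values; monomorphic variants are dropped with a warning.

## Feature decorrelation

Pairwise Spearman correlations (on raw relative abundances, zeros included —
rank-based, so monotone transforms are irrelevant) define a graph with an
edge when |ρ| > 0.995 (configurable; signed ρ and ρ² are available because
conventions differ). The greedy pass keeps the max-degree node (seeded
random tie-break), deletes it and its neighbours, and recomputes degrees on
the residual graph. By construction the kept set is an independent set and a
dominating set: every discarded feature is correlated beyond threshold with
its recorded representative.

## Association models

Features split by prevalence: > 95% → **AB channel**, 10–95% → **PA
channel**. The AB channel uses the two-stage residual scheme: log₁₀
abundance (zeros floored at half the feature's smallest nonzero value) is
residualized once on the covariate roster (age, sex, BMI, sequencing read
count, top ten host PCs), then each variant is tested by univariate
regression of the residuals on dosage. This is faster than per-variant
multiple regression and matches the two-stage convention; the residual df of
the second stage (n − 2) is slightly generous because the first-stage
covariates are not re-counted — negligible at cohort sizes of interest and
confirmed calibrated by the null suite. The PA channel fits logistic
regression with covariates in-model by Newton/IRLS, warm-started per variant
from the covariate-only fit, and reports a Wald z test on the dosage
coefficient; non-convergence and quasi-separation are flagged results, never
exceptions.

β-diversity associations use Pillai's trace. For a single-df hypothesis the
trace reduces to V = h′S⁻¹h, where h is the cross-product of the
covariate-residualized PCo matrix with the normalized covariate-residualized
dosage and S the residualized responses' SSCP; F = V/(1−V)·(νₑ−k+1)/k on
(k, νₑ−k+1) df. This rank-1 identity makes the scan fully vectorized and is
verified against the explicit H/E SSCP eigendecomposition in the tests.

λ_GC is the median association chi-square divided by 0.4549 (the χ²₁
median). Clumping is greedy by ascending p among results below the
significance cutoff: the best unassigned variant indexes a locus and absorbs
unassigned variants that are *both* within 1 Mb *and* at dosage r² ≥ 0.2
with it (an `or` reading is available by flag). LD is composite (squared
Pearson correlation of dosages; no phasing). Bonferroni thresholds are
α/m — e.g. 5×10⁻⁸/293 = 1.71×10⁻¹⁰ study-wide for 293 decorrelated
features, 0.05/402 = 1.24×10⁻⁴ for a 402-pair MR batch.

## Variance partitioning

dbRDA projects the positive-eigenvalue PCoA axes (scaled by √eigenvalue) on
the predictors; R² is fitted sum of squares over total inertia (sum of
positive eigenvalues), and the Ezekiel adjustment
adj R² = 1 − (1−R²)(n−1)/(n−p−1) corrects for predictor count. Forward
selection adds the candidate maximizing adjusted R² subject to (a) strict
increase, (b) an optional row-permutation p ≤ α_in, and (c) never exceeding
the all-candidates adjusted R². In (c) and in per-step penalties the
predictor count is the *effective rank* of the block (QR column dropping),
so duplicated or collinear candidates neither earn adjusted R² nor tighten
the bound. A consequence of the scope bound worth knowing: when the
candidate pool is one real signal plus pure noise, the all-candidates
adjusted R² equals the single-signal adjusted R² in expectation and the
bound blocks selection in about half of replicates; with realistically
pre-screened candidate pools (top-associated lead SNPs) this does not arise.

The permutation null for genotype-explained β-diversity variance shuffles
the sample→species-profile assignment (genotypes and covariates stay with
the individual; the distance matrix and PCos permute coherently), then
re-runs the *entire* pipeline — MANOVA scan, clumping to the top n loci,
forward selection of the lead variants — inside every permutation, so
selection bias is identical under the observed and null runs. The reported
p is the plain fraction of permutations with adjusted R² ≥ observed (the
(k+1)/(n+1) estimator is available by flag). A one-sample t-test p of the
permuted list against the observed value is also emitted because both
summaries circulate in the literature; note a permutation fraction over 100
permutations cannot be smaller than 0.01, so t-test p's far below that are a
different (parametric) statement, not a sharper permutation p. Inside the
nested permutation pipeline the forward-selection permutation gate defaults
off (α_in = 1, adjusted-R²-only stopping): a permutation test inside each of
100 outer permutations would multiply cost by two orders of magnitude while
the outer-null statistic only needs the cumulative adjusted R²; the gate
remains available for one-shot analyses.

## Screening and enrichment

The observational scan regresses each trait on each feature (log₁₀
abundance for AB features, 0/1 presence for PA) with covariates in-model —
by default age, sex, BMI, read depth and the top *four* host PCs, a smaller
roster than the GWAS uses, both configurable — and applies
Benjamini–Hochberg jointly across all pairs. BH adjusted values preserve the
ordering of raw p's and lie in [p, 1]; BH is not idempotent on its own
output (re-adjusting adjusted values inflates them), which is a property of
the step-up formula, not a defect. PheWAS enrichment builds, per trait, the
2×2 table of (microbiome-associated variants vs background universe) ×
(trait-associated vs not) and applies the two-sided Fisher exact test
(probability-mass rule) with the sample odds ratio ad/bc; the background
universe is an explicit input because enrichment is only meaningful relative
to a stated variant pool.

## Mendelian randomization

One-sample, individual-level, bidirectional. Instruments: variants
associated with the exposure at p < 10⁻⁶, greedily clumped to pairwise
r² < 0.1 within 1 Mb, oriented so the effect allele increases the exposure.
Score: unweighted sum of oriented dosages. TSLS stage 1 regresses exposure
on [1, score, covariates] and keeps fitted values plus the partial F of the
score (t² of its coefficient — partial R² = F/(F+df) is reported as
instrument strength); stage 2 regresses the outcome on [1, fitted exposure,
covariates]. The standard error uses the proper TSLS residual — the stage-2
coefficients applied to the *observed* exposure — not the naive stage-2 OLS
residual. F < 10 flags a weak instrument but still returns the estimate.
Presence/absence exposures enter stage 1 as a 0/1 indicator in OLS (a linear
probability model); how dichotomous exposures should enter TSLS is genuinely
undetermined by convention, so this choice is stated rather than hidden.
Instruments are selected on the same sample used for estimation, as
one-sample designs do; the winner's-curse bias this induces is documented,
not corrected. No Egger/median sensitivity estimators are included.

## Synthetic cohort generator

The generator produces the structure the analysis assumes; every
distributional choice is a stand-in, not an estimate from real data.

* **Genotypes** — Balding–Nichols: ancestral frequency p ~ U(maf_range),
  two subpopulation frequencies ~ Beta(p(1−F)/F, (1−p)(1−F)/F) with
  F = F_ST (default 0.01; 0 disables structure), genotypes Binomial(2, ·).
  HWE holds within subpopulation by construction. Variants sit 10 kb apart
  on one chromosome and are generated independently (no LD beyond what
  structure induces), so clumping behaviour at fine LD scales is exercised
  by constructed fixtures, not by this generator.
* **Covariates** — age ~ N(30, 5), sex ~ Bernoulli(0.63), BMI ~ N(22, 3),
  read count ~ LogNormal, matching a young, majority-female deeply-sequenced
  cohort profile.
* **Abundances** — hurdle model: latent log₁₀ abundance = per-taxon baseline
  N(−2, 1) + planted per-allele AB effects + 0.05·z(age) + 0.05·z(BMI) +
  subpopulation shift N(0, 0.25) + confounder loadings + N(0, noise_sd²)
  (noise_sd default 1.0, log₁₀ units). The first ~20% of taxa are "core"
  with presence probability 0.995; the rest draw presence ~ U(0.15, 0.9);
  planted PA effects shift the presence log-odds per centred allele. Present
  values are closed to sum to one per sample. Closure attenuates planted
  per-taxon effects; the tests measure the attenuation factor empirically on
  replicates rather than assuming a value.
* **Traits** — α·log₁₀(abundance, half-minimum pseudocount) + confounder
  loadings·U + 0.05·z(age) + 0.05·sex + N(0, 1), with U ~ N(0, 1) drawn once
  per causal entry from a seed-derived stream shared with the abundance
  generator, so U loads on both the taxon and the trait. Naive regression of
  trait on taxon is then biased while the planted SNPs remain valid
  instruments (no direct SNP→trait path).

What passing tests show: the pipeline is calibrated under its own null
(per-feature λ_GC within [0.9, 1.1] and 5% type-I error at n = 500 with
5000 variants), recovers planted effects with correct sign and genome-wide
significance at standardized effect 0.3 and n = 1000, and the TSLS interval
covers a confounded causal effect where naive OLS misses by > 5 SE. What
they do not show: robustness to real-data features the generator omits —
LD blocks, batch effects, compositional microbe–microbe interactions,
non-Gaussian trait tails, population-scale relatedness.

## Validation problem sizes

The canned experiments (`mgwas.validation`, driven by
`scripts/acceptance.py` and the whole-pipeline tests) use: null calibration
at n = 500, 5000 variants, 20 features; recovery over 20 replicates at
n = 1000; MR coverage over 100 replicates at n = 2000 with five instruments
(per-allele effect 0.55, first-stage F well above 30); permutation nulls at
n = 400 with 500 variants, 100 permutations, top-5 loci, with 20 independent
null cohorts for the calibration check; greedy invariants on 20 random
graphs of 10–40 nodes. These sizes were chosen once as the package's
standing validation conditions so results are comparable across runs.

## Numerical conventions

OLS fits go through QR/least-squares, never explicit normal equations,
except in tiny closed-form oracles inside the tests. Logistic IRLS caps the
linear predictor at ±35, declares convergence at step < 10⁻⁸ (10⁻⁶ in the
per-variant scan), and flags |β| > 100 or vanishing working weights as
separation. PCoA eigenvalues within 10⁻¹² of the largest (or below 10⁻⁹
absolute) count as zero. Degenerate inputs fail loudly and specifically:
all-zero abundance rows name the sample, rank-deficient designs name the
collinear column, zero-variance predictors name the predictor; monomorphic
variants in scans are flagged rows, not errors, because skipping silently
would corrupt multiplicity accounting.
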