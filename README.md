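# mgwas — metagenome genome-wide association toolkit

`mgwas` is a Python library and command-line tool for asking how much a host's
genome shapes its microbiome, in the style of a metagenome genome-wide
association study (M-GWAS) of a shotgun-sequenced cohort such as a nasal-swab
study. It takes genotypes (VCF or dosage TSV), a MetaPhlAn-style relative-
abundance table, and covariate/trait tables, and provides the full analysis
chain a microbiome-GWAS group needs:

* **QC** — variant filters (MAF ≥ 1%, exact-test HWE p > 10⁻⁶, call rate
  > 98%) and feature filters (prevalence > 10%, mean relative abundance
  > 10⁻⁴);
* **ecology** — Shannon/Simpson α-diversity, Bray–Curtis β-diversity, PCoA
  (Gower centering, negative eigenvalues reported, not corrected), host
  genetic PCA, and covariate-adjusted host-PC ↔ diversity associations;
* **feature decorrelation** — the greedy correlation-graph algorithm:
  connect features with |Spearman ρ| > 0.995, repeatedly keep the
  highest-degree node and delete it with its neighbours; the kept set is an
  independent *and* dominating set, so every discarded feature has a kept
  representative;
* **association engine** — prevalence-dispatched per-feature GWAS: features
  present in > 95% of samples are tested with a linear model on
  covariate-residualized log₁₀ abundance (AB channel), features present in
  10–95% with covariate-adjusted logistic regression on presence/absence (PA
  channel, Wald test); β-diversity is tested against every variant with a
  Pillai-trace MANOVA of the top principal coordinates; λ_GC inflation
  control, greedy LD clumping into independent loci (< 1 Mb, r² ≥ 0.2), and
  Bonferroni thresholds (e.g. 5×10⁻⁸ / 293 features = 1.71×10⁻¹⁰);
* **variance partitioning** — distance-based redundancy analysis with the
  Ezekiel adjustment adj R² = 1 − (1 − R²)(n − 1)/(n − p − 1), forward
  selection, and a permutation null that shuffles the sample→profile
  assignment and re-runs the whole scan→clump→select pipeline inside every
  permutation;
* **screening** — trait × microbe observational scan with joint
  Benjamini–Hochberg FDR, and Fisher-exact PheWAS enrichment of
  microbiome-associated variants;
* **causal inference** — one-sample bidirectional Mendelian randomization:
  instruments at p < 10⁻⁶ clumped to LD r² < 0.1, an unweighted genetic risk
  score (sum of risk-increasing allele counts), and two-stage least squares
  with proper TSLS standard errors, first-stage partial F and instrument R²;
* **simulation** — a synthetic genotype–microbiome–trait cohort generator
  (Balding–Nichols population structure, hurdle-model compositional
  abundances with planted SNP effects, confounded taxon→trait causal
  effects) with a truth table, used throughout the test suite to verify the
  pipeline recovers what was planted.

## Worked example

Plant a single abundance effect (standardized effect 0.3 at MAF 0.3, i.e.
per-allele β ≈ 0.463 on latent log₁₀ abundance) in a 1000-sample synthetic
cohort and scan the affected taxon against 200 variants:

```python
from mgwas import SimConfig, simulate_cohort, feature_gwas, lambda_gc
from mgwas.simulate import beta_for_standardized

beta = beta_for_standardized(0.3, maf=0.3, noise_sd=1.0)   # 0.4629
cfg = SimConfig(n_samples=1000, n_variants=200, n_taxa=15, fst=0.0,
                maf_range=(0.3, 0.3), effect_table=[(0, 0, beta, "AB")], seed=7)
c = simulate_cohort(cfg)
feat = c.abundance.features[0]
res = feature_gwas(c.abundance.values[feat], c.genotypes, c.covariates, feature=feat)
print(res.sort_values("p").head(3)[["model", "variant_id", "beta", "se", "p"]])
print("lambda_GC:", round(lambda_gc(res["p"].dropna()), 3))
```

```
model variant_id      beta       se            p
   AB       var0  0.381490 0.047885 4.420405e-15
   AB      var36 -0.152821 0.049727 2.175146e-03
   AB      var59  0.137862 0.050733 6.693338e-03
lambda_GC: 1.001
```

The planted variant `var0` tops the scan at p ≈ 4×10⁻¹⁵, well past the
genome-wide 5×10⁻⁸ line. Its estimate (0.38) sits slightly below the planted
0.46 because closing the composition (dividing by the per-sample sum)
attenuates per-taxon effects — the test suite measures this attenuation
empirically rather than assuming it away. λ_GC ≈ 1.0 shows the remaining 199
null variants are well calibrated.

The same pipeline runs from the shell:

```bash
mgwas simulate --out cohort --seed 5
mgwas run --config run.yaml          # QC → diversity → GWAS → clump → varpart → scan → MR
```

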