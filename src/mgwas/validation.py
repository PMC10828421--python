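"""Canned validation experiments on synthetic cohorts.

These routines define the study conditions used to validate the pipeline:
null calibration of the per-feature GWAS channels, recovery of planted
abundance effects, instrumented-estimate coverage under confounding, the
genotype-variance permutation null with and without planted structure, and
the structural invariants of the greedy feature selection.  Problem sizes are
fixed here (and documented in the methods note) so that results are
comparable across runs; only the seed varies.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulate import SimConfig, simulate_cohort, beta_for_standardized
from . import assoc, causal, varpart, featsel


def null_calibration(
    seed: int, n_samples: int = 500, n_variants: int = 5000, n_taxa: int = 20
) -> dict:
    """Per-feature lambda_GC and empirical type-I error on a null cohort."""
    c = simulate_cohort(
        SimConfig(n_samples=n_samples, n_variants=n_variants, n_taxa=n_taxa,
                  fst=0.0, seed=seed)
    )
    G = c.genotypes.imputed().dosages
    lambdas, type_i, models = [], [], []
    for feat in c.abundance.features:
        v = c.abundance.values[feat].to_numpy()
        model = assoc.choose_model(float((v > 0).mean()))
        if model == "AB":
            resid = assoc.residualize_log_abundance(v, c.covariates)
            res = assoc.linear_gwas(resid, G)
        else:
            res = assoc.logistic_gwas((v > 0).astype(float), G, c.covariates)
        p = res["p"].dropna().to_numpy()
        lambdas.append(assoc.lambda_gc(p))
        type_i.append(float((p < 0.05).mean()))
        models.append(model)
    return {
        "lambda_gc": lambdas,
        "type_i_error": type_i,
        "models": models,
        "n_tests": n_variants * n_taxa,
    }


def ab_recovery(
    seed: int, n_reps: int = 20, n_samples: int = 1000, target: float = 0.3,
    maf: float = 0.3,
) -> dict:
    """Detection and sign-recovery rates for a planted AB effect.

    The per-allele effect is chosen so the standardized effect on the latent
    log10 abundance equals ``target`` at the configured MAF.
    """
    beta = beta_for_standardized(target, maf, 1.0)
    detected = sign_ok = 0
    for rep in range(n_reps):
        cfg = SimConfig(
            n_samples=n_samples, n_variants=30, n_taxa=15, fst=0.0,
            maf_range=(maf, maf), effect_table=[(0, 0, beta, "AB")],
            seed=seed * 1000 + rep,
        )
        c = simulate_cohort(cfg)
        resid = assoc.residualize_log_abundance(
            c.abundance.values.iloc[:, 0], c.covariates
        )
        res = assoc.linear_gwas(resid, c.genotypes.imputed().dosages)
        row = res.iloc[0]
        if row["p"] < 5e-8:
            detected += 1
        if row["beta"] > 0:
            sign_ok += 1
    return {"detected": detected, "sign_correct": sign_ok, "n_reps": n_reps,
            "planted_beta": beta}


def mr_coverage(
    seed: int, n_reps: int = 100, n_samples: int = 2000, alpha: float = 0.4
) -> dict:
    """TSLS coverage and naive-OLS bias under a shared confounder.

    Five unlinked variants instrument the exposure taxon (per-allele effect
    0.55 on latent log10 abundance, giving first-stage F well above 30 at
    n = 2000); the confounder loads +1 on the taxon and -1 on the trait, so
    observational regression is badly biased while the instruments stay valid.
    """
    instruments = (0, 6, 12, 18, 24)
    cover = 0
    bias_se = []
    f_stats = []
    for rep in range(n_reps):
        cfg = SimConfig(
            n_samples=n_samples, n_variants=30, n_taxa=10, n_traits=1, fst=0.0,
            effect_table=[(j, 0, 0.55, "AB") for j in instruments],
            causal_table=[(0, 0, alpha, 1.0, -1.0)],
            seed=seed * 1000 + rep,
        )
        c = simulate_cohort(cfg)
        v = c.abundance.values.iloc[:, 0].to_numpy()
        expo = np.log10(np.maximum(v, assoc.half_min_pseudocount(v)))
        y = c.traits["trait0"].to_numpy()
        resid = assoc.residualize_log_abundance(v, c.covariates)
        ss = assoc.linear_gwas(resid, c.genotypes.imputed().dosages,
                               variant_ids=c.genotypes.variants["id"])
        est = causal.mr_one_direction(expo, y, ss, c.genotypes, c.covariates)
        if not est.estimable:
            continue
        if est.beta - 1.96 * est.se <= alpha <= est.beta + 1.96 * est.se:
            cover += 1
        f_stats.append(est.first_stage_f)
        ols = assoc.covariate_gwas(y, expo[:, None], c.covariates)
        bias_se.append(abs(float(ols["beta"][0]) - alpha) / float(ols["se"][0]))
    return {
        "coverage": cover,
        "n_reps": n_reps,
        "bias_in_se": bias_se,
        "min_f": min(f_stats) if f_stats else np.nan,
    }


def _planted_composition_config(seed: int, n_samples: int = 400,
                                n_variants: int = 500) -> SimConfig:
    """Five variants with ~0.4-standardized effects on pairs of core taxa."""
    effects = []
    for i, v in enumerate([10, 110, 210, 310, 410]):
        tx_a = i % 4
        tx_b = tx_a + 1 if tx_a + 1 < 4 else 0
        for tx in (tx_a, tx_b):
            effects.append((v, tx, beta_for_standardized(0.4, 0.3, 1.0), "AB"))
    return SimConfig(n_samples=n_samples, n_variants=n_variants, n_taxa=20,
                     fst=0.0, effect_table=effects, seed=seed)


def permutation_null_planted(seed: int, n_perm: int = 100) -> dict:
    """Permutation-null empirical p with planted genotype->composition structure."""
    c = simulate_cohort(_planted_composition_config(seed))
    res = varpart.snp_variance_permutation_null(
        c.abundance, c.genotypes, c.covariates, n_top=5, n_perm=n_perm, seed=seed
    )
    return {"empirical_p": res.empirical_p, "observed_r2": res.observed_r2,
            "mean_permuted_r2": float(np.mean(res.permuted_r2)), "n_perm": n_perm}


def permutation_null_null(seed: int, n_runs: int = 20, n_perm: int = 100) -> dict:
    """Permutation-null empirical p's over repeated null cohorts."""
    ps = []
    for run in range(n_runs):
        c = simulate_cohort(
            SimConfig(n_samples=400, n_variants=500, n_taxa=20, fst=0.0,
                      seed=seed * 1000 + run)
        )
        res = varpart.snp_variance_permutation_null(
            c.abundance, c.genotypes, c.covariates, n_top=5, n_perm=n_perm,
            seed=seed + run,
        )
        ps.append(res.empirical_p)
    return {"empirical_p": ps, "n_runs": n_runs}


def greedy_invariant_violations(seed: int, n_fixtures: int = 20) -> dict:
    """Count dominating-set / independent-set violations on random graphs."""
    rng = np.random.default_rng(seed)
    violations = 0
    for fix in range(n_fixtures):
        n = int(rng.integers(10, 40))
        density = float(rng.uniform(0.05, 0.4))
        adj = np.triu(rng.random((n, n)) < density, 1)
        adj = adj | adj.T
        names = [f"f{i}" for i in range(n)]
        kept, rep = featsel.greedy_from_adjacency(adj, names, seed=fix)
        kept_idx = [names.index(k) for k in kept]
        for a in kept_idx:
            for b in kept_idx:
                if a != b and adj[a, b]:
                    violations += 1       # kept set not independent
        discarded = set(names) - set(kept)
        if set(rep) != discarded:
            violations += 1
        for dname, rname in rep.items():
            if not adj[names.index(dname), names.index(rname)]:
                violations += 1           # representative not adjacent
    return {"violations": violations, "n_fixtures": n_fixtures}
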