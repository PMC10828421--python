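"""Observational trait-microbe scanning and PheWAS enrichment.

The scan regresses each host trait on each microbial feature (log10 abundance
for abundant features, 0/1 presence otherwise) with covariates in-model, and
controls the false discovery rate by Benjamini-Hochberg across all pairs
jointly.  PheWAS enrichment asks, per trait, whether microbiome-associated
variants (MAVs) hit the trait more often than the background variant universe,
by a two-sided Fisher exact test on the 2x2 table.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_qc import AbundanceTable
from .assoc import choose_model, half_min_pseudocount, _design


@dataclasses.dataclass
class EnrichmentResult:
    trait: str
    table: tuple   # ((a, b), (c, d)) = (MAV hit, MAV miss), (bg hit, bg miss)
    odds_ratio: float
    p: float
    fdr_p: float = np.nan


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserved)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fisher_exact(table) -> tuple[float, float]:
    """Two-sided Fisher exact p (probability-mass rule) and sample odds ratio.

    A zero margin yields p = 1 and a missing (NaN) odds ratio.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("table must be 2x2 non-negative integers")
    t = t.astype(int)
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return 1.0, np.nan
    res = stats.fisher_exact(t, alternative="two-sided")
    a, b, c, d = t.ravel()
    orat = (a * d) / (b * c) if b * c > 0 else np.inf
    return float(res.pvalue), float(orat)


def trait_microbe_scan(
    features: AbundanceTable,
    traits: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    prevalence_split: float = 0.95,
) -> pd.DataFrame:
    """OLS scan of every trait on every feature with covariates in-model.

    Abundant features (prevalence > ``prevalence_split``) enter as log10
    abundance (half-minimum pseudocount for zeros), the rest as a 0/1 presence
    indicator.  BH adjustment is applied across all pairs jointly.  Constant
    traits are skipped with a reason column.
    """
    prev = features.prevalence
    n = features.n_samples
    C = _design(covariates, n)
    rows = []
    for feat in features.features:
        v = features.values[feat].to_numpy(dtype=float)
        model = choose_model(max(prev[feat], 0.10001))
        if model == "AB":
            x = np.maximum(v, half_min_pseudocount(v))
            x = np.log10(x)
        else:
            x = (v > 0).astype(float)
        X = np.column_stack([C, x])
        xtx_inv = np.linalg.pinv(X.T @ X)
        df = n - X.shape[1]
        for trait in traits.columns:
            y = traits[trait].to_numpy(dtype=float)
            if np.ptp(y) == 0:
                rows.append((feat, trait, model, np.nan, np.nan, np.nan, "constant_trait"))
                continue
            coef = xtx_inv @ (X.T @ y)
            resid = y - X @ coef
            sigma2 = float(resid @ resid) / df
            se = np.sqrt(sigma2 * xtx_inv[-1, -1])
            beta = float(coef[-1])
            t = beta / se if se > 0 else np.nan
            p = 2.0 * stats.t.sf(abs(t), df)
            rows.append((feat, trait, model, beta, float(se), float(p), None))
    out = pd.DataFrame(
        rows, columns=["feature", "trait", "model", "beta", "se", "p", "flag"]
    )
    ok = out["p"].notna()
    out["fdr_p"] = np.nan
    if ok.any():
        out.loc[ok, "fdr_p"] = bh_fdr(out.loc[ok, "p"].to_numpy())
    return out


def phewas_enrichment(
    assoc_matrix: pd.DataFrame,
    mav_ids,
    universe=None,
) -> list[EnrichmentResult]:
    """Per-trait Fisher enrichment of MAVs among trait-associated variants.

    ``assoc_matrix`` is a variants x traits boolean indicator of variant-trait
    association; ``mav_ids`` the microbiome-associated variants; ``universe``
    the background variant set (defaults to all rows of the matrix).  Traits
    with no associated variant anywhere are skipped; BH adjusts across the
    tested traits.
    """
    mav_ids = list(mav_ids)
    if len(mav_ids) == 0:
        raise ValueError("MAV set is empty")
    if universe is None:
        universe = list(assoc_matrix.index)
    universe = list(universe)
    mav_set = set(mav_ids)
    bg_ids = [v for v in universe if v not in mav_set]
    results = []
    for trait in assoc_matrix.columns:
        hits = assoc_matrix[trait].astype(bool)
        if not hits.any():
            continue
        a = int(hits.reindex(mav_ids, fill_value=False).sum())
        b = len(mav_ids) - a
        c = int(hits.reindex(bg_ids, fill_value=False).sum())
        dd = len(bg_ids) - c
        p, orat = fisher_exact(((a, b), (c, dd)))
        results.append(EnrichmentResult(trait, ((a, b), (c, dd)), orat, p))
    if results:
        adj = bh_fdr([r.p for r in results])
        for r, q in zip(results, adj):
            r.fdr_p = float(q)
    return results
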