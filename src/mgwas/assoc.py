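"""The M-GWAS association engine.

Microbial features are dispatched by prevalence: features present in more than
95% of samples use a linear model on log10 relative abundance (AB channel,
two-stage residual scheme: residualize once on covariates, then a univariate
regression per variant); features present in 10-95% use a logistic model on
presence/absence (PA channel, covariates in-model, Wald test on the dosage
coefficient).  Multivariate genotype -> beta-diversity association uses
Pillai's trace MANOVA of the top principal coordinates on dosage plus
covariates.  Genome-wide inflation (lambda_GC), greedy LD clumping into
independent loci, and Bonferroni thresholds complete the engine.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .io_qc import GenotypeMatrix

CHI2_NULL_MEDIAN = 0.45493642311957   # median of chi-square with 1 df


@dataclasses.dataclass
class AssocResult:
    """One feature-variant (or x-y) association fit."""

    feature: str
    model: str          # "linear" | "logistic" | "manova"
    n: int
    beta: float
    se: float
    stat: float
    p: float
    variant_id: str | None = None
    chrom: str | None = None
    pos: int | None = None
    flag: str | None = None   # e.g. "not_converged", "monomorphic"


@dataclasses.dataclass
class ManovaResult:
    variant_id: str
    pillai: float
    f_stat: float
    df1: int
    df2: int
    p: float
    n: int


@dataclasses.dataclass
class LocusClump:
    index_id: str
    index_p: float
    members: list
    span_bp: int


def choose_model(prevalence: float) -> str:
    """AB (linear, log abundance) if prevalence > 0.95, else PA (logistic)."""
    if prevalence <= 0.10:
        raise ValueError(
            f"prevalence {prevalence:.3f} <= 0.10; feature should have been filtered"
        )
    if prevalence > 1.0:
        raise ValueError("prevalence cannot exceed 1")
    return "AB" if prevalence > 0.95 else "PA"


def half_min_pseudocount(values: np.ndarray) -> float:
    """Half the smallest nonzero value; floor for log of zero abundances."""
    nz = values[values > 0]
    if nz.size == 0:
        raise ValueError("feature has no nonzero abundance")
    return float(nz.min() / 2.0)


def _design(covariates: pd.DataFrame | None, n: int) -> np.ndarray:
    if covariates is None:
        return np.ones((n, 1))
    return np.column_stack([np.ones(n), covariates.to_numpy(dtype=float)])


def _ols_fit(X: np.ndarray, y: np.ndarray, coef_index: int):
    """OLS via QR; returns (beta, se, t, p, residuals) for one coefficient."""
    n, p = X.shape
    coef, res_ss, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    rss = float(resid @ resid)
    df = n - p
    if df <= 0:
        raise ValueError("no residual degrees of freedom")
    sigma2 = rss / df
    xtx_inv = np.linalg.inv(X.T @ X)
    se = float(np.sqrt(sigma2 * xtx_inv[coef_index, coef_index]))
    b = float(coef[coef_index])
    t = b / se if se > 0 else np.nan
    pval = 2.0 * stats.t.sf(abs(t), df) if np.isfinite(t) else np.nan
    return b, se, t, pval, resid


def residualize(Y: np.ndarray, covariates: pd.DataFrame | None) -> np.ndarray:
    """Residuals of each column of Y on [1, covariates] (mean zero)."""
    Y = np.asarray(Y, dtype=float)
    one_d = Y.ndim == 1
    if one_d:
        Y = Y[:, None]
    C = _design(covariates, Y.shape[0])
    coef, *_ = np.linalg.lstsq(C, Y, rcond=None)
    R = Y - C @ coef
    return R[:, 0] if one_d else R


def residualize_log_abundance(
    values, covariates: pd.DataFrame | None, pseudocount: float | None = None
) -> np.ndarray:
    """Covariate residuals of log10 abundance for an AB-channel feature.

    Zeros are floored at ``pseudocount`` (default: half the smallest nonzero
    value of the feature).
    """
    v = np.asarray(values, dtype=float)
    if (v == 0).any():
        pc = half_min_pseudocount(v) if pseudocount is None else pseudocount
        if pc <= 0:
            raise ValueError("zero abundance requires a positive pseudocount")
        v = np.maximum(v, pc)
    return residualize(np.log10(v), covariates)


# ---------------------------------------------------------------------------
# linear channel


def linear_assoc(residuals, dosage, feature: str = "feature") -> AssocResult:
    """Univariate regression of precomputed residuals on one dosage vector."""
    df = linear_gwas(residuals, np.asarray(dosage, float)[:, None])
    r = df.iloc[0]
    return AssocResult(
        feature=feature,
        model="linear",
        n=int(r["n"]),
        beta=r["beta"],
        se=r["se"],
        stat=r["stat"],
        p=r["p"],
        flag=r["flag"] if isinstance(r["flag"], str) else None,
    )


def linear_gwas(residuals, G: np.ndarray, variant_ids=None) -> pd.DataFrame:
    """Vectorized per-variant slope test of residuals on dosage columns.

    Monomorphic columns are reported with flag "monomorphic" and NaN
    statistics rather than raising.
    """
    y = np.asarray(residuals, dtype=float)
    G = np.asarray(G, dtype=float)
    n = y.shape[0]
    yc = y - y.mean()
    gc = G - G.mean(axis=0)
    sxx = (gc**2).sum(axis=0)
    sxy = gc.T @ yc
    syy = float(yc @ yc)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = sxy / sxx
        rss = syy - beta * sxy
        sigma2 = np.maximum(rss, 0.0) / df
        se = np.sqrt(sigma2 / sxx)
        t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    mono = sxx <= 0
    out = pd.DataFrame(
        {
            "variant_id": variant_ids if variant_ids is not None else np.arange(G.shape[1]),
            "n": n,
            "beta": np.where(mono, np.nan, beta),
            "se": np.where(mono, np.nan, se),
            "stat": np.where(mono, np.nan, t),
            "p": np.where(mono, np.nan, p),
            "flag": np.where(mono, "monomorphic", None),
        }
    )
    return out


def covariate_gwas(y, G: np.ndarray, covariates: pd.DataFrame | None, variant_ids=None) -> pd.DataFrame:
    """Per-variant OLS of y on [1, dosage, covariates] with covariates in-model.

    Implemented by the Frisch-Waugh-Lovell route: y and every dosage column
    are residualized on the covariates, then a univariate slope test with the
    degrees of freedom of the full model.
    """
    y = np.asarray(y, dtype=float)
    G = np.asarray(G, dtype=float)
    n = y.shape[0]
    n_cov = 0 if covariates is None else covariates.shape[1]
    yr = residualize(y, covariates)
    gr = residualize(G, covariates)
    sxx = (gr**2).sum(axis=0)
    sxy = gr.T @ yr
    syy = float(yr @ yr)
    df = n - n_cov - 2
    if df <= 0:
        raise ValueError("no residual degrees of freedom")
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = sxy / sxx
        rss = syy - beta * sxy
        se = np.sqrt(np.maximum(rss, 0.0) / df / sxx)
        t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    mono = sxx <= max(1e-12, 1e-12 * n)
    return pd.DataFrame(
        {
            "variant_id": variant_ids if variant_ids is not None else np.arange(G.shape[1]),
            "n": n,
            "beta": np.where(mono, np.nan, beta),
            "se": np.where(mono, np.nan, se),
            "stat": np.where(mono, np.nan, t),
            "p": np.where(mono, np.nan, p),
            "flag": np.where(mono, "monomorphic", None),
        }
    )


def diversity_gwas(
    y, g: GenotypeMatrix, covariates: pd.DataFrame | None, feature: str = "diversity"
) -> pd.DataFrame:
    """GWAS of a diversity index or PCo with covariates in the model."""
    out = covariate_gwas(
        y, g.imputed().dosages, covariates, variant_ids=g.variants["id"].to_numpy()
    )
    out.insert(0, "feature", feature)
    out["chrom"] = g.variants["chrom"].to_numpy()
    out["pos"] = g.variants["pos"].to_numpy()
    return out


# ---------------------------------------------------------------------------
# logistic channel


def _logistic_irls(X: np.ndarray, y: np.ndarray, beta0=None, max_iter=30, tol=1e-8):
    """Newton/IRLS logistic fit; returns (beta, cov, converged)."""
    n, p = X.shape
    beta = np.zeros(p) if beta0 is None else beta0.copy()
    converged = False
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -35, 35)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        if w.max() < 1e-12:
            break
        XtW = X.T * w
        H = XtW @ X
        grad = X.T @ (y - mu)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    eta = np.clip(X @ beta, -35, 35)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    H = (X.T * w) @ X
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
        converged = False
    # quasi-separation: fitted probabilities pinned at 0/1 or exploding coefs
    if converged and (np.max(np.abs(beta)) > 1e2 or w.max() < 1e-10):
        converged = False
    return beta, cov, converged


def logistic_assoc(
    presence, dosage, covariates: pd.DataFrame | None = None, feature: str = "feature"
) -> AssocResult:
    """Logistic regression of presence/absence on dosage plus covariates.

    Non-convergence or separation is reported as a flagged result with NaN
    statistics, never raised.
    """
    y = np.asarray(presence, dtype=float)
    d = np.asarray(dosage, dtype=float)
    n = y.shape[0]
    if np.ptp(d) == 0:
        return AssocResult(feature, "logistic", n, np.nan, np.nan, np.nan, np.nan,
                           flag="monomorphic")
    C = _design(covariates, n)
    X = np.column_stack([C, d])
    beta, cov, converged = _logistic_irls(X, y)
    if not converged or not np.isfinite(cov[-1, -1]) or cov[-1, -1] <= 0:
        return AssocResult(feature, "logistic", n, np.nan, np.nan, np.nan, np.nan,
                           flag="not_converged")
    b = float(beta[-1])
    se = float(np.sqrt(cov[-1, -1]))
    z = b / se
    p = 2.0 * stats.norm.sf(abs(z))
    return AssocResult(feature, "logistic", n, b, se, z, p)


def logistic_gwas(
    presence, G: np.ndarray, covariates: pd.DataFrame | None, variant_ids=None,
    tol: float = 1e-6,
) -> pd.DataFrame:
    """Per-variant logistic Wald scan, warm-started from the covariate-only fit."""
    y = np.asarray(presence, dtype=float)
    G = np.asarray(G, dtype=float)
    n, m = G.shape
    C = _design(covariates, n)
    base, _, base_ok = _logistic_irls(C, y)
    if not base_ok:
        base = np.zeros(C.shape[1])
    start = np.append(base, 0.0)
    X = np.column_stack([C, np.zeros(n)])
    rows = np.empty((m, 4))
    flags = np.full(m, None, dtype=object)
    for j in range(m):
        d = G[:, j]
        if np.ptp(d) == 0:
            rows[j] = np.nan
            flags[j] = "monomorphic"
            continue
        X[:, -1] = d
        beta, cov, converged = _logistic_irls(X, y, beta0=start, tol=tol)
        if not converged or not np.isfinite(cov[-1, -1]) or cov[-1, -1] <= 0:
            rows[j] = np.nan
            flags[j] = "not_converged"
            continue
        b = beta[-1]
        se = np.sqrt(cov[-1, -1])
        rows[j] = (b, se, b / se, 0.0)
    with np.errstate(invalid="ignore"):
        rows[:, 3] = 2.0 * stats.norm.sf(np.abs(rows[:, 2]))
    return pd.DataFrame(
        {
            "variant_id": variant_ids if variant_ids is not None else np.arange(m),
            "n": n,
            "beta": rows[:, 0],
            "se": rows[:, 1],
            "stat": rows[:, 2],
            "p": rows[:, 3],
            "flag": flags,
        }
    )


# ---------------------------------------------------------------------------
# feature GWAS dispatch


def feature_gwas(
    abundance_values: pd.Series | np.ndarray,
    g: GenotypeMatrix,
    covariates: pd.DataFrame | None,
    feature: str = "feature",
    prevalence: float | None = None,
) -> pd.DataFrame:
    """Run the prevalence-dispatched GWAS for one microbial feature."""
    v = np.asarray(abundance_values, dtype=float)
    if prevalence is None:
        prevalence = float((v > 0).mean())
    model = choose_model(prevalence)
    dimp = g.imputed().dosages
    ids = g.variants["id"].to_numpy()
    if model == "AB":
        resid = residualize_log_abundance(v, covariates)
        out = linear_gwas(resid, dimp, variant_ids=ids)
        out.insert(0, "model", "AB")
    else:
        out = logistic_gwas((v > 0).astype(float), dimp, covariates, variant_ids=ids)
        out.insert(0, "model", "PA")
    out.insert(0, "feature", feature)
    out["chrom"] = g.variants["chrom"].to_numpy()
    out["pos"] = g.variants["pos"].to_numpy()
    return out


# ---------------------------------------------------------------------------
# beta-diversity MANOVA


def manova_beta_gwas(
    pcos: np.ndarray | pd.DataFrame,
    G: np.ndarray,
    covariates: pd.DataFrame | None,
    variant_ids=None,
) -> pd.DataFrame:
    """Pillai-trace MANOVA of the PCo matrix on each dosage plus covariates.

    For a single-df hypothesis the Pillai trace reduces to
    V = h' S^{-1} h with h the cross-product of the covariate-residualized
    responses with the normalized residualized dosage and S their total SSCP;
    F = V/(1-V) * (nu_e - k + 1)/k on (k, nu_e - k + 1) df.
    """
    Y = np.asarray(pcos, dtype=float)
    G = np.asarray(G, dtype=float)
    n, k = Y.shape
    n_cov = 0 if covariates is None else covariates.shape[1]
    nu_e = n - n_cov - 2           # residual df of the full model
    if nu_e - k + 1 <= 0:
        raise ValueError(f"residual SSCP singular: n={n} too small for k={k} responses")
    Yr = residualize(Y, covariates)
    Gr = residualize(G, covariates)
    S = Yr.T @ Yr                   # H + E, shared across variants
    gss = (Gr**2).sum(axis=0)
    ok = gss > max(1e-12, 1e-12 * n)
    with np.errstate(divide="ignore", invalid="ignore"):
        Hmat = (Yr.T @ Gr) / np.sqrt(gss)        # k x m, columns h_j
    Hsafe = np.where(ok, Hmat, 0.0)
    V = np.einsum("km,km->m", Hsafe, np.linalg.solve(S, Hsafe))
    V = np.clip(V, 0.0, 1.0 - 1e-15)
    df1, df2 = k, nu_e - k + 1
    F = V / (1.0 - V) * df2 / df1
    p = stats.f.sf(F, df1, df2)
    m = G.shape[1]
    return pd.DataFrame(
        {
            "variant_id": variant_ids if variant_ids is not None else np.arange(m),
            "pillai": np.where(ok, V, np.nan),
            "f_stat": np.where(ok, F, np.nan),
            "df1": df1,
            "df2": df2,
            "p": np.where(ok, p, np.nan),
            "n": n,
        }
    )


def manova_assoc(pcos, dosage, covariates=None, variant_id: str = "variant") -> ManovaResult:
    """Single-variant Pillai-trace MANOVA."""
    df = manova_beta_gwas(np.asarray(pcos, float), np.asarray(dosage, float)[:, None],
                          covariates, variant_ids=[variant_id])
    r = df.iloc[0]
    return ManovaResult(variant_id, r["pillai"], r["f_stat"], int(r["df1"]),
                        int(r["df2"]), r["p"], int(r["n"]))


# ---------------------------------------------------------------------------
# inflation, clumping, thresholds


def lambda_gc(p_values) -> float:
    """Genomic inflation factor: median association chi-square over 0.4549."""
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    if p.size < 100:
        raise ValueError(f"need >= 100 p-values for lambda_GC, got {p.size}")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / CHI2_NULL_MEDIAN)


def ld_r2(dosage_a: np.ndarray, dosage_b: np.ndarray) -> float:
    """Composite LD as squared Pearson correlation of dosages."""
    a = dosage_a - dosage_a.mean()
    b = dosage_b - dosage_b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0:
        return 0.0
    return float((a @ b) / denom) ** 2


def clump_loci(
    results: pd.DataFrame,
    g: GenotypeMatrix,
    window_bp: int = 1_000_000,
    r2: float = 0.2,
    p_max: float = 5e-8,
    max_clumps: int | None = None,
    rule: str = "and",
) -> list[LocusClump]:
    """Greedy p-ascending clumping of associated variants into independent loci.

    The best unassigned variant becomes a clump index; unassigned variants
    join it when (rule="and") they lie within ``window_bp`` AND have dosage
    r^2 >= ``r2`` with the index, or (rule="or") satisfy either condition.
    ``results`` needs columns variant_id and p; the best p per variant is used
    when a variant was tested against several features.
    """
    res = results.dropna(subset=["p"])
    res = res[res["p"] <= p_max]
    if res.empty:
        return []
    best = res.sort_values("p").drop_duplicates("variant_id")
    vinfo = g.variants.set_index("id")
    col = {vid: j for j, vid in enumerate(g.variants["id"])}
    dimp = g.imputed().dosages
    order = best.sort_values("p")
    unassigned = {row.variant_id: row.p for row in order.itertuples()}
    clumps: list[LocusClump] = []
    for row in order.itertuples():
        if row.variant_id not in unassigned:
            continue
        idx_id = row.variant_id
        idx_chrom = vinfo.at[idx_id, "chrom"]
        idx_pos = int(vinfo.at[idx_id, "pos"])
        idx_dos = dimp[:, col[idx_id]]
        members = [idx_id]
        del unassigned[idx_id]
        for other in list(unassigned):
            same_chrom = vinfo.at[other, "chrom"] == idx_chrom
            within = same_chrom and abs(int(vinfo.at[other, "pos"]) - idx_pos) < window_bp
            if rule == "and":
                if not within:
                    continue
                linked = ld_r2(idx_dos, dimp[:, col[other]]) >= r2
                joins = within and linked
            else:
                linked = same_chrom and ld_r2(idx_dos, dimp[:, col[other]]) >= r2
                joins = within or linked
            if joins:
                members.append(other)
                del unassigned[other]
        span = 0
        if len(members) > 1:
            pos = [int(vinfo.at[mid, "pos"]) for mid in members]
            span = max(pos) - min(pos)
        clumps.append(LocusClump(idx_id, float(row.p), members, span))
        if max_clumps is not None and len(clumps) >= max_clumps:
            break
    return clumps


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test significance threshold alpha/m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m
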