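"""One-sample bidirectional Mendelian randomization.

Instruments are variants associated with the exposure at p < 1e-6, greedily
clumped to pairwise LD r^2 < 0.1, and oriented so the effect allele increases
the exposure.  The genetic risk score is the unweighted sum of oriented
dosages.  Causal effects come from two-stage least squares: stage 1 regresses
the exposure on [1, GRS, covariates] and keeps fitted values plus the partial
F of the score; stage 2 regresses the outcome on [1, fitted exposure,
covariates], with the standard error computed from the proper TSLS residual
(observed exposure, stage-2 coefficients).  A partial F below 10 flags a weak
instrument; the estimate is still returned.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .io_qc import GenotypeMatrix
from .assoc import ld_r2, bonferroni_threshold


@dataclasses.dataclass
class InstrumentSet:
    exposure: str
    variant_ids: list
    orientations: list   # +1 (ALT increases exposure) or -1 per variant
    p_values: list

    def __len__(self) -> int:
        return len(self.variant_ids)


@dataclasses.dataclass
class MrEstimate:
    direction: str
    beta: float
    se: float
    p: float
    first_stage_f: float
    r2_instrument: float
    n: int
    n_instruments: int
    flags: list = dataclasses.field(default_factory=list)

    @property
    def estimable(self) -> bool:
        return np.isfinite(self.beta)


def not_estimable(direction: str, reason: str) -> MrEstimate:
    return MrEstimate(direction, np.nan, np.nan, np.nan, np.nan, np.nan, 0, 0,
                      flags=[reason])


def select_instruments(
    sumstats: pd.DataFrame,
    g: GenotypeMatrix,
    p_max: float = 1e-6,
    ld_r2_max: float = 0.1,
    window_bp: int = 1_000_000,
    exposure: str = "exposure",
) -> InstrumentSet:
    """Greedy p-ascending selection of independent instruments for one exposure.

    ``sumstats`` needs columns variant_id, beta, p.  A candidate within
    ``window_bp`` of an already-kept instrument with dosage r^2 >= the clump
    threshold is dropped.  An empty set is returned (never raised) when no
    variant passes ``p_max``.
    """
    cand = sumstats.dropna(subset=["p", "beta"])
    cand = cand[cand["p"] < p_max].sort_values("p")
    if cand.empty:
        return InstrumentSet(exposure, [], [], [])
    vinfo = g.variants.set_index("id")
    col = {vid: j for j, vid in enumerate(g.variants["id"])}
    dimp = g.imputed().dosages
    kept_ids, kept_orients, kept_p = [], [], []
    for row in cand.itertuples():
        vid = row.variant_id
        if vid in kept_ids or vid not in col:
            continue
        chrom, pos = vinfo.at[vid, "chrom"], int(vinfo.at[vid, "pos"])
        independent = True
        for kid in kept_ids:
            same = vinfo.at[kid, "chrom"] == chrom
            close = same and abs(int(vinfo.at[kid, "pos"]) - pos) < window_bp
            if close and ld_r2(dimp[:, col[vid]], dimp[:, col[kid]]) >= ld_r2_max:
                independent = False
                break
        if independent:
            kept_ids.append(vid)
            kept_orients.append(1 if row.beta > 0 else -1)
            kept_p.append(float(row.p))
    return InstrumentSet(exposure, kept_ids, kept_orients, kept_p)


def grs(g: GenotypeMatrix, iv: InstrumentSet) -> np.ndarray:
    """Unweighted genetic risk score: sum of risk-allele dosages per sample."""
    col = {vid: j for j, vid in enumerate(g.variants["id"])}
    missing = [vid for vid in iv.variant_ids if vid not in col]
    if missing:
        raise KeyError(f"instrument variants absent from genotypes: {missing}")
    dimp = g.imputed().dosages
    score = np.zeros(g.n_samples)
    for vid, orient in zip(iv.variant_ids, iv.orientations):
        d = dimp[:, col[vid]]
        score += d if orient > 0 else 2.0 - d
    return score


def tsls(
    exposure,
    outcome,
    score,
    covariates: pd.DataFrame | None = None,
    direction: str = "exposure->outcome",
    n_instruments: int = 1,
) -> MrEstimate:
    """Two-stage least squares with proper TSLS standard errors."""
    x = np.asarray(exposure, dtype=float)
    y = np.asarray(outcome, dtype=float)
    z = np.asarray(score, dtype=float)
    n = len(y)
    n_cov = 0 if covariates is None else covariates.shape[1]
    if n <= n_cov + 3:
        raise ValueError("too few samples for TSLS")
    if np.ptp(z) == 0:
        raise ValueError("instrument score has zero variance")
    C = (np.ones((n, 1)) if covariates is None
         else np.column_stack([np.ones(n), covariates.to_numpy(dtype=float)]))
    # stage 1: exposure ~ [C, z]
    X1 = np.column_stack([C, z])
    b1, *_ = np.linalg.lstsq(X1, x, rcond=None)
    fitted = X1 @ b1
    resid1 = x - fitted
    df1 = n - X1.shape[1]
    sigma2_1 = float(resid1 @ resid1) / df1
    xtx1_inv = np.linalg.inv(X1.T @ X1)
    se_z = np.sqrt(sigma2_1 * xtx1_inv[-1, -1])
    t_z = b1[-1] / se_z if se_z > 0 else np.nan
    first_stage_f = float(t_z**2)
    r2_instrument = float(first_stage_f / (first_stage_f + df1))  # partial R^2
    # stage 2: outcome ~ [C, fitted exposure]
    X2 = np.column_stack([C, fitted])
    b2, *_ = np.linalg.lstsq(X2, y, rcond=None)
    beta = float(b2[-1])
    # proper TSLS residual: stage-2 coefficients applied to the observed exposure
    X2_obs = np.column_stack([C, x])
    resid = y - X2_obs @ b2
    df2 = n - X2.shape[1]
    sigma2 = float(resid @ resid) / df2
    xtx2_inv = np.linalg.inv(X2.T @ X2)
    se = float(np.sqrt(sigma2 * xtx2_inv[-1, -1]))
    t = beta / se if se > 0 else np.nan
    p = 2.0 * stats.t.sf(abs(t), df2) if np.isfinite(t) else np.nan
    flags = []
    if first_stage_f < 10:
        flags.append("weak_instrument")
    return MrEstimate(direction, beta, se, p, first_stage_f, r2_instrument,
                      n, n_instruments, flags)


def mr_one_direction(
    exposure_values,
    outcome_values,
    exposure_sumstats: pd.DataFrame,
    g: GenotypeMatrix,
    covariates: pd.DataFrame | None,
    p_max: float = 1e-6,
    ld_r2_max: float = 0.1,
    direction: str = "exposure->outcome",
) -> MrEstimate:
    iv = select_instruments(exposure_sumstats, g, p_max=p_max, ld_r2_max=ld_r2_max,
                            exposure=direction)
    if len(iv) == 0:
        return not_estimable(direction, "no_instruments")
    score = grs(g, iv)
    if np.ptp(score) == 0:
        return not_estimable(direction, "constant_score")
    est = tsls(exposure_values, outcome_values, score, covariates,
               direction=direction, n_instruments=len(iv))
    return est


def bidirectional_mr(
    feature_values,
    trait_values,
    feature_sumstats: pd.DataFrame,
    trait_sumstats: pd.DataFrame,
    g: GenotypeMatrix,
    covariates: pd.DataFrame | None = None,
    p_max: float = 1e-6,
    ld_r2_max: float = 0.1,
    n_pairs: int = 1,
    alpha: float = 0.05,
) -> dict:
    """One-sample MR in both causal directions for a feature-trait pair.

    Exposures enter on the scale used in their GWAS (log10 abundance for AB
    features, 0/1 presence for PA features — the caller supplies the already
    transformed vector).  The report carries the batch Bonferroni threshold
    alpha / n_pairs.
    """
    forward = mr_one_direction(
        feature_values, trait_values, feature_sumstats, g, covariates,
        p_max=p_max, ld_r2_max=ld_r2_max, direction="feature->trait",
    )
    reverse = mr_one_direction(
        trait_values, feature_values, trait_sumstats, g, covariates,
        p_max=p_max, ld_r2_max=ld_r2_max, direction="trait->feature",
    )
    return {
        "feature->trait": forward,
        "trait->feature": reverse,
        "bonferroni_threshold": bonferroni_threshold(alpha, n_pairs),
    }
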