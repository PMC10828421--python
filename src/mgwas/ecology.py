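"""Diversity indices, Bray-Curtis dissimilarity, ordination, and adjusted
correlations between host genetic structure and community structure.

Shannon entropy is in natural-log units and Simpson is the Gini-Simpson form
1 - sum(p^2), matching the defaults of vegan's ``diversity``.  PCoA applies
Gower double-centering with no Lingoes/Cailliez correction: negative
eigenvalues are reported and their axes dropped, and the proportion explained
is taken relative to the sum of the positive eigenvalues.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy import stats

from .io_qc import AbundanceTable, GenotypeMatrix
from .assoc import AssocResult, _ols_fit


@dataclasses.dataclass
class DistanceMatrix:
    """Symmetric sample x sample dissimilarity matrix with zero diagonal."""

    ids: list
    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape[0] != m.shape[1] or m.shape[0] != len(self.ids):
            raise ValueError("distance matrix must be square, one row per id")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(m), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal must be zero")
        self.matrix = m

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.ids, columns=self.ids)


@dataclasses.dataclass
class OrdinationResult:
    """Eigenvalues and sample scores from PCoA / PCA.

    ``coordinates`` columns are scaled by sqrt(eigenvalue) (PCoA) or singular
    value (PCA) so embedded distances approximate the input dissimilarities.
    """

    eigenvalues: np.ndarray
    coordinates: pd.DataFrame
    proportion_explained: np.ndarray
    negative_eigenvalues: np.ndarray = dataclasses.field(
        default_factory=lambda: np.empty(0)
    )


def alpha_diversity(a: AbundanceTable) -> pd.DataFrame:
    """Per-sample Shannon (nats) and Simpson (1 - sum p^2) indices."""
    v = a.values.to_numpy(dtype=float)
    row_sums = v.sum(axis=1)
    zero = row_sums <= 0
    if zero.any():
        bad = [a.samples[i] for i in np.where(zero)[0]]
        raise ValueError(f"all-zero abundance rows for samples {bad}")
    p = v / row_sums[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.where(p > 0, np.log(p), 0.0)
    shannon = -(p * logs).sum(axis=1)
    simpson = 1.0 - (p**2).sum(axis=1)
    return pd.DataFrame(
        {"shannon": shannon, "simpson": simpson}, index=pd.Index(a.samples, name="sample_id")
    )


def bray_curtis(a: AbundanceTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity, BC(x,y) = sum|x-y| / sum(x+y)."""
    v = a.values.to_numpy(dtype=float)
    if (v.sum(axis=1) <= 0).sum() >= 2:
        raise ValueError("Bray-Curtis undefined between two all-zero samples")
    d = squareform(pdist(v, metric="braycurtis"))
    return DistanceMatrix(a.samples, d)


def _fix_signs(coords: np.ndarray) -> np.ndarray:
    """Orient each axis so its largest-magnitude score is positive."""
    for j in range(coords.shape[1]):
        col = coords[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, j] = -col
    return coords


def pcoa(d: DistanceMatrix, k: int | None = None, axis_prefix: str = "PCo") -> OrdinationResult:
    """Principal coordinates analysis by Gower double-centering.

    Eigen-decomposes G = -1/2 J D^2 J; axes for positive eigenvalues are the
    eigenvectors scaled by sqrt(eigenvalue).  Negative eigenvalues (non-
    Euclidean input) are reported but not corrected.
    """
    n = d.n
    if k is not None and k > n - 1:
        raise ValueError(f"k={k} exceeds n-1={n - 1}")
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ (d.matrix**2) @ j
    evals, evecs = np.linalg.eigh((g + g.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(1e-9, abs(evals[0]) * 1e-12) if evals.size else 1e-9
    pos = evals > tol
    neg = evals[evals < -tol]
    pos_evals = evals[pos]
    coords = evecs[:, pos] * np.sqrt(pos_evals)
    coords = _fix_signs(coords)
    total = pos_evals.sum() if pos_evals.size else 1.0
    if k is not None:
        coords = coords[:, :k]
        pos_evals = pos_evals[:k]
    cols = [f"{axis_prefix}{i + 1}" for i in range(coords.shape[1])]
    return OrdinationResult(
        eigenvalues=pos_evals,
        coordinates=pd.DataFrame(coords, index=d.ids, columns=cols),
        proportion_explained=pos_evals / total,
        negative_eigenvalues=neg,
    )


def genotype_pca(g: GenotypeMatrix, k: int = 10) -> OrdinationResult:
    """Host genetic PCA on variant-standardized dosages.

    Each variant is standardized as (g - 2p)/sqrt(2p(1-p)) with p the ALT
    frequency; monomorphic variants are excluded with a warning.  Scores are
    the top-k left singular vectors scaled by the singular values.
    """
    d = g.imputed().dosages
    p_hat = d.mean(axis=0) / 2.0
    poly = (p_hat > 0) & (p_hat < 1)
    if (~poly).any():
        warnings.warn(f"excluding {int((~poly).sum())} monomorphic variants from PCA")
    d = d[:, poly]
    p_hat = p_hat[poly]
    z = (d - 2 * p_hat) / np.sqrt(2 * p_hat * (1 - p_hat))
    z -= z.mean(axis=0)
    u, s, _ = np.linalg.svd(z, full_matrices=False)
    k = min(k, s.size)
    coords = _fix_signs(u[:, :k] * s[:k])
    evals = (s**2) / max(g.n_samples - 1, 1)
    return OrdinationResult(
        eigenvalues=evals[:k],
        coordinates=pd.DataFrame(
            coords, index=g.samples, columns=[f"PC{i + 1}" for i in range(k)]
        ),
        proportion_explained=evals[:k] / evals.sum(),
    )


def covariate_adjusted_assoc(
    x, y, covariates: pd.DataFrame | None = None, name: str = "x"
) -> AssocResult:
    """OLS of y on [1, x, covariates]; returns the coefficient of x.

    Used for host-PC vs alpha-diversity / PCo correlations with sex, age, BMI
    and read counts as covariates.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if covariates is not None:
        c = covariates.to_numpy(dtype=float)
        if n <= c.shape[1] + 2:
            raise ValueError("too few samples for the covariate set")
        design = np.column_stack([np.ones(n), x, c])
        colnames = ["const", name, *covariates.columns]
    else:
        design = np.column_stack([np.ones(n), x])
        colnames = ["const", name]
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # name a collinear column by greedy rank check
        for j in range(1, design.shape[1]):
            if np.linalg.matrix_rank(design[:, : j + 1]) <= np.linalg.matrix_rank(design[:, :j]):
                raise ValueError(f"design is rank-deficient at column {colnames[j]!r}")
        raise ValueError("design is rank-deficient")
    beta, se, tval, p, _ = _ols_fit(design, y, coef_index=1)
    return AssocResult(
        feature=name, model="linear", n=n, beta=beta, se=se, stat=tval, p=p
    )


def wilcoxon_rank_sum(x, y) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact by enumeration for combined n <= 20 without ties, otherwise the
    normal approximation with tie correction (scipy's Mann-Whitney U).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return 1.0
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (x.size + y.size <= 20 and not has_ties) else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)
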