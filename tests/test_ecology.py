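"""Diversity indices, Bray-Curtis, PCoA, genotype PCA, adjusted associations."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr

from mgwas.io_qc import AbundanceTable
from mgwas.ecology import (
    DistanceMatrix,
    alpha_diversity,
    bray_curtis,
    pcoa,
    genotype_pca,
    covariate_adjusted_assoc,
    wilcoxon_rank_sum,
)
from mgwas.simulate import SimConfig, simulate_genotypes


def _table(rows, names=None):
    rows = np.atleast_2d(np.asarray(rows, float))
    return AbundanceTable(
        pd.DataFrame(
            rows,
            index=[f"S{i}" for i in range(rows.shape[0])],
            columns=names or [f"f{j}" for j in range(rows.shape[1])],
        )
    )


class TestAlphaDiversity:
    @pytest.mark.parametrize(
        "row, shannon, simpson",
        [
            ([0.25, 0.25, 0.25, 0.25], np.log(4), 0.75),
            ([1.0, 0.0, 0.0], 0.0, 0.0),
            (
                [0.5, 0.3, 0.2],
                -(0.5 * np.log(0.5) + 0.3 * np.log(0.3) + 0.2 * np.log(0.2)),
                1 - (0.25 + 0.09 + 0.04),
            ),
        ],
    )
    def test_closed_forms(self, row, shannon, simpson):
        div = alpha_diversity(_table([row]))
        assert div["shannon"].iloc[0] == pytest.approx(shannon, abs=1e-12)
        assert div["simpson"].iloc[0] == pytest.approx(simpson, abs=1e-12)

    def test_values_match_skbio(self, rng):
        skbio_alpha = pytest.importorskip("skbio.diversity.alpha")
        p = rng.dirichlet(np.ones(8))
        div = alpha_diversity(_table([p]))
        assert div["shannon"].iloc[0] == pytest.approx(
            float(skbio_alpha.shannon(p, base=np.e)), abs=1e-10
        )
        assert div["simpson"].iloc[0] == pytest.approx(
            float(skbio_alpha.simpson(p)), abs=1e-10
        )

    def test_shannon_maximal_iff_uniform(self, rng):
        s = 6
        uniform = alpha_diversity(_table([np.ones(s) / s]))["shannon"].iloc[0]
        assert uniform == pytest.approx(np.log(s), abs=1e-12)
        for _ in range(5):
            p = rng.dirichlet(np.ones(s))
            if np.ptp(p) > 1e-6:
                assert alpha_diversity(_table([p]))["shannon"].iloc[0] < uniform

    def test_simpson_invariant_under_zero_padding(self):
        base = [0.5, 0.3, 0.2]
        padded = base + [0.0, 0.0]
        d1 = alpha_diversity(_table([base]))["simpson"].iloc[0]
        d2 = alpha_diversity(_table([padded]))["simpson"].iloc[0]
        assert d1 == pytest.approx(d2, abs=1e-12)

    def test_all_zero_row_names_sample(self):
        with pytest.raises(ValueError, match="S1"):
            alpha_diversity(_table([[0.5, 0.5], [0.0, 0.0]]))


class TestBrayCurtis:
    def test_identity_and_disjoint(self):
        d = bray_curtis(_table([[0.2, 0.8, 0.0], [0.2, 0.8, 0.0], [0.0, 0.0, 1.0]]))
        assert d.matrix[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert d.matrix[0, 2] == pytest.approx(1.0, abs=1e-12)

    def test_hand_example(self):
        d = bray_curtis(_table([[2, 2, 0], [0, 2, 2]]))
        assert d.matrix[0, 1] == pytest.approx(0.5, abs=1e-12)  # (2+0+2)/8

    def test_two_all_zero_samples_error(self):
        with pytest.raises(ValueError):
            bray_curtis(_table([[0, 0], [0, 0], [1, 0]]))


class TestPcoa:
    def test_zero_distances_zero_eigenvalues(self):
        d = DistanceMatrix(["a", "b", "c"], np.zeros((3, 3)))
        res = pcoa(d)
        assert res.eigenvalues.size == 0

    def test_collinear_points_recovered(self):
        pts = np.array([[0.0], [1.0], [3.0]])
        d = DistanceMatrix(["a", "b", "c"], squareform(pdist(pts)))
        res = pcoa(d)
        coords = res.coordinates.to_numpy()
        emb = squareform(pdist(coords))
        np.testing.assert_allclose(emb, d.matrix, atol=1e-10)
        # one positive axis only, recovering the line up to sign/translation
        assert coords.shape[1] == 1

    def test_euclidean_input_has_no_negative_eigenvalues(self, rng):
        pts = rng.normal(size=(15, 4))
        d = DistanceMatrix(list(range(15)), squareform(pdist(pts)))
        res = pcoa(d)
        assert (res.negative_eigenvalues > -1e-9).all()
        emb = squareform(pdist(res.coordinates.to_numpy()))
        np.testing.assert_allclose(emb, d.matrix, atol=1e-8)

    def test_matches_skbio(self, rng):
        skbio_ord = pytest.importorskip("skbio.stats.ordination")
        v = rng.dirichlet(np.ones(10), size=12)
        d = squareform(pdist(v, metric="braycurtis"))
        mine = pcoa(DistanceMatrix(list(range(12)), d))
        theirs = skbio_ord.pcoa(d)
        k = mine.eigenvalues.size
        np.testing.assert_allclose(
            mine.eigenvalues, theirs.eigvals.to_numpy()[:k], atol=1e-8
        )
        np.testing.assert_allclose(
            np.abs(mine.coordinates.to_numpy()),
            np.abs(theirs.samples.to_numpy()[:, :k]),
            atol=1e-8,
        )

    def test_asymmetric_input_rejected(self):
        m = np.array([[0, 1.0], [0.5, 0]])
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], m)


class TestGenotypePca:
    def test_structured_cohort_separates_on_pc1(self):
        g, labels = simulate_genotypes(
            SimConfig(n_samples=500, n_variants=2000, fst=0.2, seed=9)
        )
        res = genotype_pca(g, k=2)
        r = pearsonr(res.coordinates["PC1"], labels).statistic
        assert abs(r) > 0.9

    def test_unstructured_cohort_does_not_separate(self):
        g, labels = simulate_genotypes(
            SimConfig(n_samples=500, n_variants=1000, fst=0.0, seed=10)
        )
        res = genotype_pca(g, k=2)
        for c in res.coordinates.columns:
            assert abs(pearsonr(res.coordinates[c], labels).statistic) < 0.2

    def test_duplicated_samples_identical_scores(self, rng):
        d = rng.binomial(2, 0.4, size=(20, 50)).astype(float)
        d[1] = d[0]
        variants = pd.DataFrame(
            {"chrom": "1", "pos": np.arange(50) + 1, "id": [f"v{j}" for j in range(50)],
             "ref": "A", "alt": "G"}
        )
        from mgwas.io_qc import GenotypeMatrix

        g = GenotypeMatrix([f"S{i}" for i in range(20)], variants, d)
        res = genotype_pca(g, k=3)
        np.testing.assert_allclose(
            res.coordinates.iloc[0], res.coordinates.iloc[1], atol=1e-10
        )


class TestCovariateAdjustedAssoc:
    def test_exact_linear_relation(self, rng):
        x = rng.normal(size=50)
        r = covariate_adjusted_assoc(x, 2.0 * x, None)
        assert r.beta == pytest.approx(2.0, abs=1e-10)
        assert r.p < 1e-30

    def test_matches_normal_equations_oracle(self, rng):
        n = 10
        x = rng.normal(size=n)
        c = pd.DataFrame({"c1": rng.normal(size=n), "c2": rng.normal(size=n)})
        y = 0.7 * x + 0.2 * c["c1"].to_numpy() + rng.normal(size=n)
        r = covariate_adjusted_assoc(x, y, c)
        X = np.column_stack([np.ones(n), x, c.to_numpy()])
        beta = np.linalg.inv(X.T @ X) @ X.T @ y
        resid = y - X @ beta
        sigma2 = resid @ resid / (n - X.shape[1])
        se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
        assert r.beta == pytest.approx(beta[1], abs=1e-10)
        assert r.se == pytest.approx(se, abs=1e-10)

    def test_frisch_waugh_property(self, rng):
        n = 80
        c = pd.DataFrame({"c1": rng.normal(size=n), "c2": rng.normal(size=n)})
        x = 0.5 * c["c1"].to_numpy() + rng.normal(size=n)
        y = 0.3 * x + 0.4 * c["c2"].to_numpy() + rng.normal(size=n)
        full = covariate_adjusted_assoc(x, y, c)
        from mgwas.assoc import residualize

        xr = residualize(x, c)
        yr = residualize(y, c)
        partial = covariate_adjusted_assoc(xr, yr, None)
        assert full.beta == pytest.approx(partial.beta, abs=1e-10)

    def test_null_type_i_error_calibrated(self, rng):
        # 1000 independent null regressions, vectorized as a GWAS scan
        from mgwas.assoc import covariate_gwas

        n = 500
        c = pd.DataFrame({"c1": rng.normal(size=n)})
        y = rng.normal(size=n)
        X = rng.normal(size=(n, 1000))
        res = covariate_gwas(y, X, c)
        frac = (res["p"] < 0.05).mean()
        assert 0.03 < frac < 0.07

    def test_collinear_design_named(self, rng):
        x = rng.normal(size=30)
        c = pd.DataFrame({"dup": x})
        with pytest.raises(ValueError, match="dup"):
            covariate_adjusted_assoc(x, rng.normal(size=30), c)


class TestWilcoxon:
    def test_exact_small_sample(self):
        # all 20 rank assignments; only the two extreme orderings are as extreme
        assert wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1, abs=1e-12)

    def test_identical_multisets(self):
        assert wilcoxon_rank_sum([1.0, 1.0], [1.0, 1.0]) == 1.0

    def test_large_sample_null_uniform(self, rng):
        pvals = [
            wilcoxon_rank_sum(rng.normal(size=40), rng.normal(size=40))
            for _ in range(300)
        ]
        from scipy.stats import kstest

        assert kstest(pvals, "uniform").pvalue > 0.01
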