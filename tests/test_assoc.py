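"""Association engine: model dispatch, linear/logistic/MANOVA fits, lambda_GC,
LD clumping and Bonferroni thresholds."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mgwas.io_qc import GenotypeMatrix
from mgwas.assoc import (
    choose_model,
    residualize_log_abundance,
    residualize,
    linear_assoc,
    linear_gwas,
    covariate_gwas,
    logistic_assoc,
    manova_assoc,
    manova_beta_gwas,
    lambda_gc,
    ld_r2,
    clump_loci,
    bonferroni_threshold,
)


def _matrix(dosages, positions=None):
    d = np.asarray(dosages, float)
    m = d.shape[1]
    variants = pd.DataFrame(
        {
            "chrom": "1",
            "pos": positions if positions is not None else 1000 * (np.arange(m) + 1),
            "id": [f"v{j}" for j in range(m)],
            "ref": "A",
            "alt": "G",
        }
    )
    return GenotypeMatrix([f"S{i}" for i in range(d.shape[0])], variants, d)


class TestChooseModel:
    def test_dispatch(self):
        assert choose_model(0.96) == "AB"
        assert choose_model(0.50) == "PA"
        assert choose_model(0.95) == "PA"   # boundary: AB requires > 0.95

    def test_filtered_prevalence_rejected(self):
        with pytest.raises(ValueError):
            choose_model(0.10)


class TestResidualize:
    def test_orthogonal_covariates_give_centered_y(self, rng):
        n = 40
        y = 10.0 ** rng.normal(-2, 0.5, n)
        c = pd.DataFrame({"c": np.ones(n) * 2.0})  # constant, absorbed by intercept
        r = residualize_log_abundance(y, None)
        np.testing.assert_allclose(r, np.log10(y) - np.log10(y).mean(), atol=1e-10)
        r2 = residualize_log_abundance(y, c)
        np.testing.assert_allclose(r, r2, atol=1e-10)

    def test_exact_linear_dependence_gives_zero(self, rng):
        n = 30
        c = pd.DataFrame({"c1": rng.normal(size=n)})
        y = 10.0 ** (1.5 + 0.4 * c["c1"].to_numpy())
        r = residualize_log_abundance(y, c)
        assert np.linalg.norm(r) < 1e-10

    def test_matches_normal_equations(self, rng):
        n = 10
        c = pd.DataFrame({"c1": rng.normal(size=n), "c2": rng.normal(size=n)})
        y = 10.0 ** rng.normal(-1, 1, n)
        r = residualize_log_abundance(y, c)
        X = np.column_stack([np.ones(n), c.to_numpy()])
        expected = np.log10(y) - X @ (np.linalg.inv(X.T @ X) @ X.T @ np.log10(y))
        np.testing.assert_allclose(r, expected, atol=1e-10)

    def test_zeros_floored_at_half_minimum(self):
        y = np.array([0.0, 0.01, 0.04, 0.02])
        r = residualize_log_abundance(y, None)
        logv = np.log10(np.array([0.005, 0.01, 0.04, 0.02]))
        np.testing.assert_allclose(r, logv - logv.mean(), atol=1e-12)


class TestLinearAssoc:
    def test_matches_statsmodels_ols(self, rng):
        import statsmodels.api as sm

        n = 15
        d = rng.binomial(2, 0.4, n).astype(float)
        y = 0.5 * d + rng.normal(size=n)
        res = linear_assoc(y, d)
        fit = sm.OLS(y, sm.add_constant(d)).fit()
        assert res.beta == pytest.approx(fit.params[1], abs=1e-8)
        assert res.se == pytest.approx(fit.bse[1], abs=1e-8)
        assert res.p == pytest.approx(fit.pvalues[1], abs=1e-8)

    def test_planted_effect_recovered(self, rng):
        n = 1000
        d = rng.binomial(2, 0.3, n).astype(float)
        y = 0.5 * d + rng.normal(size=n)
        res = linear_assoc(y - y.mean(), d)
        assert abs(res.beta - 0.5) < 3 * res.se

    def test_monomorphic_flagged(self):
        res = linear_assoc(np.random.default_rng(0).normal(size=20), np.ones(20))
        assert res.flag == "monomorphic" and np.isnan(res.p)

    def test_allele_flip_inverts_beta_keeps_p(self, rng):
        n = 200
        d = rng.binomial(2, 0.3, n).astype(float)
        y = 0.3 * d + rng.normal(size=n)
        a = linear_assoc(y, d)
        b = linear_assoc(y, 2.0 - d)
        assert a.beta == pytest.approx(-b.beta, abs=1e-10)
        assert a.p == pytest.approx(b.p, abs=1e-12)


class TestLogisticAssoc:
    def test_matches_statsmodels_logit(self, rng):
        import statsmodels.api as sm

        n = 20
        d = rng.binomial(2, 0.5, n).astype(float)
        c = pd.DataFrame({"c1": rng.normal(size=n)})
        y = (rng.random(n) < 1 / (1 + np.exp(-(0.3 * d)))).astype(float)
        res = logistic_assoc(y, d, c)
        X = np.column_stack([np.ones(n), c.to_numpy(), d])
        fit = sm.Logit(y, X).fit(disp=0, method="newton", tol=1e-12)
        assert res.beta == pytest.approx(fit.params[-1], abs=1e-8)
        assert res.se == pytest.approx(fit.bse[-1], abs=1e-8)

    def test_separable_fixture_flagged(self):
        d = np.array([0, 0, 0, 0, 0, 0, 2, 2, 2, 2, 2, 2], dtype=float)
        y = (d > 1).astype(float)   # perfect separation
        res = logistic_assoc(y, d)
        assert res.flag == "not_converged"
        assert np.isnan(res.p)

    def test_allele_flip_inverts_beta_keeps_p(self, rng):
        n = 300
        d = rng.binomial(2, 0.4, n).astype(float)
        y = (rng.random(n) < 1 / (1 + np.exp(-(0.4 * d - 0.5)))).astype(float)
        a = logistic_assoc(y, d)
        b = logistic_assoc(y, 2.0 - d)
        assert a.beta == pytest.approx(-b.beta, abs=1e-6)
        assert a.p == pytest.approx(b.p, abs=1e-8)


class TestManova:
    def test_univariate_reduction_matches_linear(self, rng):
        n = 60
        y = rng.normal(size=(n, 1))
        d = rng.binomial(2, 0.4, n).astype(float)
        c = pd.DataFrame({"c1": rng.normal(size=n)})
        mv = manova_assoc(y, d, c)
        lin = covariate_gwas(y[:, 0], d[:, None], c)
        assert mv.p == pytest.approx(lin["p"][0], abs=1e-10)

    def test_matches_sscp_eigendecomposition_oracle(self, rng):
        n, k = 20, 3
        Y = rng.normal(size=(n, k))
        d = rng.binomial(2, 0.3, n).astype(float)
        c = pd.DataFrame({"c1": rng.normal(size=n)})
        mv = manova_assoc(Y, d, c)
        Xf = np.column_stack([np.ones(n), c.to_numpy(), d])
        Xr = np.column_stack([np.ones(n), c.to_numpy()])
        Bf, *_ = np.linalg.lstsq(Xf, Y, rcond=None)
        Br, *_ = np.linalg.lstsq(Xr, Y, rcond=None)
        E = (Y - Xf @ Bf).T @ (Y - Xf @ Bf)
        H = (Xf @ Bf - Xr @ Br).T @ (Xf @ Bf - Xr @ Br)
        V = float(np.trace(H @ np.linalg.inv(H + E)))
        nu_e = n - Xf.shape[1]
        F = V / (1 - V) * (nu_e - k + 1) / k
        assert mv.pillai == pytest.approx(V, abs=1e-8)
        assert mv.f_stat == pytest.approx(F, abs=1e-8)
        assert mv.p == pytest.approx(stats.f.sf(F, k, nu_e - k + 1), abs=1e-10)

    def test_null_p_uniform(self, rng):
        n, k, m = 300, 5, 2000
        Y = rng.normal(size=(n, k))
        G = rng.binomial(2, rng.uniform(0.1, 0.5, m), size=(n, m)).astype(float)
        res = manova_beta_gwas(Y, G, None)
        assert stats.kstest(res["p"].dropna(), "uniform").pvalue > 0.01

    def test_planted_shift_detected(self, rng):
        n, k = 1000, 5
        d = rng.binomial(2, 0.3, n).astype(float)
        Y = rng.normal(size=(n, k))
        Y[:, 1] += 0.3 * d          # dosage shift along the second axis
        mv = manova_assoc(Y, d)
        assert mv.p < 1e-6

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError):
            manova_assoc(rng.normal(size=(6, 5)), rng.binomial(2, 0.5, 6).astype(float))


class TestLambdaGc:
    def test_all_half_is_one(self):
        assert lambda_gc(np.full(200, 0.5)) == pytest.approx(1.0, abs=1e-12)

    def test_scaled_chi2_recovers_scale(self, rng):
        chi2 = rng.chisquare(1, size=100_000) * 1.2
        p = stats.chi2.sf(chi2, 1)
        assert lambda_gc(p) == pytest.approx(1.2, abs=0.02)

    def test_uniform_p_near_one(self, rng):
        p = rng.uniform(size=100_000)
        assert 0.95 < lambda_gc(p) < 1.05

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            lambda_gc(np.concatenate([np.full(150, 0.5), [1.5]]))

    def test_too_few_p_rejected(self):
        with pytest.raises(ValueError):
            lambda_gc(np.full(50, 0.5))


class TestClumping:
    def _ld_fixture(self):
        rng = np.random.default_rng(8)
        n = 400
        a = rng.binomial(2, 0.4, n).astype(float)
        b = a.copy()
        flip = rng.random(n) < 0.3
        b[flip] = rng.binomial(2, 0.4, int(flip.sum()))     # r2 ~ 0.5 with a
        c = rng.binomial(2, 0.4, n).astype(float)           # independent
        g = _matrix(np.column_stack([a, b, c]),
                    positions=[1_000_000, 1_400_000, 1_600_000])
        assert ld_r2(a, b) >= 0.2 and ld_r2(a, c) < 0.2
        return g

    def test_single_significant_variant(self):
        g = self._ld_fixture()
        res = pd.DataFrame({"variant_id": ["v0"], "p": [1e-10]})
        clumps = clump_loci(res, g)
        assert len(clumps) == 1 and clumps[0].members == ["v0"]

    def test_hand_trace_linked_and_independent(self):
        g = self._ld_fixture()
        res = pd.DataFrame(
            {"variant_id": ["v0", "v1", "v2"], "p": [1e-10, 1e-9, 1e-8]}
        )
        clumps = clump_loci(res, g)
        assert len(clumps) == 2
        assert sorted(clumps[0].members) == ["v0", "v1"]
        assert clumps[1].members == ["v2"]

    def test_distance_rule_splits_far_linked_pair(self, rng):
        n = 200
        a = rng.binomial(2, 0.4, n).astype(float)
        g = _matrix(np.column_stack([a, a]), positions=[1_000_000, 3_000_000])
        res = pd.DataFrame({"variant_id": ["v0", "v1"], "p": [1e-10, 1e-9]})
        clumps = clump_loci(res, g)
        assert len(clumps) == 2           # r2 = 1 but 2 Mb apart

    def test_indices_mutually_independent(self, rng):
        n, m = 300, 40
        G = rng.binomial(2, 0.3, size=(n, m)).astype(float)
        g = _matrix(G, positions=(np.arange(m) * 50_000 + 1))
        res = pd.DataFrame(
            {"variant_id": [f"v{j}" for j in range(m)], "p": rng.uniform(1e-12, 1e-9, m)}
        )
        clumps = clump_loci(res, g, p_max=1e-8)
        pos = g.variants.set_index("id")["pos"]
        col = {vid: j for j, vid in enumerate(g.variants["id"])}
        for i, ci in enumerate(clumps):
            for cj in clumps[i + 1:]:
                far = abs(pos[ci.index_id] - pos[cj.index_id]) >= 1_000_000
                unlinked = ld_r2(G[:, col[ci.index_id]], G[:, col[cj.index_id]]) < 0.2
                assert far or unlinked


class TestBonferroni:
    def test_study_wide_and_mr_thresholds(self):
        assert bonferroni_threshold(5e-8, 293) == pytest.approx(1.71e-10, rel=5e-3)
        assert bonferroni_threshold(0.05, 402) == pytest.approx(1.24e-4, rel=5e-3)
        assert bonferroni_threshold(0.05, 1) == 0.05

    def test_zero_tests_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)
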