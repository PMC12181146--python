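"""Regression engine: exact recovery on noise-free data, oracle
equivalence against independent solvers, null calibration, and the
fast-path contract."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import statsmodels.api as sm

from agescan.engine import (
    MarginalModel,
    SnpAgeInteractionModel,
    build_covariates,
    fit_interaction,
    fit_interaction_block,
    fit_marginal,
    fit_marginal_block,
)
from agescan.exceptions import CollinearityError, DimensionError, MonomorphicVariantError


def simulate_dataset(rng, n, m=1, maf=0.3, beta_g=0.0, beta_int=0.0, noise=1.0):
    G = rng.binomial(2, maf, size=(m, n)).astype(float)
    age = rng.integers(40, 71, n).astype(float)
    sex = rng.integers(0, 2, n).astype(float)
    pcs = rng.standard_normal((n, 10))
    covars = pd.DataFrame(np.column_stack([sex, pcs]), columns=["sex"] + [f"pc{i}" for i in range(1, 11)])
    y = 1.0 + 0.01 * age + 0.2 * sex + beta_g * G[0] + beta_int * G[0] * age + noise * rng.standard_normal(n)
    return y, G, age, covars


class TestInteractionModel:
    def test_noise_free_interaction_recovered_exactly(self):
        rng = np.random.default_rng(0)
        g = rng.binomial(2, 0.4, 200).astype(float)
        age = rng.integers(40, 71, 200).astype(float)
        y = 1.0 + 0.5 * g + 0.02 * age + 0.003 * g * age
        res = fit_interaction(y, g, age, covars=None)
        assert res.beta_int == pytest.approx(0.003, abs=1e-12)
        assert res.beta_g == pytest.approx(0.5, abs=1e-10)

    def test_monomorphic_raises(self):
        rng = np.random.default_rng(1)
        y, _, age, covars = simulate_dataset(rng, 100)
        with pytest.raises(MonomorphicVariantError):
            fit_interaction(y, np.zeros(100), age, covars)

    def test_matches_brute_force_normal_equations(self):
        """Coefficients equal an independent solve of (X'X) b = X'y to
        relative 1e-10; SEs match the closed-form covariance."""
        rng = np.random.default_rng(2)
        y, G, age, covars = simulate_dataset(rng, 500, beta_g=0.1, beta_int=0.002)
        res = fit_interaction(y, G[0], age, covars)
        X = np.column_stack(
            [np.ones(500), G[0], age, G[0] * age, covars.to_numpy()]
        )
        b = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(res.params.to_numpy(), b, rtol=1e-10)
        resid = y - X @ b
        sigma2 = resid @ resid / (500 - X.shape[1])
        se = np.sqrt(np.diag(sigma2 * np.linalg.inv(X.T @ X)))
        np.testing.assert_allclose(res.bse.to_numpy(), se, rtol=1e-8)

    def test_matches_statsmodels_including_robust(self):
        rng = np.random.default_rng(3)
        y, G, age, covars = simulate_dataset(rng, 400, beta_int=0.003)
        X = np.column_stack([np.ones(400), G[0], age, G[0] * age, covars.to_numpy()])
        ref = sm.OLS(y, X).fit()
        res = fit_interaction(y, G[0], age, covars)
        np.testing.assert_allclose(res.params.to_numpy(), ref.params, rtol=1e-10)
        np.testing.assert_allclose(res.bse.to_numpy(), ref.bse, rtol=1e-10)
        np.testing.assert_allclose(res.pvalues.to_numpy(), ref.pvalues, rtol=1e-8, atol=1e-300)
        robust = fit_interaction(y, G[0], age, covars, se_type="robust")
        ref_hc0 = ref.get_robustcov_results(cov_type="HC0")
        np.testing.assert_allclose(robust.bse.to_numpy(), ref_hc0.bse, rtol=1e-10)

    def test_age_centering_invariance(self):
        """Replacing age by age - c leaves beta_int, se_int and p_int
        unchanged (exact reparametrisation)."""
        rng = np.random.default_rng(4)
        y, G, age, covars = simulate_dataset(rng, 300, beta_int=0.002)
        base = fit_interaction(y, G[0], age, covars)
        for c in (0.0, 58.0):
            shifted = fit_interaction(y, G[0], age - c, covars)
            assert shifted.beta_int == pytest.approx(base.beta_int, rel=1e-9)
            assert shifted.se_int == pytest.approx(base.se_int, rel=1e-9)
            assert shifted.p_int == pytest.approx(base.p_int, rel=1e-6)

    def test_collinear_design_names_column(self):
        rng = np.random.default_rng(5)
        y, G, age, covars = simulate_dataset(rng, 200)
        covars["pc2"] = covars["pc1"]
        with pytest.raises(CollinearityError, match="pc2"):
            fit_interaction(y, G[0], age, covars)

    def test_missing_dosages_mean_imputed(self):
        rng = np.random.default_rng(6)
        y, G, age, covars = simulate_dataset(rng, 300)
        g = G[0].copy()
        g[:30] = np.nan
        res = fit_interaction(y, g, age, covars)
        g_imp = g.copy()
        g_imp[:30] = np.nanmean(g)
        ref = fit_interaction(y, g_imp, age, covars)
        assert res.beta_g == ref.beta_g and res.n == 300

    def test_summary_renders(self):
        rng = np.random.default_rng(7)
        y, G, age, covars = simulate_dataset(rng, 150)
        text = fit_interaction(y, G[0], age, covars).summary()
        assert "g_x_age" in text and "interaction" in text


class TestMarginalModel:
    def test_noise_free_main_effect_exact(self):
        rng = np.random.default_rng(8)
        g = rng.binomial(2, 0.3, 100).astype(float)
        age = rng.integers(40, 71, 100).astype(float)
        y = 2.0 * g + age
        res = fit_marginal(y, g, age, covars=None)
        assert res.beta_g == pytest.approx(2.0, abs=1e-10)

    def test_null_pvalues_uniform(self):
        """Under the null the marginal Wald p across 2,000 independent
        variants is uniform (KS test)."""
        rng = np.random.default_rng(9)
        n, m = 500, 2000
        G = rng.binomial(2, rng.uniform(0.1, 0.5, m)[:, None], size=(m, n)).astype(float)
        age = rng.integers(40, 71, n).astype(float)
        covars = pd.DataFrame({"sex": rng.integers(0, 2, n).astype(float)})
        y = 0.02 * age + rng.standard_normal(n)
        res = fit_marginal_block(y, G, age, covars)
        ks = stats.kstest(res["p_g"], "uniform")
        assert ks.pvalue > 0.01

    def test_duplicated_rows_shrink_se_by_known_factor(self):
        """Duplicating every sample leaves beta unchanged and scales the
        SE by sqrt((n-p)/(2n-p))/sqrt(2) exactly."""
        rng = np.random.default_rng(10)
        y, G, age, covars = simulate_dataset(rng, 250, beta_g=0.2)
        res1 = fit_marginal(y, G[0], age, covars)
        y2 = np.tile(y, 2)
        g2 = np.tile(G[0], 2)
        age2 = np.tile(age, 2)
        covars2 = pd.concat([covars, covars], ignore_index=True)
        res2 = fit_marginal(y2, g2, age2, covars2)
        assert res2.beta_g == pytest.approx(res1.beta_g, rel=1e-12)
        # closed form: X'X doubles and sigma2 becomes 2*RSS/(2n-p), so
        # se2 = se1 * sqrt((n-p)/(2n-p)) ~ se1/sqrt(2) at large n
        n, p = 250, 14
        expected = res1.se_g * np.sqrt((n - p) / (2 * n - p))
        assert res2.se_g == pytest.approx(expected, rel=1e-10)


class TestFastPath:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_block_equals_per_variant_fits(self, seed):
        """The FWL fast path reproduces per-variant OLS betas, SEs and
        p-values to relative 1e-10 for both models."""
        rng = np.random.default_rng(seed)
        n, m = 500, 100
        mafs = rng.uniform(0.05, 0.5, m)
        G = rng.binomial(2, mafs[:, None], size=(m, n)).astype(float)
        age = rng.integers(40, 71, n).astype(float)
        sex = rng.integers(0, 2, n).astype(float)
        pcs = rng.standard_normal((n, 10))
        covars = pd.DataFrame(
            np.column_stack([sex, pcs]), columns=["sex"] + [f"pc{i}" for i in range(1, 11)]
        )
        y = 1 + 0.01 * age + 0.1 * G[0] + 0.002 * G[0] * age + rng.standard_normal(n)
        block = fit_interaction_block(y, G, age, covars)
        mblock = fit_marginal_block(y, G, age, covars)
        for j in range(m):
            ref = fit_interaction(y, G[j], age, covars)
            for col, attr in [
                ("beta_g", "beta_g"), ("se_g", "se_g"), ("beta_age", "beta_age"),
                ("se_age", "se_age"), ("beta_int", "beta_int"), ("se_int", "se_int"),
            ]:
                assert block[col][j] == pytest.approx(getattr(ref, attr), rel=1e-10)
            assert block["p_int"][j] == pytest.approx(ref.p_int, rel=1e-8, abs=1e-300)
            mref = fit_marginal(y, G[j], age, covars)
            assert mblock["beta_g"][j] == pytest.approx(mref.beta_g, rel=1e-10)
            assert mblock["p_g"][j] == pytest.approx(mref.p_g_marginal, rel=1e-8, abs=1e-300)

    def test_monomorphic_row_flagged_not_fatal(self):
        rng = np.random.default_rng(11)
        y, G, age, covars = simulate_dataset(rng, 200, m=5)
        G[2] = 1.0
        out = fit_interaction_block(y, G, age, covars)
        assert not out["ok"][2] and np.isnan(out["beta_int"][2])
        assert out["ok"].drop(2).all() and out["beta_int"].drop(2).notna().all()

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(12)
        y, G, age, covars = simulate_dataset(rng, 300, m=4)
        perm = rng.permutation(300)
        a = fit_interaction_block(y, G, age, covars)
        b = fit_interaction_block(y[perm], G[:, perm], age[perm], covars.iloc[perm].reset_index(drop=True))
        np.testing.assert_allclose(a["beta_int"], b["beta_int"], rtol=1e-9)
        np.testing.assert_allclose(a["se_int"], b["se_int"], rtol=1e-9)

    def test_too_few_samples_raises(self):
        rng = np.random.default_rng(13)
        y, G, age, covars = simulate_dataset(rng, 14)
        with pytest.raises(DimensionError):
            fit_interaction_block(y, G, age, covars)
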