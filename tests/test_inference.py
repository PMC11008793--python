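"""Model fitting: OLS, sandwich covariances, FGLS and term tests.

Cross-checked against hand-built normal equations, scipy's pooled t test,
and statsmodels' independent implementations.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import hetpower as hp
from hetpower.inference import (
    FGLSConvergenceError,
    design_matrix,
    fit_ols_arrays,
)


def _design_from(dataset, include_interaction):
    sex_var = dataset.frame["sex"].to_numpy() == "variable"
    treated = dataset.frame["treatment"].to_numpy() == "treated"
    return design_matrix(sex_var, treated, include_interaction)


class TestOLS:
    def test_noiseless_data_recovers_coefficients_exactly(self):
        scen = hp.build_scenario(
            mu0=5.0, beta_trt=0.5, beta_sex=0.3, beta_int=0.2, sigma_ref=2.0
        )
        frame = pd.DataFrame(
            {
                "sex": np.repeat([c[0] for c in hp.CELLS], 3),
                "treatment": np.repeat([c[1] for c in hp.CELLS], 3),
                "response": np.repeat(scen.cell_means, 3),
            }
        )
        fit = hp.fit_ols(hp.Dataset(frame=frame), include_interaction=True)
        # effects are standardised, so coefficients carry a sigma_ref factor
        assert fit.params == pytest.approx([5.0, 0.6, 1.0, 0.4], abs=1e-12)

    def test_toy_dataset_matches_normal_equation_solve(self, toy_dataset):
        fit = hp.fit_ols(toy_dataset)
        X, _ = _design_from(toy_dataset, include_interaction=False)
        y = toy_dataset.frame["response"].to_numpy()
        expected = np.linalg.solve(X.T @ X, X.T @ y)  # independent brute force
        np.testing.assert_allclose(fit.params, expected, atol=1e-12)
        np.testing.assert_allclose(fit.params, [1.5, 4.0, 2.0], atol=1e-12)

    def test_two_group_model_equals_pooled_t_test(self):
        """A treatment-only design reproduces the classical pooled t test."""
        rng = np.random.default_rng(77)
        y = np.concatenate([rng.normal(0, 1, 15), rng.normal(0.8, 1, 12)])
        treated = np.arange(27) >= 15
        X = np.column_stack([np.ones(27), treated.astype(float)])
        fit = fit_ols_arrays(X, y, ("intercept", "treatment"), treated)
        tt = hp.term_test(fit, "treatment")
        ref = stats.ttest_ind(y[treated], y[~treated], equal_var=True)
        assert tt.t == pytest.approx(ref.statistic, rel=1e-12)
        assert tt.p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_residuals_orthogonal_and_leverage_sums_to_k(self, random_dataset):
        for flag in (False, True):
            fit = hp.fit_ols(random_dataset, include_interaction=flag)
            assert np.max(np.abs(fit.X.T @ fit.residuals)) < 1e-8
            assert np.all((fit.leverage > 0) & (fit.leverage < 1))
            assert fit.leverage.sum() == pytest.approx(fit.k)

    def test_rank_deficient_design_rejected(self, toy_dataset):
        frame = toy_dataset.frame.copy()
        frame["treatment"] = "control"  # empty treated cells
        with pytest.raises(np.linalg.LinAlgError):
            hp.fit_ols(hp.Dataset(frame=frame))

    def test_matches_statsmodels(self, random_dataset):
        sm = pytest.importorskip("statsmodels.api")
        fit = hp.fit_ols(random_dataset, include_interaction=True)
        res = sm.OLS(random_dataset.frame["response"].to_numpy(), fit.X).fit()
        np.testing.assert_allclose(fit.params, res.params, rtol=1e-10)
        np.testing.assert_allclose(fit.cov_classical, res.cov_params(), rtol=1e-10)


class TestSandwich:
    def test_hc1_equals_classical_when_residuals_equal_magnitude(self, toy_dataset):
        # saturated model on 2-per-cell data: every residual is +-0.5
        fit = hp.fit_ols(toy_dataset, include_interaction=True)
        assert np.allclose(np.abs(fit.residuals), 0.5)
        np.testing.assert_allclose(
            hp.sandwich_cov(fit, "HC1"), fit.cov_classical, rtol=1e-12
        )

    def test_hc3_dominates_hc0(self, random_dataset):
        fit = hp.fit_ols(random_dataset)
        d0 = np.diag(hp.sandwich_cov(fit, "HC0"))
        d3 = np.diag(hp.sandwich_cov(fit, "HC3"))
        assert np.all(d3 >= d0)

    def test_hc0_matches_brute_force_product(self, toy_dataset):
        fit = hp.fit_ols(toy_dataset)
        X, e = fit.X, fit.residuals
        bread = np.linalg.inv(X.T @ X)
        expected = bread @ (X.T @ np.diag(e**2) @ X) @ bread
        np.testing.assert_allclose(hp.sandwich_cov(fit, "HC0"), expected, rtol=1e-12)

    @pytest.mark.parametrize("flavor", ["HC0", "HC1", "HC2", "HC3"])
    def test_matches_statsmodels(self, random_dataset, flavor):
        sm = pytest.importorskip("statsmodels.api")
        fit = hp.fit_ols(random_dataset)
        res = sm.OLS(random_dataset.frame["response"].to_numpy(), fit.X).fit(
            cov_type=flavor
        )
        np.testing.assert_allclose(
            hp.sandwich_cov(fit, flavor), res.cov_params(), rtol=1e-9
        )

    def test_covariances_symmetric_psd(self, random_dataset):
        fit = hp.fit_ols(random_dataset)
        for flavor in ("HC0", "HC1", "HC2", "HC3"):
            cov = hp.sandwich_cov(fit, flavor)
            np.testing.assert_allclose(cov, cov.T, atol=1e-14)
            assert np.all(np.linalg.eigvalsh(cov) > -1e-12)

    def test_unknown_flavor(self, random_dataset):
        fit = hp.fit_ols(random_dataset)
        with pytest.raises(ValueError, match="unknown sandwich flavor"):
            hp.sandwich_cov(fit, "HC9")


class TestFGLS:
    def test_equal_sex_variances_reduce_to_ols(self, toy_dataset):
        ols = hp.fit_ols(toy_dataset)
        fgls = hp.fit_fgls(toy_dataset)
        np.testing.assert_allclose(fgls.params, ols.params, atol=1e-10)
        s2_ref, s2_var = fgls.sigma2_by_sex
        assert s2_ref == pytest.approx(s2_var)

    def test_self_consistent_with_brute_force_wls(self, random_dataset):
        """At convergence the coefficients solve the WLS normal equations for
        the reported per-sex variances."""
        fit = hp.fit_fgls(random_dataset)
        assert fit.converged
        s2_ref, s2_var = fit.sigma2_by_sex
        w = np.where(fit.sex_is_variable, 1.0 / s2_var, 1.0 / s2_ref)
        X, y = fit.X, fit.X @ fit.params + fit.residuals
        expected = np.linalg.solve((X * w[:, None]).T @ X, (X * w[:, None]).T @ y)
        np.testing.assert_allclose(fit.params, expected, atol=1e-8)

    def test_known_weights_match_statsmodels_wls(self, random_dataset):
        sm = pytest.importorskip("statsmodels.api")
        fit = hp.fit_fgls(random_dataset)
        s2_ref, s2_var = fit.sigma2_by_sex
        w = np.where(fit.sex_is_variable, 1.0 / s2_var, 1.0 / s2_ref)
        res = sm.WLS(
            random_dataset.frame["response"].to_numpy(), fit.X, weights=w
        ).fit()
        np.testing.assert_allclose(fit.params, res.params, rtol=1e-8)

    def test_nonconvergence_carries_last_iterate(self, random_dataset):
        with pytest.raises(FGLSConvergenceError) as err:
            hp.fit_fgls(random_dataset, max_iter=1, tol=0.0)
        assert err.value.last_fit.params.shape == (3,)

    def test_zero_within_sex_variance_rejected(self):
        frame = pd.DataFrame(
            {
                "sex": ["reference"] * 4 + ["variable"] * 4,
                "treatment": ["control", "control", "treated", "treated"] * 2,
                "response": [1.0, 1.0, 2.0, 2.0, 3.0, 4.0, 5.0, 7.0],
            }
        )
        # saturated model: fitted values are the cell means, so the constant
        # reference-sex cells leave exactly zero residual variance
        with pytest.raises(ValueError, match="zero within-sex"):
            hp.fit_fgls(hp.Dataset(frame=frame), include_interaction=True)


class TestTermTest:
    def test_zero_estimate_gives_p_one(self):
        frame = pd.DataFrame(
            {
                "sex": ["reference"] * 4 + ["variable"] * 4,
                "treatment": ["control", "control", "treated", "treated"] * 2,
                # treated and control cells identical within each sex
                "response": [1.0, 2.0, 1.0, 2.0, 5.0, 6.0, 5.0, 6.0],
            }
        )
        tt = hp.term_test(hp.fit_ols(hp.Dataset(frame=frame)), "treatment")
        assert tt.estimate == pytest.approx(0.0, abs=1e-12)
        assert tt.p == pytest.approx(1.0)

    def test_location_invariance(self, random_dataset):
        shifted = hp.Dataset(
            frame=random_dataset.frame.assign(
                response=random_dataset.frame["response"] + 123.0
            )
        )
        for term in ("sex", "treatment"):
            a = hp.term_test(hp.fit_ols(random_dataset), term)
            b = hp.term_test(hp.fit_ols(shifted), term)
            assert a.p == pytest.approx(b.p, rel=1e-9)

    def test_unknown_term_and_bad_source(self, random_dataset):
        fit = hp.fit_ols(random_dataset)
        with pytest.raises(KeyError):
            hp.term_test(fit, "sex:treatment")  # not in main-effects model
        with pytest.raises(ValueError):
            hp.term_test(fit, "sex", se_source="fgls")
        with pytest.raises(ValueError):
            hp.term_test(fit, "sex", se_source="huber")

    def test_null_p_values_uniform(self, homoscedastic):
        """Under a true null with a correct model, p-values are U(0,1)."""
        pvals = []
        counts = np.array([6, 6, 6, 6])
        sex_var = np.repeat([False, False, True, True], counts)
        treated = np.repeat([False, True, False, True], counts)
        X, terms = design_matrix(sex_var, treated, include_interaction=False)
        rng = np.random.default_rng(2024)
        for _ in range(5000):
            y = rng.standard_normal(24)
            fit = fit_ols_arrays(X, y, terms, sex_var)
            pvals.append(hp.term_test(fit, "treatment").p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.001
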