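"""Tests of the nonlinear mixed model: likelihood approximations, fitting, LRT."""

import numpy as np
import pytest

from growthgwas.nmm import (
    NMMParams,
    NonlinearMixedModel,
    lrt,
    marginal_loglik,
    quadrature_loglik,
)
from growthgwas.simulate import SimulationConfig, simulate_cohort


def iid_gaussian_loglik(params, cohort):
    """Direct log-likelihood of the no-random-effect logistic regression."""
    W = cohort.weight_matrix
    t = cohort.schedule.astype(float)
    mu = params.beta_A[0] / (1.0 + params.b * np.exp(-params.beta_K[0] * t))
    r = (W - mu)[np.isfinite(W)]
    s2 = params.sigma2_e
    return -0.5 * r.size * np.log(2 * np.pi * s2) - 0.5 * (r**2).sum() / s2


class TestLikelihoodApproximation:
    def test_zero_sigma_collapses_to_iid_gaussian(self, small_bundle):
        p = NMMParams([2615.45, 0.0], [0.054, 0.0], 15.35, np.zeros((2, 2)), 3600.0)
        direct = iid_gaussian_loglik(p, small_bundle.cohort)
        assert marginal_loglik(p, small_bundle.cohort) == pytest.approx(direct, abs=1e-8)
        assert quadrature_loglik(p, small_bundle.cohort) == pytest.approx(direct, abs=1e-8)

    def test_linearization_close_to_quadrature_oracle(self, small_bundle, default_params):
        foce = marginal_loglik(default_params, small_bundle.cohort)
        agh = quadrature_loglik(default_params, small_bundle.cohort, n_nodes=21)
        assert abs(foce - agh) < 0.5

    def test_quadrature_converged_in_node_count(self, small_bundle, default_params):
        l11 = quadrature_loglik(default_params, small_bundle.cohort, n_nodes=11)
        l21 = quadrature_loglik(default_params, small_bundle.cohort, n_nodes=21)
        assert abs(l21 - l11) < 1e-4

    def test_quadrature_agrees_with_monte_carlo(self, small_bundle, default_params):
        p = default_params
        agh = quadrature_loglik(p, small_bundle.cohort, n_nodes=21)
        # independent Monte-Carlo integration of the same marginal likelihood
        rng = np.random.default_rng(123)
        n_draws = 100_000
        L = np.linalg.cholesky(p.Sigma + 1e-30 * np.eye(2))
        eps = rng.standard_normal((n_draws, 2)) @ L.T
        W = small_bundle.cohort.weight_matrix
        t = small_bundle.cohort.schedule.astype(float)
        total, se_sq = 0.0, 0.0
        for i in range(W.shape[0]):
            obs = np.isfinite(W[i])
            A = p.beta_A[0] + eps[:, 0]
            K = p.beta_K[0] + eps[:, 1]
            mu = A[:, None] / (1.0 + p.b * np.exp(-K[:, None] * t[None, obs]))
            r = W[i, obs][None, :] - mu
            logp = (
                -0.5 * obs.sum() * np.log(2 * np.pi * p.sigma2_e)
                - 0.5 * (r**2).sum(axis=1) / p.sigma2_e
            )
            m = logp.max()
            vals = np.exp(logp - m)
            mean = vals.mean()
            total += m + np.log(mean)
            se_sq += (vals.std(ddof=1) / (mean * np.sqrt(n_draws))) ** 2
        assert abs(agh - total) < 3 * np.sqrt(se_sq)

    def test_zero_coefficient_snp_leaves_loglik_unchanged(self, small_bundle, default_params):
        p = default_params
        d = small_bundle.genotypes.dosages[:, 0]
        base = marginal_loglik(p, small_bundle.cohort)
        with_snp = marginal_loglik(
            NMMParams(
                np.append(p.beta_A, 0.0), np.append(p.beta_K, 0.0),
                p.b, p.Sigma, p.sigma2_e,
            ),
            small_bundle.cohort,
            dosage=d,
            snp_target="both",
        )
        assert with_snp == pytest.approx(base, abs=1e-10)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            NMMParams([1.0], [1.0], 1.0, np.array([[1.0, 2.0], [2.0, 1.0]]), 1.0)
        with pytest.raises(ValueError):
            NMMParams([1.0], [1.0], 1.0, np.eye(2), -1.0)
        with pytest.raises(ValueError):
            NMMParams([1.0], [1.0], -2.0, np.eye(2), 1.0)

    def test_quadrature_needs_enough_nodes(self, small_bundle, default_params):
        with pytest.raises(ValueError):
            quadrature_loglik(default_params, small_bundle.cohort, n_nodes=3)


class TestModelStructure:
    """Parameter counting drives the LRT degrees of freedom."""

    def test_parameter_counts_give_expected_df(self, small_bundle):
        cohort = small_bundle.cohort
        d = small_bundle.genotypes.dosages[:, 0]
        counts = {}
        for target in ("none", "both", "A", "K"):
            m = NonlinearMixedModel(snp_target=target, max_iter=3).fit(
                cohort, None if target == "none" else d
            )
            counts[target] = m.n_params_
        assert counts["both"] - counts["none"] == 2
        assert counts["A"] - counts["none"] == 1
        assert counts["K"] - counts["none"] == 1

    def test_snp_dosage_required_when_model_carries_snp(self, small_bundle):
        with pytest.raises(ValueError):
            NonlinearMixedModel(snp_target="both").fit(small_bundle.cohort, None)

    def test_degenerate_cohort_rejected(self, small_bundle):
        from growthgwas.containers import LongitudinalCohort

        one_day = LongitudinalCohort(
            small_bundle.cohort.individuals,
            small_bundle.cohort.weights[[35]],
        )
        with pytest.raises(ValueError):
            NonlinearMixedModel().fit(one_day)


class TestFittedModels:
    def test_recovery_of_population_means(self, m0_fit_400):
        # generator truth: mu_A 2615.45 g, mu_K 0.054/day, mu_b 15.35
        assert m0_fit_400.mu_A_ == pytest.approx(2615.45, rel=0.02)
        assert m0_fit_400.mu_K_ == pytest.approx(0.054, rel=0.05)
        assert m0_fit_400.mu_b_ == pytest.approx(15.35, rel=0.10)
        assert m0_fit_400.converged_

    def test_variance_components_recovered(self, m0_fit_400):
        S = m0_fit_400.params_.Sigma
        assert np.sqrt(S[0, 0]) == pytest.approx(210.0, rel=0.15)
        assert np.sqrt(S[1, 1]) == pytest.approx(0.0054, rel=0.20)
        assert np.sqrt(m0_fit_400.params_.sigma2_e) == pytest.approx(60.0, rel=0.05)

    def test_nesting_of_likelihoods(self, cohort400, m0_fit_400):
        d = cohort400.genotypes.dosages[:, 0]
        ll = {"none": m0_fit_400.loglik_}
        for target in ("both", "A", "K"):
            ll[target] = (
                NonlinearMixedModel(snp_target=target, start=m0_fit_400.fit_)
                .fit(cohort400.cohort, d)
                .loglik_
            )
        slack = 1e-4
        assert ll["both"] >= ll["A"] - slack >= ll["none"] - 2 * slack
        assert ll["both"] >= ll["K"] - slack >= ll["none"] - 2 * slack

    def test_refit_from_optimum_is_stationary(self, cohort400, m0_fit_400):
        refit = NonlinearMixedModel(start=m0_fit_400.fit_).fit(cohort400.cohort)
        assert refit.loglik_ == pytest.approx(m0_fit_400.loglik_, abs=0.05)

    def test_random_effect_modes_track_truth(self, cohort400, m0_fit_400):
        # conditional modes should correlate strongly with the generator's
        # realized deviations at these variance settings
        re = m0_fit_400.random_effects_
        truth = cohort400.truth
        # shrinkage and the extrapolated asymptote cap the attainable
        # correlation well below 1; direction and strength are what matter
        r = np.corrcoef(re["eps_A"], truth["eps_A"])[0, 1]
        assert r > 0.7

    def test_null_snp_coefficients_covered_by_two_standard_errors(self):
        # scaled-down coverage check: across replicate null cohorts the M1
        # SNP coefficients on A and K fall within 2 SE of zero at roughly
        # the nominal 95% rate
        covered = total = 0
        for seed in range(12):
            bundle = simulate_cohort(
                SimulationConfig(n_individuals=120, n_snps=2, seed=4000 + seed)
            )
            m0 = NonlinearMixedModel().fit(bundle.cohort)
            m1 = NonlinearMixedModel(snp_target="both", start=m0.fit_).fit(
                bundle.cohort, bundle.genotypes.dosages[:, 0]
            )
            se = m1.standard_errors()
            for part in ("beta_A", "beta_K"):
                z = (m1.beta_A_ if part == "beta_A" else m1.beta_K_)["snp"] / se[part]["snp"]
                total += 1
                covered += np.isfinite(z) and abs(z) < 2
        assert total == 24
        assert covered >= 19


class TestLRT:
    def _fit(self, loglik, n_params, converged=True):
        from growthgwas.nmm import NMMFit

        p = NMMParams([1.0], [1.0], 1.0, np.eye(2), 1.0)
        return NMMFit(p, loglik, n_params, converged, 1, "none", ((), ()))

    def test_closed_form_chi2_df2(self):
        res = lrt(self._fit(-50.0, 11), self._fit(-52.0, 9))
        assert res.statistic == pytest.approx(4.0)
        assert res.df == 2
        assert res.p_value == pytest.approx(np.exp(-2.0), rel=1e-12)

    def test_identical_fits_give_null_result(self):
        res = lrt(self._fit(-50.0, 10), self._fit(-50.0, 9))
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_negative_improvement_clamped_to_zero(self):
        res = lrt(self._fit(-50.001, 10), self._fit(-50.0, 9))
        assert res.statistic == 0.0

    def test_nonconverged_fit_marks_result_unavailable(self):
        res = lrt(self._fit(-50.0, 10, converged=False), self._fit(-52.0, 9))
        assert not res.available
        assert np.isnan(res.p_value)

    def test_non_nested_pair_rejected(self):
        with pytest.raises(ValueError):
            lrt(self._fit(-50.0, 9), self._fit(-52.0, 9))
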