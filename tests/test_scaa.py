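"""Statistical catch-at-age estimator: design bases, population dynamics,
likelihood, fitting, resampling and GCV."""

import numpy as np
import pytest

from scaaverage.scaa import (
    FitData,
    PopulationState,
    SCAAConfig,
    SubmodelSpec,
    _ParamMap,
    baranov_catch,
    bspline_basis,
    build_design,
    compute_gcv,
    default_submodel_grid,
    fit_scaa,
    negative_log_likelihood,
    predict_index,
    project_population,
    sample_estimation_uncertainty,
    summarize_fit,
)

AGES = np.arange(0, 5)
YEARS = np.arange(2000, 2010)


def self_generated_data(fit, data):
    """Noise-free observations regenerated from a fitted parameter vector."""
    state, qs = fit.pmap.state_and_q(fit.theta_hat, data)
    c_pred = baranov_catch(state)
    surveys = []
    for q, idx, t in zip(qs, data.survey_year_idx, data.survey_timing):
        sub = PopulationState(n=state.n[:, idx], f=state.f[:, idx], m=state.m[:, idx])
        surveys.append(predict_index(sub, q, t))
    return FitData(
        ages=data.ages, years=data.years, catch_n=c_pred, weight=data.weight,
        m=data.m, maturity=data.maturity, survey_abundance=surveys,
        survey_year_idx=data.survey_year_idx, survey_timing=data.survey_timing,
    ), c_pred


class TestDesigns:
    def test_factor_design_column_count(self):
        pred = build_design(SubmodelSpec("fmodel", "age_year_factors"), np.arange(3), np.arange(4))
        assert pred.n_params == 1 + 2 + 3  # intercept + (3-1) ages + (4-1) years

    def test_year_smoother_constant_over_ages(self):
        pred = build_design(SubmodelSpec("qmodel", "age_and_year_smoothers", df=(3, 3)), AGES, YEARS)
        assert pred.n_params == 3 + 2
        spec = SubmodelSpec("rmodel", "year_smoother", df=3)
        rpred = build_design(spec, AGES, YEARS)
        assert rpred.n_params == 3
        # the fmodel-style year smoother surface is flat across ages
        fy = build_design(SubmodelSpec("fmodel", "tensor_spline", df=(2, 3)), AGES, YEARS)
        assert fy.n_params == 6

    def test_year_smoother_rows_identical_across_ages(self):
        X = np.tile(bspline_basis(YEARS.astype(float), 3), (AGES.size, 1))
        grid = (X @ np.array([1.0, -2.0, 0.5])).reshape(AGES.size, YEARS.size)
        assert np.allclose(grid, grid[0][None, :])

    def test_tensor_rows_match_pointwise_basis_product(self):
        """Each tensor design row equals the outer product of the marginal
        bases evaluated at that (age, year)."""
        df_a, df_y = 3, 4
        pred = build_design(SubmodelSpec("fmodel", "tensor_spline", df=(df_a, df_y)), AGES, YEARS)
        Ba = bspline_basis(AGES.astype(float), df_a)
        By = bspline_basis(YEARS.astype(float), df_y)
        for a in range(AGES.size):
            for y in range(YEARS.size):
                row = pred.X[a * YEARS.size + y]
                np.testing.assert_allclose(row, np.outer(Ba[a], By[y]).ravel(), atol=1e-12)

    def test_basis_partition_of_unity(self):
        for df in (2, 3, 4, 6):
            B = bspline_basis(np.linspace(0, 9, 50), df)
            np.testing.assert_allclose(B.sum(axis=1), 1.0, atol=1e-10)

    def test_df_exceeding_levels_rejected(self):
        with pytest.raises(ValueError):
            build_design(SubmodelSpec("fmodel", "tensor_spline", df=(10, 3)), AGES, YEARS)

    def test_inadmissible_form_rejected(self):
        with pytest.raises(ValueError):
            SubmodelSpec("rmodel", "tensor_spline")


class TestPopulationDynamics:
    def test_no_mortality_preserves_cohorts(self):
        f = np.zeros((4, 6))
        m = np.zeros((4, 6))
        state = project_population(np.full(6, 100.0), np.array([50.0, 40.0, 30.0]), f, m)
        # cohort abundance constant along diagonals (below the plusgroup)
        assert state.n[1, 1] == pytest.approx(100.0)
        assert state.n[2, 2] == pytest.approx(100.0)
        assert state.n[2, 1] == pytest.approx(50.0)  # cohort from n_init age 1
        assert state.n[3, 1] == pytest.approx(40.0 + 30.0)  # plusgroup absorbs

    def test_two_age_plusgroup_recursion(self):
        z = 0.5
        f = np.full((2, 2), z)
        m = np.zeros((2, 2))
        state = project_population(np.array([10.0, 20.0]), np.array([7.0]), f, m)
        expected = 10.0 * np.exp(-z) + 7.0 * np.exp(-z)
        assert state.n[1, 1] == pytest.approx(expected)

    def test_single_age_geometric_accumulation(self):
        z = 0.3
        f = np.full((1, 4), z)
        m = np.zeros((1, 4))
        r = np.array([5.0, 5.0, 5.0, 5.0])
        state = project_population(r, np.array([]), f, m)
        expected = 5.0
        for _ in range(3):
            expected = 5.0 + expected * np.exp(-z)
        assert state.n[0, -1] == pytest.approx(expected)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            project_population(np.array([-1.0]), np.array([]), np.zeros((1, 1)), np.zeros((1, 1)))


class TestObservationModels:
    def test_baranov_zero_f_zero_catch(self):
        state = PopulationState(n=np.full((2, 2), 100.0), f=np.zeros((2, 2)), m=np.full((2, 2), 0.2))
        assert np.all(baranov_catch(state) == 0)

    def test_baranov_half_population_at_ln2(self):
        state = PopulationState(
            n=np.array([[100.0]]), f=np.array([[np.log(2)]]), m=np.array([[0.0]])
        )
        assert baranov_catch(state)[0, 0] == pytest.approx(50.0)

    def test_baranov_known_value(self):
        state = PopulationState(n=np.array([[100.0]]), f=np.array([[0.2]]), m=np.array([[0.4]]))
        expected = (0.2 / 0.6) * (1 - np.exp(-0.6)) * 100
        assert baranov_catch(state)[0, 0] == pytest.approx(expected)
        assert baranov_catch(state)[0, 0] == pytest.approx(15.0396, abs=1e-4)

    def test_index_at_timing_zero_unit_q(self):
        state = PopulationState(n=np.full((2, 3), 7.0), f=np.zeros((2, 3)), m=np.full((2, 3), 0.3))
        np.testing.assert_allclose(predict_index(state, np.ones((2, 3)), 0.0), state.n)

    def test_index_november_survey_value(self):
        state = PopulationState(
            n=np.array([[1000.0]]), f=np.array([[0.2]]), m=np.array([[0.4]])
        )
        got = predict_index(state, np.array([[0.1]]), 0.875)
        assert got[0, 0] == pytest.approx(0.1 * 1000 * np.exp(-0.875 * 0.6), rel=1e-12)
        assert got[0, 0] == pytest.approx(59.155, abs=1e-3)

    def test_invalid_timing_rejected(self):
        state = PopulationState(n=np.ones((1, 1)), f=np.ones((1, 1)), m=np.ones((1, 1)))
        with pytest.raises(ValueError):
            predict_index(state, np.ones((1, 1)), 1.0)


class TestLikelihood:
    def test_noise_free_self_consistency(self, base_fit, fit_data, base_config):
        """Catch residuals vanish at the generating parameters and any
        perturbation increases the negative log likelihood."""
        data2, c_pred = self_generated_data(base_fit, fit_data)
        pmap = _ParamMap(data2, base_config)
        state, _ = pmap.state_and_q(base_fit.theta_hat, data2)
        np.testing.assert_allclose(baranov_catch(state), c_pred, rtol=1e-12)
        nll_star = negative_log_likelihood(base_fit.theta_hat, data2, base_config, pmap)
        rng = np.random.default_rng(0)
        for scale in (1e-3, 1e-2, 1e-1):
            theta = base_fit.theta_hat + rng.normal(0, scale, base_fit.theta_hat.size)
            assert negative_log_likelihood(theta, data2, base_config, pmap) >= nll_star

    def test_scale_invariance_of_lognormal_residuals(self, fit_data, base_config):
        """Doubling observations and all abundance parameters (recruitment,
        initial numbers, catchability) leaves the residuals unchanged."""
        pmap = _ParamMap(fit_data, base_config)
        rng = np.random.default_rng(1)
        theta = rng.normal(0, 0.1, pmap.n_params)
        # give abundance parameters a realistic scale
        theta[pmap.slices[-1]] += np.log(1e6)
        tf, tqs, tr, ti = pmap.split(theta)
        nll_a = negative_log_likelihood(theta, fit_data, base_config, pmap)

        theta2 = theta.copy()
        theta2[pmap.slices[-1]] += np.log(2)  # n_init x2
        theta2[pmap.slices[-2]] += np.log(2) / _rmodel_unity(pmap)  # recruitment x2
        data2 = FitData(
            ages=fit_data.ages, years=fit_data.years, catch_n=fit_data.catch_n * 2,
            weight=fit_data.weight, m=fit_data.m, maturity=fit_data.maturity,
            survey_abundance=[a * 2 for a in fit_data.survey_abundance],
            survey_year_idx=fit_data.survey_year_idx, survey_timing=fit_data.survey_timing,
        )
        nll_b = negative_log_likelihood(theta2, data2, base_config, pmap)
        assert nll_b == pytest.approx(nll_a, rel=1e-9)

    def test_non_finite_parameters_give_infinite_nll(self, fit_data, base_config):
        pmap = _ParamMap(fit_data, base_config)
        with np.errstate(over="ignore", invalid="ignore"):
            theta = np.full(pmap.n_params, 500.0)  # exp overflow territory
            assert negative_log_likelihood(theta, fit_data, base_config, pmap) == np.inf
            theta_bad = np.full(pmap.n_params, np.nan)
            assert negative_log_likelihood(theta_bad, fit_data, base_config, pmap) == np.inf


def _rmodel_unity(pmap):
    """Year-smoother bases are a partition of unity, so adding c to every
    recruitment coefficient adds c to log R; the divisor is 1."""
    return 1.0


class TestFitting:
    def test_refit_is_deterministic(self, fit_data, base_config, base_fit):
        again = fit_scaa(fit_data, base_config, compute_covariance=False)
        np.testing.assert_array_equal(again.theta_hat, base_fit.theta_hat)

    def test_noise_free_refit_reproduces_catches(self, base_fit, fit_data, base_config):
        """Fitting self-generated noise-free data reproduces the predicted
        catch-at-age to 1e-6 relative error."""
        data2, c_pred = self_generated_data(base_fit, fit_data)
        refit = fit_scaa(data2, base_config, compute_covariance=False)
        state, _ = refit.pmap.state_and_q(refit.theta_hat, data2)
        np.testing.assert_allclose(baranov_catch(state), c_pred, rtol=1e-6)

    def test_single_fit_recovers_terminal_ssb(self, base_fit, fit_data, scenario):
        summ = summarize_fit(base_fit.state, fit_data.weight, fit_data.maturity)
        truth = scenario.truth
        assert abs(summ["ssb"][-1] - truth["ssb"][-1]) / truth["ssb"][-1] < 0.10


class TestEstimationUncertainty:
    def test_zero_covariance_returns_theta_hat(self, base_fit):
        import dataclasses

        frozen = dataclasses.replace(base_fit, covariance=np.zeros_like(base_fit.covariance))
        draws = sample_estimation_uncertainty(frozen, 10, seed=1)
        np.testing.assert_allclose(draws, np.tile(base_fit.theta_hat, (10, 1)))

    def test_seeded_reproducibility(self, base_fit):
        a = sample_estimation_uncertainty(base_fit, 20, seed=5)
        b = sample_estimation_uncertainty(base_fit, 20, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_empirical_covariance_matches(self, base_fit):
        """Sample covariance of many draws reproduces the fit covariance to
        5% of the largest entry."""
        draws = sample_estimation_uncertainty(base_fit, 10_000, seed=2)
        emp = np.cov(draws.T)
        scale = np.abs(base_fit.covariance).max()
        assert np.max(np.abs(emp - base_fit.covariance)) / scale < 0.05

    def test_mean_converges_to_theta_hat(self, base_fit):
        draws = sample_estimation_uncertainty(base_fit, 20_000, seed=3)
        sd = np.sqrt(np.diag(base_fit.covariance))
        err = np.abs(draws.mean(axis=0) - base_fit.theta_hat)
        assert np.all(err < 5 * sd / np.sqrt(20_000) + 1e-12)

    def test_requires_converged_fit(self, base_fit):
        import dataclasses

        broken = dataclasses.replace(base_fit, converged=False)
        with pytest.raises(ValueError):
            sample_estimation_uncertainty(broken, 5, seed=0)


class TestGCV:
    def test_arithmetic(self):
        assert compute_gcv(rss=2.0, n=4, p=2) == pytest.approx(2.0)
        assert compute_gcv(rss=3.0, n=6, p=0) == pytest.approx(3.0 / 6)

    def test_monotone_in_rss(self):
        assert compute_gcv(5.0, 100, 10) > compute_gcv(4.0, 100, 10)

    def test_p_at_least_n_rejected(self):
        with pytest.raises(ValueError):
            compute_gcv(1.0, 10, 10)

    def test_overfit_model_scores_worse(self, fit_data, base_config, base_fit):
        """A fishing-mortality surface with nearly one coefficient per catch
        cell is penalised relative to the parsimonious fit."""
        overfit_cfg = SCAAConfig(
            fmodel=SubmodelSpec("fmodel", "tensor_spline",
                                df=(fit_data.ages.size - 1, fit_data.years.size - 2)),
            qmodel=base_config.qmodel,
            rmodel=base_config.rmodel,
        )
        overfit = fit_scaa(fit_data, overfit_cfg, compute_covariance=False)
        assert overfit.gcv > base_fit.gcv


class TestSummaries:
    def test_zero_maturity_zero_ssb(self):
        state = PopulationState(n=np.full((2, 3), 10.0), f=np.full((2, 3), 0.1), m=np.full((2, 3), 0.2))
        s = summarize_fit(state, weight=np.ones((2, 3)), maturity=np.zeros((2, 3)))
        assert np.all(s["ssb"] == 0)

    def test_constant_f_gives_constant_fbar(self):
        state = PopulationState(n=np.ones((5, 3)), f=np.full((5, 3), 0.37), m=np.full((5, 3), 0.2))
        s = summarize_fit(state, np.ones((5, 3)), np.ones((5, 3)), fbar_range=(1, 3))
        np.testing.assert_allclose(s["fbar"], 0.37)

    def test_toy_two_age_ssb(self):
        n = np.array([[10.0], [20.0]])
        w = np.array([[0.5], [1.5]])
        mat = np.array([[0.0], [1.0]])
        state = PopulationState(n=n, f=np.zeros((2, 1)), m=np.full((2, 1), 0.2))
        s = summarize_fit(state, w, mat)
        assert s["ssb"][0] == pytest.approx(30.0)
        assert s["harvest_rate"][0] == 0.0


def test_default_grid_is_full_cross():
    grid = default_submodel_grid()
    assert len(grid) == 18
    combos = {(c.fmodel.form, c.qmodel.form, c.rmodel.form) for c in grid}
    assert len(combos) == 18
    assert [c.config_id for c in grid] == list(range(1, 19))
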