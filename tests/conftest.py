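"""Shared fixtures: a small synthetic scenario, sliced data, one reference
fit and one small end-to-end pipeline run (session-scoped; the expensive
objects are built once)."""

from __future__ import annotations

import numpy as np
import pytest

from scaaverage.config import PipelineConfig
from scaaverage.growth import GrowthEnsemble
from scaaverage.mortality import build_mortality_ensemble
from scaaverage.pipeline import (
    _fit_data_for_iteration,
    inputs_from_scenario,
    reduced_submodel_grid,
    run_pipeline,
)
from scaaverage.scaa import SCAAConfig, SubmodelSpec, fit_scaa
from scaaverage.slicing import slice_index, slice_stock
from scaaverage.synthetic import OperatingModel, generate_scenario

SCENARIO_SEED = 11
SCENARIO_YEARS = 12
SCENARIO_MAX_AGE = 8


@pytest.fixture(scope="session")
def scenario():
    """Default small synthetic scenario with known truth."""
    return generate_scenario(
        OperatingModel(seed=SCENARIO_SEED), n_years=SCENARIO_YEARS, max_age=SCENARIO_MAX_AGE
    )


@pytest.fixture(scope="session")
def true_growth(scenario):
    """Single-draw growth ensemble at the operating model's true values."""
    return GrowthEnsemble(draws=(scenario.om.true_growth,), seed=0)


@pytest.fixture(scope="session")
def sliced(scenario, true_growth):
    """Stock and indices sliced with the true growth parameters."""
    om = scenario.om
    curve = build_mortality_ensemble("gislason", scenario.catch_lf.midpoints, true_growth)
    stock = slice_stock(scenario.catch_lf, om.weight_length, curve, scenario.maturity, true_growth)
    indices = [
        slice_index(lf, true_growth, stock.plusgroups, timing=t)
        for lf, t in zip(scenario.survey_lfs, om.survey_timing)
    ]
    return stock, indices


@pytest.fixture(scope="session")
def fit_data(sliced):
    stock, indices = sliced
    return _fit_data_for_iteration(stock, indices, 0, stock.years)


@pytest.fixture(scope="session")
def base_config():
    return SCAAConfig(
        fmodel=SubmodelSpec("fmodel", "tensor_spline"),
        qmodel=SubmodelSpec("qmodel", "age_smoother"),
        rmodel=SubmodelSpec("rmodel", "year_smoother"),
        config_id=1,
    )


@pytest.fixture(scope="session")
def base_fit(fit_data, base_config):
    """Reference converged fit with covariance."""
    fit = fit_scaa(fit_data, base_config, compute_covariance=True)
    assert fit.converged
    return fit


@pytest.fixture(scope="session")
def pipeline_result(scenario, tmp_path_factory):
    """Small but complete pipeline run: 12 process-uncertainty iterations,
    two assessment configurations, both mortality models, estimation
    uncertainty on, dip bootstrap of 200."""
    cfg = PipelineConfig(n_iterations=12, seed=SCENARIO_SEED)
    cfg.scaa.n_estimation_draws = 1
    cfg.ensemble.n_boot = 200
    cfg.paths.outdir = str(tmp_path_factory.mktemp("pipeline_out"))
    grid = reduced_submodel_grid()[:2]
    result = run_pipeline(cfg, inputs=inputs_from_scenario(scenario), grid=grid)
    return cfg, result
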