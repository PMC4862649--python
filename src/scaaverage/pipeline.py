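"""Pipeline orchestration: condition, estimate, average.

``run_pipeline`` executes the three-step workflow end to end and writes
every stage's artefacts into an output directory:

1. condition — growth ensemble sampled, natural-mortality curves built per
   model, length data sliced to one age-based stock (and index set) per
   mortality model, with per-iteration plusgroups;
2. estimate — every (assessment configuration x mortality model) variant
   is fitted to every iteration; non-converged iterations are recorded and
   dropped, estimation uncertainty added by parameter resampling;
3. average — dip-test filtering of unstable variants, inverse-median-GCV
   weights, random iteration selection across variants, quantile summary.

Each stage logs structured records (stage, variant, iteration, converged,
gcv, seed) and every random draw derives from the run seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .ensemble import (
    EnsembleResult,
    ModelVariant,
    filter_variants,
    gcv_weights,
    model_average,
    summarize_ensemble,
)
from .growth import GrowthEnsemble, sample_growth_params
from .io import (
    read_length_table,
    read_maturity_table,
    write_growth_ensemble,
    write_length_table,
    write_stock,
)
from .mortality import build_mortality_ensemble
from .scaa import (
    FitData,
    SCAAConfig,
    SubmodelSpec,
    default_submodel_grid,
    fit_scaa,
    sample_estimation_uncertainty,
    summarize_fit,
)
from .slicing import AgeIndex, AgeStructuredStock, LengthFrequency, WeightLengthParams, slice_index, slice_stock
from .synthetic import SyntheticScenario, generate_scenario

__all__ = ["PipelineError", "PipelineInputs", "PipelineResult",
           "condition_step", "assess_step", "average_step", "run_pipeline",
           "reduced_submodel_grid"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Raised when the pipeline cannot produce a usable ensemble."""


@dataclass
class PipelineInputs:
    """Length-based inputs: catch, survey indices, maturity ogive."""

    catch_lf: LengthFrequency
    survey_lfs: list[LengthFrequency]
    maturity: np.ndarray  # per catch length class
    survey_timing: list[float]


@dataclass
class ConditionedStocks:
    growth: GrowthEnsemble
    stocks: dict[str, AgeStructuredStock]  # by mortality model
    indices: dict[str, list[AgeIndex]]


@dataclass
class PipelineResult:
    growth: GrowthEnsemble
    variants: list[ModelVariant]
    report: pd.DataFrame
    weights: np.ndarray
    ensemble: EnsembleResult
    summary: pd.DataFrame


def reduced_submodel_grid(fbar_range=(1, 3)) -> list[SCAAConfig]:
    """A fast 2x2 subset of the full grid: {tensor_spline, logistic fmodel}
    x age_smoother qmodel x {year_smoother, ricker rmodel}."""
    fm = [SubmodelSpec("fmodel", "tensor_spline"), SubmodelSpec("fmodel", "logistic_age_by_year_smoother")]
    rm = [SubmodelSpec("rmodel", "year_smoother"), SubmodelSpec("rmodel", "ricker")]
    q = SubmodelSpec("qmodel", "age_smoother")
    grid = []
    i = 1
    for r in rm:
        for f in fm:
            grid.append(SCAAConfig(fmodel=f, qmodel=q, rmodel=r, fbar_range=tuple(fbar_range), config_id=i))
            i += 1
    return grid


def load_inputs(config: PipelineConfig) -> PipelineInputs:
    """Read the length-based inputs named in the config paths."""
    paths = config.paths
    if paths.catch is None:
        raise PipelineError("no catch table configured; run the simulate step first")
    catch_lf = read_length_table(paths.catch)
    survey_lfs = [read_length_table(p) for p in paths.surveys]
    mat = read_maturity_table(paths.maturity)
    mat_values = np.interp(
        catch_lf.midpoints, mat["length_lower"].to_numpy(), mat["value"].to_numpy()
    )
    timing = list(config.scaa.survey_timing)[: len(survey_lfs)]
    return PipelineInputs(
        catch_lf=catch_lf, survey_lfs=survey_lfs, maturity=mat_values, survey_timing=timing
    )


def inputs_from_scenario(scenario: SyntheticScenario) -> PipelineInputs:
    return PipelineInputs(
        catch_lf=scenario.catch_lf,
        survey_lfs=scenario.survey_lfs,
        maturity=scenario.maturity,
        survey_timing=list(scenario.om.survey_timing),
    )


def condition_step(inputs: PipelineInputs, config: PipelineConfig) -> ConditionedStocks:
    """Step 1: growth ensemble, mortality curves, slicing."""
    gs = config.growth
    growth = sample_growth_params(
        gs.marginals(), gs.copula(), n=config.n_iterations, seed=config.seed
    )
    logger.info("condition: sampled %d growth parameter sets (seed %d)", len(growth), config.seed)
    wl = WeightLengthParams(a=config.scaa.weight_length_a, b=config.scaa.weight_length_b)
    midpoints = inputs.catch_lf.midpoints
    stocks: dict[str, AgeStructuredStock] = {}
    indices: dict[str, list[AgeIndex]] = {}
    for model in config.mortality.models:
        curve = build_mortality_ensemble(
            model, midpoints, growth,
            constant_value=config.mortality.constant_value,
            jensen_window=tuple(config.mortality.jensen_window),
        )
        stock = slice_stock(
            inputs.catch_lf, wl, curve, inputs.maturity, growth,
            plusgroup_threshold=config.slicing.plusgroup_threshold,
            representative=config.slicing.representative,
        )
        stocks[model] = stock
        indices[model] = [
            slice_index(lf, growth, stock.plusgroups, timing=t,
                        representative=config.slicing.representative)
            for lf, t in zip(inputs.survey_lfs, inputs.survey_timing)
        ]
        logger.info(
            "condition: sliced stock under %r mortality; plusgroups %d-%d",
            model, stock.plusgroups.min(), stock.plusgroups.max(),
        )
    return ConditionedStocks(growth=growth, stocks=stocks, indices=indices)


def _fit_data_for_iteration(
    stock: AgeStructuredStock, indices: list[AgeIndex], i: int, stock_years: np.ndarray
) -> FitData:
    it = stock.iterations[i]
    year_to_idx = {y: j for j, y in enumerate(stock_years)}
    survey_abundance, survey_year_idx, survey_timing = [], [], []
    for ix in indices:
        idx = np.array([year_to_idx[y] for y in ix.years if y in year_to_idx])
        years_mask = np.isin(ix.years, stock_years)
        survey_abundance.append(ix.iterations[i][:, years_mask])
        survey_year_idx.append(idx)
        survey_timing.append(ix.timing)
    return FitData(
        ages=it.ages, years=stock_years, catch_n=it.catch_n, weight=it.weight,
        m=it.m, maturity=it.maturity,
        survey_abundance=survey_abundance,
        survey_year_idx=survey_year_idx,
        survey_timing=survey_timing,
    )


def assess_step(
    conditioned: ConditionedStocks,
    config: PipelineConfig,
    grid: list[SCAAConfig] | None = None,
) -> list[ModelVariant]:
    """Step 2: fit every (configuration x mortality model) variant to every
    iteration, adding estimation uncertainty by parameter resampling."""
    if grid is None:
        grid = (default_submodel_grid(tuple(config.scaa.fbar_range))
                if config.scaa.grid == "full"
                else reduced_submodel_grid(tuple(config.scaa.fbar_range)))
    n_draws = config.scaa.n_estimation_draws
    want_cov = config.scaa.compute_covariance and n_draws > 0
    variants = []
    for model, stock in conditioned.stocks.items():
        indices = conditioned.indices[model]
        for sa in grid:
            summaries, gcvs = [], []
            for i in range(stock.n_iterations):
                data = _fit_data_for_iteration(stock, indices, i, stock.years)
                fit = fit_scaa(data, sa, compute_covariance=want_cov, maxiter=config.scaa.maxiter)
                logger.info(
                    "assess: variant=sa%02d-%s iteration=%d converged=%s gcv=%.4g",
                    sa.config_id, model, i, fit.converged, fit.gcv,
                )
                if not fit.converged or not np.isfinite(fit.gcv):
                    continue
                if want_cov and fit.covariance is not None:
                    draw_seed = config.seed + 100_000 + 1000 * sa.config_id + i
                    draws = sample_estimation_uncertainty(fit, n_draws, seed=draw_seed)
                    for d in draws:
                        st = fit.state_for(d)
                        summaries.append(
                            summarize_fit(st, data.weight, data.maturity, sa.fbar_range)
                        )
                        gcvs.append(fit.gcv)
                else:
                    summaries.append(
                        summarize_fit(fit.state, data.weight, data.maturity, sa.fbar_range)
                    )
                    gcvs.append(fit.gcv)
            variants.append(
                ModelVariant(
                    sa_config_id=sa.config_id, mortality_model=model,
                    iterations=summaries, gcvs=np.array(gcvs), years=stock.years,
                )
            )
            logger.info(
                "assess: variant=sa%02d-%s fitted %d/%d iterations",
                sa.config_id, model, len(summaries), stock.n_iterations,
            )
    return variants


def average_step(
    variants: list[ModelVariant], config: PipelineConfig
) -> tuple[list[ModelVariant], pd.DataFrame, np.ndarray, EnsembleResult, pd.DataFrame]:
    """Step 3: dip-test filtering, GCV weighting, model averaging."""
    es = config.ensemble
    retained, report = filter_variants(
        variants, alpha=es.alpha, n_boot=es.n_boot, seed=config.seed + 500_000,
        min_iterations=es.min_iterations,
    )
    if not retained:
        raise PipelineError(
            "all model variants were rejected by the bimodality filter; "
            f"diagnostic report:\n{report.to_string(index=False)}"
        )
    weights = gcv_weights(retained)
    report = report.merge(
        pd.DataFrame({
            "variant": [v.label for v in retained],
            "median_gcv": [v.median_gcv() for v in retained],
            "weight": weights,
        }),
        on="variant", how="left",
    )
    n_select = es.n_select or min(v.n_success for v in retained)
    result = model_average(retained, weights, n_select, seed=config.seed + 900_000)
    summary = summarize_ensemble(result, tuple(es.quantiles))
    logger.info(
        "average: retained %d/%d variants, selected %d iterations",
        len(retained), len(variants), n_select,
    )
    return retained, report, weights, result, summary


def _write_outputs(outdir: Path, conditioned: ConditionedStocks,
                   report: pd.DataFrame, result: EnsembleResult, summary: pd.DataFrame) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    write_growth_ensemble(conditioned.growth, outdir / "growth_ensemble.csv")
    for model, stock in conditioned.stocks.items():
        write_stock(stock, outdir / f"stock_{model}.csv")
    report.to_csv(outdir / "variant_report.csv", index=False)
    rows = []
    for i, (it, (variant, orig)) in enumerate(zip(result.iterations, result.provenance)):
        for qty, series in it.items():
            for yi, year in enumerate(result.years):
                rows.append((i, variant, orig, year, qty, series[yi]))
    pd.DataFrame(
        rows, columns=["iteration", "variant", "source_iteration", "year", "quantity", "value"]
    ).to_csv(outdir / "ensemble_series.csv", index=False)
    summary.to_csv(outdir / "ensemble_summary.csv", index=False)


def run_pipeline(
    config: PipelineConfig,
    inputs: PipelineInputs | None = None,
    grid: list[SCAAConfig] | None = None,
    write: bool = True,
) -> PipelineResult:
    """Execute condition -> estimate -> average and write artefacts.

    ``inputs`` defaults to the tables named in the config paths; pass a
    :class:`PipelineInputs` (e.g. from a synthetic scenario) to run fully
    in memory.
    """
    if inputs is None:
        inputs = load_inputs(config)
    conditioned = condition_step(inputs, config)
    variants = assess_step(conditioned, config, grid)
    retained, report, weights, result, summary = average_step(variants, config)
    if write:
        _write_outputs(Path(config.paths.outdir), conditioned, report, result, summary)
    return PipelineResult(
        growth=conditioned.growth, variants=retained, report=report,
        weights=weights, ensemble=result, summary=summary,
    )
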