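"""Synthetic length-based data from a known operating model.

The generator builds an age-structured true population (von Bertalanffy
growth, Baranov catches, logistic selectivity, lognormal observation
noise), then *renders* the age-based truth into the length-based tables
the assessment pipeline consumes: a catch length-frequency in 1 cm
classes, survey indices in 2 cm classes and a maturity-at-length ogive.
Because the truth is known exactly, every pipeline stage can be scored
for recovery.

Length-at-age is normally distributed around the growth curve with a
constant coefficient of variation; that individual spread is what makes
deterministic length slicing an approximation worth testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .growth import GrowthParams, vb_length_at_age
from .mortality import build_mortality_ensemble, constant_m
from .scaa import PopulationState, baranov_catch, project_population, summarize_fit
from .slicing import LengthFrequency, WeightLengthParams

__all__ = [
    "OperatingModel",
    "simulate_population",
    "render_lengths",
    "render_surveys",
    "ground_truth",
    "SyntheticScenario",
    "generate_scenario",
]

DEFAULT_N_YEARS = 15
DEFAULT_MAX_AGE = 10
DEFAULT_FIRST_YEAR = 2001
DEFAULT_SURVEY_TIMINGS = (0.75, 0.75, 0.875)  # two October surveys, one November


@dataclass(frozen=True)
class OperatingModel:
    """Fully known truth generating the synthetic length-based inputs."""

    true_growth: GrowthParams = field(
        default_factory=lambda: GrowthParams(linf=130.0, k=0.164, t0=-0.092)
    )
    mortality_model: str = "gislason"  # the truth is length-shaped by default
    constant_m_value: float = 0.4
    weight_length: WeightLengthParams = field(default_factory=WeightLengthParams)
    # fishing: logistic selectivity times a year trajectory
    sel_a50: float = 2.0
    sel_delta: float = 0.5
    fbar_start: float = 0.25
    fbar_end: float = 0.55
    # recruitment: lognormal variation around a stable mean
    mean_recruitment: float = 1.0e6
    recruitment_sigma: float = 0.2
    # maturity: logistic in length
    maturity_l50: float = 42.0
    maturity_delta: float = 5.0
    # rendering
    length_cv: float = 0.1
    obs_sigma_catch: float = 0.1
    obs_sigma_index: float = 0.1
    survey_timing: tuple[float, ...] = DEFAULT_SURVEY_TIMINGS
    survey_q_a50: tuple[float, ...] = (0.8, 1.2, 1.6)
    survey_q_scale: tuple[float, ...] = (1e-4, 8e-5, 5e-5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length_cv <= 0:
            raise ValueError("length_cv must be positive")
        if len(self.survey_timing) != len(self.survey_q_a50) or len(self.survey_timing) != len(
            self.survey_q_scale
        ):
            raise ValueError("survey settings must have equal lengths")

    @property
    def n_surveys(self) -> int:
        return len(self.survey_timing)

    def mean_length_at_age(self, ages: np.ndarray) -> np.ndarray:
        """Mid-year mean length for integer ages."""
        return vb_length_at_age(np.asarray(ages, float) + 0.5, self.true_growth)

    def m_at_age(self, ages: np.ndarray) -> np.ndarray:
        """True natural mortality at age, via the length-based curve."""
        lengths = np.arange(1.0, 130.0) + 0.5
        if self.mortality_model == "constant":
            curve = constant_m(lengths, self.constant_m_value)
        else:
            from .growth import GrowthEnsemble

            ens = GrowthEnsemble(draws=(self.true_growth,), seed=self.seed)
            curve = build_mortality_ensemble("gislason", lengths, ens)
        mean_len = np.clip(self.mean_length_at_age(ages), lengths[0], lengths[-1])
        return np.interp(mean_len, lengths, curve.m[0])

    def selectivity(self, ages: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-(np.asarray(ages, float) - self.sel_a50) / self.sel_delta))

    def survey_q(self, ages: np.ndarray, s: int) -> np.ndarray:
        sel = 1.0 / (1.0 + np.exp(-(np.asarray(ages, float) - self.survey_q_a50[s]) / 0.6))
        return self.survey_q_scale[s] * sel

    def maturity_at_length(self, lengths: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-(np.asarray(lengths, float) - self.maturity_l50) / self.maturity_delta))


def simulate_population(
    om: OperatingModel,
    n_years: int = DEFAULT_N_YEARS,
    max_age: int = DEFAULT_MAX_AGE,
) -> tuple[PopulationState, np.ndarray]:
    """True population state and true (noise-free) catch-at-age."""
    ages = np.arange(0, max_age + 1)
    rng = np.random.default_rng(om.seed)
    fbar = np.linspace(om.fbar_start, om.fbar_end, n_years)
    f = np.outer(om.selectivity(ages), fbar)
    m = np.repeat(om.m_at_age(ages)[:, None], n_years, axis=1)
    rec_dev = rng.normal(0.0, om.recruitment_sigma, size=n_years)
    recruits = om.mean_recruitment * np.exp(rec_dev - om.recruitment_sigma**2 / 2)
    # first-year column near equilibrium under the first year's mortality
    z0 = f[:, 0] + m[:, 0]
    n_init = om.mean_recruitment * np.exp(-np.cumsum(z0[:-1]))
    state = project_population(recruits, n_init, f, m)
    return state, baranov_catch(state)


def _length_distribution(om: OperatingModel, ages: np.ndarray, lower: np.ndarray, width: float) -> np.ndarray:
    """(age, length) allocation matrix: rows sum to 1 over the grid."""
    from scipy.stats import norm

    mean = om.mean_length_at_age(ages)
    sd = om.length_cv * mean
    edges = np.r_[lower, lower[-1] + width]
    cdf = norm.cdf(edges[None, :], loc=mean[:, None], scale=sd[:, None])
    probs = np.diff(cdf, axis=1)
    probs /= probs.sum(axis=1, keepdims=True)  # renormalise: conserve totals
    return probs


def render_lengths(
    catch_at_age: np.ndarray,
    om: OperatingModel,
    years: np.ndarray,
    lower: np.ndarray | None = None,
    width: float = 1.0,
) -> LengthFrequency:
    """Spread catches-at-age over length classes (totals conserved)."""
    if lower is None:
        lower = np.arange(1.0, 130.0)
    ages = np.arange(catch_at_age.shape[0])
    probs = _length_distribution(om, ages, lower, width)
    abundance = catch_at_age.T @ probs  # (year, length)
    return LengthFrequency(years=years, length_lower=lower, width=width, abundance=abundance)


def render_surveys(
    state: PopulationState,
    om: OperatingModel,
    years: np.ndarray,
    lower: np.ndarray | None = None,
    width: float = 2.0,
) -> list[LengthFrequency]:
    """Noisy survey indices, length-rendered and binned (2 cm default)."""
    if lower is None:
        lower = np.arange(1.0, 129.0, 2.0)
    ages = np.arange(state.n.shape[0])
    rng = np.random.default_rng(om.seed + 1)
    probs = _length_distribution(om, ages, lower, width)
    out = []
    for s in range(om.n_surveys):
        q = om.survey_q(ages, s)[:, None]
        idx = q * state.n * np.exp(-om.survey_timing[s] * state.z)
        if om.obs_sigma_index > 0:
            noise = rng.normal(0.0, om.obs_sigma_index, size=idx.shape)
            idx = idx * np.exp(noise - om.obs_sigma_index**2 / 2)
        out.append(
            LengthFrequency(years=years, length_lower=lower, width=width, abundance=idx.T @ probs)
        )
    return out


def ground_truth(om: OperatingModel, n_years: int = DEFAULT_N_YEARS, max_age: int = DEFAULT_MAX_AGE) -> dict[str, np.ndarray]:
    """Exact summary series of the operating model for recovery scoring."""
    state, _ = simulate_population(om, n_years, max_age)
    ages = np.arange(0, max_age + 1)
    mean_len = om.mean_length_at_age(ages)
    weight = np.repeat(om.weight_length.weight(mean_len)[:, None], n_years, axis=1)
    maturity = np.repeat(om.maturity_at_length(mean_len)[:, None], n_years, axis=1)
    return summarize_fit(state, weight, maturity)


@dataclass
class SyntheticScenario:
    """A rendered input bundle plus the truth that generated it."""

    om: OperatingModel
    years: np.ndarray
    catch_lf: LengthFrequency
    survey_lfs: list[LengthFrequency]
    maturity_lengths: np.ndarray
    maturity: np.ndarray
    truth: dict[str, np.ndarray]


def generate_scenario(
    om: OperatingModel | None = None,
    n_years: int = DEFAULT_N_YEARS,
    max_age: int = DEFAULT_MAX_AGE,
    first_year: int = DEFAULT_FIRST_YEAR,
) -> SyntheticScenario:
    """Default synthetic scenario: the full input bundle with known truth."""
    om = om or OperatingModel()
    years = np.arange(first_year, first_year + n_years)
    state, catch = simulate_population(om, n_years, max_age)
    if om.obs_sigma_catch > 0:
        rng = np.random.default_rng(om.seed + 2)
        noise = rng.normal(0.0, om.obs_sigma_catch, size=catch.shape)
        catch = catch * np.exp(noise - om.obs_sigma_catch**2 / 2)
    catch_lf = render_lengths(catch, om, years)
    survey_lfs = render_surveys(state, om, years)
    maturity = om.maturity_at_length(catch_lf.midpoints)
    return SyntheticScenario(
        om=om,
        years=years,
        catch_lf=catch_lf,
        survey_lfs=survey_lfs,
        maturity_lengths=catch_lf.midpoints,
        maturity=maturity,
        truth=ground_truth(om, n_years, max_age),
    )
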