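"""Statistical catch-at-age assessment with pluggable submodels.

The estimator models an age-structured population (exponential survival
with fishing mortality F and natural mortality M, plusgroup accumulation)
observed through catch-at-age (Baranov catch equation) and one or more
survey abundance indices.  Three submodels are configurable:

* fmodel — the fishing-mortality surface F(a, y): additive age and year
  factors, a tensor-product cubic-spline smoother over age and year, or a
  logistic selectivity-at-age curve whose plateau follows a year smoother;
* qmodel — survey catchability q(a, y): an age smoother, separate age and
  year smoothers, or the logistic-by-year-smoother form (one qmodel spec is
  applied to every survey);
* rmodel — recruitment R(y): a year smoother, or free recruitment with a
  lognormal penalty (sd 0.10) toward a Ricker curve R = alpha*S*exp(-beta*S).

Observation errors are independent lognormals, one variance per data
source, profiled out of the likelihood.  Estimation uncertainty comes from
multivariate-normal resampling of the parameters using the inverse observed
information; the generalised cross-validation score of the catch-at-age
matrix, GCV = n*RSS/(n - p)^2, scores each fit for model averaging.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import interpolate, optimize

__all__ = [
    "SubmodelSpec",
    "SCAAConfig",
    "PopulationState",
    "SCAAFit",
    "FitData",
    "bspline_basis",
    "build_design",
    "project_population",
    "baranov_catch",
    "predict_index",
    "negative_log_likelihood",
    "fit_scaa",
    "sample_estimation_uncertainty",
    "compute_gcv",
    "summarize_fit",
    "default_submodel_grid",
    "FMODEL_FORMS",
    "QMODEL_FORMS",
    "RMODEL_FORMS",
]

logger = logging.getLogger(__name__)

FMODEL_FORMS = ("age_year_factors", "tensor_spline", "logistic_age_by_year_smoother")
QMODEL_FORMS = ("age_smoother", "age_and_year_smoothers", "logistic_age_by_year_smoother")
RMODEL_FORMS = ("year_smoother", "ricker")

_ADMISSIBLE = {"fmodel": FMODEL_FORMS, "qmodel": QMODEL_FORMS, "rmodel": RMODEL_FORMS}

RICKER_SIGMA = 0.10  # lognormal sd of the Ricker recruitment penalty
_RSS_FLOOR = 1e-12  # numerical floor inside the profiled-variance log

DEFAULT_FBAR_RANGE = (1, 3)


def default_age_df(n_ages: int) -> int:
    """Default smoother basis dimension on the age margin."""
    return max(2, min(6, n_ages - 2))


def default_year_df(n_years: int) -> int:
    """Default smoother basis dimension on the year margin."""
    return max(2, min(8, int(np.ceil(n_years / 4)) + 2))


@dataclass(frozen=True)
class SubmodelSpec:
    """One submodel choice: its role, functional form and basis dimensions.

    ``df`` may be None (defaults derived from the data dimensions at design
    build time), an int (applied to the relevant margin), or a (age, year)
    pair for tensor products / additive smoothers.
    """

    role: str
    form: str
    df: int | tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.role not in _ADMISSIBLE:
            raise ValueError(f"unknown role {self.role!r}")
        if self.form not in _ADMISSIBLE[self.role]:
            raise ValueError(f"form {self.form!r} not admissible for role {self.role!r}")


@dataclass(frozen=True)
class SCAAConfig:
    """One assessment configuration: fmodel x qmodel x rmodel."""

    fmodel: SubmodelSpec
    qmodel: SubmodelSpec  # applied to every survey
    rmodel: SubmodelSpec
    fbar_range: tuple[int, int] = DEFAULT_FBAR_RANGE
    config_id: int | None = None

    def __post_init__(self) -> None:
        if self.fmodel.role != "fmodel" or self.qmodel.role != "qmodel" or self.rmodel.role != "rmodel":
            raise ValueError("submodel roles do not match their slots")


@dataclass(frozen=True)
class PopulationState:
    """Numbers, fishing and natural mortality on the age x year grid."""

    n: np.ndarray
    f: np.ndarray
    m: np.ndarray

    @property
    def z(self) -> np.ndarray:
        return self.f + self.m


@dataclass
class FitData:
    """One iteration's age-based inputs to the assessment."""

    ages: np.ndarray  # 0..plusgroup
    years: np.ndarray
    catch_n: np.ndarray  # (age, year)
    weight: np.ndarray
    m: np.ndarray
    maturity: np.ndarray
    survey_abundance: list[np.ndarray]  # (age, year_subset) per survey
    survey_year_idx: list[np.ndarray]  # indices into `years` per survey
    survey_timing: list[float]


# ---------------------------------------------------------------------------
# design bases


def bspline_basis(x: np.ndarray, df: int) -> np.ndarray:
    """B-spline basis with ``df`` columns on the range of ``x``.

    Cubic where df allows, lower order otherwise (df=2 -> linear hat
    functions).  Knots are clamped and uniformly spaced; columns form a
    partition of unity.
    """
    x = np.asarray(x, dtype=float)
    if df < 2:
        raise ValueError("smoother df must be >= 2")
    k = min(3, df - 1)
    n_interior = df - k - 1
    if n_interior < 0:
        raise ValueError(f"df={df} too small for order {k}")
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise ValueError("basis requires at least two distinct x values")
    interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
    t = np.r_[[lo] * (k + 1), interior, [hi] * (k + 1)]
    # nudge the right edge so the last basis function includes x == hi
    xe = np.where(x >= hi, hi - 1e-9 * (hi - lo), x)
    return interpolate.BSpline.design_matrix(xe, t, k).toarray()


class _LinearPredictor:
    """Linear design on the (age, year) grid: log-surface = (X @ beta)."""

    def __init__(self, X: np.ndarray, shape: tuple[int, int]):
        self.X = X
        self.shape = shape
        self.n_params = X.shape[1]

    def predict_log(self, theta: np.ndarray) -> np.ndarray:
        return (self.X @ theta).reshape(self.shape)

    def init_params(self, log_target: np.ndarray) -> np.ndarray:
        beta, *_ = np.linalg.lstsq(self.X, log_target.ravel(), rcond=None)
        return beta


class _LogisticPredictor:
    """Logistic selectivity over ages with a year smoother on the plateau.

    log-surface(a, y) = -log(1 + exp(-(a - a50)/delta)) + B_year(y) @ beta.
    theta = [a50, log_delta, beta].
    """

    def __init__(self, ages: np.ndarray, year_basis: np.ndarray):
        self.ages = np.asarray(ages, dtype=float)
        self.By = year_basis
        self.shape = (self.ages.size, year_basis.shape[0])
        self.n_params = 2 + year_basis.shape[1]

    def predict_log(self, theta: np.ndarray) -> np.ndarray:
        a50, log_delta = theta[0], theta[1]
        delta = np.exp(log_delta)
        sel = -np.logaddexp(0.0, -(self.ages - a50) / delta)  # log logistic
        plateau = self.By @ theta[2:]
        return sel[:, None] + plateau[None, :]

    def init_params(self, log_target: np.ndarray) -> np.ndarray:
        a50 = float(np.median(self.ages))
        log_delta = 0.0
        sel = -np.logaddexp(0.0, -(self.ages - a50))
        resid = (log_target - sel[:, None]).mean(axis=0)
        beta, *_ = np.linalg.lstsq(self.By, resid, rcond=None)
        return np.r_[a50, log_delta, beta]


def build_design(spec: SubmodelSpec, ages: np.ndarray, years: np.ndarray):
    """Predictor object for a submodel on the given age/year grid.

    Returns an object with ``n_params``, ``predict_log(theta)`` (an
    (n_ages, n_years) grid, or an (n_years,) vector for rmodels) and
    ``init_params(log_target)``.
    """
    ages = np.asarray(ages, dtype=float)
    years = np.asarray(years, dtype=float)
    n_a, n_y = ages.size, years.size
    if spec.role != "rmodel" and (n_a < 2 or n_y < 2):
        raise ValueError("designs require at least 2 ages and 2 years")

    def margins() -> tuple[int, int]:
        if spec.df is None:
            return default_age_df(n_a), default_year_df(n_y)
        if np.isscalar(spec.df):
            return int(spec.df), int(spec.df)
        return int(spec.df[0]), int(spec.df[1])

    df_a, df_y = margins()
    if df_a > n_a or df_y > n_y:
        raise ValueError("df exceeds the number of available levels")

    grid_shape = (n_a, n_y)
    ones = np.ones((n_a * n_y, 1))

    if spec.form == "age_year_factors":
        age_idx = np.repeat(np.arange(n_a), n_y)
        year_idx = np.tile(np.arange(n_y), n_a)
        A = np.eye(n_a)[age_idx][:, 1:]  # corner constraint: drop first level
        Y = np.eye(n_y)[year_idx][:, 1:]
        return _LinearPredictor(np.hstack([ones, A, Y]), grid_shape)

    if spec.form == "tensor_spline":
        Ba = bspline_basis(ages, df_a)
        By = bspline_basis(years, df_y)
        # row-wise Kronecker over the flattened (age-major) grid
        X = np.einsum("ap,yq->aypq", Ba, By).reshape(n_a * n_y, df_a * df_y)
        return _LinearPredictor(X, grid_shape)

    if spec.form == "age_smoother":
        Ba = bspline_basis(ages, df_a)
        X = np.repeat(Ba, n_y, axis=0)
        return _LinearPredictor(X, grid_shape)

    if spec.form == "year_smoother":
        By = bspline_basis(years, df_y)
        if spec.role == "rmodel":
            pred = _LinearPredictor(By, (n_y,))
            pred.shape = (n_y,)
            return pred
        X = np.tile(By, (n_a, 1))
        return _LinearPredictor(X, grid_shape)

    if spec.form == "age_and_year_smoothers":
        Ba = bspline_basis(ages, df_a)
        By = bspline_basis(years, df_y)[:, 1:]  # drop one column: identifiability
        X = np.hstack([np.repeat(Ba, n_y, axis=0), np.tile(By, (n_a, 1))])
        return _LinearPredictor(X, grid_shape)

    if spec.form == "logistic_age_by_year_smoother":
        By = bspline_basis(years, df_y)
        return _LogisticPredictor(ages, By)

    raise ValueError(f"unknown form {spec.form!r}")


# ---------------------------------------------------------------------------
# population dynamics


def project_population(recruits: np.ndarray, n_init: np.ndarray, f: np.ndarray, m: np.ndarray) -> PopulationState:
    """Forward-project numbers-at-age under exponential survival.

    ``recruits`` fills the first age row, ``n_init`` the first-year column
    (ages 1..A); the terminal age is a plusgroup that accumulates
    survivors from itself and the age below.
    """
    f = np.asarray(f, dtype=float)
    m = np.asarray(m, dtype=float)
    recruits = np.asarray(recruits, dtype=float)
    n_init = np.asarray(n_init, dtype=float)
    if np.any(f < 0) or np.any(m < 0) or np.any(recruits < 0) or np.any(n_init < 0):
        raise ValueError("rates and abundances must be non-negative")
    n_ages, n_years = f.shape
    if recruits.size != n_years or n_init.size != n_ages - 1:
        raise ValueError("recruits / n_init dimensions inconsistent with f")
    z = f + m
    surv = np.exp(-z)
    n = np.zeros((n_ages, n_years))
    n[0, :] = recruits
    if n_ages == 1:
        # degenerate single-age stock: the plusgroup is the recruitment age
        for y in range(1, n_years):
            n[0, y] = recruits[y] + n[0, y - 1] * surv[0, y - 1]
        return PopulationState(n=n, f=f, m=m)
    n[1:, 0] = n_init
    for y in range(1, n_years):
        n[1:, y] = n[:-1, y - 1] * surv[:-1, y - 1]
        n[-1, y] += n[-1, y - 1] * surv[-1, y - 1]  # plusgroup accumulation
    return PopulationState(n=n, f=f, m=m)


def baranov_catch(state: PopulationState) -> np.ndarray:
    """Baranov catch equation C = (F/Z)(1 - exp(-Z)) N, with C=0 where F=0."""
    z = state.z
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(z > 0, state.f / np.where(z > 0, z, 1.0), 0.0)
        c = frac * (1.0 - np.exp(-z)) * state.n
    return np.where(state.f == 0, 0.0, c)


def predict_index(state: PopulationState, q: np.ndarray, timing: float) -> np.ndarray:
    """Survey observation model I = q N exp(-timing * Z)."""
    if not (0.0 <= timing < 1.0):
        raise ValueError("timing must lie in [0, 1)")
    return q * state.n * np.exp(-timing * state.z)


# ---------------------------------------------------------------------------
# likelihood


class _ParamMap:
    """Partition of the flat parameter vector into submodel segments."""

    def __init__(self, data: FitData, config: SCAAConfig):
        ages, years = data.ages, data.years
        self.f_pred = build_design(config.fmodel, ages, years)
        self.q_preds = [
            build_design(config.qmodel, ages, years[idx]) for idx in data.survey_year_idx
        ]
        self.ricker = config.rmodel.form == "ricker"
        if self.ricker:
            self.n_r = 2 + years.size  # log_alpha, log_beta, log R per year
            self.r_pred = None
        else:
            self.r_pred = build_design(config.rmodel, ages, years)
            self.n_r = self.r_pred.n_params
        self.n_init_count = ages.size - 1
        sizes = (
            [self.f_pred.n_params]
            + [qp.n_params for qp in self.q_preds]
            + [self.n_r, self.n_init_count]
        )
        self.slices = []
        start = 0
        for s in sizes:
            self.slices.append(slice(start, start + s))
            start += s
        self.n_params = start
        self.n_catch_predictor_params = self.f_pred.n_params + self.n_r + self.n_init_count

    def split(self, theta: np.ndarray):
        parts = [theta[s] for s in self.slices]
        theta_f = parts[0]
        theta_qs = parts[1 : 1 + len(self.q_preds)]
        theta_r = parts[-2]
        theta_init = parts[-1]
        return theta_f, theta_qs, theta_r, theta_init

    def state_and_q(self, theta: np.ndarray, data: FitData):
        """Map a parameter vector to a population state and q surfaces."""
        theta_f, theta_qs, theta_r, theta_init = self.split(theta)
        f = np.exp(self.f_pred.predict_log(theta_f))
        if self.ricker:
            log_r = theta_r[2:]
        else:
            log_r = self.r_pred.predict_log(theta_r)
        recruits = np.exp(log_r)
        n_init = np.exp(theta_init)
        state = project_population(recruits, n_init, f, data.m)
        qs = [np.exp(qp.predict_log(tq)) for qp, tq in zip(self.q_preds, theta_qs)]
        return state, qs

    def ricker_penalty(self, theta: np.ndarray, state: PopulationState, data: FitData) -> float:
        if not self.ricker:
            return 0.0
        _, _, theta_r, _ = self.split(theta)
        log_alpha, log_beta = theta_r[0], theta_r[1]
        log_r = theta_r[2:]
        ssb = np.sum(state.n * data.weight * data.maturity, axis=0)
        ssb = np.maximum(ssb, 1e-12)
        expected = log_alpha + np.log(ssb) - np.exp(log_beta) * ssb
        dev = (log_r - expected) / RICKER_SIGMA
        return 0.5 * float(dev @ dev)


def _lognormal_deviance(obs: np.ndarray, pred: np.ndarray) -> tuple[float, int]:
    """Profiled-variance lognormal contribution: (n/2) log(RSS/n), and n.

    Cells with non-positive observations carry no information under the
    lognormal model and are excluded.
    """
    mask = obs > 0
    n = int(mask.sum())
    if n == 0:
        return 0.0, 0
    pred_m = np.maximum(pred[mask], 1e-300)
    resid = np.log(obs[mask]) - np.log(pred_m)
    rss = float(resid @ resid)
    return 0.5 * n * np.log(rss / n + _RSS_FLOOR), n


def _pooled_rss(theta: np.ndarray, data: FitData, config: SCAAConfig, pmap: _ParamMap) -> float:
    """Unweighted pooled sum of squared log residuals over all sources.

    Used as a well-conditioned warm-start objective before the profiled
    likelihood, which has steep per-source log-holes near perfect fits.
    """
    try:
        state, qs = pmap.state_and_q(theta, data)
    except (FloatingPointError, OverflowError, ValueError):
        return np.inf
    if not np.all(np.isfinite(state.n)):
        return np.inf
    total = 0.0
    c_pred = baranov_catch(state)
    mask = data.catch_n > 0
    r = np.log(data.catch_n[mask]) - np.log(np.maximum(c_pred[mask], 1e-300))
    total += float(r @ r)
    for ab, idx, timing, q in zip(
        data.survey_abundance, data.survey_year_idx, data.survey_timing, qs
    ):
        sub = PopulationState(n=state.n[:, idx], f=state.f[:, idx], m=state.m[:, idx])
        i_pred = predict_index(sub, q, timing)
        mk = ab > 0
        r = np.log(ab[mk]) - np.log(np.maximum(i_pred[mk], 1e-300))
        total += float(r @ r)
    total += pmap.ricker_penalty(theta, state, data)
    return total if np.isfinite(total) else np.inf


def negative_log_likelihood(theta: np.ndarray, data: FitData, config: SCAAConfig, pmap: _ParamMap | None = None) -> float:
    """Profiled lognormal NLL of catch and indices plus Ricker penalty."""
    if pmap is None:
        pmap = _ParamMap(data, config)
    try:
        state, qs = pmap.state_and_q(theta, data)
    except (FloatingPointError, OverflowError, ValueError):
        return np.inf
    if not np.all(np.isfinite(state.n)):
        return np.inf
    nll = 0.0
    c_pred = baranov_catch(state)
    term, _ = _lognormal_deviance(data.catch_n, c_pred)
    nll += term
    for ab, idx, timing, q in zip(
        data.survey_abundance, data.survey_year_idx, data.survey_timing, qs
    ):
        sub = PopulationState(n=state.n[:, idx], f=state.f[:, idx], m=state.m[:, idx])
        i_pred = predict_index(sub, q, timing)
        term, _ = _lognormal_deviance(ab, i_pred)
        nll += term
    nll += pmap.ricker_penalty(theta, state, data)
    return float(nll) if np.isfinite(nll) else np.inf


# ---------------------------------------------------------------------------
# fitting


@dataclass
class SCAAFit:
    """A fitted assessment: estimates, covariance, scores and state."""

    config: SCAAConfig
    data: FitData
    theta_hat: np.ndarray
    covariance: np.ndarray | None
    loglik: float
    gcv: float
    converged: bool
    state: PopulationState
    q_hat: list[np.ndarray]
    pmap: _ParamMap = field(repr=False, default=None)

    def state_for(self, theta: np.ndarray) -> PopulationState:
        """Population state implied by an arbitrary parameter vector."""
        state, _ = self.pmap.state_and_q(theta, self.data)
        return state


def _initial_theta(data: FitData, config: SCAAConfig, pmap: _ParamMap) -> np.ndarray:
    """Deterministic data-driven start values.

    Total mortality is roughed out from the catch-curve slope of the
    time-aggregated catch; numbers back-calculated from the Baranov
    equation seed recruitment, initial abundance and survey catchability.
    """
    catch = np.maximum(data.catch_n, 1e-8)
    by_age = catch.sum(axis=1)
    top = int(np.argmax(by_age))
    if by_age.size - top >= 3:
        slope = np.polyfit(np.arange(top, by_age.size), np.log(by_age[top:]), 1)[0]
        z_hat = max(-slope, 0.15)
    else:
        z_hat = 0.6
    f0 = max(z_hat - float(np.mean(data.m)), 0.05)

    f_grid = np.full_like(data.m, f0)
    theta_f = pmap.f_pred.init_params(np.log(f_grid))

    z0 = f0 + data.m
    n_guess = catch * z0 / (f0 * (1.0 - np.exp(-z0)))
    log_n = np.log(np.maximum(n_guess, 1e-8))
    if pmap.ricker:
        log_r = log_n[0, :]
        ssb0 = np.maximum((n_guess * data.weight * data.maturity).sum(axis=0), 1e-12)
        # log(R/S) = log_alpha - beta * S, linear in S
        coef = np.polyfit(ssb0, log_r - np.log(ssb0), 1)
        beta0 = max(-coef[0], 1e-12)
        theta_r = np.r_[coef[1], np.log(beta0), log_r]
    else:
        theta_r = pmap.r_pred.init_params(log_n[0, :])
    theta_init = log_n[1:, 0]

    theta_qs = []
    for ab, idx, timing, qp in zip(
        data.survey_abundance, data.survey_year_idx, data.survey_timing, pmap.q_preds
    ):
        n_sub = n_guess[:, idx]
        z_sub = z0[:, idx]
        with np.errstate(divide="ignore"):
            log_q = np.log(np.maximum(ab, 1e-12)) - np.log(n_sub) + timing * z_sub
        log_q = np.where(ab > 0, log_q, np.nan)
        fill = np.nanmean(log_q) if np.any(ab > 0) else 0.0
        log_q = np.where(np.isnan(log_q), fill, log_q)
        theta_qs.append(qp.init_params(log_q))

    return np.concatenate([theta_f, *theta_qs, theta_r, theta_init])


def _numerical_hessian(fun, theta: np.ndarray, step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian of a scalar function."""
    p = theta.size
    h = step * np.maximum(1.0, np.abs(theta))
    hess = np.zeros((p, p))
    f0 = fun(theta)
    for i in range(p):
        ei = np.zeros(p)
        ei[i] = h[i]
        fpp = fun(theta + ei)
        fmm = fun(theta - ei)
        hess[i, i] = (fpp - 2 * f0 + fmm) / h[i] ** 2
        for j in range(i + 1, p):
            ej = np.zeros(p)
            ej[j] = h[j]
            fij = fun(theta + ei + ej)
            fi = fun(theta + ei - ej)
            fj = fun(theta - ei + ej)
            fmj = fun(theta - ei - ej)
            hess[i, j] = hess[j, i] = (fij - fi - fj + fmj) / (4 * h[i] * h[j])
    return hess


def compute_gcv(rss: float, n: int, p: int) -> float:
    """Generalised cross-validation score n*RSS/(n - p)^2."""
    if p >= n:
        raise ValueError("effective parameters must be fewer than catch cells")
    return n * rss / (n - p) ** 2


def _catch_rss(fit_state: PopulationState, data: FitData) -> tuple[float, int]:
    c_pred = baranov_catch(fit_state)
    mask = data.catch_n > 0
    resid = np.log(data.catch_n[mask]) - np.log(np.maximum(c_pred[mask], 1e-300))
    return float(resid @ resid), int(mask.sum())


def fit_scaa(
    data: FitData,
    config: SCAAConfig,
    compute_covariance: bool = True,
    maxiter: int = 500,
) -> SCAAFit:
    """Maximum-likelihood fit of one assessment configuration.

    Optimisation starts from a deterministic data-driven initial vector, so
    refitting the same data is bit-reproducible.  A fit is ``converged``
    when the optimizer reports success and (when requested) the observed
    information is finite and positive definite; failures are recorded on
    the returned object, never raised.
    """
    pmap = _ParamMap(data, config)
    theta0 = _initial_theta(data, config, pmap)
    # stage 1: unweighted pooled least squares (well conditioned everywhere)
    warm = optimize.minimize(
        lambda th: _pooled_rss(th, data, config, pmap), theta0,
        method="L-BFGS-B", options={"maxiter": maxiter, "maxfun": 200000},
    )
    # stage 2: profiled-variance likelihood from the warm start
    obj = lambda th: negative_log_likelihood(th, data, config, pmap)
    res = optimize.minimize(obj, warm.x, method="L-BFGS-B", options={"maxiter": maxiter, "maxfun": 200000})
    theta = res.x
    state, qs = pmap.state_and_q(theta, data)

    converged = bool(res.success) and np.all(np.isfinite(theta))
    cov = None
    if converged and compute_covariance:
        hess = _numerical_hessian(obj, theta)
        try:
            eig = np.linalg.eigvalsh((hess + hess.T) / 2)
            if np.all(np.isfinite(hess)) and eig.min() > 0:
                cov = np.linalg.inv((hess + hess.T) / 2)
                cov = (cov + cov.T) / 2
            else:
                converged = False
        except np.linalg.LinAlgError:
            converged = False

    rss, n_cells = _catch_rss(state, data)
    p_eff = pmap.n_catch_predictor_params
    gcv = compute_gcv(rss, n_cells, p_eff) if p_eff < n_cells else np.inf
    if not converged:
        logger.info("fit did not converge (config %s): %s", config.config_id, res.message)
    return SCAAFit(
        config=config,
        data=data,
        theta_hat=theta,
        covariance=cov,
        loglik=-float(res.fun),
        gcv=gcv,
        converged=converged,
        state=state,
        q_hat=qs,
        pmap=pmap,
    )


def sample_estimation_uncertainty(fit: SCAAFit, n: int, seed: int) -> np.ndarray:
    """Multivariate-normal parameter draws around the fitted estimates.

    Returns an (n, p) array; each row maps to a population state via
    ``fit.state_for``.
    """
    if not fit.converged or fit.covariance is None:
        raise ValueError("estimation uncertainty requires a converged fit with covariance")
    rng = np.random.default_rng(seed)
    cov = fit.covariance
    if not np.any(cov):
        return np.tile(fit.theta_hat, (n, 1))
    # eigendecomposition tolerates the semi-definite boundary
    vals, vecs = np.linalg.eigh(cov)
    root = vecs * np.sqrt(np.maximum(vals, 0.0))
    z = rng.standard_normal((n, fit.theta_hat.size))
    return fit.theta_hat[None, :] + z @ root.T


def summarize_fit(
    state: PopulationState,
    weight: np.ndarray,
    maturity: np.ndarray,
    fbar_range: tuple[int, int] = DEFAULT_FBAR_RANGE,
) -> dict[str, np.ndarray]:
    """Per-year summary series of a population state.

    recruitment = first-age numbers; SSB = sum_a N*w*mat; Fbar = mean F over
    the reference ages; catch biomass = sum_a C*w; harvest rate = catch
    biomass / total stock biomass.
    """
    lo, hi = fbar_range
    n_ages = state.n.shape[0]
    lo = max(0, min(lo, n_ages - 1))
    hi = max(lo, min(hi, n_ages - 1))
    catch = baranov_catch(state)
    ssb = np.sum(state.n * weight * maturity, axis=0)
    total_biomass = np.sum(state.n * weight, axis=0)
    catch_biomass = np.sum(catch * weight, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        harvest_rate = np.where(total_biomass > 0, catch_biomass / total_biomass, 0.0)
    return {
        "recruitment": state.n[0, :].copy(),
        "ssb": ssb,
        "fbar": state.f[lo : hi + 1, :].mean(axis=0),
        "catch": catch_biomass,
        "harvest_rate": harvest_rate,
    }


def default_submodel_grid(
    fbar_range: tuple[int, int] = DEFAULT_FBAR_RANGE,
) -> list[SCAAConfig]:
    """The 18-configuration grid: {3 fmodels} x {3 qmodels} x {2 rmodels}.

    Ordered rmodel-major, then qmodel, then fmodel, numbered 1..18.
    """
    fmodels = [SubmodelSpec("fmodel", f) for f in FMODEL_FORMS]
    qmodels = [SubmodelSpec("qmodel", q) for q in QMODEL_FORMS]
    rmodels = [SubmodelSpec("rmodel", r) for r in RMODEL_FORMS]
    grid = []
    i = 1
    for r in rmodels:
        for q in qmodels:
            for f in fmodels:
                grid.append(SCAAConfig(fmodel=f, qmodel=q, rmodel=r, fbar_range=fbar_range, config_id=i))
                i += 1
    return grid
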