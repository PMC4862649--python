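"""Process uncertainty in von Bertalanffy growth parameters.

Correlated parameter sets (L-infinity, k, t0) are drawn from a Student-t
copula with triangle marginal distributions.  The triangle marginals make
very few assumptions beyond hard bounds, which guarantees every sampled
parameter set stays inside well-specified limits; the copula couples the
marginals so that the well-known life-history relationships between the
parameters (large-Linf stocks grow slowly, etc.) are respected.

The copula is parameterised by a correlation matrix: because copula
sampling is invariant to the scale of a covariance matrix, any covariance
supplied by the user is reduced to its correlation structure before use.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "TriangleMarginal",
    "CopulaSpec",
    "GrowthParams",
    "GrowthEnsemble",
    "triangle_bounds_from_cv",
    "triangle_quantile",
    "sample_growth_params",
    "vb_length_at_age",
    "vb_age_at_length",
    "default_marginals",
    "default_copula",
]

# Defaults replicate a hake-like stock: Linf 130 cm, k 0.164 / yr with 10% CV
# bounds at +-1.96 sd, and t0 a symmetric triangle on [-0.184, 0].
DEFAULT_LINF_MEDIAN = 130.0
DEFAULT_K_MEDIAN = 0.164
DEFAULT_CV = 0.10
DEFAULT_Z = 1.96
DEFAULT_T0_MIN = -0.184
DEFAULT_T0_MAX = 0.0

#: Default copula correlation: Linf-k strongly negative, k-t0 moderately
#: positive, Linf-t0 weakly negative (demersal life-history pattern).
DEFAULT_CORRELATION = np.array(
    [
        [1.0, -0.7, -0.2],
        [-0.7, 1.0, 0.5],
        [-0.2, 0.5, 1.0],
    ]
)
DEFAULT_TAIL_DF = 4.0


@dataclass(frozen=True)
class TriangleMarginal:
    """Triangle distribution on [lower, upper] with a single mode.

    The central parameter is treated as the *mode* of the triangle.  For
    symmetric triangles (all defaults here) the mode and the median
    coincide; for asymmetric user input they differ and the mode
    interpretation is used.
    """

    lower: float
    mode: float
    upper: float

    def __post_init__(self) -> None:
        if not (self.lower <= self.mode <= self.upper):
            raise ValueError(
                f"triangle requires lower <= mode <= upper, got "
                f"({self.lower}, {self.mode}, {self.upper})"
            )

    @property
    def _frozen(self) -> bool:
        """True when the triangle has collapsed to a point mass."""
        return self.upper == self.lower

    def _dist(self) -> stats.rv_continuous:
        scale = self.upper - self.lower
        c = (self.mode - self.lower) / scale
        return stats.triang(c, loc=self.lower, scale=scale)

    def ppf(self, u: np.ndarray | float) -> np.ndarray | float:
        return triangle_quantile(u, self)

    def cdf(self, x: np.ndarray | float) -> np.ndarray | float:
        if self._frozen:
            return np.where(np.asarray(x) < self.lower, 0.0, 1.0)
        return self._dist().cdf(x)


@dataclass(frozen=True)
class CopulaSpec:
    """Student-t copula: a correlation matrix plus tail degrees of freedom."""

    correlation: np.ndarray = field(default_factory=lambda: DEFAULT_CORRELATION.copy())
    tail_df: float = DEFAULT_TAIL_DF

    def __post_init__(self) -> None:
        corr = np.asarray(self.correlation, dtype=float)
        object.__setattr__(self, "correlation", corr)
        if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
            raise ValueError("correlation must be a square matrix")
        if not np.allclose(corr, corr.T):
            raise ValueError("correlation must be symmetric")
        if not np.allclose(np.diag(corr), 1.0):
            raise ValueError("correlation must have unit diagonal")
        if np.any(np.linalg.eigvalsh(corr) <= 0):
            raise ValueError("correlation must be positive definite")
        if not self.tail_df > 0:
            raise ValueError("tail_df must be positive")

    @classmethod
    def from_covariance(cls, cov: np.ndarray, tail_df: float = DEFAULT_TAIL_DF) -> "CopulaSpec":
        """Build a spec from any (unscaled) covariance matrix.

        Only the correlation structure of ``cov`` matters for copula
        sampling; multiplying ``cov`` by a positive scalar yields an
        identical spec.
        """
        cov = np.asarray(cov, dtype=float)
        sd = np.sqrt(np.diag(cov))
        if np.any(sd <= 0):
            raise ValueError("covariance diagonal must be positive")
        corr = cov / np.outer(sd, sd)
        # force exact symmetry / unit diagonal against round-off
        corr = (corr + corr.T) / 2.0
        np.fill_diagonal(corr, 1.0)
        return cls(correlation=corr, tail_df=tail_df)


@dataclass(frozen=True)
class GrowthParams:
    """One von Bertalanffy parameter set: L(a) = linf * (1 - exp(-k (a - t0)))."""

    linf: float  # asymptotic length, cm
    k: float  # growth rate, 1/year
    t0: float  # theoretical age at zero length, year

    def __post_init__(self) -> None:
        if not self.linf > 0:
            raise ValueError("linf must be positive")
        if not self.k > 0:
            raise ValueError("k must be positive")
        if self.t0 > 0:
            raise ValueError("t0 must be <= 0")


@dataclass(frozen=True)
class GrowthEnsemble:
    """Ordered collection of growth-parameter draws with its seed."""

    draws: tuple[GrowthParams, ...]
    seed: int

    def __len__(self) -> int:
        return len(self.draws)

    def __iter__(self):
        return iter(self.draws)

    def __getitem__(self, i: int) -> GrowthParams:
        return self.draws[i]

    def as_array(self) -> np.ndarray:
        """(n, 3) array of (linf, k, t0)."""
        return np.array([[p.linf, p.k, p.t0] for p in self.draws])


def triangle_bounds_from_cv(mode: float, cv: float, z: float = DEFAULT_Z) -> tuple[float, float]:
    """Symmetric triangle bounds at ``z`` standard deviations from the mode.

    With a coefficient of variation ``cv``, the bounds are
    ``mode * (1 -/+ z * cv)``; z = 1.96 covers roughly 95% of the variation
    of the matching normal.
    """
    if not np.isfinite(mode):
        raise ValueError("mode must be finite")
    if cv < 0:
        raise ValueError("cv must be non-negative")
    if not z > 0:
        raise ValueError("z must be positive")
    half = z * cv * mode
    return mode - half, mode + half


def triangle_quantile(u, marginal: TriangleMarginal):
    """Inverse CDF of a triangle distribution (vectorised in ``u``)."""
    u_arr = np.asarray(u, dtype=float)
    if np.any((u_arr < 0) | (u_arr > 1)):
        raise ValueError("u must lie in [0, 1]")
    if marginal._frozen:
        out = np.full_like(u_arr, marginal.lower)
        return float(out) if np.isscalar(u) else out
    out = marginal._dist().ppf(u_arr)
    return float(out) if np.isscalar(u) else out


def sample_growth_params(
    marginals: tuple[TriangleMarginal, TriangleMarginal, TriangleMarginal] | None = None,
    copula: CopulaSpec | None = None,
    n: int = 1000,
    seed: int = 0,
) -> GrowthEnsemble:
    """Draw ``n`` correlated (linf, k, t0) sets from the t-copula.

    Sampling follows the standard construction: draw multivariate normal
    with the copula correlation, divide by sqrt(chi2_df / df) to obtain a
    multivariate t, push each coordinate through the t CDF to get uniform
    margins with t-copula dependence, then invert each triangle CDF.
    """
    if marginals is None:
        marginals = default_marginals()
    if copula is None:
        copula = default_copula()
    if len(marginals) != 3:
        raise ValueError("exactly three marginals required (linf, k, t0)")
    if n < 1:
        raise ValueError("n must be >= 1")

    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(copula.correlation)
    z = rng.standard_normal((n, 3)) @ chol.T
    w = rng.chisquare(copula.tail_df, size=(n, 1)) / copula.tail_df
    t_samples = z / np.sqrt(w)
    u = stats.t.cdf(t_samples, df=copula.tail_df)

    cols = [triangle_quantile(u[:, j], m) for j, m in enumerate(marginals)]
    # clip against floating-point excursions at the exact bounds
    cols = [np.clip(c, m.lower, m.upper) for c, m in zip(cols, marginals)]
    # t0 must remain <= 0 for GrowthParams validity
    draws = tuple(
        GrowthParams(linf=float(a), k=float(b), t0=float(min(c, 0.0)))
        for a, b, c in zip(*cols)
    )
    return GrowthEnsemble(draws=draws, seed=seed)


def vb_length_at_age(age, p: GrowthParams):
    """von Bertalanffy mean length at age: linf * (1 - exp(-k (age - t0)))."""
    age_arr = np.asarray(age, dtype=float)
    if np.any(age_arr < p.t0):
        raise ValueError(f"age must be >= t0 ({p.t0})")
    out = p.linf * (1.0 - np.exp(-p.k * (age_arr - p.t0)))
    return float(out) if np.isscalar(age) else out


def vb_age_at_length(length, p: GrowthParams):
    """Inverse growth curve: age at which mean length equals ``length``."""
    length_arr = np.asarray(length, dtype=float)
    if np.any(length_arr < 0):
        raise ValueError("length must be non-negative")
    if np.any(length_arr >= p.linf):
        raise ValueError(f"length must be below linf ({p.linf})")
    out = p.t0 - np.log(1.0 - length_arr / p.linf) / p.k
    return float(out) if np.isscalar(length) else out


def default_marginals(
    linf_median: float = DEFAULT_LINF_MEDIAN,
    linf_cv: float = DEFAULT_CV,
    k_median: float = DEFAULT_K_MEDIAN,
    k_cv: float = DEFAULT_CV,
    t0_min: float = DEFAULT_T0_MIN,
    t0_max: float = DEFAULT_T0_MAX,
    z: float = DEFAULT_Z,
) -> tuple[TriangleMarginal, TriangleMarginal, TriangleMarginal]:
    """Default (linf, k, t0) triangle marginals.

    linf and k bounds sit z standard deviations from the median using the
    given CVs; t0 is a symmetric triangle on [t0_min, t0_max] with its mode
    at the midpoint.
    """
    lo, hi = triangle_bounds_from_cv(linf_median, linf_cv, z)
    linf = TriangleMarginal(lo, linf_median, hi)
    lo, hi = triangle_bounds_from_cv(k_median, k_cv, z)
    k = TriangleMarginal(lo, k_median, hi)
    t0 = TriangleMarginal(t0_min, (t0_min + t0_max) / 2.0, t0_max)
    return linf, k, t0


def default_copula() -> CopulaSpec:
    return CopulaSpec()
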