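"""Filtering and model averaging across fitted model variants.

Unstable model variants are detected by Hartigan's dip test for
multimodality applied to the final-year harvest rates across iterations: a
clearly bimodal distribution of harvest rates signals that the fits of a
variant flip between conflicting solutions, so the variant is rejected.
Surviving variants are weighted by the inverse of their median
generalised-cross-validation score, and a fixed number of iterations is
drawn across variants (variant by weight, then an unused iteration
uniformly within the variant) to build a single model-averaged result set.

The dip statistic is the maximum distance between the empirical CDF and
the closest unimodal CDF, computed by the iterative greatest-convex-
minorant / least-concave-majorant construction of Hartigan & Hartigan;
p-values come from a bootstrap null of uniform samples, the calibration
Hartigan proposed (the uniform is the asymptotically least favourable
unimodal distribution).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ModelVariant",
    "BimodalityResult",
    "EnsembleResult",
    "dip_statistic",
    "dip_test",
    "filter_variants",
    "gcv_weights",
    "model_average",
    "summarize_ensemble",
]

DEFAULT_ALPHA = 0.05
DEFAULT_N_BOOT = 2000
DEFAULT_MIN_ITERATIONS = 10
DEFAULT_QUANTILES = (0.10, 0.50, 0.90)


# ---------------------------------------------------------------------------
# Hartigan's dip


def _gcm_pointers(x: np.ndarray) -> np.ndarray:
    """Predecessor pointers tracing the greatest convex minorant of the
    points (x_i, i).  mn[j] is the previous touch point of the minorant."""
    n = x.size
    mn = np.zeros(n, dtype=np.int64)
    for j in range(1, n):
        mn[j] = j - 1
        while True:
            a = mn[j]
            b = mn[a]
            if a == 0 or (x[j] - x[a]) * (a - b) < (x[a] - x[b]) * (j - a):
                break
            mn[j] = b
    return mn


def _lcm_pointers(x: np.ndarray) -> np.ndarray:
    """Successor pointers tracing the least concave majorant."""
    n = x.size
    mj = np.zeros(n, dtype=np.int64)
    mj[n - 1] = n - 1
    for k in range(n - 2, -1, -1):
        mj[k] = k + 1
        while True:
            a = mj[k]
            b = mj[a]
            if a == n - 1 or (x[k] - x[a]) * (a - b) < (x[a] - x[b]) * (k - a):
                break
            mj[k] = b
    return mj


def dip_statistic(sample: np.ndarray) -> float:
    """Hartigan & Hartigan's dip statistic of a univariate sample.

    The sup-distance between the empirical CDF and the nearest unimodal
    CDF.  Within the working modal interval the greatest convex minorant
    and least concave majorant of the empirical CDF are traced; the modal
    interval shrinks to where the two hulls separate most, and the dip is
    half the largest deviation of the empirical CDF from the hull on
    either flank.  The statistic is bounded below by 1/(2n).
    """
    x = np.sort(np.asarray(sample, dtype=float))
    n = x.size
    if n < 2:
        raise ValueError("dip statistic requires at least 2 observations")
    if x[0] == x[-1] or n <= 3:
        return 1.0 / (2.0 * n)

    low, high = 0, n - 1
    dip = 1.0  # in count units; final statistic is dip / (2n)

    while True:
        if high - low < 1:
            break
        mn = _gcm_pointers(x[low : high + 1])
        mj = _lcm_pointers(x[low : high + 1])
        xs = x[low : high + 1]
        m = xs.size

        # touch points of the minorant, from the top down to 0
        gcm = [m - 1]
        while gcm[-1] > 0:
            gcm.append(int(mn[gcm[-1]]))
        l_gcm = len(gcm)
        # touch points of the majorant, from 0 up to the top
        lcm = [0]
        while lcm[-1] < m - 1:
            lcm.append(int(mj[lcm[-1]]))
        l_lcm = len(lcm)

        # largest separation (count units) between the two hulls
        d = 0.0
        ig, ih = l_gcm - 1, 0
        if l_gcm != 2 or l_lcm != 2:
            ix, iv = l_gcm - 2, 1
            while True:
                gx = gcm[ix]
                lv = lcm[iv]
                if gx > lv:
                    # next point along is an LCM touch: distance from the
                    # interpolated minorant up to the majorant there
                    gx1 = gcm[ix + 1]
                    dx = (lv - gx1 + 1) - (xs[lv] - xs[gx1]) * (gx - gx1) / (xs[gx] - xs[gx1])
                    iv += 1
                    if dx >= d:
                        d = dx
                        ig = ix + 1
                        ih = iv - 1
                else:
                    # next point along is a GCM touch
                    lv1 = lcm[iv - 1]
                    dx = (xs[gx] - xs[lv1]) * (lv - lv1) / (xs[lv] - xs[lv1]) - (gx - lv1 - 1)
                    ix -= 1
                    if dx >= d:
                        d = dx
                        ig = ix + 1
                        ih = iv
                ix = max(ix, 0)
                iv = min(iv, l_lcm - 1)
                if gcm[ix] == lcm[iv]:
                    break
        else:
            d = 1.0

        if d < dip:
            break

        # deviation of the ecdf above the minorant, on the lower flank
        dip_l = 0.0
        for j in range(ig, l_gcm - 1):
            je, jb = gcm[j], gcm[j + 1]
            max_t = 1.0
            if je - jb > 1 and xs[je] != xs[jb]:
                jj = np.arange(jb, je + 1)
                c = (je - jb) / (xs[je] - xs[jb])
                max_t = max(max_t, np.max((jj - jb + 1) - (xs[jj] - xs[jb]) * c))
            dip_l = max(dip_l, max_t)

        # deviation of the ecdf below the majorant, on the upper flank
        dip_u = 0.0
        for j in range(ih, l_lcm - 1):
            jb, je = lcm[j], lcm[j + 1]
            max_t = 1.0
            if je - jb > 1 and xs[je] != xs[jb]:
                jj = np.arange(jb, je + 1)
                c = (je - jb) / (xs[je] - xs[jb])
                max_t = max(max_t, np.max((xs[jj] - xs[jb]) * c - (jj - jb - 1)))
            dip_u = max(dip_u, max_t)

        dip = max(dip, dip_l, dip_u)
        new_low = low + gcm[ig]
        new_high = low + lcm[ih]
        if new_low == low and new_high == high:
            break
        low, high = new_low, new_high

    return dip / (2.0 * n)


@dataclass(frozen=True)
class BimodalityResult:
    """Outcome of a dip test."""

    dip: float
    p_value: float
    rejected: bool


def dip_test(
    sample: np.ndarray,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
    alpha: float = DEFAULT_ALPHA,
) -> BimodalityResult:
    """Bootstrap dip test of unimodality.

    The p-value is the proportion of ``n_boot`` uniform(0,1) samples of the
    same size whose dip statistic is at least the observed one.
    """
    sample = np.asarray(sample, dtype=float)
    n = sample.size
    if n < 10:
        raise ValueError("dip test requires at least 10 observations")
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    observed = dip_statistic(sample)
    rng = np.random.default_rng(seed)
    boot = rng.random((n_boot, n))
    boot_dips = np.fromiter((dip_statistic(row) for row in boot), dtype=float, count=n_boot)
    p_value = float(np.mean(boot_dips >= observed))
    return BimodalityResult(dip=observed, p_value=p_value, rejected=p_value < alpha)


# ---------------------------------------------------------------------------
# model variants and averaging


@dataclass
class ModelVariant:
    """One (assessment configuration x mortality model) cell of the grid.

    Holds the per-iteration summary series of the successfully fitted
    iterations (dicts keyed by quantity with per-year arrays, including
    ``harvest_rate``) and their GCV scores.
    """

    sa_config_id: int
    mortality_model: str
    iterations: list[dict[str, np.ndarray]]
    gcvs: np.ndarray
    years: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.gcvs = np.asarray(self.gcvs, dtype=float)
        if self.gcvs.size != len(self.iterations):
            raise ValueError("one gcv per stored iteration required")

    @property
    def n_success(self) -> int:
        return len(self.iterations)

    @property
    def label(self) -> str:
        return f"sa{self.sa_config_id:02d}-{self.mortality_model}"

    def final_year_harvest_rates(self) -> np.ndarray:
        return np.array([it["harvest_rate"][-1] for it in self.iterations])

    def median_gcv(self) -> float:
        return float(np.median(self.gcvs))


@dataclass
class EnsembleResult:
    """Model-averaged iteration set with provenance and variant weights."""

    iterations: list[dict[str, np.ndarray]]
    provenance: list[tuple[str, int]]  # (variant label, original iteration index)
    weights: dict[str, float]
    years: np.ndarray = None

    def __post_init__(self) -> None:
        if len(self.provenance) != len(self.iterations):
            raise ValueError("provenance must pair each selected iteration")


def filter_variants(
    variants: list[ModelVariant],
    alpha: float = DEFAULT_ALPHA,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
    min_iterations: int = DEFAULT_MIN_ITERATIONS,
) -> tuple[list[ModelVariant], pd.DataFrame]:
    """Reject variants whose final-year harvest rates are multimodal.

    Returns the retained variants plus a per-variant report mirroring the
    grid layout: dip, p-value and decision for every variant.
    """
    retained = []
    rows = []
    floor = max(min_iterations, 10)  # dip test needs at least 10 observations
    for i, v in enumerate(variants):
        if v.n_success < floor:
            rows.append(
                dict(variant=v.label, sa_model=v.sa_config_id, mortality_model=v.mortality_model,
                     n_success=v.n_success, dip=np.nan, p_value=np.nan,
                     rejected=True, reason="insufficient iterations")
            )
            continue
        res = dip_test(v.final_year_harvest_rates(), n_boot=n_boot, seed=seed + i, alpha=alpha)
        rejected = res.rejected
        rows.append(
            dict(variant=v.label, sa_model=v.sa_config_id, mortality_model=v.mortality_model,
                 n_success=v.n_success, dip=res.dip, p_value=res.p_value,
                 rejected=rejected, reason="bimodal harvest rates" if rejected else "")
        )
        if not rejected:
            retained.append(v)
    return retained, pd.DataFrame(rows)


def gcv_weights(variants: list[ModelVariant]) -> np.ndarray:
    """Inverse-median-GCV weights, normalised to sum to one."""
    medians = np.array([v.median_gcv() for v in variants])
    if np.any(~np.isfinite(medians)) or np.any(medians <= 0):
        raise ValueError("all variant median GCVs must be positive and finite")
    inv = 1.0 / medians
    return inv / inv.sum()


def model_average(
    variants: list[ModelVariant],
    weights: np.ndarray,
    n_select: int,
    seed: int = 0,
) -> EnsembleResult:
    """Draw ``n_select`` iterations across variants by weight.

    Each draw first picks a variant with probability proportional to its
    weight, then an as-yet-unused iteration uniformly within that variant
    (without replacement within a variant), so no original iteration enters
    the ensemble twice.
    """
    if not variants:
        raise ValueError("no variants to average")
    weights = np.asarray(weights, dtype=float)
    if weights.size != len(variants):
        raise ValueError("one weight per variant required")
    min_success = min(v.n_success for v in variants)
    if n_select > min_success:
        raise ValueError(
            f"n_select={n_select} exceeds the minimum variant size {min_success}"
        )
    rng = np.random.default_rng(seed)
    chosen_variants = rng.choice(len(variants), size=n_select, p=weights / weights.sum())
    pools = [rng.permutation(v.n_success) for v in variants]
    used = [0] * len(variants)
    iterations, provenance = [], []
    for vi in chosen_variants:
        original = int(pools[vi][used[vi]])
        used[vi] += 1
        iterations.append(variants[vi].iterations[original])
        provenance.append((variants[vi].label, original))
    years = variants[0].years
    weight_map = {v.label: float(w) for v, w in zip(variants, weights)}
    return EnsembleResult(iterations=iterations, provenance=provenance, weights=weight_map, years=years)


def summarize_ensemble(
    result: EnsembleResult,
    quantiles: tuple[float, ...] = DEFAULT_QUANTILES,
    quantities: tuple[str, ...] = ("recruitment", "ssb", "fbar", "catch"),
) -> pd.DataFrame:
    """Per-year empirical quantiles of the selected iterations.

    Returns a tidy frame with columns (quantity, year, quantile, value).
    """
    if not result.iterations:
        raise ValueError("empty ensemble")
    years = result.years
    rows = []
    for qty in quantities:
        stack = np.vstack([it[qty] for it in result.iterations])
        qs = np.quantile(stack, quantiles, axis=0)
        for qi, q in enumerate(quantiles):
            for yi in range(stack.shape[1]):
                year = years[yi] if years is not None else yi
                rows.append(dict(quantity=qty, year=year, quantile=q, value=qs[qi, yi]))
    return pd.DataFrame(rows)
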