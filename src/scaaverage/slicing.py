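"""Deterministic length-to-age slicing.

Length-based catch and survey observations are allocated to ages through
the inverse von Bertalanffy curve: a length class belongs to the age whose
growth-curve interval contains its representative length.  Although the
slicing itself is deterministic, it is applied once per draw of the growth
ensemble, so the biological process uncertainty propagates into the
age-based data.  Each iteration receives its own plusgroup, set at the age
that accumulates a target share (default 95%) of the time-averaged catch
biomass.

Aggregation conventions: abundances are summed into ages, mean weights are
abundance-weighted means, natural mortality and maturity are unweighted
means over the contributing length classes.  Within the plusgroup all
quantities are abundance-weighted, which preserves total biomass exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .growth import GrowthEnsemble, GrowthParams, vb_age_at_length
from .mortality import MortalityCurve

__all__ = [
    "LengthFrequency",
    "WeightLengthParams",
    "StockIteration",
    "AgeStructuredStock",
    "AgeIndex",
    "assign_ages",
    "slice_stock",
    "compute_plusgroup",
    "slice_index",
]

logger = logging.getLogger(__name__)

DEFAULT_PLUSGROUP_THRESHOLD = 0.95


@dataclass(frozen=True)
class LengthFrequency:
    """Abundance by year and length class (contiguous, uniform width)."""

    years: np.ndarray  # ordered years
    length_lower: np.ndarray  # lower bound of each class, cm
    width: float  # class width, cm
    abundance: np.ndarray  # (year, length) counts
    unit: str = "thousands"

    def __post_init__(self) -> None:
        years = np.asarray(self.years)
        lower = np.asarray(self.length_lower, dtype=float)
        abundance = np.asarray(self.abundance, dtype=float)
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "length_lower", lower)
        object.__setattr__(self, "abundance", abundance)
        if abundance.shape != (years.size, lower.size):
            raise ValueError("abundance must be (n_years, n_lengths)")
        if np.any(abundance < 0):
            raise ValueError("abundance must be non-negative")
        if lower.size > 1:
            steps = np.diff(lower)
            if not np.allclose(steps, self.width):
                raise ValueError("length classes must be contiguous with uniform width")

    @property
    def midpoints(self) -> np.ndarray:
        return self.length_lower + self.width / 2.0


@dataclass(frozen=True)
class WeightLengthParams:
    """Allometric weight-length relation W = a * L^b."""

    a: float = 6.59e-5
    b: float = 3.01721

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0):
            raise ValueError("weight-length parameters must be positive")

    def weight(self, length) -> np.ndarray:
        return self.a * np.asarray(length, dtype=float) ** self.b


@dataclass(frozen=True)
class StockIteration:
    """One iteration of age-based stock data (ages 0..plusgroup)."""

    ages: np.ndarray  # 0..plusgroup
    catch_n: np.ndarray  # (age, year)
    weight: np.ndarray  # (age, year) mean weight
    m: np.ndarray  # (age, year) natural mortality
    maturity: np.ndarray  # (age, year) proportion mature
    plusgroup: int


@dataclass(frozen=True)
class AgeStructuredStock:
    """Sliced stock: one StockIteration per growth draw, shared years."""

    years: np.ndarray
    iterations: tuple[StockIteration, ...]
    mortality_model: str = "constant"
    unit: str = "thousands"

    @property
    def n_iterations(self) -> int:
        return len(self.iterations)

    @property
    def plusgroups(self) -> np.ndarray:
        return np.array([it.plusgroup for it in self.iterations])


@dataclass(frozen=True)
class AgeIndex:
    """Sliced survey index: per-iteration abundance-at-age plus timing."""

    years: np.ndarray
    iterations: tuple[np.ndarray, ...]  # (age, year) abundance per iteration
    plusgroups: np.ndarray
    timing: float = 0.0  # survey timing as fraction of the year

    def __post_init__(self) -> None:
        if not (0.0 <= self.timing < 1.0):
            raise ValueError("survey timing must lie in [0, 1)")


def assign_ages(midpoints: np.ndarray, p: GrowthParams) -> np.ndarray:
    """Integer age label for each length-class representative length.

    age = floor(inverse growth curve), clamped below at 0.  Lengths at or
    above linf (where the inverse curve is undefined) are mapped to one age
    above the oldest finite age on the grid; the plusgroup absorbs them.
    """
    midpoints = np.asarray(midpoints, dtype=float)
    finite = midpoints < p.linf
    ages = np.zeros(midpoints.size, dtype=int)
    if np.any(finite):
        real_age = vb_age_at_length(midpoints[finite], p)
        ages[finite] = np.maximum(np.floor(real_age).astype(int), 0)
        oldest = ages[finite].max()
    else:
        oldest = -1
    ages[~finite] = oldest + 1
    return ages


def _aggregate_to_ages(
    values_by_length: np.ndarray,
    weights_by_length: np.ndarray | None,
    age_labels: np.ndarray,
    ages: np.ndarray,
) -> np.ndarray:
    """Group length-class values into ages (weighted or unweighted mean)."""
    out = np.full(ages.size, np.nan)
    for j, a in enumerate(ages):
        sel = age_labels == a
        if not np.any(sel):
            continue
        vals = values_by_length[sel]
        if weights_by_length is None:
            out[j] = vals.mean()
        else:
            w = weights_by_length[sel]
            tot = w.sum()
            out[j] = vals.mean() if tot == 0 else (vals * w).sum() / tot
    return out


def _fill_gaps(arr: np.ndarray) -> np.ndarray:
    """Fill NaN entries (ages no length class mapped to) from the nearest
    younger populated age; leading NaNs from the nearest older one."""
    arr = arr.copy()
    isnan = np.isnan(arr)
    if not isnan.any():
        return arr
    idx = np.arange(arr.size)
    good = idx[~isnan]
    if good.size == 0:
        raise ValueError("no populated ages to fill from")
    pos = np.searchsorted(good, idx[isnan], side="right") - 1
    pos = np.clip(pos, 0, good.size - 1)  # leading gap -> first populated age
    arr[idx[isnan]] = arr[good[pos]]
    return arr


def compute_plusgroup(catch_biomass_by_age: np.ndarray, threshold: float = DEFAULT_PLUSGROUP_THRESHOLD) -> int:
    """Smallest age whose cumulative share of time-averaged catch biomass
    reaches ``threshold`` (ages indexed from 0)."""
    biomass = np.asarray(catch_biomass_by_age, dtype=float)
    if np.any(biomass < 0):
        raise ValueError("biomass must be non-negative")
    total = biomass.sum()
    if total == 0:
        raise ValueError("catch biomass is zero at every age")
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    share = np.cumsum(biomass) / total
    # tolerance against accumulated round-off when threshold == 1
    return int(np.argmax(share >= threshold - 1e-12))


def _apply_plusgroup(
    catch_n: np.ndarray,
    weight: np.ndarray,
    m: np.ndarray,
    maturity: np.ndarray,
    plusgroup: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Collapse ages >= plusgroup into the terminal age, abundance-weighted."""
    if plusgroup >= catch_n.shape[0] - 1:
        return catch_n, weight, m, maturity
    head = slice(0, plusgroup)
    tail = slice(plusgroup, None)
    n_tail = catch_n[tail]  # (tail_ages, year)
    tot = n_tail.sum(axis=0)  # per year

    def wmean(x: np.ndarray) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            out = (x * n_tail).sum(axis=0) / tot
        fallback = x.mean(axis=0)
        return np.where(tot > 0, out, fallback)

    return (
        np.vstack([catch_n[head], tot]),
        np.vstack([weight[head], wmean(weight[tail])]),
        np.vstack([m[head], wmean(m[tail])]),
        np.vstack([maturity[head], wmean(maturity[tail])]),
    )


def _slice_one_iteration(
    lf: LengthFrequency,
    wl: WeightLengthParams,
    m_at_length: np.ndarray,
    maturity_at_length: np.ndarray,
    p: GrowthParams,
    threshold: float,
    representative: str,
) -> StockIteration:
    rep = lf.midpoints if representative == "midpoint" else lf.length_lower
    labels = assign_ages(rep, p)
    ages = np.arange(0, labels.max() + 1)
    n_years = lf.years.size

    w_len = wl.weight(lf.midpoints)
    catch_n = np.zeros((ages.size, n_years))
    weight = np.zeros((ages.size, n_years))
    for y in range(n_years):
        ab = lf.abundance[y]
        catch_n[:, y] = np.bincount(labels, weights=ab, minlength=ages.size)
        weight[:, y] = _aggregate_to_ages(w_len, ab, labels, ages)
    weight = np.apply_along_axis(_fill_gaps, 0, weight)
    zero_cells = int((catch_n == 0).sum())
    if zero_cells:
        logger.debug(
            "slicing: %d age-year cells with zero abundance; their mean "
            "weight is the unweighted mean of contributing classes", zero_cells
        )

    m_age = _fill_gaps(_aggregate_to_ages(m_at_length, None, labels, ages))
    mat_age = _fill_gaps(_aggregate_to_ages(maturity_at_length, None, labels, ages))
    m = np.repeat(m_age[:, None], n_years, axis=1)
    maturity = np.repeat(mat_age[:, None], n_years, axis=1)

    biomass_by_age = (catch_n * weight).mean(axis=1)
    plusgroup = compute_plusgroup(biomass_by_age, threshold)
    catch_n, weight, m, maturity = _apply_plusgroup(catch_n, weight, m, maturity, plusgroup)
    return StockIteration(
        ages=np.arange(0, plusgroup + 1),
        catch_n=catch_n,
        weight=weight,
        m=m,
        maturity=maturity,
        plusgroup=plusgroup,
    )


def slice_stock(
    lf: LengthFrequency,
    wl: WeightLengthParams,
    m_curve: MortalityCurve,
    maturity_at_length: np.ndarray,
    growth: GrowthEnsemble,
    plusgroup_threshold: float = DEFAULT_PLUSGROUP_THRESHOLD,
    representative: str = "midpoint",
) -> AgeStructuredStock:
    """Slice length-based stock data to age-based, once per growth draw."""
    maturity_at_length = np.asarray(maturity_at_length, dtype=float)
    if maturity_at_length.size != lf.length_lower.size:
        raise ValueError("maturity ogive must match the length grid")
    if m_curve.lengths.size != lf.length_lower.size:
        raise ValueError("mortality curve must match the length grid")
    if representative not in ("midpoint", "lower"):
        raise ValueError("representative must be 'midpoint' or 'lower'")

    iterations = tuple(
        _slice_one_iteration(
            lf, wl, m_curve.iteration(i), maturity_at_length, p, plusgroup_threshold, representative
        )
        for i, p in enumerate(growth)
    )
    return AgeStructuredStock(
        years=lf.years,
        iterations=iterations,
        mortality_model=m_curve.model_id,
        unit=lf.unit,
    )


def slice_index(
    index: LengthFrequency,
    growth: GrowthEnsemble,
    plusgroups: np.ndarray,
    timing: float = 0.0,
    representative: str = "midpoint",
) -> AgeIndex:
    """Slice a survey length-frequency with the stock's growth draws.

    The per-iteration plusgroup of the stock is reused so the index ages
    line up with the stock ages.
    """
    plusgroups = np.asarray(plusgroups, dtype=int)
    if plusgroups.size != len(growth):
        raise ValueError("plusgroups must have one entry per growth draw")
    rep = index.midpoints if representative == "midpoint" else index.length_lower
    out = []
    for i, p in enumerate(growth):
        labels = np.minimum(assign_ages(rep, p), plusgroups[i])
        n_ages = plusgroups[i] + 1
        ab = np.zeros((n_ages, index.years.size))
        for y in range(index.years.size):
            ab[:, y] = np.bincount(labels, weights=index.abundance[y], minlength=n_ages)
        out.append(ab)
    return AgeIndex(years=index.years, iterations=tuple(out), plusgroups=plusgroups, timing=timing)
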