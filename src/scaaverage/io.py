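"""Readers and writers for the pipeline's plain-text tables.

All tables are UTF-8 CSV with mandatory headers.  Length-based inputs are
long format (year, length_lower, value); age-based intermediates and
results are long format keyed by iteration / year / age or quantity, so
every artefact diffs and version-controls cleanly.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .growth import GrowthEnsemble, GrowthParams
from .slicing import AgeIndex, AgeStructuredStock, LengthFrequency, StockIteration

__all__ = [
    "read_length_table",
    "write_length_table",
    "prepare_maturity",
    "read_maturity_table",
    "write_growth_ensemble",
    "read_growth_ensemble",
    "write_stock",
    "read_stock",
    "write_index",
    "read_index",
    "write_variants",
    "read_variants",
]

logger = logging.getLogger(__name__)

_STOCK_VARIABLES = ("catch_n", "weight", "m", "maturity")


def read_length_table(path: str | Path, unit: str = "thousands") -> LengthFrequency:
    """Read a long-format (year, length_lower, value) table.

    The length grid must be contiguous with a uniform class width; cells
    absent from the file are zero-filled with a logged warning.
    """
    df = pd.read_csv(path)
    required = {"year", "length_lower", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}, got {list(df.columns)}")
    for col in required:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()].index[0]
            raise ValueError(f"{path}: non-numeric {col!r} at data row {bad}")
    dup = df.duplicated(subset=["year", "length_lower"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValueError(
            f"{path}: duplicate (year, length) pair ({row['year']}, {row['length_lower']})"
        )
    years = np.sort(df["year"].unique())
    lowers = np.sort(df["length_lower"].unique())
    widths = np.unique(np.round(np.diff(lowers), 9))
    if lowers.size > 1 and widths.size != 1:
        raise ValueError(f"{path}: mixed length-class widths {widths}")
    width = float(widths[0]) if lowers.size > 1 else 1.0
    grid = df.pivot(index="year", columns="length_lower", values="value")
    grid = grid.reindex(index=years, columns=lowers)
    n_missing = int(grid.isna().sum().sum())
    if n_missing:
        logger.warning("%s: %d missing (year, length) cells treated as zero", path, n_missing)
        grid = grid.fillna(0.0)
    return LengthFrequency(
        years=years, length_lower=lowers, width=width, abundance=grid.to_numpy(), unit=unit
    )


def write_length_table(lf: LengthFrequency, path: str | Path) -> None:
    rows = []
    for yi, year in enumerate(lf.years):
        for li, lower in enumerate(lf.length_lower):
            rows.append((year, lower, lf.abundance[yi, li]))
    pd.DataFrame(rows, columns=["year", "length_lower", "value"]).to_csv(path, index=False)


def prepare_maturity(ogive_by_year: pd.DataFrame, last_n: int = 3) -> pd.DataFrame:
    """Time-invariant maturity ogive: mean over the final ``last_n`` years.

    Input columns (year, length_lower, value); output (length_lower,
    value) with values clipped to [0, 1].
    """
    years = np.sort(ogive_by_year["year"].unique())
    if years.size < last_n:
        raise ValueError(f"need at least {last_n} years of ogive data, have {years.size}")
    recent = ogive_by_year[ogive_by_year["year"].isin(years[-last_n:])]
    out = recent.groupby("length_lower", as_index=False)["value"].mean()
    out["value"] = out["value"].clip(0.0, 1.0)
    return out.sort_values("length_lower").reset_index(drop=True)


def read_maturity_table(path: str | Path, last_n: int | None = None) -> pd.DataFrame:
    """Maturity table: either already time-invariant (length_lower, value)
    or per-year, in which case the last ``last_n`` (default 3) years are
    averaged."""
    df = pd.read_csv(path)
    if "year" in df.columns:
        return prepare_maturity(df, last_n or 3)
    if not {"length_lower", "value"}.issubset(df.columns):
        raise ValueError(f"{path}: expected (length_lower, value) columns")
    return df[["length_lower", "value"]].sort_values("length_lower").reset_index(drop=True)


def write_growth_ensemble(ensemble: GrowthEnsemble, path: str | Path) -> None:
    pd.DataFrame(ensemble.as_array(), columns=["linf", "k", "t0"]).to_csv(path, index=False)


def read_growth_ensemble(path: str | Path, seed: int = 0) -> GrowthEnsemble:
    df = pd.read_csv(path)
    draws = tuple(
        GrowthParams(linf=row.linf, k=row.k, t0=row.t0) for row in df.itertuples()
    )
    return GrowthEnsemble(draws=draws, seed=seed)


def write_stock(stock: AgeStructuredStock, path: str | Path) -> None:
    """Serialize an age-structured stock as a long table
    (iteration, year, age, variable, value)."""
    frames = []
    for i, it in enumerate(stock.iterations):
        for var in _STOCK_VARIABLES:
            arr = getattr(it, var)
            df = pd.DataFrame(arr, index=it.ages, columns=stock.years)
            df = df.stack().rename("value").reset_index()
            df.columns = ["age", "year", "value"]
            df["iteration"] = i
            df["variable"] = var
            frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out[["iteration", "year", "age", "variable", "value"]].to_csv(path, index=False)


def read_stock(path: str | Path, mortality_model: str = "constant") -> AgeStructuredStock:
    df = pd.read_csv(path)
    years = np.sort(df["year"].unique())
    iterations = []
    for i, grp in df.groupby("iteration"):
        ages = np.sort(grp["age"].unique())
        arrays = {}
        for var in _STOCK_VARIABLES:
            sub = grp[grp["variable"] == var].pivot(index="age", columns="year", values="value")
            arrays[var] = sub.reindex(index=ages, columns=years).to_numpy()
        iterations.append(
            StockIteration(
                ages=ages.astype(int),
                catch_n=arrays["catch_n"],
                weight=arrays["weight"],
                m=arrays["m"],
                maturity=arrays["maturity"],
                plusgroup=int(ages.max()),
            )
        )
    return AgeStructuredStock(
        years=years, iterations=tuple(iterations), mortality_model=mortality_model
    )


def write_index(index: AgeIndex, path: str | Path) -> None:
    rows = []
    for i, arr in enumerate(index.iterations):
        for ai in range(arr.shape[0]):
            for yi, year in enumerate(index.years):
                rows.append((i, year, ai, arr[ai, yi]))
    df = pd.DataFrame(rows, columns=["iteration", "year", "age", "value"])
    df.to_csv(path, index=False)


def read_index(path: str | Path, timing: float = 0.0) -> AgeIndex:
    df = pd.read_csv(path)
    years = np.sort(df["year"].unique())
    iterations = []
    plusgroups = []
    for i, grp in df.groupby("iteration"):
        sub = grp.pivot(index="age", columns="year", values="value")
        arr = sub.reindex(columns=years).to_numpy()
        iterations.append(arr)
        plusgroups.append(int(grp["age"].max()))
    return AgeIndex(
        years=years,
        iterations=tuple(iterations),
        plusgroups=np.array(plusgroups),
        timing=timing,
    )


def write_variants(variants, series_path: str | Path, meta_path: str | Path) -> None:
    """Serialize model variants: a long series table and a per-iteration
    metadata table (gcv per fitted iteration)."""
    series_rows, meta_rows = [], []
    for v in variants:
        for i, it in enumerate(v.iterations):
            meta_rows.append((v.label, v.sa_config_id, v.mortality_model, i, v.gcvs[i]))
            for qty, arr in it.items():
                for yi, year in enumerate(v.years):
                    series_rows.append((v.label, i, year, qty, arr[yi]))
    pd.DataFrame(
        series_rows, columns=["variant", "iteration", "year", "quantity", "value"]
    ).to_csv(series_path, index=False)
    pd.DataFrame(
        meta_rows, columns=["variant", "sa_model", "mortality_model", "iteration", "gcv"]
    ).to_csv(meta_path, index=False)


def read_variants(series_path: str | Path, meta_path: str | Path):
    """Inverse of :func:`write_variants`."""
    from .ensemble import ModelVariant

    series = pd.read_csv(series_path)
    meta = pd.read_csv(meta_path)
    variants = []
    for label, m in meta.groupby("variant", sort=False):
        sub = series[series["variant"] == label]
        years = np.sort(sub["year"].unique())
        iterations = []
        for i in np.sort(m["iteration"].unique()):
            it_rows = sub[sub["iteration"] == i]
            grid = it_rows.pivot(index="quantity", columns="year", values="value")
            grid = grid.reindex(columns=years)
            iterations.append({qty: grid.loc[qty].to_numpy() for qty in grid.index})
        variants.append(
            ModelVariant(
                sa_config_id=int(m["sa_model"].iloc[0]),
                mortality_model=str(m["mortality_model"].iloc[0]),
                iterations=iterations,
                gcvs=m.sort_values("iteration")["gcv"].to_numpy(),
                years=years,
            )
        )
    return variants
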