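"""Long-format demographic panels: schemas, validation, CSV I/O.

Two panel kinds circulate through the pipeline:

* **population** — January-1 stocks: one row per (region, year, age) with a
  non-negative ``count``; an optional ``cluster`` label column may tag regions.
* **events** — flows over the interval [year, year+1): ``deaths`` (>= 0)
  and/or ``net_migration`` (any sign) per (region, year, age).  The ``age``
  column of an events panel records the age a cohort *attains* during the
  interval (see :mod:`democonv.synthetic` for the bookkeeping convention).

Every panel must cover the complete age grid 0..open_age for every
(region, year) it contains; ``open_age`` is inferred as the maximum age
present.  Validation errors name the offending region, year, and ages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

POPULATION_COLUMNS = ("region", "year", "age", "count")
DEATHS_COLUMNS = ("region", "year", "age", "deaths")
MIGRATION_COLUMNS = ("region", "year", "age", "net_migration")


class PanelError(ValueError):
    """A panel violates its schema or coverage invariants."""


def _require_columns(df: pd.DataFrame, columns: tuple[str, ...], name: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise PanelError(f"{name} panel is missing column(s) {missing}; has {list(df.columns)}")


def _check_rows(df: pd.DataFrame, col: str, name: str, *, non_negative: bool) -> None:
    values = pd.to_numeric(df[col], errors="coerce")
    bad = ~np.isfinite(values.to_numpy(dtype=float))
    if bad.any():
        rows = df.index[bad][:10].tolist()
        raise PanelError(f"{name} panel: non-numeric or missing '{col}' at rows {rows}")
    if non_negative and (values < 0).any():
        rows = df.index[values < 0][:10].tolist()
        raise PanelError(f"{name} panel: negative '{col}' at rows {rows}")


def check_age_coverage(df: pd.DataFrame, name: str, open_age: int | None = None) -> int:
    """Verify the full 0..open_age grid per (region, year); return open_age.

    Raises :class:`PanelError` naming the first offending region-year and its
    missing or duplicated ages.
    """
    if open_age is None:
        open_age = int(df["age"].max())
    expected = open_age + 1
    grouped = df.groupby(["region", "year"], sort=False)["age"]
    stats = grouped.agg(["size", "nunique", "min", "max"])
    ok = (
        (stats["size"] == expected)
        & (stats["nunique"] == expected)
        & (stats["min"] == 0)
        & (stats["max"] == open_age)
    )
    if not ok.all():
        region, year = stats.index[~ok][0]
        ages = df.loc[(df["region"] == region) & (df["year"] == year), "age"]
        missing = sorted(set(range(expected)) - set(int(a) for a in ages))
        dupes = sorted(ages[ages.duplicated()].unique().tolist())
        detail = []
        if missing:
            detail.append(f"missing ages {missing}")
        if dupes:
            detail.append(f"duplicated ages {dupes}")
        raise PanelError(
            f"{name} panel: region {region!r}, year {year}: " + "; ".join(detail or ["incomplete age grid"])
        )
    return open_age


def validate_population(df: pd.DataFrame) -> int:
    """Validate a population panel; return its open_age."""
    _require_columns(df, POPULATION_COLUMNS, "population")
    _check_rows(df, "count", "population", non_negative=True)
    return check_age_coverage(df, "population")


def validate_events(df: pd.DataFrame, value_col: str) -> int:
    name = "deaths" if value_col == "deaths" else "migration"
    _require_columns(df, ("region", "year", "age", value_col), name)
    _check_rows(df, value_col, name, non_negative=(value_col == "deaths"))
    return check_age_coverage(df, name)


def merge_events(deaths: pd.DataFrame | None, migration: pd.DataFrame | None) -> pd.DataFrame:
    """Join deaths and net-migration panels into one events panel."""
    if deaths is None and migration is None:
        raise PanelError("merge_events needs at least one of deaths, migration")
    if deaths is None:
        return migration.copy()
    if migration is None:
        return deaths.copy()
    merged = deaths.merge(
        migration[["region", "year", "age", "net_migration"]],
        on=["region", "year", "age"],
        how="outer",
        validate="one_to_one",
    )
    if merged[["deaths", "net_migration"]].isna().any().any():
        raise PanelError("deaths and migration panels do not cover the same (region, year, age) grid")
    return merged


@dataclass(frozen=True)
class Cube:
    """Dense (region, year, age) array view of a validated long panel."""

    regions: np.ndarray  # sorted unique region ids, shape (R,)
    years: np.ndarray    # sorted unique years, shape (Y,)
    values: np.ndarray   # shape (R, Y, A)

    @property
    def open_age(self) -> int:
        return self.values.shape[2] - 1

    def year_index(self, year: int) -> int:
        idx = np.searchsorted(self.years, year)
        if idx >= len(self.years) or self.years[idx] != year:
            raise PanelError(f"year {year} not present in panel (have {self.years.min()}..{self.years.max()})")
        return int(idx)


def to_cube(df: pd.DataFrame, value_col: str) -> Cube:
    """Reshape a long panel into a dense cube; requires a complete grid."""
    open_age = check_age_coverage(df, value_col)
    d = df.sort_values(["region", "year", "age"], kind="mergesort")
    regions = d["region"].unique()
    years = d["year"].unique()
    years.sort()
    expected = len(regions) * len(years) * (open_age + 1)
    if len(d) != expected:
        # some region lacks some year entirely
        counts = d.groupby("region", sort=False)["year"].nunique()
        bad = counts.index[counts != len(years)].tolist()
        raise PanelError(f"panel is not rectangular over region x year; offending regions: {bad[:10]}")
    values = d[value_col].to_numpy(dtype=float).reshape(len(regions), len(years), open_age + 1)
    return Cube(regions=np.asarray(regions), years=np.asarray(years, dtype=int), values=values)


def read_population(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    validate_population(df)
    return df


def read_events(path, value_col: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    validate_events(df, value_col)
    return df


def write_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
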