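"""Tabular containers for cause-of-death counts, shares and exposures.

The central object is :class:`DeathsTable`: death counts for one stratum
(year, sex, age group) laid out as areas x causes, with exactly one cause
designated *ill-defined*.  Counts are stored as floats so that fractional
redistributed deaths survive intermediate computations; rounding to integers
happens only at export.

Long-format CSV is the canonical interchange format
(area, cause, age_group, sex, year, deaths).  A wide-format reader is
provided for spreadsheets laid out as one area per row and one cause per
column.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import (
    ConfigurationError,
    DataValidationError,
    EmptyResultError,
    SchemaError,
)

logger = logging.getLogger(__name__)

LONG_COLUMNS = ("area", "cause", "age_group", "sex", "year", "deaths")


@dataclass(frozen=True, order=True)
class StratumKey:
    """One (year, sex, age group) slice of the data, processed independently."""

    year: int
    sex: str
    age_group: str


@dataclass
class SchemaConfig:
    """Names the input columns and the designated ill-defined cause label.

    ``age_order`` supplies the total order of age-group labels; if omitted,
    labels are ordered lexically (a warning is logged, since labels such as
    ``"5-14"`` do not sort correctly as strings).
    """

    illdefined_label: str
    area_col: str = "area"
    cause_col: str = "cause"
    age_col: str = "age_group"
    sex_col: str = "sex"
    year_col: str = "year"
    count_col: str = "deaths"
    missing_as_zero: bool = False
    age_order: list[str] | None = None

    @classmethod
    def from_file(cls, path: str | Path) -> "SchemaConfig":
        path = Path(path)
        with open(path) as fh:
            raw = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
        if not isinstance(raw, Mapping):
            raise SchemaError(f"schema config {path} is not a mapping")
        unknown = set(raw) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise SchemaError(f"unknown schema config keys: {sorted(unknown)}")
        if "illdefined_label" not in raw:
            raise SchemaError("schema config must name 'illdefined_label'")
        return cls(**raw)

    def sort_ages(self, ages: Iterable[str]) -> list[str]:
        ages = list(dict.fromkeys(ages))
        if self.age_order is None:
            logger.warning("no age_order supplied; ordering age groups lexically")
            return sorted(ages)
        missing = set(ages) - set(self.age_order)
        if missing:
            raise ConfigurationError(f"age groups {sorted(missing)} not in configured age_order")
        return [a for a in self.age_order if a in set(ages)]


@dataclass
class DeathsTable:
    """Death counts for one stratum: rows are areas, columns are causes.

    Exactly one column, named by ``illdefined``, holds the ill-defined deaths
    delta_g; the remaining columns are the well-defined causes d_cg.
    """

    counts: pd.DataFrame
    illdefined: str
    stratum: StratumKey | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.counts, pd.DataFrame):
            raise DataValidationError("counts must be a DataFrame (areas x causes)")
        if self.counts.columns.duplicated().any() or self.counts.index.duplicated().any():
            raise DataValidationError("duplicate area or cause labels")
        if self.illdefined not in self.counts.columns:
            raise ConfigurationError(
                f"ill-defined label {self.illdefined!r} absent from cause set"
            )
        if len(self.counts.columns) < 2:
            raise DataValidationError("need at least one well-defined cause")
        values = self.counts.to_numpy(dtype=float)
        if np.isnan(values).any():
            raise DataValidationError("missing death counts (set missing_as_zero to accept)")
        if (values < 0).any():
            raise DataValidationError("negative death counts")
        self.counts = self.counts.astype(float)

    # -- basic accessors -------------------------------------------------

    @property
    def areas(self) -> list:
        return list(self.counts.index)

    @property
    def n_areas(self) -> int:
        return len(self.counts.index)

    @property
    def causes(self) -> list:
        """Well-defined cause labels, in column order."""
        return [c for c in self.counts.columns if c != self.illdefined]

    @property
    def delta(self) -> pd.Series:
        """Ill-defined deaths per area."""
        return self.counts[self.illdefined]

    @property
    def well_defined(self) -> pd.DataFrame:
        return self.counts[self.causes]

    @property
    def usable_for_regression(self) -> bool:
        return self.n_areas >= 2

    def area_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def national_totals(self) -> tuple[pd.Series, float]:
        """Aggregate over areas: (d_c for well-defined causes, delta)."""
        return self.well_defined.sum(axis=0), float(self.delta.sum())

    def aggregated(self, label: str = "TOTAL") -> "DeathsTable":
        """Collapse all areas into a single national row."""
        agg = self.counts.sum(axis=0).to_frame(name=label).T
        return DeathsTable(agg, self.illdefined, self.stratum)


@dataclass
class ShareTable:
    """Observed shares per retained area: X_g (ill-defined) and Y_cg (by cause).

    Areas whose total death count is zero have undefined shares; they are
    excluded here and listed in ``excluded_areas``.
    """

    X: pd.Series
    Y: pd.DataFrame
    excluded_areas: list = field(default_factory=list)

    @property
    def n_areas(self) -> int:
        return len(self.X)

    def closure_error(self) -> pd.Series:
        """|X_g + sum_c Y_cg - 1| per retained area (should be ~0)."""
        return (self.X + self.Y.sum(axis=1) - 1.0).abs()


def compute_shares(table: DeathsTable) -> ShareTable:
    """Compute X_g = delta_g / T_g and Y_cg = d_cg / T_g, T_g the area total.

    Zero-total areas are excluded (logged); if every area is zero-total the
    result would be empty and an error is raised.
    """
    totals = table.area_totals()
    retained = totals > 0
    if not retained.any():
        raise EmptyResultError("all areas have zero total deaths; shares undefined")
    excluded = list(totals.index[~retained])
    if excluded:
        logger.info("excluding %d zero-total areas from shares: %s", len(excluded), excluded)
    t = totals[retained]
    X = table.delta[retained] / t
    Y = table.well_defined.loc[retained].div(t, axis=0)
    return ShareTable(X=X, Y=Y, excluded_areas=excluded)


# ---------------------------------------------------------------------------
# readers / writers


def _require_columns(df: pd.DataFrame, cols: Iterable[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")


def read_deaths(path: str | Path, schema: SchemaConfig) -> dict[StratumKey, DeathsTable]:
    """Read a long-format CSV into one DeathsTable per stratum."""
    path = Path(path)
    df = pd.read_csv(path)
    cols = [schema.area_col, schema.cause_col, schema.age_col,
            schema.sex_col, schema.year_col, schema.count_col]
    _require_columns(df, cols, path)
    counts = pd.to_numeric(df[schema.count_col], errors="coerce")
    if counts.isna().any():
        if not schema.missing_as_zero:
            raise DataValidationError(f"{path}: non-numeric or missing death counts")
        counts = counts.fillna(0.0)
    if (counts < 0).any():
        raise DataValidationError(f"{path}: negative death counts")
    df = df.assign(**{schema.count_col: counts})
    if schema.illdefined_label not in set(df[schema.cause_col]):
        raise ConfigurationError(
            f"ill-defined label {schema.illdefined_label!r} absent from cause set in {path}"
        )
    out: dict[StratumKey, DeathsTable] = {}
    for (year, sex, age), grp in df.groupby([schema.year_col, schema.sex_col, schema.age_col]):
        key = StratumKey(year=int(year), sex=str(sex), age_group=str(age))
        wide = grp.pivot_table(index=schema.area_col, columns=schema.cause_col,
                               values=schema.count_col, aggfunc="sum")
        if wide.isna().any().any():
            if not schema.missing_as_zero:
                raise DataValidationError(
                    f"{path}: stratum {key} has missing (area, cause) cells; "
                    "set missing_as_zero to treat them as zero"
                )
            wide = wide.fillna(0.0)
        if schema.illdefined_label not in wide.columns:
            if not schema.missing_as_zero:
                raise ConfigurationError(
                    f"stratum {key} lacks the ill-defined cause {schema.illdefined_label!r}"
                )
            wide[schema.illdefined_label] = 0.0
        table = DeathsTable(wide, schema.illdefined_label, stratum=key)
        if not table.usable_for_regression:
            logger.warning("stratum %s has N=%d areas; unusable for regression", key, table.n_areas)
        out[key] = table
    return out


def write_deaths(tables: Mapping[StratumKey, DeathsTable] | DeathsTable,
                 path: str | Path, schema: SchemaConfig | None = None) -> None:
    """Write tables back to long-format CSV (inverse of :func:`read_deaths`)."""
    if isinstance(tables, DeathsTable):
        key = tables.stratum or StratumKey(0, "all", "all")
        tables = {key: tables}
    schema = schema or SchemaConfig(illdefined_label=next(iter(tables.values())).illdefined)
    rows = []
    for key, table in tables.items():
        long = (table.counts.rename_axis(index=schema.area_col, columns=schema.cause_col)
                .stack().rename(schema.count_col).reset_index())
        long[schema.age_col] = key.age_group
        long[schema.sex_col] = key.sex
        long[schema.year_col] = key.year
        rows.append(long)
    out = pd.concat(rows, ignore_index=True)
    out = out[[schema.area_col, schema.cause_col, schema.age_col,
               schema.sex_col, schema.year_col, schema.count_col]]
    out.to_csv(path, index=False)


def read_deaths_wide(path: str | Path, illdefined: str,
                     stratum: StratumKey | None = None,
                     sheet: int | str = 0) -> DeathsTable:
    """Read a wide-format sheet (one area per row, one cause per column).

    Supports ``.xlsx`` (first sheet by default) and ``.csv``.  The first
    column is taken as the area identifier.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xlsm"):
        df = pd.read_excel(path, sheet_name=sheet)
    else:
        df = pd.read_csv(path)
    if df.shape[1] < 3:
        raise SchemaError(f"{path}: wide layout needs an area column and >=2 cause columns")
    df = df.set_index(df.columns[0])
    if illdefined not in df.columns:
        raise ConfigurationError(f"ill-defined label {illdefined!r} absent from {path}")
    values = df.apply(pd.to_numeric, errors="coerce")
    if values.isna().any().any():
        raise DataValidationError(f"{path}: non-numeric cells in wide layout")
    return DeathsTable(values, illdefined, stratum=stratum)


@dataclass
class ExposureTable:
    """Person-years at risk by area, age group, sex and year (long format)."""

    data: pd.DataFrame

    COLUMNS = ("area", "age_group", "sex", "year", "exposure")

    def __post_init__(self) -> None:
        _require_columns(self.data, self.COLUMNS, "exposures")
        if (pd.to_numeric(self.data["exposure"], errors="coerce") < 0).any():
            raise DataValidationError("negative exposures")

    @classmethod
    def read(cls, path: str | Path) -> "ExposureTable":
        return cls(pd.read_csv(path))

    def national(self, year: int, sex: str) -> pd.Series:
        """Exposure summed over areas, indexed by age group."""
        sel = self.data[(self.data["year"] == year) & (self.data["sex"] == sex)]
        return sel.groupby("age_group")["exposure"].sum()

    def for_area(self, area, year: int, sex: str) -> pd.Series:
        sel = self.data[(self.data["area"] == area)
                        & (self.data["year"] == year) & (self.data["sex"] == sex)]
        return sel.groupby("age_group")["exposure"].sum()
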