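"""End-to-end orchestration: read, fit, smooth, redistribute, rate, diagnose.

Each stratum (year, sex, age group) is processed independently:

    shares -> per-cause OLS -> truncate/rescale (-> smooth across ages)
           -> national adjustment + dissimulation coefficients
           -> per-area allocation -> diagnostics (-> standardized rates)

Conservation of the stratum's total death count is asserted before anything
is written.  A failure in one stratum is recorded and the remaining strata
are still processed.  Strata where no cause is negatively associated with
the ill-defined share fall back to proportional-redistribution coefficients,
with the stratum flagged.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import baseline, diagnostics, national, subnational
from .data_model import (
    DeathsTable,
    ExposureTable,
    SchemaConfig,
    StratumKey,
    compute_shares,
    read_deaths,
)
from .errors import ConfigurationError, LedermannError, NoReceivingCauseError
from .rates import StandardPopulation, standardized_death_rate

logger = logging.getLogger(__name__)

STRATUM_COLS = ["year", "sex", "age_group"]


@dataclass
class RunConfig:
    """Serializable description of one adjustment run."""

    deaths_path: str
    schema: SchemaConfig
    out_dir: str | None = None
    methods: tuple = ("ledermann", "pr")
    smooth: bool = False
    smooth_span: float = 1.0
    integerize: bool = False
    exposures_path: str | None = None
    standard_path: str | None = None
    rate_per: float = 100_000.0

    def __post_init__(self) -> None:
        unknown = set(self.methods) - {"ledermann", "pr"}
        if unknown:
            raise ConfigurationError(f"unknown methods {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, Mapping):
            raise ConfigurationError(f"run config {path} is not a mapping")
        raw = dict(raw)
        schema = raw.pop("schema", None)
        if schema is None:
            raise ConfigurationError("run config must contain a 'schema' section")
        if isinstance(schema, str):
            schema = SchemaConfig.from_file(schema)
        else:
            schema = SchemaConfig(**schema)
        if "methods" in raw:
            raw["methods"] = tuple(raw["methods"])
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown run config keys: {sorted(unknown)}")
        return cls(schema=schema, **raw)


@dataclass
class RunResult:
    """Tidy outputs of one run, also written as CSVs when out_dir is set."""

    coefficients: pd.DataFrame
    national: pd.DataFrame
    subnational: pd.DataFrame
    diagnostics: pd.DataFrame
    rates: pd.DataFrame | None = None
    errors: list = field(default_factory=list)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.coefficients.to_csv(out / "coefficients.csv", index=False)
        self.national.to_csv(out / "adjusted_national.csv", index=False)
        self.subnational.to_csv(out / "adjusted_subnational.csv", index=False)
        self.diagnostics.to_csv(out / "diagnostics.csv", index=False)
        if self.rates is not None:
            self.rates.to_csv(out / "rates.csv", index=False)
        if self.errors:
            pd.DataFrame(self.errors).to_csv(out / "errors.csv", index=False)


def _stratum_dict(key: StratumKey) -> dict:
    return {"year": key.year, "sex": key.sex, "age_group": key.age_group}


def _ledermann_coefficients_for_group(
    tables: Mapping[StratumKey, DeathsTable],
    keys: list[StratumKey],
    config: RunConfig,
    errors: list,
) -> dict[StratumKey, tuple[national.RedistributionCoefficients, dict, bool]]:
    """Fit each age's regressions, optionally smoothing m across ages.

    Returns {stratum: (coefficients, fits, used_pr_fallback)} for the strata
    that succeeded.
    """
    fitted: dict[StratumKey, tuple[pd.Series, dict]] = {}
    for key in keys:
        table = tables[key]
        try:
            shares = compute_shares(table)
            fits = national.fit_all_causes(shares)
            fitted[key] = (national.raw_coefficients(fits), fits)
        except LedermannError as exc:
            errors.append({**_stratum_dict(key), "stage": "regression",
                           "error": type(exc).__name__, "message": str(exc)})

    out: dict[StratumKey, tuple] = {}
    keys_ok = [k for k in keys if k in fitted]
    cause_sets = {tuple(fitted[k][0].index) for k in keys_ok}
    smooth = config.smooth and len(keys_ok) >= 2 and len(cause_sets) == 1
    if config.smooth and not smooth and keys_ok:
        logger.warning("smoothing disabled: %s",
                       "inconsistent cause sets across ages" if len(cause_sets) > 1
                       else "fewer than two fitted age groups")

    if smooth:
        series = [fitted[k][0] for k in keys_ok]
        try:
            smoothed = national.smooth_coefficients_over_age(
                series, span=config.smooth_span, enabled=True)
            for key, coeffs in zip(keys_ok, smoothed):
                out[key] = (coeffs, fitted[key][1], False)
            return out
        except NoReceivingCauseError:
            logger.warning("smoothing produced no receiving cause; "
                           "falling back to per-age coefficients")

    for key in keys_ok:
        m_raw, fits = fitted[key]
        try:
            out[key] = (national.truncate_and_rescale(m_raw), fits, False)
        except NoReceivingCauseError:
            # no cause is negatively associated with X: use PR coefficients
            d_c, delta = tables[key].national_totals()
            _, pr_coeff = baseline.proportional_redistribution(d_c, delta)
            coeffs = national.RedistributionCoefficients(
                m_raw=pr_coeff * 0.0, m_prime=pr_coeff, sum_m_raw=0.0)
            logger.warning("stratum %s: all m <= 0; falling back to PR coefficients", key)
            out[key] = (coeffs, fits, True)
    return out


def run_adjustment(config: RunConfig) -> RunResult:
    """Run the full adjustment described by ``config``; see module docstring."""
    tables = read_deaths(config.deaths_path, config.schema)
    errors: list = []
    coeff_rows, national_rows, sub_rows, diag_rows = [], [], [], []

    # group strata by (year, sex) so smoothing can run across ordered ages
    groups: dict[tuple, list[StratumKey]] = {}
    for key in tables:
        groups.setdefault((key.year, key.sex), []).append(key)

    for (year, sex), keys in sorted(groups.items()):
        ages = config.schema.sort_ages([k.age_group for k in keys])
        keys = [StratumKey(year, sex, a) for a in ages]
        led = (_ledermann_coefficients_for_group(tables, keys, config, errors)
               if "ledermann" in config.methods else {})

        for key in keys:
            table = tables[key]
            d_c, delta = table.national_totals()
            total_before = float(table.counts.to_numpy().sum())

            if "ledermann" in config.methods and key in led:
                coeffs, fits, used_pr = led[key]
                try:
                    D_nat = national.redistribute_national(d_c, delta, coeffs)
                    theta = national.dissimulation_coefficients(d_c, delta, coeffs)
                    alloc = subnational.allocate_table(table, theta,
                                                       fallback_weights=coeffs.m_prime)
                    _assert_conserved(D_nat.sum(), total_before, key, "ledermann-national")
                    _assert_conserved(alloc.D.to_numpy().sum(), total_before,
                                      key, "ledermann-subnational")
                    for cause in coeffs.causes:
                        coeff_rows.append({**_stratum_dict(key), "cause": cause,
                                           "m_raw": coeffs.m_raw[cause],
                                           "m_prime": coeffs.m_prime[cause],
                                           "theta": theta.theta[cause],
                                           "pr_fallback": used_pr})
                    national_rows += _national_rows(key, "ledermann", d_c, D_nat)
                    sub_rows += _sub_rows(key, "ledermann", table, alloc.r, config.integerize)
                    diag_rows.append(_diagnostic_row(key, fits, alloc, table))
                except LedermannError as exc:
                    errors.append({**_stratum_dict(key), "stage": "ledermann",
                                   "error": type(exc).__name__, "message": str(exc)})

            if "pr" in config.methods:
                try:
                    D_pr, _ = baseline.proportional_redistribution(d_c, delta)
                    _assert_conserved(D_pr.sum(), total_before, key, "pr-national")
                    national_rows += _national_rows(key, "pr", d_c, D_pr)
                    pr_sub = baseline.pr_table(table)
                    _assert_conserved(pr_sub.to_numpy().sum(), total_before,
                                      key, "pr-subnational")
                    r_pr = pr_sub - table.well_defined
                    sub_rows += _sub_rows(key, "pr", table, r_pr, config.integerize)
                except LedermannError as exc:
                    errors.append({**_stratum_dict(key), "stage": "pr",
                                   "error": type(exc).__name__, "message": str(exc)})

    result = RunResult(
        coefficients=_frame(coeff_rows, STRATUM_COLS + ["cause"]),
        national=_frame(national_rows, STRATUM_COLS + ["method", "cause"]),
        subnational=_frame(sub_rows, STRATUM_COLS + ["method", "area", "cause"]),
        diagnostics=_frame(diag_rows, STRATUM_COLS),
        errors=errors,
    )
    if config.exposures_path is not None:
        try:
            result.rates = _national_rates(result.national, config)
        except LedermannError as exc:
            errors.append({"year": "", "sex": "", "age_group": "", "stage": "rates",
                           "error": type(exc).__name__, "message": str(exc)})
    if config.out_dir is not None:
        result.write(config.out_dir)
    return result


def _assert_conserved(total_after: float, total_before: float,
                      key: StratumKey, stage: str) -> None:
    if not np.isclose(total_after, total_before, rtol=0, atol=1e-6 * max(total_before, 1)):
        raise LedermannError(
            f"conservation violated at {stage} for {key}: "
            f"{total_after!r} != {total_before!r}"
        )


def _national_rows(key: StratumKey, method: str,
                   d_c: pd.Series, D: pd.Series) -> list[dict]:
    return [{**_stratum_dict(key), "method": method, "cause": cause,
             "reported": float(d_c[cause]), "adjusted": float(D[cause])}
            for cause in d_c.index]


def _sub_rows(key: StratumKey, method: str, table: DeathsTable,
              r: pd.DataFrame, integerize: bool) -> list[dict]:
    rows = []
    for area in table.areas:
        realloc = r.loc[area]
        if integerize:
            realloc = pd.Series(
                subnational.integerize_allocation(realloc, float(table.delta[area])),
                index=realloc.index, dtype=float)
        for cause in r.columns:
            reported = float(table.well_defined.loc[area, cause])
            rows.append({**_stratum_dict(key), "method": method, "area": area,
                         "cause": cause, "reported": reported,
                         "reallocated": float(realloc[cause]),
                         "adjusted": reported + float(realloc[cause])})
    return rows


def _diagnostic_row(key: StratumKey, fits, alloc, table: DeathsTable) -> dict:
    sum_check = diagnostics.check_sum_m(fits)
    n_outliers = 0
    for fit in fits.values():
        report = diagnostics.residual_and_outlier_report(fit)
        n_outliers += len(report.outliers)
    shares = compute_shares(table)
    cov = diagnostics.covariance_check(alloc.Y_adj.loc[shares.X.index], shares.X)
    return {**_stratum_dict(key),
            "sum_m_signed": sum_check.sum_signed,
            "sum_m_truncated": sum_check.sum_truncated,
            "sum_m_flagged": sum_check.flagged,
            "n_outlier_areas": n_outliers,
            "max_abs_cov_adjusted_share_X": float(cov["covariance"].abs().max()),
            "n_fallback_areas": len(alloc.fallback_areas)}


def _national_rates(national_df: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    """Standardized rates by (year, sex, method, cause) from national counts."""
    exposures = ExposureTable.read(config.exposures_path)
    rows = []
    for (year, sex, method, cause), grp in national_df.groupby(
            ["year", "sex", "method", "cause"]):
        deaths = grp.set_index("age_group")["adjusted"]
        exposure = exposures.national(year, sex).reindex(deaths.index)
        std = (StandardPopulation.read(config.standard_path)
               if config.standard_path else StandardPopulation.uniform(deaths.index))
        rate = standardized_death_rate(deaths, exposure, std, per=config.rate_per)
        rows.append({"year": year, "sex": sex, "method": method, "cause": cause,
                     "standardized_rate": rate, "per": config.rate_per})
    return _frame(rows, ["year", "sex", "method", "cause"])


def _frame(rows: list[dict], sort_cols: list[str]) -> pd.DataFrame:
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    return df.sort_values(sort_cols, kind="stable").reset_index(drop=True)
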