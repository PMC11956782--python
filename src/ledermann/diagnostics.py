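"""Assumption checks and robustness diagnostics.

The method's assumptions (independence of the ill-defined share from the
latent true shares; uniform registration practice across areas) cannot be
tested directly, but several observable consequences can: the raw
coefficients should sum to about one; the regression residuals should look
normal with no outlying areas; the adjusted shares should be uncorrelated
with the ill-defined share; and the coefficients should vary little between
years.  Diagnostics report, never modify: no area is excluded or reweighted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .national import RegressionFit


@dataclass
class SumMCheck:
    """Sum of the raw coefficients, signed and truncated, with a flag."""

    sum_signed: float          # sum of m_c before truncation
    sum_truncated: float       # sum after negative coefficients are zeroed
    deviation: float           # |sum_truncated - 1|
    threshold: float
    flagged: bool


def check_sum_m(fits: Mapping[object, RegressionFit],
                threshold: float = 0.10) -> SumMCheck:
    """Report sum_c m_c and flag deviations from 1 beyond ``threshold``."""
    signed = float(sum(f.m for f in fits.values()))
    truncated = float(sum(max(f.m, 0.0) for f in fits.values()))
    deviation = abs(truncated - 1.0)
    return SumMCheck(sum_signed=signed, sum_truncated=truncated,
                     deviation=deviation, threshold=threshold,
                     flagged=deviation > threshold)


@dataclass
class OutlierReport:
    """Standardized residuals, flagged areas and a moment-based normality statistic."""

    standardized: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    outliers: list = field(default_factory=list)
    normality_statistic: float = float("nan")
    normality_pvalue: float = float("nan")
    degenerate: bool = False
    skipped: bool = False
    note: str = ""


def residual_and_outlier_report(fit: RegressionFit,
                                threshold: float = 3.0) -> OutlierReport:
    """Areas with |standardized residual| beyond ``threshold`` (default 3).

    The normality statistic is Jarque-Bera (skewness/kurtosis based).  An
    exact fit leaves zero residual variance; that degenerate case is flagged
    rather than scored.  Fits on fewer than four areas are skipped.
    """
    if fit.n_areas < 4:
        return OutlierReport(skipped=True,
                             note=f"only {fit.n_areas} areas; report skipped")
    resid = fit.residuals.astype(float)
    sd = float(resid.std(ddof=2))  # two regression parameters
    if float(resid.abs().max()) < 1e-10:  # shares are O(1): this is an exact fit
        sd = 0.0
    if sd == 0.0 or not np.isfinite(sd):
        return OutlierReport(standardized=resid * 0.0, degenerate=True,
                             note="zero residual variance (exact fit)")
    z = resid / sd
    jb, p = stats.jarque_bera(resid.to_numpy())
    return OutlierReport(
        standardized=z,
        outliers=list(z.index[z.abs() > threshold]),
        normality_statistic=float(jb),
        normality_pvalue=float(p),
    )


def covariance_check(Y_adj: pd.DataFrame, X: pd.Series,
                     flag_threshold: float | None = None) -> pd.DataFrame:
    """Empirical covariance of each adjusted share with the ill-defined share.

    Under the independence assumption these covariances should be near zero.
    Returns one row per cause with the covariance and, if ``flag_threshold``
    is given, a magnitude flag.
    """
    x = X.loc[Y_adj.index].astype(float)
    cov = Y_adj.astype(float).apply(lambda col: col.cov(x))
    out = cov.rename("covariance").rename_axis("cause").reset_index()
    if flag_threshold is not None:
        out["flagged"] = out["covariance"].abs() > flag_threshold
    return out


def coefficient_stability(m_prime_by_year: Mapping[int, pd.Series]) -> pd.DataFrame:
    """Year-to-year variation of the rescaled coefficients, per cause.

    Reports mean, standard deviation and coefficient of variation across
    years.  The method expects only minor variation; thresholds are left to
    the user.
    """
    wide = pd.DataFrame({year: pd.Series(m, dtype=float)
                         for year, m in sorted(m_prime_by_year.items())})
    mean = wide.mean(axis=1)
    sd = wide.std(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = (sd / mean).where(mean > 0)
    return pd.DataFrame({"mean": mean, "sd": sd, "cv": cv}).rename_axis("cause")
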