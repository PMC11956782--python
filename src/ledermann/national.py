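"""National-level estimation of redistribution coefficients.

For each well-defined cause c, the observed share Y_cg is regressed across
areas on the ill-defined share X_g:

    Y_cg = a_c - m_c * X_g + eps_cg            (unweighted OLS, intercept)

Under the method's assumptions (X independent of the latent true shares;
registration practice roughly uniform across areas) the negated slope m_c
estimates the average fraction of ill-defined deaths attributable to cause c,
and the intercept a_c estimates the true national share of cause c.
The m_c are truncated at zero and rescaled to sum to one, then applied as

    D_c = d_c + m'_c * delta

which conserves the stratum's total death count.  The dissimulation
coefficient Theta_c = m'_c*delta / D_c is the estimated fraction of cause c's
true deaths that were registered as ill-defined; it drives the subnational
allocation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.nonparametric.smoothers_lowess import lowess

from .data_model import ShareTable
from .errors import (
    ConfigurationError,
    DataValidationError,
    DegenerateDesignError,
    InsufficientDataError,
    NoReceivingCauseError,
)

logger = logging.getLogger(__name__)


@dataclass
class RegressionFit:
    """One per-cause OLS fit of Y_c on X across areas."""

    cause: object
    intercept: float
    slope: float
    residuals: pd.Series
    r_squared: float
    n_areas: int

    @property
    def m(self) -> float:
        """Raw redistribution coefficient: the negated slope."""
        return -self.slope

    def fitted(self, X: pd.Series) -> pd.Series:
        return self.intercept + self.slope * X


@dataclass
class RedistributionCoefficients:
    """Truncated (m_raw) and rescaled (m_prime) coefficients over causes.

    ``sum_m_raw`` is the truncated sum used as the rescaling denominator
    (1.026 in the worked national example of the docs).
    """

    m_raw: pd.Series
    m_prime: pd.Series
    sum_m_raw: float

    def __post_init__(self) -> None:
        if (self.m_prime < 0).any():
            raise DataValidationError("rescaled coefficients must be non-negative")
        if self.sum_m_raw > 0 and abs(self.m_prime.sum() - 1.0) > 1e-12:
            raise DataValidationError("rescaled coefficients must sum to 1")

    @property
    def causes(self) -> list:
        return list(self.m_prime.index)


@dataclass
class DissimulationCoefficients:
    """Theta_c: estimated fraction of cause c's true deaths hidden as ill-defined."""

    theta: pd.Series

    def __post_init__(self) -> None:
        if ((self.theta < 0) | (self.theta > 1)).any():
            raise DataValidationError("dissimulation coefficients must lie in [0, 1]")


def fit_cause_regression(shares: ShareTable, cause) -> RegressionFit:
    """Unweighted OLS of Y_cg on X_g with intercept, for one cause."""
    if cause not in shares.Y.columns:
        raise ConfigurationError(f"unknown cause {cause!r}")
    if shares.n_areas < 3:
        raise InsufficientDataError(
            f"regression needs >= 3 areas, got {shares.n_areas}"
        )
    X = shares.X.to_numpy(dtype=float)
    y = shares.Y[cause].to_numpy(dtype=float)
    if np.ptp(X) == 0.0:
        raise DegenerateDesignError("ill-defined share X is constant across areas")
    design = sm.add_constant(X)
    res = sm.OLS(y, design).fit()
    resid = pd.Series(res.resid, index=shares.X.index, name=cause)
    return RegressionFit(
        cause=cause,
        intercept=float(res.params[0]),
        slope=float(res.params[1]),
        residuals=resid,
        r_squared=float(res.rsquared) if y.std() > 0 else 1.0,
        n_areas=shares.n_areas,
    )


def fit_all_causes(shares: ShareTable) -> dict:
    """Fit every well-defined cause; returns {cause: RegressionFit}."""
    return {c: fit_cause_regression(shares, c) for c in shares.Y.columns}


def raw_coefficients(fits: Mapping[object, RegressionFit]) -> pd.Series:
    """Signed m_c = -slope per cause, in cause order."""
    return pd.Series({c: f.m for c, f in fits.items()}, name="m_raw")


def truncate_and_rescale(m_by_cause: pd.Series) -> RedistributionCoefficients:
    """Set negative m_c to zero, then divide by the truncated sum.

    Causes whose OLS slope is positive (m_c < 0) receive no ill-defined
    deaths.  If every coefficient is non-positive there is no receiving
    cause and an error is raised (callers may fall back to proportional
    redistribution).
    """
    m = pd.Series(m_by_cause, dtype=float)
    truncated = m.clip(lower=0.0)
    total = float(truncated.sum())
    if total <= 0.0:
        raise NoReceivingCauseError("all redistribution coefficients are <= 0")
    return RedistributionCoefficients(
        m_raw=truncated, m_prime=truncated / total, sum_m_raw=total
    )


def redistribute_national(d_c: pd.Series, delta: float,
                          coeffs: RedistributionCoefficients) -> pd.Series:
    """Adjusted national counts D_c = d_c + m'_c * delta (total conserved)."""
    if delta < 0:
        raise DataValidationError("ill-defined deaths must be non-negative")
    d = pd.Series(d_c, dtype=float)
    if not d.index.equals(coeffs.m_prime.index):
        if set(d.index) != set(coeffs.m_prime.index):
            raise DataValidationError("cause labels of counts and coefficients differ")
        d = d.reindex(coeffs.m_prime.index)
    return d + coeffs.m_prime * float(delta)


def dissimulation_coefficients(d_c: pd.Series, delta: float,
                               coeffs: RedistributionCoefficients) -> DissimulationCoefficients:
    """Theta_c = m'_c*delta / (d_c + m'_c*delta); 0/0 is defined as 0."""
    D = redistribute_national(d_c, delta, coeffs)
    hidden = coeffs.m_prime * float(delta)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = hidden / D
    theta = theta.where(D > 0, 0.0)
    return DissimulationCoefficients(theta=theta.rename("theta"))


def smooth_coefficients_over_age(
    m_by_age: Sequence[pd.Series],
    span: float = 1.0,
    enabled: bool = True,
) -> list[RedistributionCoefficients]:
    """Smooth each cause's m_c series across the ordered age groups.

    Smoothing is a tricube-weighted locally linear regression (LOWESS) of
    m_c on the age-group index; ``span`` is the fraction of age groups in
    each local window (default 1.0, i.e. the full range; admissible range
    (0, 1] with at least two points per window).  After smoothing, each
    age's coefficients are re-truncated and rescaled so they again sum to 1.
    With ``enabled=False`` the input passes through truncate-and-rescale
    unchanged.
    """
    vectors = [pd.Series(m, dtype=float) for m in m_by_age]
    if not vectors:
        return []
    index = vectors[0].index
    for v in vectors[1:]:
        if not v.index.equals(index):
            raise DataValidationError("age-specific coefficient vectors must share causes")
    if not (0.0 < span <= 1.0):
        raise ConfigurationError("smoothing span must lie in (0, 1]")
    n_ages = len(vectors)
    if enabled and n_ages < 2:
        warnings.warn("only one age group; smoothing skipped", stacklevel=2)
        enabled = False
    if enabled:
        x = np.arange(n_ages, dtype=float)
        frac = max(span, 2.0 / n_ages)  # local-linear fit needs >= 2 points
        stacked = np.vstack([v.to_numpy() for v in vectors])  # ages x causes
        smoothed = np.empty_like(stacked)
        for j in range(stacked.shape[1]):
            smoothed[:, j] = lowess(stacked[:, j], x, frac=frac, it=0,
                                    return_sorted=False)
        vectors = [pd.Series(smoothed[i], index=index) for i in range(n_ages)]
    return [truncate_and_rescale(v) for v in vectors]
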