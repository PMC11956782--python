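"""Directly age-standardized death rates from adjusted counts and exposures.

The standardized rate is the weighted mean of age-specific rates,
sum_a w_a * (D_a / E_a), with weights from a standard population normalized
to sum to one.  No particular standard is bundled beyond a uniform default
over the supplied age groups; callers wanting ESP/WHO weights supply them.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import ConfigurationError, DataValidationError, UndefinedRateError


@dataclass
class StandardPopulation:
    """Age-group weights of a standard population (normalized internally)."""

    weights: pd.Series

    def __post_init__(self) -> None:
        w = pd.Series(self.weights, dtype=float)
        if (w < 0).any():
            raise DataValidationError("standard population weights must be non-negative")
        total = float(w.sum())
        if total <= 0:
            raise DataValidationError("standard population weights sum to zero")
        self.weights = w / total

    @classmethod
    def uniform(cls, age_groups) -> "StandardPopulation":
        ages = list(age_groups)
        if not ages:
            raise ConfigurationError("uniform standard needs at least one age group")
        return cls(pd.Series(1.0, index=ages))

    @classmethod
    def read(cls, path: str | Path) -> "StandardPopulation":
        """CSV with columns ``age_group, weight``."""
        df = pd.read_csv(path)
        for col in ("age_group", "weight"):
            if col not in df.columns:
                raise ConfigurationError(f"{path}: standard population needs column {col!r}")
        return cls(df.set_index("age_group")["weight"])


def standardized_death_rate(deaths_by_age: pd.Series,
                            exposure_by_age: pd.Series,
                            std: StandardPopulation,
                            per: float = 1.0) -> float:
    """Directly standardized rate, per ``per`` person-years (default 1).

    Age groups with zero standard weight are ignored.  Zero exposure with
    positive weight is an error if deaths are positive there; with zero
    deaths the age group contributes a zero rate.
    """
    w = std.weights[std.weights > 0]
    deaths = pd.Series(deaths_by_age, dtype=float).reindex(w.index)
    exposure = pd.Series(exposure_by_age, dtype=float).reindex(w.index)
    if deaths.isna().any() or exposure.isna().any():
        raise DataValidationError(
            "deaths/exposures missing for age groups with positive standard weight"
        )
    bad = (exposure <= 0) & (deaths > 0)
    if bad.any():
        raise UndefinedRateError(
            f"zero exposure with positive deaths in age groups {list(deaths.index[bad])}"
        )
    rates = (deaths / exposure.where(exposure > 0)).fillna(0.0)
    return float((w * rates).sum()) * per
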