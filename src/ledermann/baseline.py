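"""Proportional redistribution (PR), the comparator method.

Ill-defined deaths are reassigned to the well-defined causes in proportion
to their observed shares of the well-defined total.  PR assumes every cause
is equally likely to end up in the ill-defined category — the assumption the
regression-based method relaxes.  The same formula applies at national and
area level; both entry points are provided.
"""

from __future__ import annotations

import pandas as pd

from .data_model import DeathsTable
from .errors import DataValidationError, NoReceivingCauseError


def proportional_redistribution(d_c: pd.Series, delta: float
                                ) -> tuple[pd.Series, pd.Series]:
    """PR-adjusted counts and coefficients for one unit (nation or area).

    Returns ``(D_c, coefficients)`` with coefficient_c = d_c / sum_k d_k and
    D_c = d_c + coefficient_c * delta; the total is conserved exactly.
    """
    if delta < 0:
        raise DataValidationError("ill-defined deaths must be non-negative")
    d = pd.Series(d_c, dtype=float)
    total = float(d.sum())
    if total <= 0:
        if delta > 0:
            raise NoReceivingCauseError(
                "all well-defined counts are zero; PR has no basis"
            )
        zero = pd.Series(0.0, index=d.index)
        return d.copy(), zero
    coeff = d / total
    return d + coeff * float(delta), coeff


def pr_table(table: DeathsTable) -> pd.DataFrame:
    """Area-wise PR: apply the PR formula independently in every area."""
    rows = {}
    for area in table.areas:
        D, _ = proportional_redistribution(
            table.well_defined.loc[area], float(table.delta[area])
        )
        rows[area] = D
    return pd.DataFrame.from_dict(rows, orient="index").reindex(table.areas)
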