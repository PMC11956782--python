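"""Subnational allocation of ill-defined deaths.

Each area g splits its ill-defined deaths delta_g across causes using
division weights p_c = Theta_c * d_cg (national dissimulation coefficient
times the area's reported count).  The allocation fractions
gamma_cg = p_c / sum_k p_k are invariant under any common positive scaling
of the weights, so a single normalization fixes the allocation:

    r_c = delta_g * gamma_cg,   D_cg = d_cg + r_c

and the adjusted shares satisfy Y^e_cg = Y_cg + gamma_cg * X_g.

Fractional counts are the default; largest-remainder apportionment turns an
area's r_c into integers that sum exactly to delta_g.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import DeathsTable
from .errors import DataValidationError
from .national import DissimulationCoefficients

logger = logging.getLogger(__name__)


@dataclass
class AreaAllocation:
    """Allocation of one area's ill-defined deaths across causes."""

    p: pd.Series          # division weights Theta_c * d_cg
    gamma: pd.Series      # allocation fractions, sum to 1 when any weight > 0
    r: pd.Series          # reallocated deaths, sum to delta_g
    D: pd.Series          # adjusted counts d_cg + r_c
    used_fallback: bool = False


@dataclass
class SubnationalAllocation:
    """Table-level allocation: all DataFrames are areas x well-defined causes."""

    p: pd.DataFrame
    gamma: pd.DataFrame
    r: pd.DataFrame
    D: pd.DataFrame
    Y_adj: pd.DataFrame          # adjusted shares D_cg / sum_k D_kg
    fallback_areas: list


def allocate_area(d_cg: pd.Series, delta_g: float,
                  theta: DissimulationCoefficients,
                  fallback_weights: pd.Series | None = None) -> AreaAllocation:
    """Split one area's delta_g across causes by weights Theta_c * d_cg.

    If every weight is zero while delta_g > 0 (the area reports deaths only
    for causes with Theta_c = 0, or reports only ill-defined deaths), the
    allocation falls back to ``fallback_weights`` — typically the national
    m'_c — with a logged warning.
    """
    if delta_g < 0:
        raise DataValidationError("ill-defined deaths must be non-negative")
    d = pd.Series(d_cg, dtype=float)
    th = theta.theta.reindex(d.index)
    if th.isna().any():
        raise DataValidationError("dissimulation coefficients missing for some causes")
    p = th * d
    total = float(p.sum())
    used_fallback = False
    if total > 0:
        gamma = p / total
    elif delta_g == 0:
        gamma = pd.Series(0.0, index=d.index)
    else:
        if fallback_weights is None:
            raise DataValidationError(
                "no positive division weights and no fallback weights supplied"
            )
        fb = pd.Series(fallback_weights, dtype=float).reindex(d.index)
        if fb.isna().any() or float(fb.sum()) <= 0:
            raise DataValidationError("fallback weights invalid for this cause set")
        logger.warning("area has zero division weights; falling back to national coefficients")
        gamma = fb / float(fb.sum())
        used_fallback = True
    r = float(delta_g) * gamma
    return AreaAllocation(p=p, gamma=gamma, r=r, D=d + r, used_fallback=used_fallback)


def allocate_table(table: DeathsTable, theta: DissimulationCoefficients,
                   fallback_weights: pd.Series | None = None) -> SubnationalAllocation:
    """Apply :func:`allocate_area` to every area of a stratum's table."""
    rows_p, rows_g, rows_r, rows_D, fallback = {}, {}, {}, {}, []
    for area in table.areas:
        alloc = allocate_area(table.well_defined.loc[area], float(table.delta[area]),
                              theta, fallback_weights)
        rows_p[area], rows_g[area] = alloc.p, alloc.gamma
        rows_r[area], rows_D[area] = alloc.r, alloc.D
        if alloc.used_fallback:
            fallback.append(area)
    p = pd.DataFrame.from_dict(rows_p, orient="index").reindex(table.areas)
    gamma = pd.DataFrame.from_dict(rows_g, orient="index").reindex(table.areas)
    r = pd.DataFrame.from_dict(rows_r, orient="index").reindex(table.areas)
    D = pd.DataFrame.from_dict(rows_D, orient="index").reindex(table.areas)
    totals = D.sum(axis=1)
    Y_adj = D.div(totals.where(totals > 0), axis=0).fillna(0.0)
    return SubnationalAllocation(p=p, gamma=gamma, r=r, D=D, Y_adj=Y_adj,
                                 fallback_areas=fallback)


def integerize_allocation(r_c, delta_g: float) -> np.ndarray:
    """Largest-remainder apportionment of fractional reallocated deaths.

    Returns an integer vector summing exactly to delta_g.  Ties in the
    fractional remainders are broken by cause order (earlier causes win).
    """
    r = np.asarray(pd.Series(r_c, dtype=float).to_numpy())
    if (r < -1e-9).any():
        raise DataValidationError("reallocated deaths must be non-negative")
    delta_int = round(float(delta_g))
    if abs(delta_g - delta_int) > 1e-9:
        raise DataValidationError("delta_g must be integral to integerize")
    if abs(r.sum() - delta_g) > 1e-6:
        raise DataValidationError("reallocated deaths do not sum to delta_g")
    base = np.floor(r + 1e-12).astype(int)
    leftover = delta_int - int(base.sum())
    if leftover > 0:
        remainders = r - base
        # stable argsort on negated remainders -> ties broken by first cause
        order = np.argsort(-remainders, kind="stable")
        base[order[:leftover]] += 1
    return base
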