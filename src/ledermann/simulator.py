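"""Synthetic subnational datasets with known ground truth, and method validation.

Generating model
----------------
Latent true cause shares Z_cg are independent normals per cause (clipped to
(0, 1)).  Area-level dissimulation draws theta*_cg are independent normals
with low variance.  Two regimes:

* ``enforce_zero_cov=True`` (assumption-conforming).  The candidate
  ill-defined share X* = sum_c theta*_cg Z_cg is residualized on the Z field
  so the sample covariance of X with every Z_c is exactly zero (the
  independence assumption, enforced in-sample).  The attribution of X to
  causes follows near-constant fractions lambda_cg = k_c(1+w_cg)/sum_k(...),
  where k_c = mean(theta* Z_c)/mean(X*) and w_cg is small relative noise
  (``attribution_cv``), so the uniform-registration assumption holds up to
  that noise.  The theta field is then defined by theta_cg = lambda_cg X_g / Z_cg.
  A per-area scaling adjustment was considered instead and rejected: it
  concentrates the attribution on causes with large Z^2 * var(theta) and
  biases the recovered slopes away from Z_c theta_c / X.
* ``enforce_zero_cov=False`` (violation regime).  theta*_cg is used as-is,
  so X covaries with Z (cov(X, Z_c) = theta_c var(Z_c)) and the
  independence assumption fails — increasingly so as the theta variance is
  inflated.

In both regimes the accounting identities hold exactly by construction:
X_g = sum_c theta_cg Z_cg and Y_cg = Z_cg (1 - theta_cg).

Evaluation applies the full regression pipeline (per-cause OLS, truncation
and rescaling, national dissimulation coefficients, per-area allocation) and
proportional redistribution to the observed (X, Y), and scores the estimated
shares against the latent Z by RMSE, R^2 and the F statistic of the
estimated-on-true regression.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import yaml

from .baseline import proportional_redistribution
from .data_model import DeathsTable, ShareTable, StratumKey
from .errors import ConfigurationError, InsufficientDataError
from .national import (
    dissimulation_coefficients,
    fit_all_causes,
    raw_coefficients,
    truncate_and_rescale,
)
from .subnational import allocate_table, integerize_allocation

LEDERMANN = "ledermann"
PR = "pr"


@dataclass
class SimulationConfig:
    """Parameters of the generating model.

    Defaults emulate 95 areas (the size of the French department example)
    and three causes with a mean ill-defined share of about 0.10.
    """

    n_areas: int = 95
    z_means: tuple = (0.35, 0.30, 0.25)
    z_sds: tuple = (0.03, 0.03, 0.03)
    theta_means: tuple = (0.15, 0.10, 0.08)
    theta_sds: tuple = (0.01, 0.01, 0.01)
    attribution_cv: float = 0.03
    enforce_zero_cov: bool = True
    deaths_per_area: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.z_means = tuple(float(v) for v in self.z_means)
        self.z_sds = tuple(float(v) for v in self.z_sds)
        self.theta_means = tuple(float(v) for v in self.theta_means)
        self.theta_sds = tuple(float(v) for v in self.theta_sds)
        n = len(self.z_means)
        if not (len(self.z_sds) == len(self.theta_means) == len(self.theta_sds) == n):
            raise ConfigurationError("per-cause parameter vectors must share length")
        if n < 2:
            raise ConfigurationError("need at least two causes")
        if any(not (0 < m < 1) for m in self.z_means):
            raise ConfigurationError("z_means must lie in (0, 1)")
        if any(m < 0 or m >= 1 for m in self.theta_means):
            raise ConfigurationError("theta_means must lie in [0, 1)")
        if any(s < 0 for s in self.z_sds + self.theta_sds):
            raise ConfigurationError("standard deviations must be non-negative")
        if any(m + 3 * s >= 1 for m, s in zip(self.theta_means, self.theta_sds)):
            raise ConfigurationError(
                "theta_mean + 3*theta_sd must stay below 1 (clipping would distort draws)"
            )
        if self.n_areas < 2:
            raise ConfigurationError("need at least two areas")
        if self.enforce_zero_cov and self.n_areas < n + 2:
            raise ConfigurationError(
                f"zero-covariance enforcement needs at least n_causes+2={n + 2} areas"
            )
        if self.attribution_cv < 0:
            raise ConfigurationError("attribution_cv must be non-negative")

    @property
    def n_causes(self) -> int:
        return len(self.z_means)

    @property
    def causes(self) -> list[str]:
        return [f"cause_{i + 1}" for i in range(self.n_causes)]

    @property
    def expected_x_mean(self) -> float:
        """Population mean ill-defined share, sum_c theta_mean_c * z_mean_c."""
        return float(np.dot(self.theta_means, self.z_means))

    @property
    def expected_m(self) -> pd.Series:
        """Population redistribution coefficients Z_c theta_c / X_bar."""
        prod = np.asarray(self.theta_means) * np.asarray(self.z_means)
        return pd.Series(prod / prod.sum(), index=self.causes)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown simulation config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class SimulatedDataset:
    """Latent truth (Z, theta) and derived observables (X, Y) for one draw."""

    Z: pd.DataFrame
    theta: pd.DataFrame
    X: pd.Series
    Y: pd.DataFrame
    config: SimulationConfig

    def to_share_table(self) -> ShareTable:
        return ShareTable(X=self.X.copy(), Y=self.Y.copy())

    def to_deaths_table(self, total_per_area: int,
                        illdefined: str = "ill-defined") -> DeathsTable:
        """Integer death counts: renormalize (Y, X) per area and apportion.

        The latent shares need not close to one (Z draws are independent),
        so the observed composition (Y_1..Y_n, X) is renormalized before
        being turned into counts by largest-remainder apportionment.
        """
        comp = self.Y.copy()
        comp[illdefined] = self.X
        comp = comp.div(comp.sum(axis=1), axis=0)
        rows = {
            area: integerize_allocation(comp.loc[area] * total_per_area, total_per_area)
            for area in comp.index
        }
        counts = pd.DataFrame.from_dict(rows, orient="index")
        counts.columns = comp.columns
        return DeathsTable(counts.astype(float), illdefined,
                           stratum=StratumKey(0, "all", "all"))


def _residualize_keep_mean(x: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Remove the in-sample projection of x on [1, Z]; restore the mean."""
    design = np.column_stack([np.ones(len(x)), Z])
    beta, *_ = np.linalg.lstsq(design, x, rcond=None)
    return x - design @ beta + x.mean()


def simulate_dataset(config: SimulationConfig,
                     seed: int | None = None) -> SimulatedDataset:
    """Draw one synthetic dataset; reproducible given (config, seed)."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n, N = config.n_causes, config.n_areas
    areas = [f"area_{i + 1:04d}" for i in range(N)]
    eps = 1e-9
    Z = rng.normal(config.z_means, config.z_sds, size=(N, n)).clip(eps, 1 - eps)
    theta_raw = rng.normal(config.theta_means, config.theta_sds, size=(N, n)).clip(0.0, 1 - eps)
    x_star = (theta_raw * Z).sum(axis=1)

    if not config.enforce_zero_cov:
        theta = theta_raw
        X = x_star
    elif x_star.mean() == 0.0:
        theta = np.zeros_like(theta_raw)
        X = np.zeros(N)
    else:
        X = _residualize_keep_mean(x_star, Z)
        if (X <= 0).any():
            raise ConfigurationError(
                "residualized ill-defined share is non-positive; "
                "theta variance too large relative to its mean"
            )
        k = (theta_raw * Z).mean(axis=0) / x_star.mean()
        w = rng.normal(0.0, config.attribution_cv, size=(N, n))
        lam = k * (1.0 + w)
        if (lam <= 0).any():
            raise ConfigurationError("attribution_cv too large; attribution went negative")
        lam /= lam.sum(axis=1, keepdims=True)
        theta = lam * X[:, None] / Z
        if (theta >= 1).any():
            raise ConfigurationError("derived theta reached 1; infeasible configuration")

    Y = Z * (1.0 - theta)
    causes = config.causes
    return SimulatedDataset(
        Z=pd.DataFrame(Z, index=areas, columns=causes),
        theta=pd.DataFrame(theta, index=areas, columns=causes),
        X=pd.Series((theta * Z).sum(axis=1), index=areas, name="X"),
        Y=pd.DataFrame(Y, index=areas, columns=causes),
        config=config,
    )


# ---------------------------------------------------------------------------
# method application and scoring


def estimate_shares_ledermann(shares: ShareTable) -> tuple[pd.DataFrame, dict]:
    """Full pipeline on observed shares: per-area estimated true shares.

    Areas are weighted equally when forming the national aggregate (the
    simulated shares carry no death totals).  Returns the estimates and a
    detail dict with the fitted coefficients.
    """
    fits = fit_all_causes(shares)
    m_raw = raw_coefficients(fits)
    coeffs = truncate_and_rescale(m_raw)
    d_c = shares.Y.mean(axis=0)
    delta = float(shares.X.mean())
    theta = dissimulation_coefficients(d_c, delta, coeffs)
    p = shares.Y.mul(theta.theta, axis=1)
    totals = p.sum(axis=1)
    gamma = p.div(totals.where(totals > 0), axis=0).fillna(0.0)
    estimates = shares.Y + gamma.mul(shares.X, axis=0)
    details = {
        "fits": fits,
        "m_hat": m_raw,
        "a_hat": pd.Series({c: f.intercept for c, f in fits.items()}),
        "sum_m_hat": float(m_raw.sum()),
        "coefficients": coeffs,
        "theta": theta,
    }
    return estimates, details


def estimate_shares_pr(shares: ShareTable) -> pd.DataFrame:
    """Proportional redistribution on observed shares, area by area."""
    well_defined_total = shares.Y.sum(axis=1)
    frac = shares.Y.div(well_defined_total.where(well_defined_total > 0), axis=0).fillna(0.0)
    return shares.Y + frac.mul(shares.X, axis=0)


def rmse(estimate, truth) -> float:
    """Root mean square error between estimated and true shares."""
    e = np.asarray(estimate, dtype=float)
    t = np.asarray(truth, dtype=float)
    if e.shape != t.shape:
        raise ConfigurationError("estimate and truth must share shape")
    return float(np.sqrt(np.mean((e - t) ** 2)))


def _fit_statistics(estimate: np.ndarray, truth: np.ndarray) -> tuple[float, float]:
    """R^2 and F statistic of the OLS regression of estimate on truth."""
    if np.allclose(estimate, truth):
        return 1.0, float("inf")
    if np.ptp(truth) == 0.0:
        return float("nan"), float("nan")
    res = sm.OLS(estimate, sm.add_constant(truth)).fit()
    return float(res.rsquared), float(res.fvalue)


@dataclass
class EvaluationResult:
    """Per-method, per-cause (plus pooled) fit metrics for one dataset."""

    metrics: pd.DataFrame          # columns: method, cause, rmse, r_squared, f_statistic
    estimates: dict
    m_hat: pd.Series
    a_hat: pd.Series
    sum_m_hat: float

    def pooled_rmse(self, method: str) -> float:
        sel = self.metrics[(self.metrics["method"] == method)
                           & (self.metrics["cause"] == "pooled")]
        return float(sel["rmse"].iloc[0])

    def cause_rmse(self, method: str) -> pd.Series:
        sel = self.metrics[(self.metrics["method"] == method)
                           & (self.metrics["cause"] != "pooled")]
        return sel.set_index("cause")["rmse"]


def evaluate_methods(dataset: SimulatedDataset) -> EvaluationResult:
    """Score the regression method and PR against the latent truth."""
    if dataset.config.n_areas < 3:
        raise InsufficientDataError("evaluation needs at least 3 areas")
    shares = dataset.to_share_table()
    est_led, details = estimate_shares_ledermann(shares)
    est_pr = estimate_shares_pr(shares)
    truth = dataset.Z
    rows = []
    for method, est in ((LEDERMANN, est_led), (PR, est_pr)):
        for cause in truth.columns:
            e, t = est[cause].to_numpy(), truth[cause].to_numpy()
            r2, fstat = _fit_statistics(e, t)
            rows.append({"method": method, "cause": cause,
                         "rmse": rmse(e, t),
                         "r_squared": r2, "f_statistic": fstat})
        e, t = est.to_numpy().ravel(), truth.to_numpy().ravel()
        r2, fstat = _fit_statistics(e, t)
        rows.append({"method": method, "cause": "pooled",
                     "rmse": rmse(e, t),
                     "r_squared": r2, "f_statistic": fstat})
    return EvaluationResult(
        metrics=pd.DataFrame(rows),
        estimates={LEDERMANN: est_led, PR: est_pr},
        m_hat=details["m_hat"],
        a_hat=details["a_hat"],
        sum_m_hat=details["sum_m_hat"],
    )


# ---------------------------------------------------------------------------
# scenarios


def replicate_seed(base_seed: int, rep: int) -> list[int]:
    """Deterministic per-replicate seed material (fed to SeedSequence)."""
    return [int(base_seed) % (2**31), int(rep)]


def run_replicates(config: SimulationConfig, n_reps: int,
                   base_seed: int = 0) -> pd.DataFrame:
    """Replicate-level summary: pooled and per-cause RMSE per method, sum m̂."""
    rows = []
    for rep in range(n_reps):
        ds = simulate_dataset(config, seed=replicate_seed(base_seed, rep))
        ev = evaluate_methods(ds)
        row = {"rep": rep, "sum_m_hat": ev.sum_m_hat}
        for method in (LEDERMANN, PR):
            row[f"rmse_{method}"] = ev.pooled_rmse(method)
            for cause, value in ev.cause_rmse(method).items():
                row[f"rmse_{method}_{cause}"] = value
        rows.append(row)
    return pd.DataFrame(rows)


def violation_config(config: SimulationConfig, sd_factor: float = 6.0
                     ) -> SimulationConfig:
    """High-theta-variance regime: inflate theta_sds, drop zero-cov enforcement."""
    return dataclasses.replace(
        config,
        theta_sds=tuple(s * sd_factor for s in config.theta_sds),
        enforce_zero_cov=False if sd_factor != 1.0 else config.enforce_zero_cov,
    )


def violation_scenario(config: SimulationConfig, n_reps: int = 100,
                       sd_factor: float = 6.0, base_seed: int = 0) -> pd.DataFrame:
    """Paired conforming-vs-violation comparison over shared replicate seeds.

    One row per replicate with the |sum m̂ - 1| diagnostic and pooled /
    per-cause RMSEs under both regimes (columns suffixed ``_conforming`` /
    ``_violation``).
    """
    conforming = run_replicates(config, n_reps, base_seed)
    violated = run_replicates(violation_config(config, sd_factor), n_reps, base_seed)
    merged = conforming.merge(violated, on="rep", suffixes=("_conforming", "_violation"))
    for col in ("sum_m_hat_conforming", "sum_m_hat_violation"):
        merged[col.replace("sum_m_hat", "sum_m_deviation")] = (merged[col] - 1.0).abs()
    return merged


def sensitivity_sweep(axis: str, grid: Sequence[float], reps: int,
                      base_config: SimulationConfig,
                      base_seed: int = 0) -> pd.DataFrame:
    """Replicate-averaged performance along one design axis.

    ``axis="n_areas"``: grid values are area counts.  ``axis="illdefined_share"``:
    grid values are target mean ill-defined shares; theta_means are scaled
    accordingly.  Grid points too small for the regression (or for the
    zero-covariance construction) are recorded as infeasible rather than run.
    """
    if axis not in ("n_areas", "illdefined_share"):
        raise ConfigurationError(f"unknown sweep axis {axis!r}")
    rows = []
    for value in grid:
        try:
            if axis == "n_areas":
                cfg = dataclasses.replace(base_config, n_areas=int(value))
                if cfg.n_areas < 3:
                    raise InsufficientDataError("regression needs >= 3 areas")
            else:
                scale = float(value) / base_config.expected_x_mean
                cfg = dataclasses.replace(
                    base_config,
                    theta_means=tuple(m * scale for m in base_config.theta_means),
                    theta_sds=tuple(s * scale for s in base_config.theta_sds),
                )
        except (ConfigurationError, InsufficientDataError) as exc:
            rows.append({"axis": axis, "value": value, "feasible": False,
                         "note": str(exc), "rmse_ledermann": float("nan"),
                         "rmse_pr": float("nan"), "gap_pr_minus_ledermann": float("nan")})
            continue
        reps_df = run_replicates(cfg, reps, base_seed)
        rows.append({
            "axis": axis, "value": value, "feasible": True, "note": "",
            "rmse_ledermann": float(reps_df["rmse_ledermann"].mean()),
            "rmse_pr": float(reps_df["rmse_pr"].mean()),
            "gap_pr_minus_ledermann": float((reps_df["rmse_pr"]
                                             - reps_df["rmse_ledermann"]).mean()),
        })
    return pd.DataFrame(rows)
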