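# Methods

## Model and procedure

Each stratum — one (year, sex, age group) combination — is processed
independently.  Within a stratum, for areas g = 1..N and well-defined causes
c = 1..n, the latent quantity of interest is Z_cg, the true share of cause c
in area g's deaths.  A fraction Θ_cg of those deaths is registered as
ill-defined, so the observables are

    X_g = Σ_c Θ_cg · Z_cg        (ill-defined share)
    Y_cg = Z_cg · (1 − Θ_cg)     (observed cause share)

Two assumptions make Z estimable from (X, Y):

* **A1 (independence).** X_g is independent of Z_cg, and the regression
  residuals are normal without outliers.  Not directly testable (Z is
  latent); its observable consequences are monitored by the diagnostics.
* **A2 (uniform registration).** The attribution fraction
  Z_cgΘ_cg / X_g is approximately the same in every area, i.e. coding
  practice does not vary much geographically.

Under A1–A2, the per-cause unweighted OLS fit Y_cg = a_c − m_c X_g + ε has

    m̂_c → Z̄_c Θ̄_c / X̄     and     â_c → Z̄_c,

and the m̂_c sum to one in theory.  Empirically the sum drifts from one
(sampling noise, assumption failure), so negative coefficients are truncated
to zero — causes whose share *rises* with ill-defined coding cannot receive
deaths — and the remainder rescaled to m′_c with unit sum.  The rescaling
divides by the truncated sum, which reproduces published coefficient tables;
the signed and truncated sums are both reported by the diagnostics.  National
adjusted counts are D_c = d_c + m′_c δ (total conserved exactly), and the
dissimulation coefficient Θ_c = m′_c δ / D_c.

Subnationally, area g's ill-defined deaths are divided with weights
p_c = Θ_c d_cg.  The original formulation describes an iterative rescaling
p′_c = p_c(1 + δ_g/Σp_k); because that factor is common to all causes, the
normalized fractions γ_cg = p_c/Σp_k are invariant under it, so a single
normalization is implemented and the rounding concern the iteration was
meant to address is handled explicitly by largest-remainder apportionment
(ties broken by cause order).  The adjusted shares satisfy the identity
Yᵉ_cg = Y_cg + γ_cg X_g.  When an area has no positive division weight but
δ_g > 0 (deaths reported only for causes with Θ_c = 0), the allocation falls
back to the national m′_c with a logged warning; when an entire stratum has
no receiving cause (all m̂ ≤ 0), it falls back to PR coefficients and is
flagged.  Zero-total areas are excluded from the regressions but retained in
outputs unchanged.

Proportional redistribution — coefficient_c = d_c/Σd, identical formula
nationally and per area — is the comparator throughout.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `smooth_span` | 1.0 | LOWESS window as a fraction of the age range, in (0, 1]; tricube-weighted locally linear fit of each cause's m_c on the age-group index, followed by re-truncation/rescaling per age.  Smoothing is off by default and a no-op with fewer than two fitted ages. |
| `check_sum_m` threshold | 0.10 | flag when the truncated Σm̂ deviates from 1 by more than this. |
| outlier threshold | 3.0 | flag areas with standardized residual beyond ±3; normality is summarized by the Jarque–Bera statistic and never used to exclude data. |
| `rate_per` | 100 000 | scale of standardized rates (per person-years). |
| standard population | uniform | weights over the supplied age groups unless a CSV standard is given; no external standard is bundled. |

Counts are carried as floats end to end; integerization (largest remainder,
exact per-area conservation) is opt-in at export.

## The simulation harness

`SimulationConfig` defaults describe 95 areas and three causes with
Z-means (0.35, 0.30, 0.25), Z-sds 0.03, Θ-means (0.15, 0.10, 0.08), Θ-sds
0.01 — a mean ill-defined share X̄ ≈ 0.10, comparable to the worked
example's 15.5% national stratum.  The published validation does not state
its parameter values, so these defaults are this package's own choices,
fixed once in the config dataclass.

**Conforming regime** (`enforce_zero_cov=True`).  Z is drawn as independent
normals.  Raw Θ* draws fix the scale of X* = ΣΘ*Z, which is then
residualized on the Z field so the sample covariance of X with every Z_c is
zero to machine precision (A1 exact in-sample).  X is attributed to causes
through fractions λ_cg = k_c(1+w_cg)/Σ_k k_k(1+w_kg), with
k_c = mean(Θ*Z_c)/mean(X*) and w_cg ~ N(0, `attribution_cv`); Θ_cg is then
λ_cg X_g / Z_cg.  A2 thus holds up to the attribution noise
(`attribution_cv` = 0.03, a modest geographic non-uniformity in coding).
A per-area *scaling* adjustment of the Θ field was considered and rejected:
one can show (and the prototype confirmed numerically) that it concentrates
the attribution in proportion to Z̄²·var(Θ) and biases m̂ away from
Z̄Θ̄/X̄, contradicting the identities the harness is meant to verify.

**Violation regime** (`enforce_zero_cov=False`, Θ-sds inflated ×6 by
default).  Raw Θ draws are used directly, so cov(X, Z_c) = Θ̄_c·var(Z_c) ≠ 0
and A1 fails; the inflated variance further destabilizes the slopes.  This
regime reproduces the expected failure signature: |Σm̂ − 1| grows by an
order of magnitude and per-cause recovery degrades.

Both regimes satisfy X = ΣΘZ and Y = Z(1−Θ) identically.  Z draws are *not*
renormalized to a unit sum (a `to_deaths_table` conversion renormalizes the
observed composition when integer counts are needed), so the generator
mirrors the independence structure of the validation design rather than
strict compositional closure.  Consequences for interpreting results:
passing tests demonstrate recovery under the stated assumptions, not
robustness to real-data features the generator omits — spatial correlation
of coding practice, Poisson noise in small counts, more than three causes,
or age/period structure.

Evaluation scores estimated against true shares by RMSE, and by the R² and
F statistic of the OLS regression of estimate on truth (the fit-comparison
regression is a design choice; a perfect fit reports R² = 1 with infinite
F).  Parameter-recovery checks compare replicate means of m̂, â against the
generator's population values Z̄Θ̄/Σ Z̄Θ̄ and Z̄ within 3 Monte-Carlo
standard errors; per-dataset empirical means were deliberately not used as
targets because E[X/Z] ≠ X̄/Z̄ introduces a Jensen-type gap of the same
order as the Monte-Carlo error.

Problem sizes used by the test suite and the acceptance script — 100 paired
replicates at N = 95 for the method comparison and violation contrast, 60
replicates at N = 1000 for parameter recovery, 30 replicates per grid point
for the sensitivity sweeps — were chosen to keep Monte-Carlo error well
below the effect sizes being tested while remaining quick to run.

## Numerical choices and degenerate inputs

* OLS via statsmodels; an independent closed-form two-variable oracle guards
  it in the tests.  Regression requires ≥3 retained areas and non-constant X.
* The zero-covariance construction requires N ≥ n+2 areas (the
  residualization consumes n+1 degrees of freedom).
* Largest-remainder ties: earlier cause wins (stable sort); documented and
  tested.
* Θ = 0/0 (no deaths, nothing redistributed) is defined as 0.
* Exact fits (residuals < 1e-10 on the share scale) are flagged degenerate
  in the outlier report instead of producing meaningless standardized
  residuals.
* Missing (area, cause) cells in long-format input are an error unless the
  schema opts into zero-filling; age-group order is taken from the schema
  (lexical order, with a warning, otherwise).

## Known limitations

* Regressions are unweighted across areas; population-size weighting is a
  plausible extension, not implemented.
* The method borrows strength from the national Θ_c (A2); no area-specific
  regression is attempted, and genuinely heterogeneous coding across areas
  violates the premise (the covariance diagnostic is the monitoring tool).
* Aggregating adjusted subnational counts reproduces the national adjustment
  exactly only for compositionally homogeneous areas; heterogeneity leaves a
  small gap (≈1% relative in conforming simulations).
* Standardization uses whatever age groups the input provides; no
  within-band refinement.
* Cause labels are opaque strings: ICD grouping, revision bridging and data
  download are the caller's responsibility.
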