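import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ledermann import (
    ShareTable,
    dissimulation_coefficients,
    fit_all_causes,
    fit_cause_regression,
    raw_coefficients,
    redistribute_national,
    smooth_coefficients_over_age,
    truncate_and_rescale,
)
from ledermann.errors import (
    DataValidationError,
    DegenerateDesignError,
    InsufficientDataError,
    NoReceivingCauseError,
)


def share_table(X, **causes):
    X = pd.Series(X, dtype=float)
    Y = pd.DataFrame({k: pd.Series(v, dtype=float) for k, v in causes.items()})
    return ShareTable(X=X, Y=Y)


def closed_form_ols(x, y):
    """Independent two-variable OLS oracle: slope and intercept."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    slope = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
    return y.mean() - slope * x.mean(), slope


class TestFitCauseRegression:
    def test_exact_collinear_points(self):
        shares = share_table([0.1, 0.2, 0.3], c=[0.5, 0.4, 0.3])
        fit = fit_cause_regression(shares, "c")
        assert fit.slope == pytest.approx(-1.0, abs=1e-12)
        assert fit.intercept == pytest.approx(0.6, abs=1e-12)
        assert fit.m == pytest.approx(1.0, abs=1e-12)

    def test_flat_response_gives_zero_slope(self):
        shares = share_table([0.1, 0.2, 0.3, 0.4], c=[0.2, 0.2, 0.2, 0.2])
        fit = fit_cause_regression(shares, "c")
        assert fit.slope == pytest.approx(0.0, abs=1e-14)
        assert fit.m == pytest.approx(0.0, abs=1e-14)
        assert fit.intercept == pytest.approx(0.2, abs=1e-14)

    @given(st.integers(0, 200))
    @settings(max_examples=25, deadline=None)
    def test_matches_closed_form_oracle_on_random_fixtures(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0.01, 0.4, size=5)
        if np.ptp(x) == 0:  # pragma: no cover - measure-zero
            return
        y = rng.uniform(0.0, 0.6, size=5)
        fit = fit_cause_regression(share_table(x, c=y), "c")
        a, b = closed_form_ols(x, y)
        assert fit.slope == pytest.approx(b, abs=1e-10)
        assert fit.intercept == pytest.approx(a, abs=1e-10)

    def test_fitted_plus_residuals_reproduce_observations(self, rng):
        x = rng.uniform(0.05, 0.3, size=8)
        y = rng.uniform(0.0, 0.5, size=8)
        shares = share_table(x, c=y)
        fit = fit_cause_regression(shares, "c")
        recon = fit.fitted(shares.X) + fit.residuals
        np.testing.assert_allclose(recon.to_numpy(), y, atol=1e-12)
        assert abs(fit.residuals.sum()) < 1e-10

    def test_constant_x_is_degenerate(self):
        with pytest.raises(DegenerateDesignError):
            fit_cause_regression(share_table([0.2, 0.2, 0.2], c=[0.1, 0.2, 0.3]), "c")

    def test_two_areas_insufficient(self):
        with pytest.raises(InsufficientDataError):
            fit_cause_regression(share_table([0.1, 0.2], c=[0.3, 0.4]), "c")


class TestTruncateAndRescale:
    def test_worked_example_adjusted_coefficients(self, worked_example):
        coeffs = truncate_and_rescale(worked_example["slopes"])
        assert coeffs.sum_m_raw == pytest.approx(1.026, abs=1e-12)
        assert coeffs.m_prime["suicides"] == pytest.approx(0.447, abs=5e-4)
        assert coeffs.m_prime["accidents"] == pytest.approx(0.212, abs=5e-4)
        assert coeffs.m_prime["neoplasms"] == 0.0
        assert coeffs.m_prime.sum() == pytest.approx(1.0, abs=1e-12)

    def test_unit_sum_input_unchanged(self):
        coeffs = truncate_and_rescale(pd.Series({"a": 0.5, "b": 0.5}))
        assert coeffs.m_prime.tolist() == [0.5, 0.5]

    def test_negative_coefficient_truncated_then_rescaled(self):
        coeffs = truncate_and_rescale(pd.Series({"a": -0.1, "b": 0.6, "c": 0.5}))
        assert coeffs.m_prime["a"] == 0.0
        assert coeffs.m_prime["b"] == pytest.approx(0.6 / 1.1, abs=1e-12)
        assert coeffs.m_prime["c"] == pytest.approx(0.5 / 1.1, abs=1e-12)

    def test_no_receiving_cause_raises(self):
        with pytest.raises(NoReceivingCauseError):
            truncate_and_rescale(pd.Series({"a": -0.2, "b": 0.0}))

    @given(st.lists(st.floats(-1, 1, allow_nan=False, allow_subnormal=False),
                    min_size=2, max_size=8))
    @settings(max_examples=50, deadline=None)
    def test_rescaled_coefficients_are_a_distribution(self, values):
        m = pd.Series(values, index=[f"c{i}" for i in range(len(values))])
        if m.clip(lower=0).sum() <= 0:
            with pytest.raises(NoReceivingCauseError):
                truncate_and_rescale(m)
            return
        coeffs = truncate_and_rescale(m)
        assert (coeffs.m_prime >= 0).all()
        assert coeffs.m_prime.sum() == pytest.approx(1.0, abs=1e-12)
        # non-positive raw coefficients receive nothing, positive ones do
        assert ((m <= 0) == (coeffs.m_prime == 0)).all()


class TestRedistributeNational:
    def test_worked_example_suicides_and_neoplasms(self, worked_example):
        coeffs = truncate_and_rescale(worked_example["slopes"])
        D = redistribute_national(worked_example["deaths"], worked_example["delta"], coeffs)
        # printed column uses coefficients reported at 3 d.p.; +-1 death slack
        assert D["suicides"] == pytest.approx(1370, abs=1.0)
        assert D["neoplasms"] == 1166.0
        assert D.sum() == pytest.approx(worked_example["total"], abs=1e-9)

    def test_zero_illdefined_is_identity(self, worked_example):
        coeffs = truncate_and_rescale(worked_example["slopes"])
        D = redistribute_national(worked_example["deaths"], 0.0, coeffs)
        pd.testing.assert_series_equal(D, worked_example["deaths"], check_names=False)

    def test_conservation_exact(self, rng):
        d = pd.Series(rng.integers(0, 500, size=6).astype(float),
                      index=[f"c{i}" for i in range(6)])
        coeffs = truncate_and_rescale(pd.Series(rng.uniform(0, 1, 6), index=d.index))
        delta = 137.0
        D = redistribute_national(d, delta, coeffs)
        assert D.sum() == pytest.approx(d.sum() + delta, abs=1e-9)

    def test_monotone_in_delta_for_receiving_causes(self, worked_example):
        coeffs = truncate_and_rescale(worked_example["slopes"])
        d = worked_example["deaths"]
        lo = redistribute_national(d, 100.0, coeffs)
        hi = redistribute_national(d, 200.0, coeffs)
        receiving = coeffs.m_prime > 0
        assert (hi[receiving] > lo[receiving]).all()
        assert (hi[~receiving] == lo[~receiving]).all()

    def test_mismatched_causes_raise(self, worked_example):
        coeffs = truncate_and_rescale(worked_example["slopes"])
        with pytest.raises(DataValidationError):
            redistribute_national(pd.Series({"x": 1.0}), 10.0, coeffs)


class TestDissimulationCoefficients:
    def test_worked_example_suicides(self, worked_example):
        coeffs = truncate_and_rescale(worked_example["slopes"])
        theta = dissimulation_coefficients(
            worked_example["deaths"], worked_example["delta"], coeffs).theta
        assert theta["suicides"] == pytest.approx(0.302, abs=1e-3)
        assert theta["neoplasms"] == 0.0
        assert ((theta >= 0) & (theta <= 1)).all()

    def test_zero_coefficient_gives_zero_theta_and_vice_versa(self, worked_example):
        coeffs = truncate_and_rescale(worked_example["slopes"])
        theta = dissimulation_coefficients(
            worked_example["deaths"], worked_example["delta"], coeffs).theta
        assert ((theta == 0) == (coeffs.m_prime == 0)).all()

    def test_all_deaths_hidden_boundary(self):
        coeffs = truncate_and_rescale(pd.Series({"a": 1.0, "b": 0.0}))
        theta = dissimulation_coefficients(
            pd.Series({"a": 0.0, "b": 5.0}), 10.0, coeffs).theta
        assert theta["a"] == 1.0

    def test_zero_over_zero_defined_as_zero(self):
        coeffs = truncate_and_rescale(pd.Series({"a": 1.0, "b": 0.0}))
        theta = dissimulation_coefficients(
            pd.Series({"a": 3.0, "b": 0.0}), 0.0, coeffs).theta
        assert theta["b"] == 0.0


class TestSmoothing:
    def ages(self, series_list):
        return [pd.Series(v, index=["a", "b", "c"]) for v in series_list]

    def test_constant_series_preserved(self):
        m = self.ages([[0.3, 0.5, 0.2]] * 4)
        out = smooth_coefficients_over_age(m, span=1.0)
        for coeffs in out:
            assert coeffs.m_prime["a"] == pytest.approx(0.3, abs=1e-10)

    def test_linear_series_reproduced_by_local_linear_fit(self):
        base = np.linspace(0.1, 0.4, 6)
        m = [pd.Series({"a": v, "b": 0.5 - v, "c": 0.5}) for v in base]
        out = smooth_coefficients_over_age(m, span=0.6)
        raw = np.array([c.m_raw["a"] for c in out])
        np.testing.assert_allclose(raw, base, atol=1e-8)

    def test_disabled_smoothing_is_identity_up_to_rescaling(self):
        m = self.ages([[0.2, 0.2, 0.6], [0.6, 0.2, 0.2]])
        out = smooth_coefficients_over_age(m, enabled=False)
        direct = [truncate_and_rescale(v) for v in m]
        for got, want in zip(out, direct):
            pd.testing.assert_series_equal(got.m_prime, want.m_prime)

    def test_each_age_rescaled_to_unit_sum(self):
        rng = np.random.default_rng(5)
        m = [pd.Series(rng.uniform(0, 1, 3), index=["a", "b", "c"]) for _ in range(5)]
        for coeffs in smooth_coefficients_over_age(m, span=0.8):
            assert coeffs.m_prime.sum() == pytest.approx(1.0, abs=1e-12)

    def test_single_age_group_warns_and_passes_through(self):
        m = self.ages([[0.4, 0.4, 0.2]])
        with pytest.warns(UserWarning):
            out = smooth_coefficients_over_age(m, span=1.0)
        assert out[0].m_prime["a"] == pytest.approx(0.4, abs=1e-12)


def test_sum_m_prime_is_one_for_every_random_stratum(rng):
    # unit-sum invariant across many random strata
    for _ in range(20):
        m = pd.Series(rng.normal(0.2, 0.3, size=5), index=[f"c{i}" for i in range(5)])
        if m.clip(lower=0).sum() <= 0:
            continue
        assert truncate_and_rescale(m).m_prime.sum() == pytest.approx(1.0, abs=1e-12)


def test_parameter_recovery_matches_generating_model():
    """Slopes and intercepts recover Z*theta/X and Z on conforming data.

    At N=1000 areas, the replicate-mean m_hat and a_hat must sit within
    3 Monte-Carlo standard errors of the generator's population values.
    """
    from ledermann import SimulationConfig, simulate_dataset
    from ledermann.simulator import replicate_seed

    config = SimulationConfig(n_areas=1000)
    reps = 60
    m_hats, a_hats = [], []
    for rep in range(reps):
        ds = simulate_dataset(config, seed=replicate_seed(11, rep))
        fits = fit_all_causes(ds.to_share_table())
        m_hats.append(raw_coefficients(fits))
        a_hats.append(pd.Series({c: f.intercept for c, f in fits.items()}))
    m_hats, a_hats = pd.DataFrame(m_hats), pd.DataFrame(a_hats)
    m_err = (m_hats.mean() - config.expected_m.to_numpy()).abs()
    m_se = m_hats.std() / np.sqrt(reps)
    assert (m_err <= 3 * m_se).all(), f"m recovery off: {m_err / m_se}"
    a_err = (a_hats.mean() - np.asarray(config.z_means)).abs()
    a_se = a_hats.std() / np.sqrt(reps)
    assert (a_err <= 3 * a_se).all(), f"a recovery off: {a_err / a_se}"
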