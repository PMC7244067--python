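import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from rbcage.calibration import (
    compare_group_fits,
    correlation_p_value,
    correlation_t_stat,
    fit_loglinear,
    invert_model,
    load_model,
    published_model,
    save_model,
)
from rbcage.cohort import generate_empirical, generate_mechanistic
from rbcage.exceptions import (
    DegenerateDesignError,
    InsufficientDataError,
    InvalidMeasurementError,
    InvalidParameterError,
    NonInvertibleError,
)


def t_tail_oracle(t, df):
    """Independent two-sided t tail: direct numerical integral of the density."""
    c = math.gamma((df + 1) / 2) / (math.sqrt(df * math.pi) * math.gamma(df / 2))
    pdf = lambda x: c * (1 + x * x / df) ** (-(df + 1) / 2)
    tail, _ = quad(pdf, t, np.inf)
    return 2 * tail


class TestFit:
    def test_exact_line_recovery(self):
        m = np.array([10.0, 30.0, 55.0])
        ec = np.exp(-0.04379 * m + 2.882)
        model = fit_loglinear(m, ec)
        assert model.slope == pytest.approx(-0.04379, abs=1e-10)
        assert model.intercept == pytest.approx(2.882, abs=1e-10)
        assert model.r == pytest.approx(-1.0, abs=1e-10)
        assert model.ec_range_seen == (float(ec.min()), float(ec.max()))

    def test_noiseless_cohort_round_trip(self):
        t = generate_empirical(n=21, sigma=0.0, seed=5)
        model = fit_loglinear(t.true_mrbc_days, t.ec_umol_ghb)
        assert model.slope == pytest.approx(-0.04379, abs=1e-10)
        assert model.intercept == pytest.approx(2.882, abs=1e-10)

    def test_noisy_cohort_correlation_realistic(self):
        t = generate_empirical(n=21, sigma=0.2133, seed=1)
        model = fit_loglinear(t.true_mrbc_days, t.ec_umol_ghb)
        assert 0.85 < abs(model.r) < 0.99
        assert model.n == 21 and model.df == 19

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            fit_loglinear([1.0, 2.0], [1.0, 2.0])

    def test_nonpositive_ec(self):
        with pytest.raises(InvalidMeasurementError):
            fit_loglinear([1.0, 2.0, 3.0], [1.0, 0.0, 2.0])

    def test_degenerate_design(self):
        with pytest.raises(DegenerateDesignError):
            fit_loglinear([5.0, 5.0, 5.0], [1.0, 2.0, 3.0])


class TestCorrelationStats:
    def test_reference_t_statistic(self):
        assert round(correlation_t_stat(0.9475, 19), 2) == 12.92

    @pytest.mark.parametrize("r, df, expected", [(0.0, 19, 0.0), (0.5, 16, 2.3094)])
    def test_t_values(self, r, df, expected):
        assert correlation_t_stat(r, df) == pytest.approx(expected, abs=1e-4)

    def test_t_undefined_at_perfect_correlation(self):
        with pytest.raises(InvalidParameterError):
            correlation_t_stat(1.0, 19)

    def test_p_boundaries(self):
        assert correlation_p_value(0.0, 19) == pytest.approx(1.0)
        with pytest.raises(InvalidParameterError):
            correlation_p_value(1.0, 0)

    @pytest.mark.parametrize("t, df", [(12.9162, 19), (2.093, 19), (2.5, 5)])
    def test_p_against_tail_integral_oracle(self, t, df):
        assert correlation_p_value(t, df) == pytest.approx(
            t_tail_oracle(t, df), rel=1e-6
        )

    def test_reference_p_order_of_magnitude(self):
        t = correlation_t_stat(0.9475, 19)
        p = correlation_p_value(t, df=19)
        assert 1e-11 < p < 1e-10

    def test_critical_value(self):
        # t = 2.093 is the two-sided 5% critical value at 19 df
        assert correlation_p_value(2.093, 19) == pytest.approx(0.05, abs=5e-4)


class TestInversion:
    def test_printed_slope_magnitude(self, published):
        inverted = invert_model(published)
        assert round(inverted.inv_slope, 2) == -22.84
        assert inverted.inv_intercept == pytest.approx(65.814, abs=5e-4)

    def test_trivial_inversion(self, published):
        import dataclasses

        m = dataclasses.replace(published, slope=-1.0, intercept=0.0)
        m = invert_model(m)
        assert m.inv_slope == -1.0 and m.inv_intercept == 0.0

    def test_zero_slope_not_invertible(self, published):
        import dataclasses

        with pytest.raises(NonInvertibleError):
            invert_model(dataclasses.replace(published, slope=0.0))

    @settings(derandomize=True, max_examples=50)
    @given(
        a=st.floats(-0.2, -0.005),
        b=st.floats(0.5, 5.0),
        m=st.floats(1.0, 100.0),
    )
    def test_forward_then_inverse_round_trip(self, a, b, m):
        import dataclasses

        model = invert_model(
            dataclasses.replace(published_model(), slope=a, intercept=b)
        )
        ec = math.exp(a * m + b)
        back = model.inv_slope * math.log(ec) + model.inv_intercept
        assert back == pytest.approx(m, abs=1e-9)


class TestPublishedModel:
    def test_printed_constants(self, published):
        assert published.inv_slope == -22.84
        assert published.inv_intercept == 65.83
        assert published.df == published.n - 2 == 19
        assert published.ec_range_seen == (1.45, 11.76)
        assert published.r == -0.9475

    def test_fit_self_consistency(self):
        # stored t and p of any fitted model reproduce from r and df
        t = generate_empirical(n=21, sigma=0.2133, seed=9)
        model = fit_loglinear(t.true_mrbc_days, t.ec_umol_ghb)
        tt = correlation_t_stat(abs(model.r), model.df)
        assert tt == pytest.approx(model.t_stat, rel=1e-10)
        assert correlation_p_value(tt, model.df) == pytest.approx(
            model.p_value, rel=1e-10
        )


class TestGroupComparison:
    def test_shared_generating_line_unifies_exactly(self):
        t = generate_empirical(n=20, sigma=0.0, seed=2)
        report = compare_group_fits(t)
        s = [g["log_slope"] for g in report["groups"].values()]
        assert s[0] == pytest.approx(s[1], abs=1e-10)
        assert report["unification_score"] < 1e-9

    def test_mechanistic_cohort_unifies_on_log_scale(self):
        t = generate_mechanistic(n=40, L_range=(20.0, 120.0), ec_cv=0.0, seed=3)
        report = compare_group_fits(t)
        # linear-scale slopes of severe vs mild differ far more than the
        # log-scale slopes, and the pooled fit is better on the log scale
        assert report["linear_slope_rel_diff"] > 0.25
        assert report["log_slope_rel_diff"] < report["linear_slope_rel_diff"]
        assert report["unified"]
        assert report["pooled_log_r2"] > report["pooled_linear_r2"]

    def test_small_group_rejected(self):
        import pandas as pd

        t = pd.DataFrame(
            {
                "group": ["severe", "severe", "mild", "mild", "mild"],
                "true_mrbc_days": [10.0, 20.0, 30.0, 40.0, 50.0],
                "ec_umol_ghb": [9.0, 5.0, 3.0, 2.0, 1.5],
            }
        )
        with pytest.raises(InsufficientDataError):
            compare_group_fits(t)

    def test_missing_group_column(self):
        import pandas as pd

        t = pd.DataFrame({"true_mrbc_days": [1.0, 2.0, 3.0], "ec_umol_ghb": [1, 2, 3]})
        with pytest.raises(InvalidParameterError):
            compare_group_fits(t)


def test_model_json_round_trip(tmp_path, published):
    path = tmp_path / "model.json"
    save_model(published, path)
    loaded = load_model(path)
    assert loaded == published
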