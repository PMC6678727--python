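"""GM(1,1) fitting, time response and forecasting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import greymtd as gm
from greymtd.errors import (
    InsufficientDataError,
    NearZeroDevelopmentError,
    SingularSystemError,
)


def normal_equations_fit(values, weights):
    """Independent oracle: literal (B'B)^-1 B'Y in extended precision.

    Builds the accumulated series and weighted background values from
    scratch and solves the 2x2 normal equations explicitly with
    long-double arithmetic — no shared code with the package's QR path.
    """
    x = np.asarray(values, dtype=np.longdouble)
    w = np.asarray(weights, dtype=np.longdouble)
    x1 = np.cumsum(x)
    z = x1[:-1] + w[1:] * x[1:]
    B = np.column_stack([-z, np.ones_like(z)])
    Y = x[1:]
    BtB = B.T @ B
    BtY = B.T @ Y
    det = BtB[0, 0] * BtB[1, 1] - BtB[0, 1] * BtB[1, 0]
    a = (BtB[1, 1] * BtY[0] - BtB[0, 1] * BtY[1]) / det
    b = (BtB[0, 0] * BtY[1] - BtB[1, 0] * BtY[0]) / det
    return float(a), float(b)


class TestAccumulation:
    def test_partial_sums(self, example_window):
        np.testing.assert_allclose(
            gm.accumulate(example_window.values),
            [24.681, 47.893, 70.037, 91.888],
        )

    @pytest.mark.parametrize(
        "values, expected", [([1, 1, 1], [1, 2, 3]), ([5], [5])]
    )
    def test_small_cases(self, values, expected):
        np.testing.assert_array_equal(gm.accumulate(values), expected)

    def test_inverse_recovers_original(self, example_window):
        ago = gm.accumulate(example_window.values)
        np.testing.assert_allclose(
            gm.inverse_accumulate(ago), example_window.values
        )

    @settings(max_examples=100, derandomize=True)
    @given(
        st.lists(
            st.integers(min_value=0, max_value=10**6), min_size=1, max_size=30
        )
    )
    def test_round_trip_integer_exact(self, values):
        x = np.array(values, dtype=float)
        np.testing.assert_array_equal(gm.inverse_accumulate(gm.accumulate(x)), x)


class TestBackgroundValues:
    def test_worked_example(self, example_window):
        weights = gm.mtd_weights(example_window)
        ago = gm.accumulate(example_window.values)
        z = gm.background_values(example_window, ago, weights)
        np.testing.assert_allclose(z, [47.657, 65.369, 86.079], atol=1.5e-3)

    def test_half_weights_give_midpoints(self, example_window):
        ago = gm.accumulate(example_window.values)
        z = gm.background_values(
            example_window, ago, gm.classic_weights(len(example_window))
        )
        np.testing.assert_allclose(z, (ago[:-1] + ago[1:]) / 2)

    def test_unit_weights_give_current_ago(self, example_window):
        ago = gm.accumulate(example_window.values)
        z = gm.background_values(
            example_window, ago, gm.MembershipVector(np.ones(4))
        )
        np.testing.assert_allclose(z, ago[1:])


class TestFit:
    def test_worked_example_coefficients(self, example_window):
        f = gm.fit(example_window)
        assert round(f.a, 5) == 0.03483
        assert round(f.b, 5) == 24.71380

    def test_classic_baseline_matches_oracle(self, example_window):
        """Midpoint-background fit equals the conventional GM(1,1),
        cross-checked against the extended-precision normal equations."""
        f = gm.fit(example_window, weights=gm.classic_weights(4))
        a_ref, b_ref = normal_equations_fit(example_window.values, [0.5] * 4)
        assert f.a == pytest.approx(a_ref, rel=1e-10)
        assert f.b == pytest.approx(b_ref, rel=1e-10)
        # frozen oracle output for the 2007-2010 window
        assert f.a == pytest.approx(0.0305498, abs=1e-6)
        assert f.b == pytest.approx(24.196775, abs=1e-5)

    @settings(max_examples=150, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=1.0, max_value=1e3),
            min_size=4,
            max_size=10,
        ),
        st.floats(min_value=0.0, max_value=1.0),
    )
    def test_agrees_with_normal_equations_oracle(self, values, w):
        series = gm.TimeSeries(2000 + np.arange(len(values)), values)
        weights = gm.MembershipVector(np.full(len(values), w))
        try:
            f = gm.fit(series, weights=weights)
        except (SingularSystemError, NearZeroDevelopmentError):
            return
        a_ref, b_ref = normal_equations_fit(values, weights.weights)
        assert f.a == pytest.approx(a_ref, rel=1e-8, abs=1e-10)
        assert f.b == pytest.approx(b_ref, rel=1e-8, abs=1e-10)

    def test_too_few_points(self, make_series):
        with pytest.raises(InsufficientDataError):
            gm.fit(make_series([1, 2, 3]))

    def test_constant_series_has_zero_development(self, make_series):
        # the AGO of a constant series still grows, so the background is
        # not constant; the fit degenerates through a = 0 instead
        with pytest.raises(NearZeroDevelopmentError):
            gm.fit(make_series([5, 5, 5, 5]), weights=gm.classic_weights(4))

    def test_constant_background_is_singular(self, make_series):
        # zero weights and zeros after the first value pin every background
        # value at x(1)(1): rank-one design matrix
        with pytest.raises(SingularSystemError):
            gm.fit(
                make_series([5, 0, 0, 0]),
                weights=gm.MembershipVector(np.zeros(4)),
            )


class TestTimeResponse:
    def test_worked_example_constants(self, example_window):
        f = gm.fit(example_window)
        assert f.c_scale == pytest.approx(-684.91656, rel=1e-3)
        assert f.c_offset == pytest.approx(709.59756, rel=1e-3)

    def test_initial_condition(self, example_window):
        f = gm.fit(example_window)
        assert gm.time_response(f, 0) == pytest.approx(24.681)

    def test_monotone_toward_asymptote(self, example_window):
        f = gm.fit(example_window)  # a > 0: decline toward b/a from below
        x1 = f.time_response(np.arange(30))
        assert np.all(np.diff(x1) > 0)
        assert np.all(x1 < f.c_offset)

    def test_negative_k_rejected(self, example_window):
        f = gm.fit(example_window)
        with pytest.raises(gm.GreyModelError):
            gm.time_response(f, -1)


class TestForecast:
    def test_worked_example_one_step(self, example_window):
        f = gm.fit(example_window)
        assert f.forecast(1)[0] == pytest.approx(21.118, abs=1e-3)

    def test_geometric_ratio_identity(self, example_window):
        f = gm.fit(example_window)
        fc = f.forecast(6)
        ratios = fc[1:] / fc[:-1]
        np.testing.assert_allclose(ratios, np.exp(-f.a), rtol=1e-12)

    def test_sign_of_trend(self, make_series):
        declining = gm.fit(make_series([24.681, 23.212, 22.144, 21.851]))
        assert declining.a > 0
        assert np.all(np.diff(declining.forecast(5)) < 0)
        growing = gm.fit(make_series([10.0, 11.2, 12.4, 14.1]))
        assert growing.a < 0
        assert np.all(np.diff(growing.forecast(5)) > 0)

    def test_self_consistent_series_has_zero_residuals(self):
        """Data generated from the grey time response, fitted with the
        constant weight that makes the discrete equation consistent,
        recover the generating coefficients exactly.

        For exact exponential data the background weight that satisfies
        x(0)(k) + a z(1)(k) = b identically is the constant
        (a + e^-a - 1) / (a (1 - e^-a)).
        """
        a_true, b_true = 0.05, 25.0
        spec = gm.SyntheticSpec(a_true=a_true, b_true=b_true, x1=24.0, n=8)
        series = gm.generate(spec)
        mf_star = (a_true + np.exp(-a_true) - 1) / (a_true * (1 - np.exp(-a_true)))
        f = gm.fit(series, weights=gm.MembershipVector(np.full(8, mf_star)))
        assert f.a == pytest.approx(a_true, rel=1e-9)
        assert f.b == pytest.approx(b_true, rel=1e-9)
        residuals = series.values[1:] + f.a * f.background - f.b
        assert np.max(np.abs(residuals)) < 1e-9

    def test_parameter_recovery_noise_free(self):
        """On noise-free grey-exponential data the fitted development
        coefficient (with the package's own MTD weights) lands within 5%
        of the generating one."""
        spec = gm.SyntheticSpec(a_true=0.05, b_true=25.0, x1=24.0, n=8)
        f = gm.fit(gm.generate(spec))
        assert abs(f.a - spec.a_true) < 0.05 * spec.a_true
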