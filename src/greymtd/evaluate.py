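"""Rolling one-step backtesting, rolling multi-step forecasting, and
MAPE-based accuracy grading.

Two distinct rolling procedures are provided:

* :func:`backtest` slides a window of ACTUAL observations across the series
  and predicts each next period one step ahead — an honest out-of-sample
  pre-test.  Accuracy is summarised as the mean absolute percentage error
  (MAPE) and graded on the Lewis scale.
* :func:`rolling_forecast` extends past the end of the data: each one-step
  forecast is appended to the window and the oldest value dropped, so from
  the second step onward the windows are forecast-augmented.  This is the
  standard grey "rolling mechanism" for medium-term trend projection.

Membership weights are recomputed for every window — they depend on the
window's min, max and variance and are never reused across windows.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from . import grey
from .errors import GreyModelError
from .series import TimeSeries


class AccuracyGrade(enum.Enum):
    """Lewis interpretation of MAPE (in percent): <10 highly accurate,
    10-20 good, 20-50 reasonable, >=50 inaccurate."""

    HIGHLY_ACCURATE = "highly_accurate"
    GOOD = "good"
    REASONABLE = "reasonable"
    INACCURATE = "inaccurate"


def mape(actuals: np.ndarray, predictions: np.ndarray) -> float:
    """Mean absolute percentage error, returned as a fraction.

    (1/m) * sum |pred_i - actual_i| / actual_i.  Multiply by 100 for the
    conventional percent display.
    """
    actuals = np.asarray(actuals, dtype=np.float64)
    predictions = np.asarray(predictions, dtype=np.float64)
    if actuals.shape != predictions.shape or actuals.ndim != 1:
        raise GreyModelError("actuals and predictions must be equal-length vectors")
    if actuals.size == 0:
        raise GreyModelError("MAPE of zero points is undefined")
    if np.any(actuals == 0):
        raise GreyModelError("MAPE undefined when an actual value is zero")
    return float(np.mean(np.abs((predictions - actuals) / actuals)))


def grade(mape_percent: float) -> AccuracyGrade:
    """Lewis grade for a MAPE given in percent.

    Boundaries are half-open at the printed cut points: [10, 20) is good,
    [20, 50) reasonable, >= 50 inaccurate.
    """
    if mape_percent < 0:
        raise GreyModelError("MAPE cannot be negative")
    if mape_percent < 10:
        return AccuracyGrade.HIGHLY_ACCURATE
    if mape_percent < 20:
        return AccuracyGrade.GOOD
    if mape_percent < 50:
        return AccuracyGrade.REASONABLE
    return AccuracyGrade.INACCURATE


@dataclass(frozen=True)
class BacktestReport:
    """One-step-ahead rolling backtest results.

    ``ape`` holds per-period absolute percentage errors (fractions);
    ``mape`` is their mean, also a fraction.
    """

    periods: np.ndarray
    actuals: np.ndarray
    predictions: np.ndarray
    ape: np.ndarray
    mape: float
    grade: AccuracyGrade
    window: int

    @property
    def m(self) -> int:
        return len(self.predictions)

    @property
    def mape_percent(self) -> float:
        return 100.0 * self.mape


@dataclass(frozen=True)
class ForecastResult:
    """Rolling multi-step forecasts beyond the observed series.

    ``forecast_augmented[i]`` is False when the i-th step was fitted on a
    window of actual observations only (always the first step when starting
    from real data) and True once forecasts have entered the window.
    """

    periods: np.ndarray
    values: np.ndarray
    forecast_augmented: np.ndarray
    window: int


def backtest(
    series: TimeSeries,
    window: int = grey.MIN_WINDOW,
    background: str = "mtd",
    lb_skew: str = "sl",
) -> BacktestReport:
    """One-step-ahead rolling backtest on actual observations.

    For each period t from window+1 to n the model is fitted on the
    `window` actual values ending at t-1 (membership weights recomputed per
    window) and predicts period t; errors are summarised as MAPE with a
    Lewis grade.
    """
    n = len(series)
    if window < grey.MIN_WINDOW:
        raise GreyModelError(f"window must be >= {grey.MIN_WINDOW}")
    if n <= window:
        raise GreyModelError(
            f"series of length {n} leaves no test points for window {window}"
        )
    preds = []
    for stop in range(window, n):
        sub = TimeSeries(
            series.periods[stop - window : stop],
            series.values[stop - window : stop],
            units=series.units,
        )
        f = grey.fit(sub, weights=_weights_for(sub, background, lb_skew))
        preds.append(float(f.forecast(1)[0]))
    predictions = np.array(preds)
    actuals = series.values[window:]
    ape = np.abs((predictions - actuals) / actuals)
    m = mape(actuals, predictions)
    return BacktestReport(
        periods=series.periods[window:],
        actuals=actuals,
        predictions=predictions,
        ape=ape,
        mape=m,
        grade=grade(100.0 * m),
        window=window,
    )


def rolling_forecast(
    series: TimeSeries,
    window: int = grey.MIN_WINDOW,
    horizon: int = 1,
    background: str = "mtd",
    lb_skew: str = "sl",
) -> ForecastResult:
    """Forecast `horizon` future periods by the rolling mechanism.

    Starts from the `window` most recent actual observations; each step
    fits the model (recomputing membership weights), forecasts one period,
    appends the forecast to the window and drops the oldest value.
    """
    if horizon < 1:
        raise GreyModelError("horizon must be >= 1")
    if len(series) < window:
        raise GreyModelError(
            f"series of length {len(series)} is shorter than window {window}"
        )
    current = series.window(window)
    out_periods, out_values, augmented = [], [], []
    for step in range(horizon):
        try:
            f = grey.fit(current, weights=_weights_for(current, background, lb_skew))
            value = float(f.forecast(1)[0])
        except GreyModelError as err:
            raise GreyModelError(f"rolling step {step + 1}: {err}") from err
        out_periods.append(int(current.periods[-1]) + 1)
        out_values.append(value)
        augmented.append(step > 0)
        current = TimeSeries(
            np.append(current.periods[1:], current.periods[-1] + 1),
            np.append(current.values[1:], value),
            units=series.units,
        )
    return ForecastResult(
        periods=np.array(out_periods),
        values=np.array(out_values),
        forecast_augmented=np.array(augmented),
        window=window,
    )


def _weights_for(window: TimeSeries, background: str, lb_skew: str):
    """Resolve a background mode into a weight vector for one window."""
    if background == "mtd":
        from .mtd import mtd_weights

        return mtd_weights(window, lb_skew=lb_skew)
    if background == "classic":
        return grey.classic_weights(len(window))
    try:
        w = float(background)
    except ValueError:
        raise GreyModelError(
            f"background must be 'mtd', 'classic' or a weight in [0,1]; "
            f"got {background!r}"
        ) from None
    if not 0.0 <= w <= 1.0:
        raise GreyModelError(f"fixed background weight {w} outside [0, 1]")
    from .mtd import MembershipVector

    return MembershipVector(np.full(len(window), w))
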