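"""Time-series container for short annual (or otherwise consecutively
indexed) non-negative series.

The grey model operates on a raw series x(0)(1..n) of non-negative reals.
Period labels are integers (calendar years in the case study) and must be
strictly consecutive so that one-step-ahead forecasts have an unambiguous
label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import EmptySeriesError, GreyModelError


@dataclass(frozen=True)
class TimeSeries:
    """An ordered, consecutively labelled series of non-negative values.

    Parameters
    ----------
    periods
        Integer labels, strictly increasing by 1 (e.g. calendar years).
    values
        Non-negative observations, one per period.
    """

    periods: np.ndarray
    values: np.ndarray
    units: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        periods = np.asarray(self.periods, dtype=np.int64)
        values = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "periods", periods)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or periods.ndim != 1:
            raise GreyModelError("periods and values must be one-dimensional")
        if len(values) == 0:
            raise EmptySeriesError("series contains no observations")
        if len(periods) != len(values):
            raise GreyModelError(
                f"{len(periods)} periods but {len(values)} values"
            )
        if not np.all(np.isfinite(values)):
            raise GreyModelError("series values must be finite")
        if np.any(values < 0):
            bad = int(periods[np.argmax(values < 0)])
            raise GreyModelError(f"negative value at period {bad}")
        if len(periods) > 1 and not np.all(np.diff(periods) == 1):
            raise GreyModelError("periods must be strictly increasing and consecutive")

    def __len__(self) -> int:
        return len(self.values)

    def __getitem__(self, period: int) -> float:
        """Value at an integer period label."""
        idx = np.flatnonzero(self.periods == period)
        if idx.size == 0:
            raise KeyError(period)
        return float(self.values[idx[0]])

    @property
    def minimum(self) -> float:
        return float(self.values.min())

    @property
    def maximum(self) -> float:
        return float(self.values.max())

    def window(self, length: int, end: int | None = None) -> "TimeSeries":
        """Return the sub-series of `length` observations ending at period
        `end` (inclusive; default: the last period)."""
        if end is None:
            end = int(self.periods[-1])
        stop = np.flatnonzero(self.periods == end)
        if stop.size == 0:
            raise KeyError(end)
        stop_i = int(stop[0]) + 1
        if stop_i < length:
            raise GreyModelError(
                f"window of {length} ending at {end} exceeds available data"
            )
        return TimeSeries(
            self.periods[stop_i - length : stop_i],
            self.values[stop_i - length : stop_i],
            units=self.units,
        )

    def extended(self, value: float) -> "TimeSeries":
        """Append one value at the next consecutive period."""
        return TimeSeries(
            np.append(self.periods, self.periods[-1] + 1),
            np.append(self.values, value),
            units=self.units,
        )
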