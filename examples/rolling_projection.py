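"""Project five years beyond the data with the rolling mechanism.

Starting from the four most recent actual observations (2012-2015), each
step fits the MTD-weighted grey model, forecasts one year, appends the
forecast and drops the oldest value.  From the second step on, windows
contain the model's own forecasts — useful for trend reading, not for
point accuracy.
"""

import greymtd as gm

series = gm.china_so2()
result = gm.rolling_forecast(series, window=4, horizon=5)

print(f"{'year':>6} {'forecast':>9}  window contents")
for year, value, augmented in zip(
    result.periods, result.values, result.forecast_augmented
):
    source = "forecast-augmented" if augmented else "actuals only"
    print(f"{year:>6} {value:>9.3f}  {source}")

drop = 100 * (1 - result.values[-1] / series[2015])
print(f"\nProjected decline 2015 -> 2020: {drop:.1f}% "
      f"({series[2015]:.3f} -> {result.values[-1]:.3f} million tons)")
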