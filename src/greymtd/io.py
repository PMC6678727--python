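"""Reading delimited series files and serialising results.

The input dialect is a two-column delimited text file (default comma,
header row ``period,value``, UTF-8): integer period labels in the first
column, non-negative values in the second.  Parse failures report the
offending line number.

Serialisation offers two formats: ``json`` round-trips every quantity at
full floating precision; ``table`` is an aligned human-readable text block
that rounds for display (values 3 decimals, coefficients 5, MAPE 2) in the
style of the case study's tables.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np

from .errors import SeriesParseError
from .evaluate import BacktestReport, ForecastResult
from .grey import GreyFit
from .series import TimeSeries


def read_series(path: str | Path, delimiter: str = ",") -> TimeSeries:
    """Parse a two-column period/value file into a validated TimeSeries."""
    path = Path(path)
    periods: list[int] = []
    values: list[float] = []
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    start = 0
    if lines and _is_header(lines[0], delimiter):
        start = 1
    for lineno, raw in enumerate(lines[start:], start=start + 1):
        if not raw.strip():
            continue
        cells = [c.strip() for c in raw.split(delimiter)]
        if len(cells) != 2:
            raise SeriesParseError(
                f"expected 2 columns, found {len(cells)}", line=lineno
            )
        try:
            period = int(cells[0])
        except ValueError:
            raise SeriesParseError(
                f"period label {cells[0]!r} is not an integer", line=lineno
            ) from None
        try:
            value = float(cells[1])
        except ValueError:
            raise SeriesParseError(
                f"value {cells[1]!r} is not numeric", line=lineno
            ) from None
        if value < 0:
            raise SeriesParseError(f"negative value {value}", line=lineno)
        if periods and period != periods[-1] + 1:
            raise SeriesParseError(
                f"period {period} does not follow {periods[-1]} consecutively",
                line=lineno,
            )
        periods.append(period)
        values.append(value)
    if not periods:
        raise SeriesParseError(f"no data rows in {path}")
    return TimeSeries(np.array(periods), np.array(values))


def _is_header(line: str, delimiter: str) -> bool:
    first = line.split(delimiter)[0].strip()
    try:
        int(first)
        return False
    except ValueError:
        return True


def write_series(series: TimeSeries, path: str | Path, delimiter: str = ",") -> None:
    """Write a series in the standard two-column dialect."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"period{delimiter}value\n")
        for p, v in zip(series.periods, series.values):
            fh.write(f"{int(p)}{delimiter}{float(v)!r}\n")


def fit_payload(fit: GreyFit) -> dict[str, Any]:
    """JSON-ready view of a fitted model at full precision."""
    return {
        "model": {
            "a": fit.a,
            "b": fit.b,
            "scale": fit.c_scale,
            "offset": fit.c_offset,
        },
        "window": {
            "periods": fit.window.periods.tolist(),
            "values": fit.window.values.tolist(),
        },
        "membership": fit.weights.weights.tolist(),
        "background": fit.background.tolist(),
    }


def backtest_payload(report: BacktestReport) -> dict[str, Any]:
    return {
        "window": report.window,
        "periods": report.periods.tolist(),
        "actuals": report.actuals.tolist(),
        "predictions": report.predictions.tolist(),
        "ape": report.ape.tolist(),
        "mape_percent": report.mape_percent,
        "grade": report.grade.value,
    }


def forecast_payload(result: ForecastResult) -> dict[str, Any]:
    return {
        "window": result.window,
        "periods": result.periods.tolist(),
        "forecasts": result.values.tolist(),
        "provenance": [
            "forecast-augmented" if f else "actuals-only"
            for f in result.forecast_augmented
        ],
    }


def render(payload: dict[str, Any], fmt: str = "json") -> str:
    """Serialise a payload as JSON (lossless) or an aligned text table."""
    if fmt == "json":
        return json.dumps(payload, indent=2)
    if fmt == "table":
        return _render_table(payload)
    raise ValueError(f"unknown output format {fmt!r}")


def _render_table(payload: dict[str, Any]) -> str:
    lines: list[str] = []
    model = payload.get("model")
    if model:
        lines.append(f"a (development) = {model['a']:.5f}")
        lines.append(f"b (grey input)  = {model['b']:.5f}")
        lines.append(
            f"time response   : x1(k+1) = ({model['scale']:.5f})"
            f"*exp(-{model['a']:.5f}*k) + {model['offset']:.5f}"
        )
    if "membership" in payload:
        mf = "  ".join(f"{w:.4f}" for w in payload["membership"])
        lines.append(f"membership      : {mf}")
    if "predictions" in payload:
        lines.append(f"{'period':>8} {'actual':>10} {'predicted':>10} {'APE%':>8}")
        for p, y, yh, e in zip(
            payload["periods"],
            payload["actuals"],
            payload["predictions"],
            payload["ape"],
        ):
            lines.append(f"{p:>8} {y:>10.3f} {yh:>10.3f} {100 * e:>8.2f}")
        lines.append(f"MAPE = {payload['mape_percent']:.2f}%  ({payload['grade']})")
    if "forecasts" in payload:
        lines.append(f"{'period':>8} {'forecast':>10}  provenance")
        for p, v, src in zip(
            payload["periods"], payload["forecasts"], payload["provenance"]
        ):
            lines.append(f"{p:>8} {v:>10.3f}  {src}")
    return "\n".join(lines)
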