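"""Bundled case-study data and a synthetic-series generator.

``china_so2`` returns China's annual sulfur dioxide emissions 2007-2015
(million tons, National Bureau of Statistics of China) — the nine-point
series used throughout the package's worked examples and tests.

``generate`` produces series that follow the grey model's own exponential
time-response dynamics exactly, optionally perturbed by multiplicative
Gaussian noise.  A multiplicative noise model keeps small-noise series
positive and matches the relative-error metric (MAPE) used to judge fits.
It is test scaffolding: real emission series are not noisy realisations of
an exact exponential.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .errors import GreyModelError
from .io import read_series
from .series import TimeSeries


def china_so2() -> TimeSeries:
    """China's sulfur dioxide emissions 2007-2015 in million tons."""
    path = resources.files("greymtd.data").joinpath("china_so2.csv")
    with resources.as_file(path) as p:
        series = read_series(p)
    return TimeSeries(series.periods, series.values, units="million tons")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic grey-consistent series.

    The noise-free series is x(1) = x1, and for k >= 2 the first difference
    of ``(x1 - b/a) e^{-a (k-1)} + b/a`` — i.e. data the GM(1,1) time
    response reproduces exactly.  Each value after the first is multiplied
    by (1 + eps_k), eps_k ~ Normal(0, noise_sd^2).
    """

    a_true: float
    b_true: float
    x1: float
    n: int
    noise_sd: float = 0.0
    seed: int = 0
    start_period: int = 2000

    def __post_init__(self) -> None:
        if self.n < 4:
            raise GreyModelError("synthetic series needs n >= 4")
        if self.noise_sd < 0:
            raise GreyModelError("noise_sd must be non-negative")
        if self.x1 <= 0:
            raise GreyModelError("x1 must be positive")
        if abs(self.a_true) < 1e-12:
            raise GreyModelError("a_true must be nonzero")


def generate(spec: SyntheticSpec) -> TimeSeries:
    """Generate a synthetic series under `spec`.

    Deterministic when noise_sd = 0 (the seed is then irrelevant); byte-
    identical for identical spec + seed.  Raises if noise drives a value
    negative — retry with a smaller noise_sd.
    """
    offset = spec.b_true / spec.a_true
    scale = spec.x1 - offset
    k = np.arange(spec.n, dtype=float)
    x1 = scale * np.exp(-spec.a_true * k) + offset
    values = np.diff(x1, prepend=0.0)
    values[0] = spec.x1
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        values = values * (1.0 + rng.normal(0.0, spec.noise_sd, size=spec.n))
    if np.any(values < 0):
        raise GreyModelError(
            "noise produced a negative value; use a smaller noise_sd"
        )
    periods = spec.start_period + np.arange(spec.n)
    return TimeSeries(periods, values)
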