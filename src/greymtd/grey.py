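"""GM(1,1) grey model with membership-weighted background values.

The grey model fits the whitened differential equation
``dx(1)/dt + a*x(1) = b`` to the accumulated (cumulative-sum) series x(1) of
a short raw series x(0).  Its discrete form ``x(0)(k) + a*z(1)(k) = b`` uses
a background value z(1)(k) that interpolates between consecutive accumulated
values.  Conventionally z(1)(k) is the midpoint; here it is

    z(1)(k) = x(1)(k-1) + MF_k * x(0)(k),

where MF_k is the triangular mega-trend-diffusion membership of the k-th
observation — an observation close to the sample's central location pulls
the background value toward the newer datum.  Setting every MF_k = 0.5
recovers the classic GM(1,1) exactly.

The two coefficients (a: development coefficient, b: grey input) are
estimated by ordinary least squares on the n-1 discrete equations, and the
forecast follows from the exponential time response with initial condition
x(1)(1) = x(0)(1):

    x_hat(1)(k+1) = (x(0)(1) - b/a) e^{-a k} + b/a,
    x_hat(0)(k+1) = x_hat(1)(k+1) - x_hat(1)(k).

a > 0 yields geometrically decaying forecasts (ratio e^{-a}); a < 0 growth.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import (
    GreyModelError,
    InsufficientDataError,
    NearZeroDevelopmentError,
    SingularSystemError,
)
from .mtd import MembershipVector, mtd_weights
from .series import TimeSeries

#: Below this |a| the time response (which divides by a) is refused.
MIN_DEVELOPMENT = 1e-12

#: Grey-theory convention: at least four observations per fit.
MIN_WINDOW = 4


def accumulate(values: np.ndarray) -> np.ndarray:
    """Accumulated generating operation (AGO): running cumulative sums."""
    return np.cumsum(np.asarray(values, dtype=np.float64))


def inverse_accumulate(cumulative: np.ndarray) -> np.ndarray:
    """Inverse AGO: first differences with the first element kept."""
    cumulative = np.asarray(cumulative, dtype=np.float64)
    if cumulative.size == 0:
        raise GreyModelError("cannot difference an empty series")
    return np.diff(cumulative, prepend=0.0)


def background_values(
    series: TimeSeries, ago: np.ndarray, weights: MembershipVector
) -> np.ndarray:
    """Membership-weighted background values z(1)(k) for k = 2..n.

    z(1)(k) = x(1)(k-1) + MF_k * x(0)(k).  With all weights 0.5 this is the
    conventional midpoint (x(1)(k-1) + x(1)(k)) / 2.
    """
    if len(weights) != len(series):
        raise GreyModelError(
            f"{len(weights)} weights for {len(series)} observations"
        )
    if len(series) < 2:
        raise GreyModelError("background values need at least two observations")
    return ago[:-1] + weights.weights[1:] * series.values[1:]


@dataclass(frozen=True)
class GreyFit:
    """A fitted GM(1,1): coefficients, intermediates, and the window.

    ``c_scale`` and ``c_offset`` are the constants of the time response
    ``x_hat(1)(k+1) = c_scale * e^{-a k} + c_offset`` with
    c_scale = x(0)(1) - b/a and c_offset = b/a.
    """

    a: float
    b: float
    background: np.ndarray
    ago: np.ndarray
    window: TimeSeries
    weights: MembershipVector

    @property
    def c_offset(self) -> float:
        return self.b / self.a

    @property
    def c_scale(self) -> float:
        return float(self.window.values[0]) - self.b / self.a

    def time_response(self, k: int | np.ndarray) -> float | np.ndarray:
        """Accumulated-series prediction x_hat(1)(k+1) for k >= 0.

        k = 0 returns the initial condition x(0)(1) exactly.
        """
        out = self.c_scale * np.exp(-self.a * np.asarray(k, dtype=float)) + self.c_offset
        return float(out) if np.isscalar(k) else out

    def forecast(self, horizon: int = 1) -> np.ndarray:
        """Raw-series forecasts for the `horizon` periods after the window.

        Differences of the time response evaluated past the fitted window;
        consecutive forecasts have the exact ratio e^{-a}.  Negative
        forecasts are possible for extreme inputs and are returned as-is
        with a warning.
        """
        if horizon < 1:
            raise GreyModelError("forecast horizon must be >= 1")
        n = len(self.window)
        k = np.arange(n - 1, n + horizon)
        x1 = self.time_response(k)
        out = np.diff(x1)
        if np.any(out < 0):
            warnings.warn(
                "forecast produced negative values; the exponential grey "
                "model does not enforce non-negativity",
                stacklevel=2,
            )
        return out

    def fitted(self) -> np.ndarray:
        """In-sample reconstruction x_hat(0)(1..n) of the fitted window."""
        n = len(self.window)
        x1 = self.time_response(np.arange(n))
        return inverse_accumulate(x1)


def fit(
    series: TimeSeries,
    weights: MembershipVector | None = None,
    min_window: int = MIN_WINDOW,
) -> GreyFit:
    """Estimate the GM(1,1) coefficients by ordinary least squares.

    Stacks the n-1 discrete grey equations x(0)(k) = -a*z(1)(k) + b and
    solves the two-column system by QR-based least squares (equivalent to
    the normal-equations solution (B'B)^{-1} B'Y on well-conditioned data,
    but numerically stable).

    Parameters
    ----------
    series
        The window to fit; at least `min_window` (default 4) observations.
    weights
        Background-value weights.  Default: mega-trend-diffusion membership
        values recomputed on this window.
    """
    if min_window < MIN_WINDOW:
        raise GreyModelError(f"min_window cannot be below {MIN_WINDOW}")
    if len(series) < min_window:
        raise InsufficientDataError(
            f"grey fit needs at least {min_window} observations, got {len(series)}"
        )
    if weights is None:
        weights = mtd_weights(series)
    ago = accumulate(series.values)
    z = background_values(series, ago, weights)
    if np.ptp(z) == 0:
        raise SingularSystemError("constant background values; system is singular")
    design = np.column_stack([-z, np.ones_like(z)])
    y = series.values[1:]
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < 2:
        raise SingularSystemError("rank-deficient grey design matrix")
    a, b = float(coef[0]), float(coef[1])
    if abs(a) < MIN_DEVELOPMENT:
        raise NearZeroDevelopmentError(
            f"|a| = {abs(a):.3g} below {MIN_DEVELOPMENT}; time response undefined"
        )
    return GreyFit(a=a, b=b, background=z, ago=ago, window=series, weights=weights)


def classic_weights(n: int) -> MembershipVector:
    """Constant 0.5 weights: the conventional midpoint background."""
    return MembershipVector(np.full(n, 0.5))


def time_response(fit_: GreyFit, k: int) -> float:
    """Module-level alias for :meth:`GreyFit.time_response`."""
    if k < 0:
        raise GreyModelError("time index k must be >= 0")
    if abs(fit_.a) < MIN_DEVELOPMENT:
        raise NearZeroDevelopmentError("development coefficient is ~0")
    return float(fit_.time_response(k))


def forecast(fit_: GreyFit, horizon: int = 1) -> np.ndarray:
    """Module-level alias for :meth:`GreyFit.forecast`."""
    return fit_.forecast(horizon)
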