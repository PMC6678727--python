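"""Mega-trend-diffusion (MTD) data profile and triangular fuzzy membership.

MTD estimates a plausible range [LB, UB] around a small sample by diffusing
outward from the central location CL = (max + min)/2.  The diffusion distance
on each flank is scaled by the skew coefficients SU (share of observations
above CL) and SL (share below), the sample variance, and a fixed expansion
constant ln(1e-20).  A triangular membership function with apex at CL over
[LB_adj, UB_adj] then scores each observation in [0, 1] by its proximity to
CL.  These membership values weight the background values of the grey model;
the virtual-sample-generation use of MTD is out of scope here.

The raw bounds are clamped so that the adjusted interval always covers the
data: UB_adj = max(UB, max(x)), LB_adj = min(LB, min(x)).  The lower-bound
radical uses SL as its coefficient, mirroring the SU on the upper flank; the
mirrored literal form with SU on both flanks is available via
``lb_skew="su"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateDataError, EmptySeriesError, GreyModelError
from .series import TimeSeries

#: Fixed expansion coefficient ln(10^-20); controls how far the diffusion
#: bounds extend beyond the sample.
EXPANSION_COEFFICIENT: float = math.log(1e-20)


@dataclass(frozen=True)
class DiffusionProfile:
    """Mega-trend-diffusion summary of a small sample.

    Attributes
    ----------
    center
        Central location CL = (max + min) / 2.
    n_plus, n_minus
        Counts of observations strictly above / below CL.  Ties at CL are
        counted in neither.
    skew_upper, skew_lower
        SU = N+/(N+ + N-), SL = N-/(N+ + N-).
    variance
        Unbiased sample variance (denominator n - 1).
    ub_raw, lb_raw
        Diffusion bounds before clamping to the data range.
    ub_adj, lb_adj
        Adjusted bounds; always cover [min(x), max(x)].
    expansion
        The expansion constant ln(1e-20) actually used.
    """

    center: float
    n_plus: int
    n_minus: int
    skew_upper: float
    skew_lower: float
    variance: float
    ub_raw: float
    lb_raw: float
    ub_adj: float
    lb_adj: float
    expansion: float = EXPANSION_COEFFICIENT


@dataclass(frozen=True)
class MembershipVector:
    """Per-observation triangular membership values, ordered as the series."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        weights = np.asarray(self.weights, dtype=np.float64)
        object.__setattr__(self, "weights", weights)
        if np.any(weights < -1e-12) or np.any(weights > 1 + 1e-12):
            raise GreyModelError("membership values must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.weights)


def central_location(series: TimeSeries) -> float:
    """Midpoint of the sample extremes, CL = (max + min) / 2."""
    if len(series) == 0:  # defensive; TimeSeries forbids this
        raise EmptySeriesError("cannot locate the center of an empty series")
    return (series.maximum + series.minimum) / 2.0


def skew_profile(
    series: TimeSeries, center: float
) -> tuple[int, int, float, float]:
    """Counts and proportions of observations on each side of the center.

    Returns ``(n_plus, n_minus, skew_upper, skew_lower)`` where the counts
    use strict inequalities — an observation exactly at the center belongs
    to neither flank.
    """
    n_plus = int(np.sum(series.values > center))
    n_minus = int(np.sum(series.values < center))
    total = n_plus + n_minus
    if total == 0:
        raise DegenerateDataError(
            "all observations equal the central location; no skew profile"
        )
    return n_plus, n_minus, n_plus / total, n_minus / total


def sample_variance(series: TimeSeries) -> float:
    """Unbiased sample variance, sum((x - mean)^2) / (n - 1)."""
    if len(series) < 2:
        raise DegenerateDataError("variance needs at least two observations")
    return float(np.var(series.values, ddof=1))


def diffusion_bounds(
    series: TimeSeries, lb_skew: str = "sl"
) -> DiffusionProfile:
    """Compute the full mega-trend-diffusion profile of a sample.

    The diffusion distance on each flank is
    ``skew * sqrt(-2 * variance / count * ln(1e-20))`` with the flank's own
    skew coefficient and count; the raw bounds are then clamped outward so
    the adjusted interval covers the data.

    Parameters
    ----------
    series
        At least two observations, not all equal.
    lb_skew
        ``"sl"`` (default) uses SL as the lower-flank coefficient,
        symmetric with SU above; ``"su"`` uses SU on both flanks.
    """
    if lb_skew not in ("sl", "su"):
        raise GreyModelError(f"lb_skew must be 'sl' or 'su', got {lb_skew!r}")
    if len(series) < 2:
        raise DegenerateDataError("diffusion needs at least two observations")
    if series.maximum == series.minimum:
        raise DegenerateDataError("constant series admits no diffusion bounds")
    cl = central_location(series)
    n_plus, n_minus, su, sl = skew_profile(series, cl)
    if n_plus == 0 or n_minus == 0:
        raise DegenerateDataError(
            "one-sided sample: a flank has no observations, its diffusion "
            "distance is undefined"
        )
    var = sample_variance(series)
    ub_raw = cl + su * math.sqrt(-2.0 * var / n_plus * EXPANSION_COEFFICIENT)
    lo_coeff = sl if lb_skew == "sl" else su
    lb_raw = cl - lo_coeff * math.sqrt(
        -2.0 * var / n_minus * EXPANSION_COEFFICIENT
    )
    ub_adj = max(ub_raw, series.maximum)
    lb_adj = min(lb_raw, series.minimum)
    return DiffusionProfile(
        center=cl,
        n_plus=n_plus,
        n_minus=n_minus,
        skew_upper=su,
        skew_lower=sl,
        variance=var,
        ub_raw=ub_raw,
        lb_raw=lb_raw,
        ub_adj=ub_adj,
        lb_adj=lb_adj,
    )


def membership_values(
    series: TimeSeries, profile: DiffusionProfile
) -> MembershipVector:
    """Triangular membership of each observation, apex 1 at the center.

    For x <= CL the membership is (x - LB_adj)/(CL - LB_adj); for x > CL it
    is (UB_adj - x)/(UB_adj - CL).  Values at the adjusted bounds score 0,
    a value at CL scores 1.
    """
    cl = profile.center
    lo_width = cl - profile.lb_adj
    hi_width = profile.ub_adj - cl
    if lo_width <= 0 or hi_width <= 0:
        raise DegenerateDataError(
            "center coincides with a diffusion bound; zero-width flank"
        )
    x = series.values
    weights = np.where(
        x <= cl,
        (x - profile.lb_adj) / lo_width,
        (profile.ub_adj - x) / hi_width,
    )
    return MembershipVector(np.clip(weights, 0.0, 1.0))


def mtd_weights(series: TimeSeries, lb_skew: str = "sl") -> MembershipVector:
    """Convenience: diffusion profile + membership values in one call."""
    return membership_values(series, diffusion_bounds(series, lb_skew=lb_skew))
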