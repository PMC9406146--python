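"""Melting statistics: transition midpoints, inflection points, heat-capacity
peaks, window-convergence diagnostics and descriptor/temperature regressions.

The octamer-dissociation midpoint (the temperature where the fully
aggregated fraction crosses 1/2) is estimated by least-squares fit of a
logistic ``1/(1+exp((T-Tm)/s))``; the crossing of a monotone interpolation
serves as fallback and as an independent consistency check. β-content
profiles never reach 1, so their transition is summarized by the inflection
point of a scaled logistic ``a/(1+exp((T-Ti)/s)) + b`` instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks, savgol_filter
from scipy.stats import linregress

from .errors import OutOfRangeError
from .wham import TemperatureProfile

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MeltingSummary:
    """Headline statistics of one system."""

    T8m: float
    Ti_beta: float | None = None
    cv_peaks: tuple = ()
    converged: bool | None = None


@dataclass(frozen=True)
class ConvergenceSeries:
    """Per-window RMS deviations of f8(T) from the final window."""

    sigmas: np.ndarray
    converged: bool


@dataclass(frozen=True)
class LinearFit:
    slope: float
    intercept: float
    r: float
    sigma_residual: float


def _logistic(T, Tm, s):
    return 1.0 / (1.0 + np.exp(np.clip((T - Tm) / s, -500, 500)))


def _scaled_logistic(T, Ti, s, a, b):
    return a * _logistic(T, Ti, s) + b


def crossing_temperature(profile: TemperatureProfile,
                         level: float = 0.5) -> float:
    """Temperature of the (monotone-interpolated) crossing of ``level``.

    The profile is assumed decreasing overall; raises
    :class:`OutOfRangeError` when the level is never crossed.
    """
    v = profile.values
    if np.min(v) > level:
        raise OutOfRangeError("above grid")
    if np.max(v) < level:
        raise OutOfRangeError("below grid")
    # first downward crossing of a decreasing curve
    below = np.nonzero(v <= level)[0]
    i = below[0]
    if i == 0:
        return float(profile.grid[0])
    t0, t1 = profile.grid[i - 1], profile.grid[i]
    v0, v1 = v[i - 1], v[i]
    if v0 == v1:
        return float(t1)
    return float(t0 + (v0 - level) * (t1 - t0) / (v0 - v1))


def midpoint_temperature(profile: TemperatureProfile) -> float:
    """Logistic-fit midpoint of a sigmoidal dissociation profile."""
    t_cross = crossing_temperature(profile, 0.5)
    span = profile.grid[-1] - profile.grid[0]
    try:
        popt, _ = curve_fit(_logistic, profile.grid, profile.values,
                            p0=[t_cross, max(span / 20.0, 1.0)], maxfev=10000)
        tm = float(popt[0])
        if not profile.grid[0] <= tm <= profile.grid[-1]:
            raise RuntimeError("fitted midpoint outside grid")
        return tm
    except RuntimeError as exc:
        logger.warning("logistic fit failed (%s); using interpolated crossing",
                       exc)
        return t_cross


def inflection_temperature(profile: TemperatureProfile) -> float:
    """Maximum-|slope| temperature of a decaying (not necessarily 0-to-1)
    sigmoidal profile, via a scaled-logistic fit with derivative fallback."""
    if len(profile) < 5:
        raise ValueError("need at least 5 grid points")
    g, v = profile.grid, profile.values
    span = g[-1] - g[0]
    a0 = float(v.max() - v.min())
    p0 = [float(g[len(g) // 2]), max(span / 20.0, 1.0), a0, float(v.min())]
    try:
        if a0 <= 0:
            raise RuntimeError("flat profile")
        popt, _ = curve_fit(_scaled_logistic, g, v, p0=p0, maxfev=10000)
        ti, _, a, _ = popt
        if not g[0] <= ti <= g[-1] or a <= 0:
            raise RuntimeError("fit outside grid")
        return float(ti)
    except RuntimeError as exc:
        logger.warning("scaled-logistic fit failed (%s); using smoothed "
                       "derivative extremum", exc)
        window = min(len(v) - (len(v) + 1) % 2, 11)
        smooth = savgol_filter(v, window, 3) if window >= 5 else v
        slope = np.abs(np.gradient(smooth, g))
        # ties in |slope| (e.g. a linear profile) resolve to the middle
        cands = np.nonzero(slope >= slope.max() - 1e-12)[0]
        return float(g[cands[len(cands) // 2]])


def cv_peaks(profile: TemperatureProfile,
             prominence: float | None = None) -> list[float]:
    """Local maxima of a heat-capacity curve, sorted by height descending.

    ``prominence`` defaults to 5% of the curve's range.
    """
    if len(profile) < 5:
        raise ValueError("need at least 5 grid points")
    v = profile.values
    if prominence is None:
        prominence = 0.05 * (v.max() - v.min())
        if prominence == 0:
            return []
    idx, _ = find_peaks(v, prominence=prominence)
    order = np.argsort(v[idx])[::-1]
    return [float(profile.grid[i]) for i in idx[order]]


def window_convergence(per_window_profiles: list[TemperatureProfile],
                       rel_tol: float = 0.10) -> ConvergenceSeries:
    """RMS deviation of each window's f8(T) from the last window's.

    The run is deemed converged when the deviations have stopped
    decreasing: either the final two values differ by less than ``rel_tol``
    relative, or the tail is non-decreasing.
    """
    if len(per_window_profiles) < 3:
        raise ValueError("need at least 3 windows")
    last = per_window_profiles[-1]
    sigmas = []
    for prof in per_window_profiles[:-1]:
        if len(prof) != len(last) or not np.allclose(prof.grid, last.grid):
            raise ValueError("window profiles evaluated on mismatched grids")
        sigmas.append(float(np.sqrt(np.mean((prof.values - last.values) ** 2))))
    sigmas = np.array(sigmas)
    s_prev, s_last = sigmas[-2], sigmas[-1]
    converged = bool(
        abs(s_last - s_prev) <= rel_tol * max(s_prev, 1e-12)
        or s_last >= s_prev
    )
    return ConvergenceSeries(sigmas=sigmas, converged=converged)


def linear_correlation(x: np.ndarray, y: np.ndarray) -> LinearFit:
    """Ordinary least squares with Pearson R and residual SD (n-2 d.o.f.)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need at least 3 paired points")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x")
    res = linregress(x, y)
    residuals = y - (res.slope * x + res.intercept)
    sigma = float(np.sqrt(np.sum(residuals ** 2) / (len(x) - 2)))
    return LinearFit(slope=float(res.slope), intercept=float(res.intercept),
                     r=float(res.rvalue), sigma_residual=sigma)
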