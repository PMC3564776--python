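"""Melting-temperature estimation from thermal-shift fluorescence data.

A protein unfolding transition monitored with an environment-sensitive dye
(differential scanning fluorimetry) produces a sigmoidal fluorescence rise
with temperature. The midpoint Tm is estimated by nonlinear least squares on
the Boltzmann sigmoid

    F(T) = F_low + (F_high - F_low) / (1 + exp((Tm - T) / a))

where ``a`` (degrees C) sets the steepness of the transition. Fluorescence
past the maximum (dye release on aggregation) is excluded from the fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import (
    EmptyInputError,
    NoTransitionError,
    ParameterError,
    UnreliableFitWarning,
)


@dataclass
class MeltCurve:
    """One well's temperature-fluorescence series."""

    temperatures: np.ndarray
    fluorescence: np.ndarray
    well_id: str = ""

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.temperatures.size == 0:
            raise EmptyInputError("empty melt curve")
        if self.temperatures.shape != self.fluorescence.shape:
            raise ParameterError("temperature and fluorescence lengths differ")
        if self.temperatures.size < 10:
            raise ParameterError("melt curve needs at least 10 points")
        if not np.all(np.diff(self.temperatures) > 0):
            raise ParameterError("temperatures must be strictly increasing")

    def __len__(self) -> int:
        return self.temperatures.size


@dataclass
class BoltzmannFit:
    """Fitted Boltzmann parameters for one melt curve."""

    tm: float
    slope_a: float
    f_low: float
    f_high: float
    rss: float = 0.0
    converged: bool = False
    well_id: str = ""


def boltzmann_model(
    t: np.ndarray | float, tm: float, slope_a: float, f_low: float, f_high: float
) -> np.ndarray | float:
    """Evaluate the Boltzmann sigmoid at temperature(s) ``t``."""
    if slope_a == 0:
        raise ParameterError("slope parameter must be non-zero")
    z = np.clip((tm - np.asarray(t, dtype=float)) / slope_a, -500, 500)
    return f_low + (f_high - f_low) / (1.0 + np.exp(z))


def _smooth(y: np.ndarray, window: int = 5) -> np.ndarray:
    """Centered moving average used only to locate the transition region."""
    if window <= 1 or y.size < window:
        return y
    kernel = np.ones(window) / window
    pad = window // 2
    ypad = np.pad(y, pad, mode="edge")
    return np.convolve(ypad, kernel, mode="valid")


def fit_tm(curve: MeltCurve, smooth_window: int = 5, truncate_at_peak: bool = True) -> BoltzmannFit:
    """Fit the Boltzmann sigmoid to a melt curve and return the parameters.

    The fit is restricted to the region between the global minimum and the
    global maximum of a lightly smoothed copy of the curve, so that the
    post-peak aggregation decay does not distort the transition. Initial
    values: baselines from the 5th/95th percentiles of the region, Tm at the
    temperature of maximal finite-difference slope, slope 1 C. If the
    optimizer fails to converge, three deterministic restarts perturb the
    initial Tm by -5, +5 and -10 C.

    Raises :class:`NoTransitionError` for flat or falling curves and warns
    with :class:`UnreliableFitWarning` when the fitted Tm leaves the observed
    temperature range or the amplitude is not rising.
    """
    t = curve.temperatures
    f = curve.fluorescence
    smoothed = _smooth(f, smooth_window)
    amplitude = float(smoothed.max() - smoothed.min())
    if amplitude <= 0 or amplitude < 1e-9 * max(1.0, abs(float(smoothed.max()))):
        raise NoTransitionError(f"well {curve.well_id!r}: flat fluorescence trace")
    imin = int(np.argmin(smoothed))
    imax = int(np.argmax(smoothed))
    if imax <= imin:
        raise NoTransitionError(
            f"well {curve.well_id!r}: no rising transition (max precedes min)"
        )
    if truncate_at_peak:
        sl = slice(imin, imax + 1)
    else:
        sl = slice(None)
    tr, fr = t[sl], f[sl]
    if tr.size < 5:
        raise NoTransitionError(f"well {curve.well_id!r}: transition region too short")

    f_low0 = float(np.percentile(fr, 5))
    f_high0 = float(np.percentile(fr, 95))
    dfdt = np.diff(fr) / np.diff(tr)
    tm0 = float(tr[int(np.argmax(dfdt))])

    def residuals(p: np.ndarray) -> np.ndarray:
        tm, a, lo, hi = p
        return lo + (hi - lo) / (1.0 + np.exp(np.clip((tm - tr) / a, -500, 500))) - fr

    best = None
    for shift in (0.0, -5.0, 5.0, -10.0):
        x0 = np.array([tm0 + shift, 1.0, f_low0, f_high0])
        try:
            res = least_squares(residuals, x0, xtol=1e-8, ftol=1e-8, gtol=1e-8)
        except Exception:
            continue
        rss = float(np.sum(res.fun**2))
        if best is None or rss < best[1]:
            best = (res, rss)
        if res.success and rss <= 1e-6 * max(1.0, float(np.sum(fr**2))):
            break
    if best is None:
        raise NoTransitionError(f"well {curve.well_id!r}: optimizer failed")
    res, rss = best
    tm, a, lo, hi = (float(v) for v in res.x)
    # Normalize the sign ambiguity (tm, a, lo, hi) <-> mirrored parameterization.
    if a < 0:
        a, lo, hi = -a, hi, lo
    fit = BoltzmannFit(
        tm=tm,
        slope_a=a,
        f_low=lo,
        f_high=hi,
        rss=rss,
        converged=bool(res.success),
        well_id=curve.well_id,
    )
    if not (t[0] <= tm <= t[-1]):
        warnings.warn(
            f"well {curve.well_id!r}: fitted Tm {tm:.2f} C outside the observed range",
            UnreliableFitWarning,
            stacklevel=2,
        )
    if fit.f_low >= fit.f_high:
        warnings.warn(
            f"well {curve.well_id!r}: fitted baselines are not rising",
            UnreliableFitWarning,
            stacklevel=2,
        )
    return fit
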