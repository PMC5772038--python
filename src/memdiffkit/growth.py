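"""Growth-curve metrics: maximum specific growth rate and diauxic timing.

Yeast batch cultures on glucose grow exponentially (rate mu_max), deplete
the glucose, pass through a growth-rate minimum (the diauxic shift) and
resume slower respiratory growth.  Two summary metrics are computed from an
optical-density time series:

* the maximum specific growth rate, as the steepest log-linear window fit;
* the time of glucose depletion, proxied by the first local minimum of the
  smoothed instantaneous growth rate after the exponential phase.

Strongly inhibited cultures are flagged rather than forced through the
estimators ("non-exponential growth", "no growth in T hours").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import AnalysisError


@dataclass
class GrowthRateResult:
    mu_per_h: float | None
    window: tuple[float, float] | None
    r_squared: float | None
    flag: str | None

    @property
    def ok(self) -> bool:
        return self.mu_per_h is not None


@dataclass
class DepletionResult:
    time_h: float | None
    flag: str | None

    @property
    def ok(self) -> bool:
        return self.time_h is not None


def max_specific_growth_rate(
    times_h,
    od,
    window_h: float = 3.0,
    min_points: int = 5,
    r2_min: float = 0.98,
) -> GrowthRateResult:
    """Maximum slope of ln(OD) over sliding windows of ``window_h`` hours.

    Only windows with at least ``min_points`` points and a log-linear fit of
    r^2 >= ``r2_min`` qualify; if none do, the culture is flagged as
    non-exponential growth.
    """
    t = np.asarray(times_h, dtype=float)
    y = np.asarray(od, dtype=float)
    if np.any(y <= 0):
        raise AnalysisError("optical densities must be positive")
    if len(t) < min_points:
        raise AnalysisError(f"need at least {min_points} points")
    ln = np.log(y)
    best = None
    for i in range(len(t)):
        j = int(np.searchsorted(t, t[i] + window_h, side="right"))
        if j - i < min_points:
            continue
        if t[j - 1] - t[i] < 0.8 * window_h:  # stub window at the series end
            continue
        fit = stats.linregress(t[i:j], ln[i:j])
        r2 = fit.rvalue**2
        if r2 < r2_min or fit.slope <= 0:
            continue
        if best is None or fit.slope > best[0]:
            best = (fit.slope, (t[i], t[j - 1]), r2)
    if best is None:
        return GrowthRateResult(None, None, None, "non-exponential growth")
    return GrowthRateResult(float(best[0]), best[1], float(best[2]), None)


def _smooth(x: np.ndarray, width: int) -> np.ndarray:
    width = max(1, width)
    kernel = np.full(width, 1.0 / width)
    padded = np.r_[np.full(width // 2, x[0]), x, np.full(width - 1 - width // 2, x[-1])]
    return np.convolve(padded, kernel, mode="valid")


def instantaneous_growth_rate(times_h, od, smooth_h: float = 0.5) -> np.ndarray:
    """Smoothed d ln(OD)/dt via central differences (h^-1)."""
    t = np.asarray(times_h, dtype=float)
    y = np.asarray(od, dtype=float)
    if np.any(y <= 0):
        raise AnalysisError("optical densities must be positive")
    rate = np.gradient(np.log(y), t)
    dt = float(np.median(np.diff(t)))
    width = int(round(smooth_h / dt))
    if width % 2 == 0:  # keep the kernel symmetric: even widths shift extrema
        width += 1
    return _smooth(rate, width)


def time_to_glucose_depletion(
    times_h,
    od,
    window_h: float = 3.0,
    smooth_h: float = 0.5,
    growth_threshold: float = 1.5,
) -> DepletionResult:
    """Time of the diauxic growth-rate minimum after the exponential phase.

    The minimum of the smoothed instantaneous growth rate following the
    maximum-growth window is the glucose-depletion proxy.  A culture whose
    OD never exceeds ``growth_threshold`` times its starting value within
    the record gets a "no growth in T hours" flag instead of a time; a rate
    that only declines monotonically to the end of the record (no interior
    minimum) is also flagged.
    """
    t = np.asarray(times_h, dtype=float)
    y = np.asarray(od, dtype=float)
    if np.max(y) < growth_threshold * y[0]:
        return DepletionResult(None, f"no growth in {t[-1]:.0f} hours")
    growth = max_specific_growth_rate(t, y, window_h=window_h)
    rate = instantaneous_growth_rate(t, y, smooth_h=smooth_h)
    if growth.ok:
        start_t = 0.5 * (growth.window[0] + growth.window[1])
        start = int(np.searchsorted(t, start_t))
    else:
        start = int(np.argmax(rate))
    # the last few points carry one-sided-gradient and smoothing edge noise
    stop = len(rate) - 3
    if stop <= start:
        return DepletionResult(None, "no growth-rate minimum found in record")
    i = start + int(np.argmin(rate[start:stop]))
    if i in (0, start, stop - 1) and not (0 < i < len(rate) - 1 and rate[i] < rate[i + 1]):
        # minimum sits on the search boundary and the rate never recovers
        return DepletionResult(None, "no growth-rate minimum found in record")
    return DepletionResult(float(t[i]), None)
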