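"""Growth-curve fitting and nitrate/nitrite stoichiometry.

Fits are done on log2(OD) so the regression slope is doublings per hour and
the doubling time is its reciprocal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy import stats


@dataclass
class GrowthSeries:
    time_h: np.ndarray
    od600: np.ndarray
    condition: str = ""

    def __post_init__(self):
        self.time_h = np.asarray(self.time_h, dtype=float)
        self.od600 = np.asarray(self.od600, dtype=float)
        if self.time_h.shape != self.od600.shape:
            raise ValueError("time and OD arrays differ in length")
        if np.any(np.diff(self.time_h) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.od600 <= 0):
            raise ValueError("OD values must be positive")

    def __len__(self) -> int:
        return len(self.time_h)


@dataclass
class ChemSeries:
    time_h: np.ndarray
    nitrate_mM: np.ndarray
    nitrite_mM: np.ndarray

    def __post_init__(self):
        self.time_h = np.asarray(self.time_h, dtype=float)
        self.nitrate_mM = np.asarray(self.nitrate_mM, dtype=float)
        self.nitrite_mM = np.asarray(self.nitrite_mM, dtype=float)
        if not (len(self.time_h) == len(self.nitrate_mM) == len(self.nitrite_mM)):
            raise ValueError("chemistry arrays differ in length")
        if np.any(self.nitrate_mM < 0) or np.any(self.nitrite_mM < 0):
            raise ValueError("concentrations must be non-negative")


@dataclass(frozen=True)
class GrowthFit:
    doubling_time_h: float
    growth_rate_per_h: float  # ln(2) * slope, so doubling_time = ln2/rate
    window: Tuple[float, float]
    r_squared: float
    stderr: float  # propagated to the doubling time


@dataclass(frozen=True)
class StoichResult:
    slope: float
    intercept: float
    r_squared: float


def _window_r2_slope(t: np.ndarray, y: np.ndarray) -> Tuple[float, float]:
    """R^2 and slope of a straight-line fit (closed form)."""
    tm, ym = t.mean(), y.mean()
    st = t - tm
    sy = y - ym
    sst = float(st @ st)
    ssy = float(sy @ sy)
    if sst == 0:
        return 0.0, 0.0
    slope = float(st @ sy) / sst
    if ssy == 0:
        return 1.0, slope
    r2 = (float(st @ sy) ** 2) / (sst * ssy)
    return r2, slope


def detect_exponential_window(
    series: GrowthSeries, min_points: int = 4, r2_min: float = 0.99
) -> Tuple[int, int]:
    """Longest contiguous window (as an index pair, inclusive-exclusive) whose
    log2(OD)-vs-time fit has R^2 >= r2_min and positive slope; ties broken by
    earliest start."""
    n = len(series)
    if n < min_points:
        raise ValueError(f"need at least {min_points} points")
    y = np.log2(series.od600)
    t = series.time_h
    best: Optional[Tuple[int, int]] = None
    for i in range(0, n - min_points + 1):
        for j in range(i + min_points, n + 1):
            r2, slope = _window_r2_slope(t[i:j], y[i:j])
            if r2 >= r2_min and slope > 0:
                if best is None or (j - i) > (best[1] - best[0]):
                    best = (i, j)
    if best is None:
        raise ValueError(
            f"no exponential window with R^2 >= {r2_min}; try lowering r2_min"
        )
    return best


def fit_doubling_time(
    series: GrowthSeries,
    window: Optional[Tuple[int, int]] = None,
    min_points: int = 4,
    r2_min: float = 0.99,
) -> GrowthFit:
    """Least-squares doubling time from log2(OD) within the (auto-detected)
    exponential window."""
    if window is None:
        window = detect_exponential_window(series, min_points, r2_min)
    i, j = window
    if j - i < min_points:
        raise ValueError(f"window has fewer than {min_points} points")
    t = series.time_h[i:j]
    y = np.log2(series.od600[i:j])
    fit = stats.linregress(t, y)
    if fit.slope <= 0:
        raise ValueError("no growth detected (non-positive slope)")
    doubling = 1.0 / fit.slope
    return GrowthFit(
        doubling_time_h=doubling,
        growth_rate_per_h=math.log(2) * fit.slope,
        window=(float(t[0]), float(t[-1])),
        r_squared=float(fit.rvalue**2),
        stderr=float(fit.stderr) / fit.slope**2,
    )


def stoichiometry_fit(chem: ChemSeries) -> StoichResult:
    """Regression of nitrite produced on nitrate consumed (slope 1 means a
    1:1 conversion). Points with no consumption yet are excluded."""
    consumed = chem.nitrate_mM[0] - chem.nitrate_mM
    produced = chem.nitrite_mM - chem.nitrite_mM[0]
    mask = consumed > 0
    if not np.any(mask):
        raise ValueError("no nitrate consumption in series")
    x, y = consumed[mask], produced[mask]
    if len(x) < 2 or np.ptp(x) == 0:
        # degenerate but consumable: slope through the origin
        slope = float(y[-1] / x[-1])
        return StoichResult(slope, 0.0, 1.0)
    fit = stats.linregress(x, y)
    return StoichResult(float(fit.slope), float(fit.intercept), float(fit.rvalue**2))


def yield_ratio(treated: GrowthSeries, control: GrowthSeries) -> float:
    """Ratio of maximal OD reached (treated / control)."""
    return float(np.max(treated.od600) / np.max(control.od600))
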