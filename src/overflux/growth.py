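"""Growth-curve analysis: doubling times, biomass conversion, dose response.

Doubling time is estimated by ordinary least squares of ln(OD600) on time
over an exponential window; Td = ln 2 / slope.  When no window is given,
the maximal contiguous span of >= 3 points whose log-linear fit reaches
R^2 >= 0.99 is selected automatically (the fitting window is not prescribed
by the source study; this rule is the package's own and is configurable).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from math import log
from typing import Sequence

import numpy as np
from scipy import stats

from .core import Treatment
from .fluxmap import OD_TO_GDW_PER_L
from .inhibition import TestKind

__all__ = [
    "GrowthCurve",
    "DoseResponseFit",
    "doubling_time",
    "biomass_from_od",
    "dose_response",
    "growth_summary_ttest",
]


@dataclass
class GrowthCurve:
    """An OD600 time series under one treatment."""

    times: np.ndarray
    od600: np.ndarray
    treatment: Treatment = Treatment()

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od600 = np.asarray(self.od600, dtype=float)
        if self.times.size != self.od600.size:
            raise ValueError("times and od600 must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


class DoseResponseModel(str, Enum):
    parabolic = "parabolic"
    linear = "linear"


@dataclass
class DoseResponseFit:
    """Least-squares fit of a response (e.g. Td) against supplement dose."""

    model: DoseResponseModel
    coefficients: tuple[float, ...]  # highest degree first (numpy polyfit order)
    r_squared: float

    def predict(self, dose: float | np.ndarray) -> np.ndarray:
        return np.polyval(self.coefficients, dose)


def _log_linear(times: np.ndarray, od: np.ndarray) -> tuple[float, float]:
    """Slope and R^2 of ln(OD) vs time."""
    y = np.log(od)
    slope, _, r, *_ = stats.linregress(times, y)
    return float(slope), float(r**2)


def doubling_time(
    curve: GrowthCurve,
    window: tuple[float, float] | None = None,
    min_points: int = 3,
    r2_threshold: float = 0.99,
) -> float:
    """Doubling time (h) from log-linear regression over an exponential window.

    ``window=(t0, t1)`` restricts the fit to that time interval; otherwise
    the maximal contiguous run of points with log-linear R^2 >=
    ``r2_threshold`` and positive slope is used (ties broken toward higher
    R^2, then earlier start).  A non-positive slope means no growth and
    raises.
    """
    times, od = curve.times, curve.od600
    if window is not None:
        mask = (times >= window[0]) & (times <= window[1])
        times, od = times[mask], od[mask]
        if times.size < min_points:
            raise ValueError("window contains fewer than the minimum points")
        if np.any(od <= 0):
            raise ValueError("OD must be positive within the fit window")
        slope, _ = _log_linear(times, od)
    else:
        positive = od > 0
        best: tuple[int, float, int] | None = None  # (length, r2, -start)
        best_slope = None
        n = times.size
        for i in range(n):
            for j in range(i + min_points, n + 1):
                if not positive[i:j].all():
                    continue
                s, r2 = _log_linear(times[i:j], od[i:j])
                if r2 >= r2_threshold and s > 0:
                    key = (j - i, r2, -i)
                    if best is None or key > best:
                        best, best_slope = key, s
        if best is None:
            raise ValueError(
                "no growth: no exponential window with positive slope found"
            )
        slope = best_slope
    if slope <= 0:
        raise ValueError("no growth: non-positive exponential slope")
    return log(2.0) / slope


def biomass_from_od(od600: float, coefficient: float = OD_TO_GDW_PER_L) -> float:
    """Convert OD600 to g dry weight per litre (default 0.54 g/OD/L)."""
    if od600 < 0:
        raise ValueError("OD must be non-negative")
    return od600 * coefficient


def dose_response(
    doses: Sequence[float],
    responses: Sequence[float],
    model: DoseResponseModel = DoseResponseModel.parabolic,
) -> DoseResponseFit:
    """Fit a response (doubling time) against supplement dose.

    Linear fits need >= 3 distinct doses, parabolic (degree-2) fits >= 4,
    so there is at least one residual degree of freedom.
    """
    doses = np.asarray(doses, dtype=float)
    responses = np.asarray(responses, dtype=float)
    model = DoseResponseModel(model)
    distinct = np.unique(doses).size
    degree = 2 if model is DoseResponseModel.parabolic else 1
    if distinct < degree + 2:
        raise ValueError(
            f"{model.value} fit needs >= {degree + 2} distinct doses, got {distinct}"
        )
    coef = np.polyfit(doses, responses, degree)
    residuals = responses - np.polyval(coef, doses)
    ss_tot = float(np.sum((responses - responses.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(residuals**2)) / ss_tot
    return DoseResponseFit(
        model=model, coefficients=tuple(float(c) for c in coef), r_squared=r2
    )


def growth_summary_ttest(
    mean1: float, sd1: float, n1: int,
    mean2: float, sd2: float, n2: int,
    kind: TestKind = TestKind.student_pooled,
) -> tuple[float, float]:
    """Two-sample t test from summary statistics (mean, SD, n) per group.

    Accepts table-style inputs where raw replicates are unavailable.
    Returns (t statistic, two-sided p value).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    t, p = stats.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2,
        equal_var=(TestKind(kind) is TestKind.student_pooled),
    )
    return float(t), float(p)
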