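"""Dynamic control function: from attrition statistics to a wear schedule.

Clinical surveys report population-average attrition indices (an ordinal
0-4 wear score) by age group. Min-max normalizing age and index to [0, 1]
and fitting a cubic polynomial Y(X) yields the *dynamic control function*
u(t): the fraction of total wear accumulated by normalized age t. Sampling
u on a uniform t grid converts a linear morph sequence into an
age-realistic nonlinear one — fast wear while the immature enamel surface
abrades, a long stable plateau of fully mineralized enamel, then rapid
loss again once dentin is exposed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

log = logging.getLogger(__name__)

__all__ = [
    "AttritionSeries",
    "NormalizedSeries",
    "DynamicControlFunction",
    "DEFAULT_ATTRITION_SERIES",
    "normalize_minmax",
    "fit_dcf",
    "evaluate_dcf",
    "nonlinear_schedule",
]


@dataclass
class AttritionSeries:
    """Ages (years) and average attrition indices (0-4 ordinal scale)."""

    ages: np.ndarray
    indices: np.ndarray

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=np.float64)
        self.indices = np.asarray(self.indices, dtype=np.float64)
        if len(self.ages) != len(self.indices):
            raise ValueError("ages and indices must have equal length")
        if len(self.ages) < 4:
            raise ValueError("need at least 4 points for a cubic fit")
        if not np.all(np.diff(self.ages) > 0):
            raise ValueError("ages must be strictly increasing")


@dataclass
class NormalizedSeries:
    """Min-max normalized (X, Y) pairs in [0, 1] x [0, 1]."""

    x: np.ndarray
    y: np.ndarray


@dataclass
class DynamicControlFunction:
    """Cubic u(t) = a3 t^3 + a2 t^2 + a1 t + a0 on [0, 1], clamped by default."""

    coefficients: np.ndarray  # highest power first
    clamp: bool = True

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=np.float64)

    def __call__(self, t):
        return evaluate_dcf(self, t)


# Population-average attrition index of the lower first molar by age
# (years -> 0-4 ordinal index), from a published regional survey; eruption
# (age ~8) anchors index 0 and the life-expectancy endpoint (78) index 4.
DEFAULT_ATTRITION_SERIES = AttritionSeries(
    ages=np.array([8.0, 23.0, 30.0, 40.0, 50.0, 60.0, 66.0, 78.0]),
    indices=np.array([0.0, 0.88, 1.23, 1.43, 1.74, 1.99, 2.11, 4.0]),
)


def normalize_minmax(series: AttritionSeries) -> NormalizedSeries:
    """Map each column through (v - min) / (max - min)."""
    out = []
    for col in (series.ages, series.indices):
        lo, hi = col.min(), col.max()
        if hi <= lo:
            raise ValueError("cannot min-max normalize a constant column")
        out.append((col - lo) / (hi - lo))
    return NormalizedSeries(*out)


def fit_dcf(series: NormalizedSeries, degree: int = 3) -> DynamicControlFunction:
    """Ordinary least-squares polynomial fit of Y on X (coefficients high->low)."""
    x, y = series.x, series.y
    if len(x) < degree + 1:
        raise ValueError(f"need at least {degree + 1} points for degree {degree}")
    if len(np.unique(x)) < degree + 1:
        raise ValueError("duplicate X values make the polynomial fit ill-conditioned")
    coeffs = np.polyfit(x, y, degree)
    return DynamicControlFunction(coeffs)


def evaluate_dcf(dcf: DynamicControlFunction, t):
    """Evaluate u(t) on [0, 1] (Horner); clamped to [0, 1] unless disabled."""
    t_arr = np.asarray(t, dtype=np.float64)
    if np.any(t_arr < 0) or np.any(t_arr > 1):
        raise ValueError("t must lie in [0, 1]")
    u = np.polyval(dcf.coefficients, t_arr)
    if dcf.clamp:
        u = np.clip(u, 0.0, 1.0)
    return float(u) if np.isscalar(t) or t_arr.ndim == 0 else u


def nonlinear_schedule(dcf: DynamicControlFunction, n_frames: int) -> np.ndarray:
    """Frame schedule u_k = u(t_k) on a uniform t grid of n_frames points.

    The returned values are non-decreasing: any inversion produced by a
    non-monotone control function is removed with a cumulative maximum
    (logged when it actually changes something).
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    t = np.linspace(0.0, 1.0, n_frames)
    u = np.asarray(evaluate_dcf(dcf, t))
    mono = np.maximum.accumulate(u)
    if not np.array_equal(mono, u):
        log.info("schedule monotonized by cumulative max (non-monotone control function)")
    return mono
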