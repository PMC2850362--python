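"""Single-curve analysis: background correction, threshold crossings,
doubling times.

During exponential outgrowth the background-corrected OD doubles every
``delta`` hours, so all interpolation and slope work is done on
``log2(od_corr)``, where it is piecewise linear.  Corrected ODs are
floored at a small epsilon so logs stay finite on blank or dead wells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "EPSILON",
    "ODCurve",
    "CurveParams",
    "DoublingTime",
    "crossing_time",
    "doubling_time_inflection",
    "doubling_time_interval",
    "estimate_doubling_time",
    "apply_correction",
]

#: Floor for background-corrected OD (keeps log2 finite on blanks).
EPSILON = 1e-4


@dataclass(frozen=True)
class ODCurve:
    """One well's OD series with its run background."""

    times: np.ndarray
    od_raw: np.ndarray
    background: float = 0.0

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        od = np.asarray(self.od_raw, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "od_raw", od)
        if times.shape != od.shape or times.ndim != 1:
            raise ValueError("times and od_raw must be 1-d arrays of equal length")
        if times.size >= 2 and np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.background < 0:
            raise ValueError("background must be non-negative")

    @property
    def od_corr(self) -> np.ndarray:
        """Background-subtracted OD, floored at :data:`EPSILON`."""
        return np.maximum(self.od_raw - self.background, EPSILON)


@dataclass(frozen=True)
class CurveParams:
    """Thresholds and method selection for curve analysis.

    All OD values are background-normalized.  ``od_min``/``od_max``
    bound the window searched by the inflection (steepest-slope)
    estimator; ``dt_interval_min``/``dt_interval_max`` bound the
    interval (traversal) estimator; ``timeshift_od`` is the level at
    which outgrowth time shifts are measured.  ``correction`` is an
    affine pair ``(a, b)`` applied to doubling times as
    ``a * delta + b``; the identity ``(1, 0)`` is a documented no-op.
    """

    od_min: float = 0.2
    od_max: float = 0.5
    dt_interval_min: float = 0.2
    dt_interval_max: float = 0.5
    timeshift_od: float = 0.3
    dt_method: str = "interval"  # "interval" | "inflection"
    correction: tuple[float, float] = (1.0, 0.0)

    def __post_init__(self) -> None:
        if not 0 < self.od_min < self.od_max:
            raise ValueError("need 0 < od_min < od_max")
        if not 0 < self.dt_interval_min < self.dt_interval_max:
            raise ValueError("need 0 < dt_interval_min < dt_interval_max")
        if self.timeshift_od <= EPSILON:
            raise ValueError("timeshift_od must exceed the OD floor")
        if self.dt_method not in ("interval", "inflection"):
            raise ValueError(f"unknown doubling-time method {self.dt_method!r}")

    @property
    def has_correction(self) -> bool:
        return self.correction != (1.0, 0.0)


@dataclass(frozen=True)
class DoublingTime:
    """An estimated doubling time in hours; always positive."""

    delta: float
    method: str
    corrected: bool = False

    def __post_init__(self) -> None:
        if not (self.delta > 0 and math.isfinite(self.delta)):
            raise ValueError(f"doubling time must be positive and finite, got {self.delta}")


def crossing_time(curve: ODCurve, level: float) -> Optional[float]:
    """Earliest time the corrected OD reaches ``level``.

    Interpolates linearly in ``(time, log2 od_corr)`` between the
    bracketing samples.  Returns ``None`` when the curve never reaches
    the level (a dead culture or blank well) and ``0.0`` when the curve
    is already at or above the level at the first sample.
    """
    if level <= EPSILON:
        raise ValueError("crossing level must exceed the OD floor")
    od = curve.od_corr
    above = od >= level
    if not above.any():
        return None
    i = int(np.argmax(above))
    if i == 0:
        return 0.0
    t0, t1 = curve.times[i - 1], curve.times[i]
    lo, hi = math.log2(od[i - 1]), math.log2(od[i])
    frac = (math.log2(level) - lo) / (hi - lo)
    return float(t0 + frac * (t1 - t0))


def doubling_time_inflection(
    curve: ODCurve, p: CurveParams
) -> Optional[DoublingTime]:
    """Doubling time at the steepest log2-slope within the OD window.

    Considers consecutive sample pairs whose corrected ODs both lie in
    ``[od_min, od_max]`` and returns the reciprocal of the maximal
    slope.  ``None`` when no pair qualifies or the best slope is not
    positive.
    """
    od = curve.od_corr
    if od.size < 2:
        return None
    inside = (od >= p.od_min) & (od <= p.od_max)
    pair = inside[:-1] & inside[1:]
    if not pair.any():
        return None
    dlog = np.diff(np.log2(od))
    dt = np.diff(curve.times)
    slopes = dlog[pair] / dt[pair]
    m = float(slopes.max())
    if m <= 0:
        return None
    return DoublingTime(delta=1.0 / m, method="inflection")


def doubling_time_interval(curve: ODCurve, p: CurveParams) -> Optional[DoublingTime]:
    """Average doubling time across the interval-OD window.

    Traversal time between the crossings of ``dt_interval_min`` and
    ``dt_interval_max`` divided by the number of doublings spanned,
    ``log2(dt_interval_max / dt_interval_min)``.  Exact for exponential
    growth, and robust to single-sample noise since only two crossings
    enter.  ``None`` when either crossing is absent or the traversal
    time is not positive.
    """
    t_lo = crossing_time(curve, p.dt_interval_min)
    t_hi = crossing_time(curve, p.dt_interval_max)
    if t_lo is None or t_hi is None:
        return None
    span = t_hi - t_lo
    if span <= 0:
        return None
    return DoublingTime(
        delta=span / math.log2(p.dt_interval_max / p.dt_interval_min),
        method="interval",
    )


def estimate_doubling_time(curve: ODCurve, p: CurveParams) -> Optional[DoublingTime]:
    """Estimate by ``p.dt_method``, applying the affine correction if set."""
    est = (
        doubling_time_interval(curve, p)
        if p.dt_method == "interval"
        else doubling_time_inflection(curve, p)
    )
    if est is not None and p.has_correction:
        est = apply_correction(est, p.correction)
    return est


def apply_correction(
    dt: DoublingTime, correction: tuple[float, float]
) -> DoublingTime:
    """Affine empirical correction ``delta' = a * delta + b`` (hours)."""
    a, b = correction
    delta = a * dt.delta + b
    if delta <= 0:
        raise ValueError(
            f"correction ({a}, {b}) maps doubling time {dt.delta:.4g} h to "
            f"non-positive {delta:.4g} h"
        )
    return replace(dt, delta=delta, corrected=True)
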