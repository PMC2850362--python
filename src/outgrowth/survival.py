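"""Survival estimation from outgrowth time shifts.

The core idea: after a fixed dilution into fresh medium, a culture's
outgrowth curve is displaced rightward along the time axis by one
doubling time for every halving of the viable inoculum.  Measuring the
time shift Δt_n of age-point *n*'s curve relative to the first
age-point's curve (at a fixed corrected-OD level) therefore yields the
surviving fraction

    s_n = (1/2) ** (Δt_n / δ),

where δ is the doubling time estimated from the *first* age-point's
curve of the same well.  The first age-point defines maximal survival
(1.0); later fractions are relative to it.

Cleaning enforces what a survival curve must satisfy — it starts at 1
and never increases — by a running-minimum pass, which also flattens
spurious terminal rises ("gasping").  The survival integral is the
trapezoidal area under the cleaned curve over the age axis in days.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .curves import (
    CurveParams,
    DoublingTime,
    ODCurve,
    crossing_time,
    estimate_doubling_time,
)
from .io import OutgrowthRun, WellInfo

__all__ = [
    "AnalysisError",
    "AgePoint",
    "Lineage",
    "time_shift",
    "survival_fraction",
    "clean_survival",
    "survival_integral",
    "build_lineages",
]


class AnalysisError(ValueError):
    """Raised when a lineage cannot be analyzed; carries well/day context."""


def time_shift(
    curve_n: ODCurve, curve_ref: ODCurve, timeshift_od: float
) -> Optional[float]:
    """Rightward displacement (hours) of ``curve_n`` relative to the reference.

    Measured as the difference of the two curves' crossing times at
    ``timeshift_od``.  Returns ``None`` when ``curve_n`` never reaches
    the level (total death); raises when the *reference* curve never
    reaches it, since no shift can then be defined.
    """
    t_ref = crossing_time(curve_ref, timeshift_od)
    if t_ref is None:
        raise AnalysisError(
            f"reference outgrowth failed: curve never reaches OD {timeshift_od}"
        )
    t_n = crossing_time(curve_n, timeshift_od)
    if t_n is None:
        return None
    return t_n - t_ref


def survival_fraction(
    dt_shift: Optional[float], delta: DoublingTime | float
) -> float:
    """Surviving fraction from a time shift and a doubling time.

    ``s = 2 ** (-dt_shift / delta)``; a ``None`` shift (dead culture)
    maps to 0.0 so survival curves and integrals stay defined.  Negative
    shifts yield fractions above 1, which cleaning later caps.
    """
    d = delta.delta if isinstance(delta, DoublingTime) else float(delta)
    if not (d > 0 and math.isfinite(d)):
        raise ValueError(f"doubling time must be positive, got {d}")
    if dt_shift is None:
        return 0.0
    return 2.0 ** (-dt_shift / d)


def clean_survival(raw: Sequence[float]) -> list[float]:
    """Enforce a monotone survival curve starting at 1.0.

    ``cleaned[0] = 1.0`` (the reference age-point is maximal survival);
    each later value is capped by 1, by its raw value, and by its
    predecessor, i.e. a running minimum.  Removes both increases and
    terminal "gasping" spikes; idempotent.
    """
    if len(raw) == 0:
        raise ValueError("clean_survival: empty survival series")
    cleaned = [1.0]
    for value in raw[1:]:
        cleaned.append(min(1.0, float(value), cleaned[-1]))
    return cleaned


def survival_integral(days: Sequence[float], s: Sequence[float]) -> float:
    """Area under the survival curve (day · fraction), trapezoidal.

    Age spacing is respected, so unevenly spaced age-points weigh by
    the days actually elapsed between them.
    """
    days_arr = np.asarray(days, dtype=float)
    s_arr = np.asarray(s, dtype=float)
    if days_arr.size != s_arr.size:
        raise ValueError("days and survival series differ in length")
    if days_arr.size < 2:
        raise ValueError("survival integral needs at least 2 age-points")
    if np.any(np.diff(days_arr) <= 0):
        raise ValueError("age labels must be strictly increasing")
    return float(np.trapezoid(s_arr, days_arr))


@dataclass(frozen=True)
class AgePoint:
    """One age-point of a lineage."""

    day: float
    time_shift: Optional[float]  # hours; None = never crossed (dead)
    survival_raw: float
    survival_clean: float


@dataclass(frozen=True)
class Lineage:
    """One well position tracked across all age-points of an experiment."""

    well_position: int
    name: str
    group: str
    ref_day: float
    ref_doubling_time: Optional[DoublingTime]
    points: tuple[AgePoint, ...]
    survival_integral: Optional[float]  # over cleaned fractions
    survival_integral_raw: Optional[float]

    @property
    def days(self) -> list[float]:
        return [pt.day for pt in self.points]

    @property
    def survival_clean(self) -> list[float]:
        return [pt.survival_clean for pt in self.points]

    @property
    def survival_raw(self) -> list[float]:
        return [pt.survival_raw for pt in self.points]


def _curve(run: OutgrowthRun, position: int) -> ODCurve:
    return ODCurve(
        times=run.table.times,
        od_raw=run.table.well(position),
        background=run.background,
    )


def build_lineages(
    runs: Sequence[OutgrowthRun],
    wells: Sequence[WellInfo] | None,
    p: CurveParams | None = None,
) -> list[Lineage]:
    """Track every sample well across age-points and score its survival.

    ``runs`` must be sorted by day with unique day labels and identical
    well counts (well position is maintained across the experiment).
    The first run is the reference age-point: it contributes the
    doubling time (by ``p.dt_method``) used for every later conversion
    of time shift to survival, and its own survival is 1.0 by
    definition.  Wells marked ``blank`` in the well info are skipped.
    Failures are re-raised tagged with well position and day.
    """
    p = p or CurveParams()
    if not runs:
        raise AnalysisError("no runs given")
    days = [r.day for r in runs]
    if sorted(days) != days or len(set(days)) != len(days):
        raise AnalysisError(f"runs must be sorted by unique day labels, got {days}")
    n_wells = runs[0].table.n_wells
    for r in runs[1:]:
        if r.table.n_wells != n_wells:
            raise AnalysisError(
                f"run day {r.day:g} has {r.table.n_wells} wells, "
                f"reference has {n_wells} (well order must be maintained)"
            )

    info = {w.position: w for w in wells} if wells else {}
    lineages: list[Lineage] = []
    for pos in range(1, n_wells + 1):
        meta = info.get(pos)
        if meta is not None and meta.role == "blank":
            continue
        name = meta.name if meta else f"well{pos}"
        group = meta.group if meta else name

        ref_curve = _curve(runs[0], pos)
        try:
            delta = estimate_doubling_time(ref_curve, p)
            if delta is None:
                raise AnalysisError(
                    "doubling time undefined on the reference age-point curve"
                )
            shifts = [
                time_shift(_curve(r, pos), ref_curve, p.timeshift_od) for r in runs
            ]
        except (AnalysisError, ValueError) as exc:
            raise AnalysisError(f"well {pos} ({name}), day {runs[0].day:g}: {exc}") from exc

        raw = [survival_fraction(sh, delta) for sh in shifts]
        cleaned = clean_survival(raw)
        si = survival_integral(days, cleaned) if len(days) >= 2 else None
        si_raw = survival_integral(days, raw) if len(days) >= 2 else None
        lineages.append(
            Lineage(
                well_position=pos,
                name=name,
                group=group,
                ref_day=runs[0].day,
                ref_doubling_time=delta,
                points=tuple(
                    AgePoint(day=d, time_shift=sh, survival_raw=r, survival_clean=c)
                    for d, sh, r, c in zip(days, shifts, raw, cleaned)
                ),
                survival_integral=si,
                survival_integral_raw=si_raw,
            )
        )
    return lineages
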