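"""Synthetic plate experiments with known ground truth.

The generator produces whole experiments in the exact run-CSV /
well-info dialects the :mod:`outgrowth.io` reader consumes, so the full
pipeline can be exercised — and its parameter recovery measured —
without a plate reader.

The generative model embodies the principle the survival method rests
on: the OD of a culture after a fixed period of outgrowth reflects the
number of viable cells inoculated.  Each well's corrected OD follows a
generalized-logistic (Richards) trajectory parameterized in base 2 so
``doubling_time`` is the literal exponential-phase doubling time:

    x(t) = K * (1 + ((K / x0)**nu - 1) * 2**(-nu * t / delta))**(-1/nu)

with initial viable-cell-equivalent OD ``x0 = inoculum_od * f`` for a
well whose viable fraction is ``f``.  The sharpness ``nu`` controls how
abruptly growth saturates at the carrying capacity ``K``: ``nu = 1`` is
the plain logistic, while the default ``nu = 8`` keeps growth
exponential through the OD window used for doubling-time estimation
and then saturates sharply, as post-diauxic yeast outgrowth does.
Raw ODs add the media background and optional Gaussian read noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .curves import ODCurve
from .io import MAX_WELLS, RawRunTable, WellInfo, write_run, write_well_info

__all__ = ["SimSpec", "SimulatedExperiment", "simulate_curve", "simulate_tables", "simulate_experiment"]

#: A chronological-lifespan-like default schedule: outgrowth sampled on
#: culture days 2..13 with survival declining from 1 to a few percent.
DEFAULT_SCHEDULE: tuple[tuple[float, float], ...] = (
    (2.0, 1.0),
    (4.0, 0.85),
    (6.0, 0.55),
    (9.0, 0.25),
    (11.0, 0.12),
    (13.0, 0.05),
)


@dataclass(frozen=True)
class SimSpec:
    """Ground-truth parameters of a simulated outgrowth experiment.

    Units: hours for times, dimensionless corrected OD for densities.
    Defaults describe a typical budding-yeast outgrowth in rich medium
    read every 30 minutes for 24 hours: a 90-minute doubling time, a
    1:30 inoculum of a dense culture (0.05 OD viable-equivalent),
    saturation at 1.4 corrected OD, media background 0.15, and read
    noise of 0.005 OD.
    """

    doubling_time: float = 1.5
    carrying_capacity: float = 1.4
    inoculum_od: float = 0.05
    viability_schedule: tuple[tuple[float, float], ...] = DEFAULT_SCHEDULE
    background: float = 0.15
    noise_sd: float = 0.005
    time_step: float = 0.5
    duration: float = 24.0
    shape: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.doubling_time <= 0:
            raise ValueError("doubling_time must be positive")
        if not 0 < self.inoculum_od < self.carrying_capacity:
            raise ValueError("need 0 < inoculum_od < carrying_capacity")
        if self.noise_sd < 0 or self.background < 0:
            raise ValueError("noise_sd and background must be non-negative")
        if self.time_step <= 0 or self.duration < 2 * self.time_step:
            raise ValueError("need time_step > 0 and at least 2 time points")
        if self.shape <= 0:
            raise ValueError("shape must be positive")
        sched = tuple((float(d), float(f)) for d, f in self.viability_schedule)
        object.__setattr__(self, "viability_schedule", sched)
        if sched:
            days = [d for d, _ in sched]
            if sorted(days) != days or len(set(days)) != len(days):
                raise ValueError("schedule days must be strictly increasing")
            if sched[0][1] != 1.0:
                raise ValueError("first schedule entry must have viable fraction 1.0")
            if any(not 0 <= f <= 1 for _, f in sched):
                raise ValueError("viable fractions must lie in [0, 1]")

    @property
    def times(self) -> np.ndarray:
        n = int(np.floor(self.duration / self.time_step)) + 1
        return np.arange(n) * self.time_step


def _richards(t: np.ndarray, x0: float, K: float, delta: float, nu: float) -> np.ndarray:
    a = (K / x0) ** nu - 1.0
    return K * (1.0 + a * np.exp2(-nu * t / delta)) ** (-1.0 / nu)


def simulate_curve(
    spec: SimSpec,
    viable_fraction: float = 1.0,
    rng: np.random.Generator | None = None,
) -> ODCurve:
    """Simulate one well's raw OD series for a given viable fraction.

    ``viable_fraction = 0`` yields a flat media-only trace (background
    plus noise).  When ``rng`` is omitted a fresh generator seeded from
    ``spec.seed`` is used, so repeated calls are reproducible.
    """
    if not 0 <= viable_fraction <= 1:
        raise ValueError("viable_fraction must lie in [0, 1]")
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    t = spec.times
    if viable_fraction == 0:
        x = np.zeros_like(t)
    else:
        x = _richards(
            t,
            spec.inoculum_od * viable_fraction,
            spec.carrying_capacity,
            spec.doubling_time,
            spec.shape,
        )
    od = spec.background + x
    if spec.noise_sd > 0:
        od = od + rng.normal(0.0, spec.noise_sd, size=t.shape)
    return ODCurve(times=t, od_raw=od, background=spec.background)


@dataclass(frozen=True)
class SimulatedExperiment:
    """In-memory result of :func:`simulate_tables`."""

    tables: tuple[tuple[float, RawRunTable], ...]  # (day, table), sorted by day
    wells: tuple[WellInfo, ...]
    truth: pd.DataFrame  # well_position, name, group, day, viable_fraction, doubling_time_h

    @property
    def days(self) -> list[float]:
        return [d for d, _ in self.tables]


def simulate_tables(
    spec: SimSpec,
    n_replicate_wells: int = 3,
    groups: dict[str, Sequence[tuple[float, float]]] | None = None,
) -> SimulatedExperiment:
    """Simulate a whole experiment as in-memory run tables.

    ``groups`` maps a group name to its viability schedule (a list of
    ``(day, viable fraction)``); all groups must share the same day
    grid.  Wells are laid out group-major with ``n_replicate_wells``
    replicates each, followed by one shared media-only blank well, and
    the well order is identical in every run.
    """
    if n_replicate_wells < 1:
        raise ValueError("need at least one replicate well per group")
    if groups is None:
        groups = {"WT": spec.viability_schedule}
    if not groups:
        raise ValueError("need at least one group")
    schedules = {g: tuple((float(d), float(f)) for d, f in s) for g, s in groups.items()}
    day_grids = {g: tuple(d for d, _ in s) for g, s in schedules.items()}
    days = next(iter(day_grids.values()))
    if any(grid != days for grid in day_grids.values()):
        raise ValueError("all groups must share the same age-point days")
    for g, sched in schedules.items():
        replace(spec, viability_schedule=sched)  # reuse schedule validation

    n_samples = len(schedules) * n_replicate_wells
    if n_samples + 1 > MAX_WELLS:
        raise ValueError(
            f"{n_samples} sample wells + 1 blank exceeds the {MAX_WELLS}-well capacity"
        )

    wells: list[WellInfo] = []
    layout: list[tuple[str, int]] = []  # (group, replicate index)
    pos = 0
    for g in schedules:
        for r in range(1, n_replicate_wells + 1):
            pos += 1
            wells.append(WellInfo(position=pos, name=f"{g}-r{r}", group=g))
            layout.append((g, r))
    blank_pos = pos + 1
    wells.append(WellInfo(position=blank_pos, name="blank", role="blank"))

    rng = np.random.default_rng(spec.seed)
    tables: list[tuple[float, RawRunTable]] = []
    truth_rows: list[dict] = []
    for di, day in enumerate(days):
        od = np.empty((blank_pos, spec.times.size))
        for j, (g, _r) in enumerate(layout):
            frac = schedules[g][di][1]
            od[j] = simulate_curve(spec, frac, rng).od_raw
            truth_rows.append(
                {
                    "well_position": j + 1,
                    "name": wells[j].name,
                    "group": g,
                    "day": day,
                    "viable_fraction": frac,
                    "doubling_time_h": spec.doubling_time,
                }
            )
        od[blank_pos - 1] = simulate_curve(spec, 0.0, rng).od_raw
        tables.append(
            (day, RawRunTable(source_name=f"day{day:g}", times=spec.times, wells=od))
        )
    return SimulatedExperiment(
        tables=tuple(tables), wells=tuple(wells), truth=pd.DataFrame(truth_rows)
    )


def simulate_experiment(
    spec: SimSpec,
    out_dir: str | Path,
    n_replicate_wells: int = 3,
    groups: dict[str, Sequence[tuple[float, float]]] | None = None,
) -> tuple[list[tuple[float, Path]], Path, Path]:
    """Simulate and write an experiment in the plate-reader file dialects.

    Writes one run CSV per scheduled day (``day<label>.csv``, identical
    well ordering throughout, one shared blank well), a well-info CSV,
    and a ground-truth CSV.  Returns ``(run files as (day, path) pairs,
    well-info path, ground-truth path)``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = simulate_tables(spec, n_replicate_wells, groups)
    run_paths: list[tuple[float, Path]] = []
    for day, table in sim.tables:
        path = out / f"day{day:g}.csv"
        header = ["Time"] + [w.name for w in sim.wells]
        write_run(table, path, header=header)
        run_paths.append((day, path))
    wells_path = out / "well_info.csv"
    write_well_info(sim.wells, wells_path)
    truth_path = out / "ground_truth.csv"
    sim.truth.to_csv(truth_path, index=False)
    return run_paths, wells_path, truth_path
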