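"""Result tables: per-run growth output and per-lineage survival output.

Two table shapes are exported, mirroring the two views of a plate
experiment:

* ``runs`` — one row per (well, run): growth-rate information for each
  well at each age-point, independent of the lineage structure, with
  optional appended OD readings.
* ``lineages`` — one row per well position tracked across age-points
  (or per replicate group): doubling time, per-age survival, time
  shifts, and survival integrals, with optional statistics versus a
  reference group.

Output is CSV (UTF-8, reals at 6 decimals); column order is fixed so
downstream scripts can rely on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .curves import CurveParams, estimate_doubling_time, ODCurve, doubling_time_inflection, doubling_time_interval, apply_correction
from .io import OutgrowthRun, WellInfo, format_time
from .stats import compare_groups
from .survival import Lineage

__all__ = ["ExportConfig", "export_runs", "export_lineages", "write_table"]

_FLOAT_FORMAT = "%.6f"


@dataclass(frozen=True)
class ExportConfig:
    """Which table to emit and which optional columns to include.

    ``selected_wells`` / ``selected_runs`` restrict output to the given
    plate positions / day labels; ``None`` selects everything.  The
    t-test, percent-change and log2-ratio columns compare each group to
    ``reference_group``; the t-test additionally requires grouping
    (replicates are compared, not single wells).
    """

    output_mode: str = "lineages"  # "runs" | "lineages"
    grouping: str = "none"  # "none" | "average" | "median"
    append_ods: bool = False
    subtract_background: bool = True
    dt_inflection: bool = False
    dt_interval: bool = False
    dt_correction: bool = False
    survival: bool = True
    survival_area: bool = True
    clean: bool = True
    show_time_shifts: bool = False
    pct_change: bool = False
    log2_ratio: bool = False
    t_test: bool = False
    reference_group: Optional[str] = None
    selected_wells: Optional[frozenset[int]] = None
    selected_runs: Optional[frozenset[float]] = None

    def __post_init__(self) -> None:
        if self.output_mode not in ("runs", "lineages"):
            raise ValueError(f"unknown output mode {self.output_mode!r}")
        if self.grouping not in ("none", "average", "median"):
            raise ValueError(f"unknown grouping {self.grouping!r}")
        if self.t_test and self.grouping == "none":
            raise ValueError(
                "t-test versus reference: grouping option must be selected"
            )
        if (self.pct_change or self.log2_ratio or self.t_test) and (
            self.reference_group is None
        ):
            raise ValueError("comparisons versus reference require a reference group")
        if self.selected_wells is not None:
            object.__setattr__(self, "selected_wells", frozenset(self.selected_wells))
        if self.selected_runs is not None:
            object.__setattr__(
                self, "selected_runs", frozenset(float(d) for d in self.selected_runs)
            )

    def wants_well(self, position: int) -> bool:
        return self.selected_wells is None or position in self.selected_wells

    def wants_run(self, day: float) -> bool:
        return self.selected_runs is None or float(day) in self.selected_runs


def _day_label(day: float) -> str:
    return f"{day:g}"


def export_runs(
    runs: Sequence[OutgrowthRun],
    wells: Sequence[WellInfo] | None,
    p: CurveParams | None = None,
    cfg: ExportConfig | None = None,
) -> pd.DataFrame:
    """One row per (well, run) with doubling times and optional ODs."""
    p = p or CurveParams()
    cfg = cfg or ExportConfig(output_mode="runs")
    if cfg.output_mode != "runs":
        raise ValueError("export_runs requires output_mode='runs'")

    info = {w.position: w for w in wells} if wells else {}
    rows: list[dict] = []
    for run in runs:
        if not cfg.wants_run(run.day):
            continue
        for pos in range(1, run.table.n_wells + 1):
            if not cfg.wants_well(pos):
                continue
            meta = info.get(pos)
            curve = ODCurve(run.table.times, run.table.well(pos), run.background)
            row: dict = {
                "well_position": pos,
                "well_name": meta.name if meta else f"well{pos}",
                "group": meta.group if meta else "",
                "media": meta.media if meta else "",
                "run_name": run.table.source_name,
                "day": run.day,
                "background": run.background,
            }
            primary = estimate_doubling_time(curve, p)
            row["doubling_time_h"] = primary.delta if primary else None
            if cfg.dt_inflection:
                est = doubling_time_inflection(curve, p)
                row["dt_inflection_h"] = est.delta if est else None
            if cfg.dt_interval:
                est = doubling_time_interval(curve, p)
                row["dt_interval_h"] = est.delta if est else None
            if cfg.dt_correction:
                base = (
                    doubling_time_interval(curve, p)
                    if p.dt_method == "interval"
                    else doubling_time_inflection(curve, p)
                )
                row["dt_corrected_h"] = (
                    apply_correction(base, p.correction).delta if base else None
                )
            if cfg.append_ods:
                od = (
                    run.table.well(pos) - run.background
                    if cfg.subtract_background
                    else run.table.well(pos)
                )
                for t, v in zip(run.table.times, od):
                    row[f"od_{format_time(float(t))}"] = v
            rows.append(row)
    if not rows:
        raise ValueError("runs export: selection matched no wells or runs")
    return pd.DataFrame(rows)


def export_lineages(
    lineages: Sequence[Lineage],
    cfg: ExportConfig | None = None,
) -> pd.DataFrame:
    """Per-well (grouping none) or per-group lineage table.

    Survival columns are named ``survival_d<day>`` (cleaned values by
    default, raw when ``clean`` is off), time shifts
    ``timeshift_h_d<day>``, and the integral ``survival_integral``.
    With grouping, each numeric column becomes a center plus an
    ``_sd`` column, and the optional comparison columns are appended.
    """
    cfg = cfg or ExportConfig(output_mode="lineages")
    if cfg.output_mode != "lineages":
        raise ValueError("export_lineages requires output_mode='lineages'")
    selected = [ln for ln in lineages if cfg.wants_well(ln.well_position)]
    if not selected:
        raise ValueError("lineages export: selection matched no wells")

    days = selected[0].days

    def _survival(ln: Lineage) -> list[float]:
        return ln.survival_clean if cfg.clean else ln.survival_raw

    def _integral(ln: Lineage) -> Optional[float]:
        return ln.survival_integral if cfg.clean else ln.survival_integral_raw

    if cfg.grouping == "none":
        rows = []
        for ln in selected:
            row: dict = {
                "well_position": ln.well_position,
                "well_name": ln.name,
                "group": ln.group,
                "doubling_time_h": (
                    ln.ref_doubling_time.delta if ln.ref_doubling_time else None
                ),
            }
            if cfg.survival:
                for d, s in zip(ln.days, _survival(ln)):
                    row[f"survival_d{_day_label(d)}"] = s
            if cfg.show_time_shifts:
                for pt in ln.points:
                    row[f"timeshift_h_d{_day_label(pt.day)}"] = pt.time_shift
            if cfg.survival_area:
                row["survival_integral"] = _integral(ln)
            rows.append(row)
        return pd.DataFrame(rows)

    # grouped output
    mode = cfg.grouping
    groups: dict[str, list[Lineage]] = {}
    for ln in selected:
        groups.setdefault(ln.group, []).append(ln)
    if cfg.reference_group is not None and cfg.reference_group not in groups:
        raise ValueError(
            f"reference group {cfg.reference_group!r} not among {sorted(groups)}"
        )

    si_by_group = {
        g: [_integral(ln) for ln in lns if _integral(ln) is not None]
        for g, lns in groups.items()
    }
    comparisons = None
    if cfg.reference_group is not None and (
        cfg.pct_change or cfg.log2_ratio or cfg.t_test
    ):
        comparisons = {
            s.group: s
            for s in compare_groups(si_by_group, mode, cfg.reference_group)
        }

    from .stats import summarize_group

    rows = []
    for g, lns in groups.items():
        row = {"group": g, "n": len(lns)}
        deltas = [
            ln.ref_doubling_time.delta for ln in lns if ln.ref_doubling_time
        ]
        if deltas:
            c, sd = summarize_group(deltas, mode)
            row["doubling_time_h"], row["doubling_time_h_sd"] = c, sd
        if cfg.survival:
            for i, d in enumerate(days):
                c, sd = summarize_group([_survival(ln)[i] for ln in lns], mode)
                row[f"survival_d{_day_label(d)}"] = c
                row[f"survival_d{_day_label(d)}_sd"] = sd
        if cfg.show_time_shifts:
            for i, d in enumerate(days):
                shifts = [
                    ln.points[i].time_shift
                    for ln in lns
                    if ln.points[i].time_shift is not None
                ]
                if shifts:
                    c, sd = summarize_group(shifts, mode)
                    row[f"timeshift_h_d{_day_label(d)}"] = c
                    row[f"timeshift_h_d{_day_label(d)}_sd"] = sd
        if cfg.survival_area and si_by_group[g]:
            c, sd = summarize_group(si_by_group[g], mode)
            row["survival_integral"], row["survival_integral_sd"] = c, sd
        if comparisons is not None:
            s = comparisons[g]
            if cfg.pct_change:
                row["pct_change_vs_ref"] = s.pct_change_vs_ref
            if cfg.log2_ratio:
                row["log2_ratio_vs_ref"] = s.log2_ratio_vs_ref
            if cfg.t_test:
                row["t_stat"] = s.t_stat
                row["p_value"] = s.p_value
        rows.append(row)
    return pd.DataFrame(rows)


def write_table(df: pd.DataFrame, dest: str | Path) -> None:
    """Write a result table as UTF-8 CSV with 6-decimal reals."""
    df.to_csv(dest, index=False, float_format=_FLOAT_FORMAT)
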