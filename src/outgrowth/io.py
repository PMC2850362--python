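"""Reading and validation of plate-reader run files and well metadata.

A "run file" is one age-point's outgrowth read in the Bioscreen
EZExperiment layout: the first column holds elapsed-time stamps in
``HH:MM:SS`` (hours unbounded, so multi-day reads are fine) and every
subsequent column holds one well's optical-density readings.  CSV is the
canonical dialect; ``.xlsx`` workbooks with the same layout on the first
sheet are also accepted.

A "well info" table maps 1-based plate positions to well names,
replicate groups, media and a sample/blank role.  The expected header is
``position,name,group,media,role``; ``group``, ``media`` and ``role``
are optional (defaulting to the well name, empty, and ``sample``).
"""

from __future__ import annotations

import csv
import io as _stdio
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, TextIO

import numpy as np

__all__ = [
    "DEFAULT_BACKGROUND",
    "MAX_WELLS",
    "ParseError",
    "RawRunTable",
    "WellInfo",
    "OutgrowthRun",
    "parse_time",
    "format_time",
    "parse_run",
    "write_run",
    "parse_well_info",
    "write_well_info",
    "compute_background",
    "load_run",
]

#: OD of a media-only well when no blank well or explicit value is given
#: (approximately the reading of 150 uL of YPD in a honeycomb plate).
DEFAULT_BACKGROUND = 0.15

#: Instrument capacity: two 100-well honeycomb plates.
MAX_WELLS = 200

_TIME_RE = re.compile(r"^\s*(\d+):([0-5]\d):([0-5]\d)\s*$")


class ParseError(ValueError):
    """Raised when a run file or well-info table violates the layout."""


def parse_time(stamp: str) -> float:
    """Convert an ``H+:MM:SS`` stamp to decimal hours.

    The hours field is unbounded (runs longer than a day are legal);
    minutes and seconds must lie in 00-59.
    """
    m = _TIME_RE.match(stamp)
    if m is None:
        raise ParseError(f"malformed time stamp {stamp!r}: expected HH:MM:SS")
    h, mm, ss = (int(g) for g in m.groups())
    return h + mm / 60.0 + ss / 3600.0


def format_time(hours: float) -> str:
    """Inverse of :func:`parse_time`, rounding to the nearest second."""
    total = round(hours * 3600.0)
    if total < 0:
        raise ValueError("negative time")
    h, rem = divmod(total, 3600)
    m, s = divmod(rem, 60)
    return f"{h:02d}:{m:02d}:{s:02d}"


@dataclass(frozen=True)
class RawRunTable:
    """One run file's numeric content.

    ``wells[j][i]`` is the OD of well column ``j`` (0-based; plate
    position ``j + 1``) at ``times[i]`` hours.
    """

    source_name: str
    times: np.ndarray
    wells: np.ndarray  # shape (n_wells, n_times)

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        wells = np.atleast_2d(np.asarray(self.wells, dtype=float))
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "wells", wells)
        if times.ndim != 1 or times.size < 2:
            raise ParseError("need at least 2 time points")
        if np.any(np.diff(times) <= 0):
            raise ParseError("time stamps must be strictly increasing")
        if wells.shape[0] < 1:
            raise ParseError("no well columns")
        if wells.shape[0] > MAX_WELLS:
            raise ParseError(
                f"{wells.shape[0]} well columns exceeds the {MAX_WELLS}-well "
                "instrument capacity (two 100-well plates)"
            )
        if wells.shape[1] != times.size:
            raise ParseError(
                f"well columns have {wells.shape[1]} readings for "
                f"{times.size} time points"
            )

    @property
    def n_wells(self) -> int:
        return self.wells.shape[0]

    def well(self, position: int) -> np.ndarray:
        """OD series of the 1-based plate ``position``."""
        if not 1 <= position <= self.n_wells:
            raise KeyError(f"well position {position} not in 1..{self.n_wells}")
        return self.wells[position - 1]


@dataclass(frozen=True)
class WellInfo:
    """Plate-position metadata."""

    position: int
    name: str
    group: str = ""
    media: str = ""
    role: str = "sample"  # "sample" | "blank"

    def __post_init__(self) -> None:
        if not 1 <= self.position <= MAX_WELLS:
            raise ParseError(f"well position {self.position} outside 1..{MAX_WELLS}")
        if self.role not in ("sample", "blank"):
            raise ParseError(f"role {self.role!r} must be 'sample' or 'blank'")
        if not self.group and self.role == "sample":
            object.__setattr__(self, "group", self.name)
        if self.role == "blank":
            # blank wells never belong to a replicate group
            object.__setattr__(self, "group", "")


@dataclass(frozen=True)
class OutgrowthRun:
    """One age-point: a run table plus its day label and background."""

    table: RawRunTable
    day: float
    background: float
    background_source: str = "fixed_value"  # "named_well" | "fixed_value"

    def __post_init__(self) -> None:
        if self.background < 0:
            raise ParseError("background must be non-negative")
        if self.background_source not in ("named_well", "fixed_value"):
            raise ParseError(f"unknown background source {self.background_source!r}")


# ---------------------------------------------------------------------------
# run files


def _rows_from_csv(stream: TextIO) -> list[list[str]]:
    rows = []
    for raw in csv.reader(stream):
        # drop trailing empty cells (EZExperiment exports often end rows
        # with stray delimiters)
        while raw and raw[-1].strip() == "":
            raw.pop()
        rows.append([c.strip() for c in raw])
    # drop trailing fully-empty rows
    while rows and not rows[-1]:
        rows.pop()
    return rows


def _rows_from_workbook(path: Path) -> list[list[str]]:
    import openpyxl
    import datetime

    wb = openpyxl.load_workbook(path, read_only=True, data_only=True)
    try:
        sheet = wb.worksheets[0]
        rows: list[list[str]] = []
        for row in sheet.iter_rows(values_only=True):
            cells: list[str] = []
            for v in row:
                if v is None:
                    cells.append("")
                elif isinstance(v, datetime.time):
                    cells.append(f"{v.hour:02d}:{v.minute:02d}:{v.second:02d}")
                else:
                    cells.append(str(v).strip())
            while cells and cells[-1] == "":
                cells.pop()
            rows.append(cells)
        while rows and not rows[-1]:
            rows.pop()
        return rows
    finally:
        wb.close()


def _looks_like_time(cell: str) -> bool:
    return _TIME_RE.match(cell) is not None


def parse_run(
    source: str | Path | TextIO,
    name: str | None = None,
) -> RawRunTable:
    """Parse a run file (CSV stream/path, or ``.xlsx`` path) into a table.

    A single header row is auto-detected: if the first cell of the first
    row does not parse as a time stamp, the row is treated as a header.
    Trailing empty columns and rows are dropped.
    """
    if isinstance(source, (str, Path)):
        path = Path(source)
        src_name = name or path.name
        if path.suffix.lower() in (".xlsx", ".xlsm"):
            rows = _rows_from_workbook(path)
        else:
            with open(path, newline="", encoding="utf-8-sig") as fh:
                rows = _rows_from_csv(fh)
    else:
        src_name = name or getattr(source, "name", "<stream>")
        rows = _rows_from_csv(source)

    if not rows:
        raise ParseError(f"{src_name}: empty file")

    offset = 1  # file row number of the first data row (1-based)
    if rows and rows[0] and not _looks_like_time(rows[0][0]):
        rows = rows[1:]
        offset = 2
    if not rows:
        raise ParseError(f"{src_name}: no data rows")

    width = len(rows[0])
    if width < 2:
        raise ParseError(f"{src_name}: no well columns")
    n_wells = width - 1
    if n_wells > MAX_WELLS:
        raise ParseError(
            f"{src_name}: {n_wells} well columns exceeds the {MAX_WELLS}-well "
            "instrument capacity (two 100-well plates)"
        )

    times = np.empty(len(rows))
    od = np.empty((n_wells, len(rows)))
    for i, row in enumerate(rows):
        rowno = i + offset
        if len(row) != width:
            raise ParseError(
                f"{src_name}: row {rowno} has {len(row)} cells, expected {width}"
            )
        try:
            times[i] = parse_time(row[0])
        except ParseError as exc:
            raise ParseError(f"{src_name}: row {rowno}: {exc}") from None
        for j, cell in enumerate(row[1:]):
            try:
                od[j, i] = float(cell)
            except ValueError:
                raise ParseError(
                    f"{src_name}: row {rowno}, well column {j + 1}: "
                    f"non-numeric OD {cell!r}"
                ) from None
    if np.any(np.diff(times) <= 0):
        bad = int(np.flatnonzero(np.diff(times) <= 0)[0])
        raise ParseError(
            f"{src_name}: time stamps not strictly increasing at row {bad + 1 + offset}"
        )
    return RawRunTable(source_name=src_name, times=times, wells=od)


def write_run(
    table: RawRunTable,
    dest: str | Path | TextIO,
    header: Sequence[str] | None = None,
    decimals: int = 6,
) -> None:
    """Write a run table back to run-CSV (round-trips :func:`parse_run`)."""

    def _emit(fh: TextIO) -> None:
        w = csv.writer(fh)
        if header is not None:
            w.writerow(header)
        for i, t in enumerate(table.times):
            w.writerow(
                [format_time(float(t))]
                + [f"{v:.{decimals}f}" for v in table.wells[:, i]]
            )

    if isinstance(dest, (str, Path)):
        with open(dest, "w", newline="", encoding="utf-8") as fh:
            _emit(fh)
    else:
        _emit(dest)


# ---------------------------------------------------------------------------
# well info


_WELL_COLUMNS = ("position", "name", "group", "media", "role")


def parse_well_info(source: str | Path | TextIO) -> list[WellInfo]:
    """Parse a well-info CSV (header ``position,name,group,media,role``).

    ``group``, ``media`` and ``role`` columns may be omitted.  Records
    are returned sorted by plate position; duplicate positions are an
    error.
    """
    if isinstance(source, (str, Path)):
        with open(source, newline="", encoding="utf-8-sig") as fh:
            return parse_well_info(fh)

    reader = csv.DictReader(source)
    if reader.fieldnames is None:
        raise ParseError("well info: empty file (expected a header row)")
    fields = [f.strip().lower() for f in reader.fieldnames]
    if "position" not in fields or "name" not in fields:
        raise ParseError(
            "well info: header must contain at least 'position' and 'name' "
            f"(got {reader.fieldnames})"
        )
    unknown = set(fields) - set(_WELL_COLUMNS)
    if unknown:
        raise ParseError(f"well info: unknown columns {sorted(unknown)}")

    wells: list[WellInfo] = []
    seen: set[int] = set()
    for lineno, row in enumerate(reader, start=2):
        row = {k.strip().lower(): (v or "").strip() for k, v in row.items() if k}
        if not any(row.values()):
            continue
        try:
            pos = int(row["position"])
        except (KeyError, ValueError):
            raise ParseError(
                f"well info: row {lineno}: bad position {row.get('position')!r}"
            ) from None
        if pos in seen:
            raise ParseError(f"well info: duplicate position {pos} (row {lineno})")
        seen.add(pos)
        try:
            wells.append(
                WellInfo(
                    position=pos,
                    name=row.get("name", ""),
                    group=row.get("group", ""),
                    media=row.get("media", ""),
                    role=row.get("role") or "sample",
                )
            )
        except ParseError as exc:
            raise ParseError(f"well info: row {lineno}: {exc}") from None
    return sorted(wells, key=lambda w: w.position)


def write_well_info(wells: Iterable[WellInfo], dest: str | Path | TextIO) -> None:
    """Write well metadata in the canonical CSV dialect."""

    def _emit(fh: TextIO) -> None:
        w = csv.writer(fh)
        w.writerow(_WELL_COLUMNS)
        for well in sorted(wells, key=lambda x: x.position):
            w.writerow([well.position, well.name, well.group, well.media, well.role])

    if isinstance(dest, (str, Path)):
        with open(dest, "w", newline="", encoding="utf-8") as fh:
            _emit(fh)
    else:
        _emit(dest)


# ---------------------------------------------------------------------------
# background


def compute_background(
    table: RawRunTable,
    blank: str | float | None = None,
    wells: Sequence[WellInfo] | None = None,
) -> float:
    """Background OD for one run.

    ``blank`` may be the *name* of a media-only well (its background is
    the median of that well's full series, robust to single contaminated
    readings), a fixed OD value, or ``None`` for the default of
    ``0.15`` (the approximate reading of media alone).
    """
    if blank is None:
        return DEFAULT_BACKGROUND
    if isinstance(blank, str):
        if wells is None:
            raise ParseError("named background well requires well info")
        blanks = [w for w in wells if w.role == "blank"]
        match = [w for w in blanks if w.name == blank]
        if not match:
            known = ", ".join(w.name for w in blanks) or "(none)"
            raise ParseError(
                f"background well {blank!r} not found; known blank wells: {known}"
            )
        return float(np.median(table.well(match[0].position)))
    value = float(blank)
    if not math.isfinite(value) or value < 0:
        raise ParseError(f"background value must be a finite non-negative OD, got {blank!r}")
    return value


def load_run(
    path: str | Path,
    day: float,
    blank: str | float | None = None,
    wells: Sequence[WellInfo] | None = None,
) -> OutgrowthRun:
    """Parse a run file and attach its day label and computed background."""
    table = parse_run(path)
    background = compute_background(table, blank, wells)
    source = "named_well" if isinstance(blank, str) else "fixed_value"
    return OutgrowthRun(
        table=table, day=float(day), background=background, background_source=source
    )
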