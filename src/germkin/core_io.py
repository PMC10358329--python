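"""Data model and table I/O for germination / longevity time courses.

The on-disk layout mirrors how seed labs lay out scoring sheets: columns come
in adjacent pairs, one measurement column plus its own ``Time`` column, so a
single file can hold several measurements scored on heterogeneous time grids::

    Protrusion 1,Time,Protrusion 2,Time
    10,24,5,24
    30,48,25,48
    ,,40,72

Within each pair either order (value, Time) or (Time, value) is accepted; the
Time member is recognised by the token ``time`` in its header,
case-insensitively.  The CSV dialect is fixed (comma separator, ``.`` decimal
mark, UTF-8, header required); ``decimal_comma=True`` switches to a
semicolon-separated, comma-decimal variant on read.
"""

from __future__ import annotations

import csv
import io
import json
import math
import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, TextIO

import numpy as np

from .errors import FormatError, ParseError, ValidationError

ValueKind = Literal["counts", "percent"]
ModuleKind = Literal["germination", "longevity"]

__all__ = [
    "TimeCourse",
    "ExperimentSet",
    "parse_table",
    "read_table",
    "write_table",
    "validate_course",
    "write_report",
    "read_report",
]


@dataclass
class TimeCourse:
    """One repetition: ordered observation times and cumulative values.

    ``values`` are cumulative germinated counts (``value_kind='counts'``,
    ``n_seeds`` required) or cumulative percentages in [0, 100]
    (``value_kind='percent'``).  Time units (hours for germination, days for
    storage/longevity) are metadata and not enforced.
    """

    label: str
    times: np.ndarray
    values: np.ndarray
    value_kind: ValueKind = "counts"
    n_seeds: int | None = None
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.values.ndim != 1:
            raise ValidationError(f"{self.label!r}: times and values must be 1-D")
        if len(self.times) != len(self.values):
            raise ValidationError(
                f"{self.label!r}: {len(self.times)} times vs {len(self.values)} values"
            )
        if len(self.times) < 2:
            raise ValidationError(f"{self.label!r}: need at least 2 observations")
        if np.any(self.times < 0):
            raise ValidationError(f"{self.label!r}: negative observation time")
        if not np.all(np.isfinite(self.times)) or not np.all(np.isfinite(self.values)):
            raise ValidationError(f"{self.label!r}: non-finite entry")
        if self.value_kind == "counts":
            if self.n_seeds is None:
                raise ValidationError(f"{self.label!r}: counts require n_seeds")
            if self.n_seeds < 1:
                raise ValidationError(f"{self.label!r}: n_seeds must be positive")
            if np.any(self.values < 0) or self.values.max() > self.n_seeds:
                raise ValidationError(
                    f"{self.label!r}: counts must lie in [0, n_seeds={self.n_seeds}]"
                )
        elif self.value_kind == "percent":
            if np.any(self.values < 0) or np.any(self.values > 100):
                raise ValidationError(f"{self.label!r}: percentages must lie in [0, 100]")
        else:  # pragma: no cover - guarded by type hints
            raise ValidationError(f"{self.label!r}: unknown value_kind {self.value_kind!r}")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def percent(self) -> np.ndarray:
        """Cumulative values on the percent scale."""
        if self.value_kind == "percent":
            return self.values.copy()
        return 100.0 * self.values / self.n_seeds

    @property
    def proportions(self) -> np.ndarray:
        """Cumulative values as proportions in [0, 1]."""
        return self.percent / 100.0


@dataclass
class ExperimentSet:
    """Named collection of time courses parsed from one input file."""

    name: str
    courses: list[TimeCourse]
    module: ModuleKind = "germination"

    def __post_init__(self) -> None:
        if not self.courses:
            raise ValidationError(f"experiment {self.name!r} has no measurements")
        labels = [c.label for c in self.courses]
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValidationError(f"duplicate measurement labels: {dupes}")

    def __iter__(self):
        return iter(self.courses)

    def __len__(self) -> int:
        return len(self.courses)

    def __getitem__(self, label: str) -> TimeCourse:
        for c in self.courses:
            if c.label == label:
                return c
        raise KeyError(label)


def _is_time_header(header: str) -> bool:
    return "time" in header.strip().lower()


def _parse_cell(raw: str, row: int, col: int, decimal_comma: bool) -> float:
    text = raw.strip()
    if decimal_comma:
        text = text.replace(",", ".")
    try:
        return float(text)
    except ValueError:
        raise ParseError(f"non-numeric cell {raw!r}", row=row, column=col) from None


def parse_table(
    source: str | TextIO,
    value_kind: ValueKind = "counts",
    n_seeds: int | None = None,
    *,
    name: str = "experiment",
    module: ModuleKind = "germination",
    decimal_comma: bool = False,
) -> ExperimentSet:
    """Parse a paired wide-column table into an :class:`ExperimentSet`.

    ``source`` is CSV text or an open text stream.  Each adjacent column pair
    holds a measurement and its Time column (either order); pairs may have
    different numbers of filled rows, and a row with an empty time or value
    cell within a pair is skipped for that pair.

    Raises :class:`FormatError` for an odd column count or a pair without a
    Time header, and :class:`ParseError` (with 1-based row/column
    coordinates, the header being row 1) for non-numeric cells.
    """
    if isinstance(source, str):
        source = io.StringIO(source)
    delimiter = ";" if decimal_comma else ","
    rows = list(csv.reader(source, delimiter=delimiter))
    rows = [r for r in rows if any(cell.strip() for cell in r)]
    if not rows:
        raise FormatError("empty table: a header row is required")
    header = [h.strip() for h in rows[0]]
    while header and not header[-1]:
        header.pop()
    if len(header) % 2 != 0:
        raise FormatError(
            f"odd number of columns ({len(header)}): header {header[-1]!r} has no partner"
        )

    courses: list[TimeCourse] = []
    for pair_start in range(0, len(header), 2):
        h_left, h_right = header[pair_start], header[pair_start + 1]
        left_is_time, right_is_time = _is_time_header(h_left), _is_time_header(h_right)
        if left_is_time == right_is_time:
            raise FormatError(
                f"column pair ({h_left!r}, {h_right!r}) must contain exactly one 'Time' header"
            )
        time_col = pair_start if left_is_time else pair_start + 1
        value_col = pair_start + 1 if left_is_time else pair_start
        label = header[value_col]

        times: list[float] = []
        values: list[float] = []
        for r_idx, row in enumerate(rows[1:], start=2):
            t_raw = row[time_col].strip() if time_col < len(row) else ""
            v_raw = row[value_col].strip() if value_col < len(row) else ""
            if not t_raw or not v_raw:
                continue  # empty cell within the pair: skip the row for this pair
            times.append(_parse_cell(t_raw, r_idx, time_col + 1, decimal_comma))
            values.append(_parse_cell(v_raw, r_idx, value_col + 1, decimal_comma))
        if len(times) < 2:
            raise FormatError(f"measurement {label!r} has fewer than 2 filled rows")
        courses.append(
            TimeCourse(
                label=label,
                times=np.array(times),
                values=np.array(values),
                value_kind=value_kind,
                n_seeds=n_seeds if value_kind == "counts" else None,
            )
        )
    return ExperimentSet(name=name, courses=courses, module=module)


def read_table(
    path: str | os.PathLike,
    value_kind: ValueKind = "counts",
    n_seeds: int | None = None,
    *,
    module: ModuleKind = "germination",
    decimal_comma: bool = False,
) -> ExperimentSet:
    """Read a table from a CSV or (optionally) XLSX file.

    XLSX support reads the first sheet only and requires ``openpyxl``.
    """
    path = os.fspath(path)
    stem = os.path.splitext(os.path.basename(path))[0]
    if path.lower().endswith((".xlsx", ".xlsm")):
        import pandas as pd  # openpyxl pulled in lazily by pandas

        df = pd.read_excel(path, sheet_name=0, header=None, dtype=str)
        buf = io.StringIO()
        df.to_csv(buf, index=False, header=False)
        buf.seek(0)
        return parse_table(
            buf, value_kind, n_seeds, name=stem, module=module, decimal_comma=False
        )
    with open(path, "r", encoding="utf-8", newline="") as fh:
        return parse_table(
            fh, value_kind, n_seeds, name=stem, module=module, decimal_comma=decimal_comma
        )


def write_table(experiment: ExperimentSet, dest: str | os.PathLike | TextIO) -> None:
    """Write an :class:`ExperimentSet` in the paired wide-column CSV layout.

    Numbers are written with :func:`repr` so a read-back reproduces every
    value bit-exactly.
    """

    def _fmt(x: float) -> str:
        return repr(int(x)) if float(x).is_integer() else repr(float(x))

    header: list[str] = []
    for course in experiment.courses:
        header.extend([course.label, "Time"])
    n_rows = max(len(c) for c in experiment.courses)
    lines = [",".join(header)]
    for i in range(n_rows):
        cells: list[str] = []
        for course in experiment.courses:
            if i < len(course):
                cells.extend([_fmt(course.values[i]), _fmt(course.times[i])])
            else:
                cells.extend(["", ""])
        lines.append(",".join(cells))
    text = "\n".join(lines) + "\n"
    if hasattr(dest, "write"):
        dest.write(text)
    else:
        with open(dest, "w", encoding="utf-8", newline="") as fh:
            fh.write(text)


def validate_course(
    tc: TimeCourse, repair: bool = False, *, monotone: bool = True
) -> TimeCourse:
    """Check (and optionally repair) a parsed time course.

    Duplicate or non-increasing times are always an error.  Decreasing
    cumulative values are repaired by a running maximum when ``repair`` is
    true (a warning is attached) and rejected otherwise.  Longevity series
    legitimately decline over storage time, so callers pass
    ``monotone=False`` to skip the monotonicity check for them.
    """
    dt = np.diff(tc.times)
    if np.any(dt == 0):
        raise ValidationError(f"{tc.label!r}: duplicate observation times")
    if np.any(dt < 0):
        raise ValidationError(f"{tc.label!r}: times must be strictly increasing")
    if not monotone:
        return tc
    if np.all(np.diff(tc.values) >= 0):
        return tc
    if not repair:
        raise ValidationError(
            f"{tc.label!r}: cumulative values decrease; pass repair=True to apply a running maximum"
        )
    repaired = np.maximum.accumulate(tc.values)
    n_changed = int(np.sum(repaired != tc.values))
    out = replace(tc, values=repaired)
    out.warnings = tc.warnings + [
        f"non-monotone cumulative values: {n_changed} point(s) replaced by the running maximum"
    ]
    return out


# ---------------------------------------------------------------------------
# Machine-readable reports
# ---------------------------------------------------------------------------


def _to_jsonable(obj):
    if hasattr(obj, "to_dict"):
        return _to_jsonable(obj.to_dict())
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_to_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, float)):
        x = float(obj)
        return None if math.isnan(x) else x
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def write_report(
    results: Iterable | dict,
    dest: str | os.PathLike | TextIO,
    format: Literal["json", "csv"] = "json",
) -> None:
    """Serialize computed results (index reports, fit results) to JSON or CSV.

    Results may be a dict of named blocks or a flat iterable.  JSON is the
    round-trip format: reading it back reproduces every numeric field
    bit-exactly (floats are emitted at full ``repr`` precision).  CSV
    flattens each result to one row of ``key,value`` pairs and is meant for
    spreadsheet import, not round-tripping.
    """
    if isinstance(results, dict):
        payload = _to_jsonable(results)
    else:
        payload = _to_jsonable(list(results))

    def _write(fh: TextIO) -> None:
        if format == "json":
            json.dump(payload, fh, indent=2, sort_keys=True, allow_nan=False)
            fh.write("\n")
        elif format == "csv":
            writer = csv.writer(fh)
            writer.writerow(["block", "key", "value"])
            items = payload.items() if isinstance(payload, dict) else enumerate(payload)
            for block, entry in items:
                for key, value in _flatten(entry):
                    writer.writerow([block, key, value])
        else:
            raise ValueError(f"unknown report format {format!r}")

    if hasattr(dest, "write"):
        _write(dest)
    else:
        with open(dest, "w", encoding="utf-8", newline="") as fh:
            _write(fh)


def _flatten(entry, prefix: str = ""):
    if isinstance(entry, dict):
        for k, v in entry.items():
            yield from _flatten(v, f"{prefix}{k}." if prefix else f"{k}.")
    elif isinstance(entry, list):
        for i, v in enumerate(entry):
            yield from _flatten(v, f"{prefix}{i}.")
    else:
        yield prefix.rstrip("."), entry


def read_report(path: str | os.PathLike | TextIO):
    """Read back a JSON report written by :func:`write_report`."""
    if hasattr(path, "read"):
        return json.load(path)
    with open(path, "r", encoding="utf-8") as fh:
        return json.load(fh)
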