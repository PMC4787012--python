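"""Readers and writers for the two per-delivery log dialects.

Both formats are plain text, diff-able and language-neutral.  Numeric values
are written as shortest round-trip decimals, so ``write . read`` is the
identity to the last bit.

Text log (``.ttxt``) — one snapshot of 45 named scalars::

    # format_version = 1
    # machine_id = TB01
    # date = 2026-01-05
    pfn_hv_current = 99.1782...
    ...                              (45 "key = value" lines)

Trajectory log (``.tlog.csv``) — axis positions every ``sample_interval_ms``::

    # format_version = 1
    # machine_id = TB01
    # date = 2026-01-05
    # sample_interval_ms = 20
    # axes = gantry,jaw_x1,...       (131 names in the default dialect)
    snapshot_index,gantry,jaw_x1,...
    0,-179.0,...
    1,...

Snapshot indices must run 0..N-1 without gaps; every row must carry one value
per declared axis.
"""

from __future__ import annotations

import datetime as _dt
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, TextIO

import numpy as np

from .errors import FormatError, ValidationError

FORMAT_VERSION = "1"
TEXT_SNAPSHOT_SIZE = 45


@dataclass(frozen=True)
class TextSnapshot:
    """One day's text-log snapshot: 45 named operating values."""

    machine_id: str
    date: _dt.date
    values: dict[str, float]

    def __post_init__(self) -> None:
        if len(self.values) != TEXT_SNAPSHOT_SIZE:
            raise ValidationError(
                f"text snapshot must carry exactly {TEXT_SNAPSHOT_SIZE} values, "
                f"got {len(self.values)}"
            )


@dataclass(frozen=True)
class TrajectoryLog:
    """One day's trajectory log: axis positions sampled at a fixed interval."""

    machine_id: str
    date: _dt.date
    axis_names: tuple[str, ...]
    snapshots: np.ndarray  # shape (n_snapshots, n_axes), float64
    sample_interval_ms: float = 20.0

    def __post_init__(self) -> None:
        snaps = np.asarray(self.snapshots, dtype=float)
        object.__setattr__(self, "snapshots", snaps)
        if snaps.ndim != 2 or snaps.shape[1] != len(self.axis_names):
            raise ValidationError(
                f"snapshot matrix shape {snaps.shape} does not match "
                f"{len(self.axis_names)} axes"
            )
        if snaps.shape[0] < 1:
            raise ValidationError("trajectory log needs at least one snapshot")
        if self.sample_interval_ms <= 0:
            raise ValidationError("sample_interval_ms must be > 0")
        if len(set(self.axis_names)) != len(self.axis_names):
            raise ValidationError("axis names must be unique")

    @property
    def n_snapshots(self) -> int:
        return int(self.snapshots.shape[0])

    def axis_index(self, axis: str) -> int:
        try:
            return self.axis_names.index(axis)
        except ValueError:
            raise KeyError(f"axis {axis!r} not recorded") from None

    def trace(self, axis: str) -> np.ndarray:
        """Positional trace of one axis (view into the snapshot matrix)."""
        return self.snapshots[:, self.axis_index(axis)]


# ---------------------------------------------------------------------------
# header helpers


def _fmt(x: float) -> str:
    return repr(float(x))


def _parse_date(text: str, line: int) -> _dt.date:
    try:
        return _dt.date.fromisoformat(text)
    except ValueError:
        raise FormatError(f"unparseable date {text!r}", line=line) from None


def _read_header(lines: list[str], required: tuple[str, ...]) -> tuple[dict[str, str], int]:
    """Parse leading '# key = value' lines; returns (header, first body line no)."""
    header: dict[str, str] = {}
    i = 0
    for i, raw in enumerate(lines):
        line = raw.strip()
        if not line.startswith("#"):
            break
        body = line.lstrip("#").strip()
        if "=" not in body:
            raise FormatError("malformed header line", line=i + 1)
        key, _, value = body.partition("=")
        key, value = key.strip(), value.strip()
        if key in header:
            raise FormatError("duplicate header field", line=i + 1, key=key)
        header[key] = value
    else:
        i = len(lines)
    missing = [k for k in required if k not in header]
    if missing:
        raise FormatError(f"missing header field(s): {', '.join(missing)}", line=1)
    if header["format_version"] != FORMAT_VERSION:
        raise FormatError(
            f"unsupported format_version {header['format_version']!r}", line=1,
            key="format_version",
        )
    return header, i


def _write_header(fh: TextIO, fields: list[tuple[str, str]]) -> None:
    for key, value in fields:
        fh.write(f"# {key} = {value}\n")


# ---------------------------------------------------------------------------
# text log


def write_text_log(snapshot: TextSnapshot, destination: str | Path | TextIO) -> None:
    """Serialize a snapshot in the ``.ttxt`` dialect."""
    own = isinstance(destination, (str, Path))
    fh: TextIO = open(destination, "w") if own else destination  # type: ignore[arg-type]
    try:
        _write_header(fh, [
            ("format_version", FORMAT_VERSION),
            ("machine_id", snapshot.machine_id),
            ("date", snapshot.date.isoformat()),
        ])
        for key, value in snapshot.values.items():
            fh.write(f"{key} = {_fmt(value)}\n")
    finally:
        if own:
            fh.close()


def read_text_log(source: str | Path | TextIO,
                  expected_values: int = TEXT_SNAPSHOT_SIZE) -> TextSnapshot:
    """Parse a ``.ttxt`` file; strict about count, duplicates and scalars."""
    own = isinstance(source, (str, Path))
    fh: TextIO = open(source) if own else source  # type: ignore[arg-type]
    try:
        lines = fh.read().splitlines()
    finally:
        if own:
            fh.close()

    header, body_start = _read_header(lines, ("format_version", "machine_id", "date"))
    date = _parse_date(header["date"], line=1)

    values: dict[str, float] = {}
    for offset, raw in enumerate(lines[body_start:]):
        lineno = body_start + offset + 1
        line = raw.strip()
        if not line:
            continue
        if "=" not in line:
            raise FormatError("expected 'key = value'", line=lineno)
        key, _, text = line.partition("=")
        key, text = key.strip(), text.strip()
        if not key:
            raise FormatError("empty key", line=lineno)
        if key in values:
            raise FormatError("duplicate key", line=lineno, key=key)
        try:
            values[key] = float(text)
        except ValueError:
            raise FormatError(f"unparseable scalar {text!r}", line=lineno, key=key) from None

    if len(values) != expected_values:
        raise FormatError(
            f"expected {expected_values} values, found {len(values)}",
            line=len(lines),
        )
    return TextSnapshot(machine_id=header["machine_id"], date=date, values=values)


# ---------------------------------------------------------------------------
# trajectory log


def write_trajectory_log(log: TrajectoryLog, destination: str | Path | TextIO) -> None:
    """Serialize a trajectory log in the ``.tlog.csv`` dialect."""
    own = isinstance(destination, (str, Path))
    fh: TextIO = open(destination, "w") if own else destination  # type: ignore[arg-type]
    try:
        _write_header(fh, [
            ("format_version", FORMAT_VERSION),
            ("machine_id", log.machine_id),
            ("date", log.date.isoformat()),
            ("sample_interval_ms", _fmt(log.sample_interval_ms)),
            ("axes", ",".join(log.axis_names)),
        ])
        fh.write("snapshot_index," + ",".join(log.axis_names) + "\n")
        buf = io.StringIO()
        for i, row in enumerate(log.snapshots):
            buf.write(str(i))
            for v in row:
                buf.write(",")
                buf.write(_fmt(v))
            buf.write("\n")
        fh.write(buf.getvalue())
    finally:
        if own:
            fh.close()


def read_trajectory_log(source: str | Path | TextIO) -> TrajectoryLog:
    """Parse a ``.tlog.csv`` file; rejects ragged rows and index gaps."""
    own = isinstance(source, (str, Path))
    fh: TextIO = open(source) if own else source  # type: ignore[arg-type]
    try:
        lines = fh.read().splitlines()
    finally:
        if own:
            fh.close()

    header, body_start = _read_header(
        lines, ("format_version", "machine_id", "date", "sample_interval_ms", "axes")
    )
    date = _parse_date(header["date"], line=1)
    try:
        interval = float(header["sample_interval_ms"])
    except ValueError:
        raise FormatError("unparseable sample_interval_ms", line=1,
                          key="sample_interval_ms") from None
    if interval <= 0:
        raise FormatError("sample_interval_ms must be > 0", line=1,
                          key="sample_interval_ms")
    axes = tuple(a.strip() for a in header["axes"].split(",") if a.strip())
    if not axes:
        raise FormatError("empty axes declaration", line=1, key="axes")
    if len(set(axes)) != len(axes):
        raise FormatError("duplicate axis names", line=1, key="axes")

    if body_start >= len(lines):
        raise FormatError("missing column header row", line=body_start + 1)
    expected_cols = ["snapshot_index", *axes]
    cols = [c.strip() for c in lines[body_start].split(",")]
    if cols != expected_cols:
        raise FormatError("column header does not match declared axes",
                          line=body_start + 1)

    body = [(body_start + off + 2, raw.strip())
            for off, raw in enumerate(lines[body_start + 1:]) if raw.strip()]
    if not body:
        raise FormatError("trajectory log has no snapshot rows", line=len(lines))

    # Fast path: rectangular numeric parse; fall back to a per-line scan only
    # to produce a precise diagnostic.
    try:
        data = np.loadtxt(io.StringIO("\n".join(t for _, t in body)),
                          delimiter=",", ndmin=2)
        if data.shape[1] != len(axes) + 1:
            raise ValueError
    except ValueError:
        for lineno, line in body:
            parts = line.split(",")
            if len(parts) != len(axes) + 1:
                raise FormatError(
                    f"ragged row: expected {len(axes) + 1} fields, found {len(parts)}",
                    line=lineno,
                ) from None
            try:
                [float(p) for p in parts]
            except ValueError:
                raise FormatError("unparseable numeric field", line=lineno) from None
        raise FormatError("unparseable snapshot rows", line=body[0][0]) from None

    indices = data[:, 0]
    expected = np.arange(len(indices), dtype=float)
    if not np.array_equal(indices, expected):
        bad = int(np.nonzero(indices != expected)[0][0])
        raise FormatError(
            f"non-monotone snapshot index {indices[bad]:g} (expected {bad})",
            line=body[bad][0],
        )

    return TrajectoryLog(
        machine_id=header["machine_id"],
        date=date,
        axis_names=axes,
        snapshots=data[:, 1:],
        sample_interval_ms=interval,
    )
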