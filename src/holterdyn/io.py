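"""Reading and validation of beat-level and frequency-table inputs.

Two CSV dialects are supported:

* beat CSV — header ``time_s,hr_bpm`` or ``time_s,rr_ms``; one row per beat,
  time strictly increasing;
* frequency-table CSV — header ``hr_bpm,count``; one row per distinct
  heart-rate value with its whole-recording repetition count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Literal, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DomainError,
    EmptyInputError,
    FormatError,
    ValidationError,
)

__all__ = [
    "BeatRecord",
    "BeatSeries",
    "FrequencyCountTable",
    "rr_to_hr",
    "read_beat_csv",
    "write_beat_csv",
    "read_frequency_table",
    "write_frequency_table",
]

ColumnMode = Literal["rr_ms", "hr_bpm"]


def rr_to_hr(rr_ms: float) -> int:
    """Convert an RR interval in milliseconds to an integer heart rate.

    Uses ``60000 / rr_ms`` rounded half-up, so e.g. 857 ms -> 70 bpm.

    Raises
    ------
    DomainError
        If ``rr_ms`` is not strictly positive.
    """
    if not rr_ms > 0:
        raise DomainError(f"rr_ms must be > 0, got {rr_ms!r}")
    return int(math.floor(60000.0 / rr_ms + 0.5))


@dataclass(frozen=True)
class BeatRecord:
    """One beat: elapsed time since recording start and instantaneous HR."""

    time_s: float
    hr_bpm: int

    def __post_init__(self) -> None:
        if self.time_s < 0:
            raise ValidationError(f"time_s must be non-negative, got {self.time_s}")
        if int(self.hr_bpm) != self.hr_bpm or self.hr_bpm < 1:
            raise ValidationError(f"hr_bpm must be a positive integer, got {self.hr_bpm}")


@dataclass
class BeatSeries:
    """Ordered beat-level heart-rate observations of one recording.

    Stored as parallel numpy arrays for efficiency; iterate to obtain
    :class:`BeatRecord` views.
    """

    recording_id: str
    time_s: np.ndarray
    hr_bpm: np.ndarray

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.hr_bpm = np.asarray(self.hr_bpm, dtype=np.int64)
        if self.time_s.shape != self.hr_bpm.shape or self.time_s.ndim != 1:
            raise ValidationError("time_s and hr_bpm must be 1-D arrays of equal length")
        if self.n_beats:
            if self.time_s[0] < 0:
                raise ValidationError("time_s must be non-negative", row=0)
            bad = np.nonzero(np.diff(self.time_s) <= 0)[0]
            if bad.size:
                row = int(bad[0]) + 1
                raise ValidationError(
                    f"time_s not strictly increasing at row {row}", row=row
                )
            if (self.hr_bpm < 1).any():
                row = int(np.nonzero(self.hr_bpm < 1)[0][0])
                raise ValidationError(f"hr_bpm must be >= 1 at row {row}", row=row)

    @property
    def n_beats(self) -> int:
        return int(self.time_s.size)

    @property
    def duration_h(self) -> float:
        """Hours spanned: (last time_s - first time_s) / 3600."""
        if not self.n_beats:
            return 0.0
        return float(self.time_s[-1] - self.time_s[0]) / 3600.0

    def __len__(self) -> int:
        return self.n_beats

    def __iter__(self) -> Iterator[BeatRecord]:
        for t, hr in zip(self.time_s, self.hr_bpm):
            yield BeatRecord(float(t), int(hr))


@dataclass
class FrequencyCountTable:
    """Per-heart-rate repetition counts, as read from a frequency-table CSV."""

    rows: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for hr, count in self.rows:
            if hr < 1:
                raise ValidationError(f"hr_bpm must be positive, got {hr}")
            if count < 0:
                raise ValidationError(f"count must be non-negative, got {count} at hr {hr}")
            if hr in seen:
                raise ValidationError(f"duplicate hr_bpm value {hr}")
            seen.add(hr)
        self.rows = [(int(hr), int(c)) for hr, c in self.rows]

    def __len__(self) -> int:
        return len(self.rows)


def _read_csv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    # pandas silently renames duplicate header fields, so check the raw header.
    with open(path, newline="") as fh:
        header = fh.readline().strip()
    fields = [f.strip() for f in header.split(",")] if header else []
    dupes = sorted({f for f in fields if fields.count(f) > 1})
    if dupes:
        raise FormatError(f"{path}: duplicate columns {dupes}")
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"empty file: {path}") from None
    return frame


def _require_columns(frame: pd.DataFrame, needed: Sequence[str], path: Path | str) -> None:
    cols = list(frame.columns)
    missing = [c for c in needed if c not in cols]
    if missing:
        raise FormatError(f"{path}: missing columns {missing} (found {cols})")


def read_beat_csv(
    path: str | Path,
    column_mode: ColumnMode = "hr_bpm",
    recording_id: str | None = None,
    min_duration_h: float | None = None,
) -> BeatSeries:
    """Read a beat CSV into a :class:`BeatSeries`.

    Parameters
    ----------
    column_mode:
        ``"hr_bpm"`` expects columns ``time_s,hr_bpm``; ``"rr_ms"`` expects
        ``time_s,rr_ms`` and converts each interval with :func:`rr_to_hr`.
    min_duration_h:
        If given, reject recordings spanning fewer hours (strict-duration mode).
    """
    if column_mode not in ("rr_ms", "hr_bpm"):
        raise FormatError(f"unknown column_mode {column_mode!r}")
    frame = _read_csv(path)
    value_col = "rr_ms" if column_mode == "rr_ms" else "hr_bpm"
    _require_columns(frame, ["time_s", value_col], path)
    if frame.empty:
        raise EmptyInputError(f"{path}: no beat rows")
    time_s = frame["time_s"].to_numpy(dtype=float)
    if column_mode == "rr_ms":
        rr = frame[value_col].to_numpy(dtype=float)
        bad = np.nonzero(~(rr > 0))[0]
        if bad.size:
            raise ValidationError(
                f"{path}: rr_ms must be > 0 at row {int(bad[0])}", row=int(bad[0])
            )
        hr = np.floor(60000.0 / rr + 0.5).astype(np.int64)
    else:
        hr = frame[value_col].to_numpy()
        if not np.issubdtype(np.asarray(hr).dtype, np.number):
            raise FormatError(f"{path}: hr_bpm column is not numeric")
        hr = np.asarray(hr, dtype=np.int64)
    series = BeatSeries(
        recording_id=recording_id or Path(path).stem, time_s=time_s, hr_bpm=hr
    )
    if min_duration_h is not None and series.duration_h < min_duration_h:
        raise ValidationError(
            f"{path}: duration {series.duration_h:.3f} h below required {min_duration_h} h"
        )
    return series


def write_beat_csv(series: BeatSeries, path: str | Path) -> None:
    pd.DataFrame({"time_s": series.time_s, "hr_bpm": series.hr_bpm}).to_csv(
        path, index=False
    )


def read_frequency_table(path: str | Path) -> FrequencyCountTable:
    """Read a ``hr_bpm,count`` CSV into a :class:`FrequencyCountTable`.

    An empty body yields an empty table; duplicate heart-rate rows or
    negative counts raise :class:`ValidationError`.
    """
    frame = _read_csv(path)
    _require_columns(frame, ["hr_bpm", "count"], path)
    rows = [(int(hr), int(c)) for hr, c in zip(frame["hr_bpm"], frame["count"])]
    return FrequencyCountTable(rows=rows)


def write_frequency_table(table: FrequencyCountTable, path: str | Path) -> None:
    pd.DataFrame(table.rows, columns=["hr_bpm", "count"]).to_csv(path, index=False)
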