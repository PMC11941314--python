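"""Repetition profiles: per-heart-rate-value counts with 5-bpm labels.

A repetition count is the number of times a specific heart-rate value occurs
over the whole recording. Each value carries the nearest-multiple-of-5 label
used for grouping in the downstream probability tables; one label can hold
several distinct values (and therefore several distinct counts).
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DomainError, EmptyInputError, ValidationError
from .io import BeatSeries, FrequencyCountTable

__all__ = [
    "FrequencyRepetition",
    "RepetitionProfile",
    "label_of",
    "build_profile",
    "profile_from_table",
    "expand_profile",
    "write_profile_csv",
    "profile_report",
]


def label_of(hr_bpm: int) -> int:
    """Nearest multiple of 5 to an integer heart rate (57 -> 55, 58 -> 60).

    A tie is impossible for integer input. Non-positive input raises
    :class:`DomainError`.
    """
    if hr_bpm < 1:
        raise DomainError(f"hr_bpm must be >= 1, got {hr_bpm}")
    return ((int(hr_bpm) + 2) // 5) * 5


@dataclass(frozen=True)
class FrequencyRepetition:
    """One profile entry: a heart-rate value, its 5-bpm label, and its count.

    ``label_bpm`` is normally ``label_of(hr_bpm)`` (as produced by
    :func:`build_profile` / :func:`profile_from_table`), but it is carried as
    data so that label-grouped imports — where only the label and the count
    are known — remain representable.
    """

    hr_bpm: int
    label_bpm: int
    count: int

    def __post_init__(self) -> None:
        if self.hr_bpm < 1:
            raise ValidationError(f"hr_bpm must be positive, got {self.hr_bpm}")
        if self.label_bpm % 5 != 0 or self.label_bpm < 0:
            raise ValidationError(
                f"label_bpm must be a non-negative multiple of 5, got {self.label_bpm}"
            )
        if self.count < 0:
            raise ValidationError(f"count must be non-negative, got {self.count}")


@dataclass
class RepetitionProfile:
    """All repetition entries of one recording.

    Entries are sorted by descending count, then descending heart rate, so
    reports are deterministic. Heart-rate values are unique across entries and
    counts sum to ``total_beats``.
    """

    recording_id: str
    entries: list[FrequencyRepetition] = field(default_factory=list)

    def __post_init__(self) -> None:
        hrs = [e.hr_bpm for e in self.entries]
        if len(set(hrs)) != len(hrs):
            dupes = sorted({h for h in hrs if hrs.count(h) > 1})
            raise ValidationError(f"duplicate hr_bpm values in profile: {dupes}")
        self.entries = sorted(self.entries, key=lambda e: (-e.count, -e.hr_bpm))

    @property
    def total_beats(self) -> int:
        return sum(e.count for e in self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def labels(self) -> set[int]:
        return {e.label_bpm for e in self.entries}


def build_profile(series: BeatSeries) -> RepetitionProfile:
    """Count repetitions of each distinct heart-rate value in a beat series.

    Raises :class:`EmptyInputError` for an empty series.
    """
    if not series.n_beats:
        raise EmptyInputError(f"series {series.recording_id!r} has no beats")
    values, counts = np.unique(series.hr_bpm, return_counts=True)
    entries = [
        FrequencyRepetition(int(v), label_of(int(v)), int(c))
        for v, c in zip(values, counts)
    ]
    return RepetitionProfile(recording_id=series.recording_id, entries=entries)


def profile_from_table(
    table: FrequencyCountTable, recording_id: str = "table"
) -> RepetitionProfile:
    """Mirror a frequency-count table into a profile, assigning 5-bpm labels."""
    entries = [
        FrequencyRepetition(hr, label_of(hr), count) for hr, count in table.rows
    ]
    return RepetitionProfile(recording_id=recording_id, entries=entries)


def expand_profile(profile: RepetitionProfile) -> Counter[int]:
    """Expand a profile back to the beat multiset it summarizes (hr -> count)."""
    return Counter({e.hr_bpm: e.count for e in profile.entries if e.count})


def write_profile_csv(profile: RepetitionProfile, path: str | Path) -> None:
    pd.DataFrame(
        [(e.hr_bpm, e.label_bpm, e.count) for e in profile.entries],
        columns=["hr_bpm", "label_bpm", "count"],
    ).to_csv(path, index=False)


def profile_report(profile: RepetitionProfile) -> dict:
    """JSON-serializable summary of a profile."""
    return {
        "recording_id": profile.recording_id,
        "total_beats": profile.total_beats,
        "n_entries": len(profile),
        "entries": [
            {"hr_bpm": e.hr_bpm, "label_bpm": e.label_bpm, "count": e.count}
            for e in profile.entries
        ],
    }


def write_profile_report(profile: RepetitionProfile, path: str | Path) -> None:
    Path(path).write_text(json.dumps(profile_report(profile), indent=2))
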