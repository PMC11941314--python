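"""Within-range probability distributions and the summed-top-probabilities statistic.

A repetition range selects the profile entries whose repetition counts fall
inside an inclusive interval (default ranges: P1 = [1000, 2000] and
P2 = [2001, 3000]). Each qualifying (label, heart-rate, count) pair
contributes equally; per-label probabilities are the fraction of qualifying
pairs carrying that label, and the headline statistic is the sum of the two
largest per-label probabilities.

Probabilities are exact rationals (:class:`fractions.Fraction`); rounding is
presentation-only.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

from .errors import ConfigurationError, ValidationError
from .profiles import FrequencyRepetition, RepetitionProfile

__all__ = [
    "RepetitionRange",
    "RangeDistribution",
    "RangeFeatures",
    "DynamicsFeatures",
    "DEFAULT_RANGES",
    "filter_range",
    "range_distribution",
    "top_sum",
    "extract_features",
]

QualifyingPair = tuple[int, int, int]  # (label_bpm, hr_bpm, count)


@dataclass(frozen=True)
class RepetitionRange:
    """Inclusive interval of repetition counts, e.g. P1 = [1000, 2000]."""

    name: str
    lo: int
    hi: int

    def __post_init__(self) -> None:
        if not (0 < self.lo <= self.hi):
            raise ValidationError(
                f"range {self.name!r}: need 0 < lo <= hi, got [{self.lo}, {self.hi}]"
            )

    def __contains__(self, count: int) -> bool:
        return self.lo <= count <= self.hi


DEFAULT_RANGES: tuple[RepetitionRange, RepetitionRange] = (
    RepetitionRange("P1", 1000, 2000),
    RepetitionRange("P2", 2001, 3000),
)


def _entries_of(profile_or_entries) -> Sequence[FrequencyRepetition]:
    if isinstance(profile_or_entries, RepetitionProfile):
        return profile_or_entries.entries
    return list(profile_or_entries)


def filter_range(
    profile: RepetitionProfile | Iterable[FrequencyRepetition],
    rng: RepetitionRange,
) -> list[QualifyingPair]:
    """Qualifying (label, hr, count) pairs: entries with lo <= count <= hi.

    Accepts a profile or any iterable of entries; preserves input order.
    An empty result is valid.
    """
    return [
        (e.label_bpm, e.hr_bpm, e.count)
        for e in _entries_of(profile)
        if e.count in rng
    ]


@dataclass
class RangeDistribution:
    """Per-label probability distribution of one repetition range."""

    range: RepetitionRange
    qualifying: list[QualifyingPair]
    n_pairs: int
    label_probs: dict[int, Fraction]
    top_sum: Fraction
    freq_min: int | None
    freq_max: int | None
    peak_labels: tuple[int, ...]

    def to_dict(self) -> dict:
        return {
            "range": {"name": self.range.name, "lo": self.range.lo, "hi": self.range.hi},
            "n_pairs": self.n_pairs,
            "qualifying": [
                {"label_bpm": l, "hr_bpm": h, "count": c} for l, h, c in self.qualifying
            ],
            "label_probs": {str(l): float(p) for l, p in sorted(self.label_probs.items())},
            "top_sum": float(self.top_sum),
            "freq_min": self.freq_min,
            "freq_max": self.freq_max,
            "peak_labels": list(self.peak_labels),
        }


def _top_two_sum(probs: Mapping[int, Fraction]) -> Fraction:
    ordered = sorted(probs.values(), reverse=True)
    return sum(ordered[:2], Fraction(0))


def range_distribution(
    qualifying: Sequence[QualifyingPair], rng: RepetitionRange
) -> RangeDistribution:
    """Build the within-range distribution from qualifying pairs.

    Each per-label probability is (pairs with that label) / (total pairs);
    probabilities sum to 1 exactly whenever any pair qualifies.
    """
    for label, hr, count in qualifying:
        if count not in rng:
            raise ValidationError(
                f"count {count} at hr {hr} outside range {rng.name} [{rng.lo}, {rng.hi}]"
            )
    n = len(qualifying)
    if n == 0:
        return RangeDistribution(
            range=rng,
            qualifying=[],
            n_pairs=0,
            label_probs={},
            top_sum=Fraction(0),
            freq_min=None,
            freq_max=None,
            peak_labels=(),
        )
    tally = Counter(label for label, _, _ in qualifying)
    probs = {label: Fraction(k, n) for label, k in tally.items()}
    peak = max(probs.values())
    return RangeDistribution(
        range=rng,
        qualifying=list(qualifying),
        n_pairs=n,
        label_probs=probs,
        top_sum=_top_two_sum(probs),
        freq_min=min(tally),
        freq_max=max(tally),
        peak_labels=tuple(sorted(l for l, p in probs.items() if p == peak)),
    )


def top_sum(dist: RangeDistribution) -> Fraction:
    """Sum of the two largest per-label probabilities (the single probability
    when only one label qualifies; 0 when none does)."""
    return _top_two_sum(dist.label_probs)


@dataclass(frozen=True)
class RangeFeatures:
    """Summary features of one range, as consumed by the classifier."""

    range_name: str
    n_pairs: int
    top_sum: Fraction
    freq_min: int | None
    freq_max: int | None
    max_prob: Fraction
    peak_labels: tuple[int, ...]


@dataclass
class DynamicsFeatures:
    """Per-range feature records for one recording."""

    recording_id: str
    per_range: dict[str, RangeFeatures] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "recording_id": self.recording_id,
            "per_range": {
                name: {
                    "n_pairs": f.n_pairs,
                    "top_sum": float(f.top_sum),
                    "freq_min": f.freq_min,
                    "freq_max": f.freq_max,
                    "max_prob": float(f.max_prob),
                    "peak_labels": list(f.peak_labels),
                }
                for name, f in self.per_range.items()
            },
        }


def _check_disjoint(ranges: Sequence[RepetitionRange]) -> None:
    ordered = sorted(ranges, key=lambda r: r.lo)
    for a, b in zip(ordered, ordered[1:]):
        if b.lo <= a.hi:
            raise ConfigurationError(
                f"ranges {a.name!r} and {b.name!r} overlap: "
                f"[{a.lo},{a.hi}] vs [{b.lo},{b.hi}]"
            )


def extract_features(
    profile: RepetitionProfile | Iterable[FrequencyRepetition],
    ranges: Sequence[RepetitionRange] = DEFAULT_RANGES,
) -> DynamicsFeatures:
    """Compute per-range features (n_pairs, top_sum, frequency bounds, max
    single probability, peak labels) for each non-overlapping range."""
    _check_disjoint(ranges)
    entries = _entries_of(profile)
    recording_id = (
        profile.recording_id if isinstance(profile, RepetitionProfile) else "entries"
    )
    per_range: dict[str, RangeFeatures] = {}
    for rng in ranges:
        dist = range_distribution(filter_range(entries, rng), rng)
        per_range[rng.name] = RangeFeatures(
            range_name=rng.name,
            n_pairs=dist.n_pairs,
            top_sum=dist.top_sum,
            freq_min=dist.freq_min,
            freq_max=dist.freq_max,
            max_prob=max(dist.label_probs.values(), default=Fraction(0)),
            peak_labels=dist.peak_labels,
        )
    return DynamicsFeatures(recording_id=recording_id, per_range=per_range)
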