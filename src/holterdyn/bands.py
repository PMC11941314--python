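"""Rule-band classifier for cardiac dynamics.

Each class owns inclusive bands on per-range pair counts and summed-top
probabilities, one inclusive frequency-label interval, and an optional
peak-probability rule around the 0.3 threshold. A recording is assigned a
class when it satisfies every predicate of exactly one class; otherwise it is
``unclassified``, with a full per-predicate audit trail either way.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Literal, Sequence

import yaml

from .errors import ConfigurationError
from .ranges import DynamicsFeatures

__all__ = [
    "Interval",
    "ClassBands",
    "Diagnosis",
    "UNCLASSIFIED",
    "default_bands",
    "classify",
    "load_bands",
    "bands_to_dict",
    "save_bands",
]

UNCLASSIFIED = "unclassified"

PeakRule = Literal["below", "at_or_above"]


@dataclass(frozen=True)
class Interval:
    """Closed interval [lo, hi]."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if self.lo > self.hi:
            raise ConfigurationError(f"interval lower {self.lo} > upper {self.hi}")

    def __contains__(self, value) -> bool:
        return self.lo <= value <= self.hi


@dataclass(frozen=True)
class ClassBands:
    """All band predicates of one dynamics class.

    ``n_pairs`` / ``top_sum`` map range name -> inclusive interval;
    ``freq_bpm`` bounds the qualifying 5-bpm labels of every range.

    ``peak_prob_rule`` constrains the maximum single-label probability, and
    is evaluated only over ranges holding at least two qualifying pairs (a
    single-pair range has probability 1 structurally): ``"below"`` requires
    every such range's peak to stay under the threshold; ``"at_or_above"``
    requires some such range's peak to reach it.
    """

    class_name: str
    n_pairs: dict[str, Interval]
    top_sum: dict[str, Interval]
    freq_bpm: Interval
    peak_prob_rule: PeakRule | None = None
    peak_prob_threshold: float = 0.3


def default_bands() -> tuple[ClassBands, ...]:
    """The four reference band sets (pair counts, top-sum and frequency bands
    as published for the two default ranges P1/P2)."""
    return (
        ClassBands(
            class_name="normal",
            n_pairs={"P1": Interval(11, 14), "P2": Interval(0, 3)},
            top_sum={"P1": Interval(0.35, 0.46), "P2": Interval(0.0, 1.0)},
            freq_bpm=Interval(55, 95),
            peak_prob_rule="below",
        ),
        ClassBands(
            class_name="chronic",
            n_pairs={"P1": Interval(21, 31), "P2": Interval(10, 14)},
            top_sum={"P1": Interval(0.35, 0.48), "P2": Interval(0.54, 0.7)},
            freq_bpm=Interval(65, 105),
            peak_prob_rule="at_or_above",
        ),
        ClassBands(
            class_name="acute",
            n_pairs={"P1": Interval(9, 11), "P2": Interval(3, 6)},
            top_sum={"P1": Interval(0.5, 0.6), "P2": Interval(0.46, 0.75)},
            freq_bpm=Interval(75, 100),
            peak_prob_rule="at_or_above",
        ),
        ClassBands(
            class_name="pacemaker",
            n_pairs={"P1": Interval(4, 5), "P2": Interval(2, 2)},
            top_sum={"P1": Interval(0.5, 0.6), "P2": Interval(1.0, 1.0)},
            freq_bpm=Interval(60, 75),
            peak_prob_rule="at_or_above",
        ),
    )


@dataclass
class Diagnosis:
    """Predicted class plus the full pass/fail audit trail."""

    predicted: str
    matched: dict[str, dict[str, bool]] = field(default_factory=dict)

    def passing_classes(self) -> list[str]:
        return [c for c, preds in self.matched.items() if all(preds.values())]

    def to_dict(self) -> dict:
        return {"predicted": self.predicted, "matched": self.matched}


def _class_predicates(features: DynamicsFeatures, bands: ClassBands) -> dict[str, bool]:
    preds: dict[str, bool] = {}
    for rng_name in bands.n_pairs:
        if rng_name not in features.per_range:
            raise ConfigurationError(
                f"bands for {bands.class_name!r} reference range {rng_name!r} "
                f"absent from features ({sorted(features.per_range)})"
            )
        f = features.per_range[rng_name]
        preds[f"n_pairs[{rng_name}]"] = f.n_pairs in bands.n_pairs[rng_name]
        preds[f"top_sum[{rng_name}]"] = f.top_sum in bands.top_sum[rng_name]
        # Vacuously true for an empty range: no qualifying label to bound.
        preds[f"freq[{rng_name}]"] = f.n_pairs == 0 or (
            f.freq_min in bands.freq_bpm and f.freq_max in bands.freq_bpm
        )
    if bands.peak_prob_rule is not None:
        eligible = [
            f.max_prob for f in features.per_range.values() if f.n_pairs >= 2
        ]
        thr = bands.peak_prob_threshold
        if bands.peak_prob_rule == "below":
            preds["peak_prob"] = all(p < thr for p in eligible)
        else:
            preds["peak_prob"] = any(p >= thr for p in eligible)
    return preds


def classify(
    features: DynamicsFeatures, bands: Sequence[ClassBands] | None = None
) -> Diagnosis:
    """Evaluate every class's predicates; return the unique fully-passing
    class, else ``unclassified``. Pure and deterministic."""
    if bands is None:
        bands = default_bands()
    matched = {b.class_name: _class_predicates(features, b) for b in bands}
    passing = [c for c, preds in matched.items() if all(preds.values())]
    predicted = passing[0] if len(passing) == 1 else UNCLASSIFIED
    return Diagnosis(predicted=predicted, matched=matched)


# ---------------------------------------------------------------------------
# Band (de)serialization


def bands_to_dict(bands: Sequence[ClassBands]) -> dict:
    return {
        b.class_name: {
            "n_pairs": {k: [v.lo, v.hi] for k, v in b.n_pairs.items()},
            "top_sum": {k: [v.lo, v.hi] for k, v in b.top_sum.items()},
            "freq_bpm": [b.freq_bpm.lo, b.freq_bpm.hi],
            "peak_prob_rule": b.peak_prob_rule,
            "peak_prob_threshold": b.peak_prob_threshold,
        }
        for b in bands
    }


def _bands_from_dict(payload: dict) -> tuple[ClassBands, ...]:
    out = []
    for class_name, spec in payload.items():
        try:
            out.append(
                ClassBands(
                    class_name=class_name,
                    n_pairs={k: Interval(*v) for k, v in spec["n_pairs"].items()},
                    top_sum={k: Interval(*v) for k, v in spec["top_sum"].items()},
                    freq_bpm=Interval(*spec["freq_bpm"]),
                    peak_prob_rule=spec.get("peak_prob_rule"),
                    peak_prob_threshold=spec.get("peak_prob_threshold", 0.3),
                )
            )
        except (KeyError, TypeError) as exc:
            raise ConfigurationError(f"bad band spec for {class_name!r}: {exc}") from exc
    return tuple(out)


def load_bands(path: str | Path) -> tuple[ClassBands, ...]:
    """Load class bands from a YAML or JSON file mirroring ``bands_to_dict``."""
    path = Path(path)
    text = path.read_text()
    payload = (
        json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    )
    if not isinstance(payload, dict) or not payload:
        raise ConfigurationError(f"{path}: expected a non-empty mapping of classes")
    return _bands_from_dict(payload)


def save_bands(bands: Sequence[ClassBands], path: str | Path) -> None:
    path = Path(path)
    payload = bands_to_dict(bands)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(payload, indent=2))
    else:
        path.write_text(yaml.safe_dump(payload, sort_keys=True))
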