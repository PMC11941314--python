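"""Bundled reference prototypes for the four dynamics classes.

One prototype recording per class (normal, chronic, acute, pacemaker) is
shipped as label-grouped repetition data: for each 5-bpm label, the list of
whole-recording repetition counts observed at heart-rate values in that
label. Counts are split by the two default repetition ranges (P1 = 1000-2000,
P2 = 2001-3000).

Only (label, count) pairs are known for these references, not the underlying
exact heart-rate values, so :func:`prototype_entries` assigns each count a
distinct placeholder integer heart rate as close to its label as possible
(greedy nearest-free-integer). When a label holds more than five counts the
placeholder must leave the label's own +/-2 neighbourhood — five integers map
to any 5-bpm label — and the stored label stays authoritative.
"""

from __future__ import annotations

from .profiles import FrequencyRepetition, RepetitionProfile

__all__ = [
    "CLASS_NAMES",
    "PROTOTYPE_PAIRS",
    "prototype_pairs",
    "prototype_entries",
    "prototype_profile",
]

CLASS_NAMES: tuple[str, ...] = ("normal", "chronic", "acute", "pacemaker")

# (count, label_bpm) per class and per default range, sorted by descending count.
PROTOTYPE_PAIRS: dict[str, dict[str, tuple[tuple[int, int], ...]]] = {
    "normal": {
        "P1": (
            (1858, 90), (1858, 85), (1814, 65), (1792, 90), (1792, 85),
            (1780, 70), (1484, 70), (1354, 60), (1331, 55), (1216, 70),
            (1203, 60),
        ),
        "P2": ((2023, 90),),
    },
    "chronic": {
        "P1": (
            (1982, 85), (1938, 70), (1938, 75), (1934, 80), (1659, 90),
            (1534, 90), (1498, 85), (1484, 90), (1473, 70), (1472, 85),
            (1449, 95), (1419, 95), (1174, 80), (1171, 95), (1162, 100),
            (1161, 90), (1140, 95), (1122, 100), (1101, 85), (1086, 100),
            (1080, 75), (1065, 90), (1029, 90),
        ),
        "P2": (
            (2524, 80), (2496, 75), (2427, 75), (2426, 80), (2184, 75),
            (2161, 70), (2124, 70), (2094, 85), (2084, 80), (2073, 85),
        ),
    },
    "acute": {
        "P1": (
            (1993, 95), (1921, 85), (1407, 80), (1392, 75), (1316, 75),
            (1288, 85), (1215, 75), (1202, 80), (1160, 95), (1119, 85),
            (1087, 100),
        ),
        "P2": ((2999, 90), (2997, 100), (2279, 90), (2219, 80)),
    },
    "pacemaker": {
        "P1": ((1539, 75), (1536, 65), (1120, 70), (1115, 60)),
        "P2": ((2412, 65), (2397, 60)),
    },
}


def _check_class(class_name: str) -> None:
    if class_name not in CLASS_NAMES:
        raise KeyError(f"unknown class {class_name!r}; expected one of {CLASS_NAMES}")


def prototype_pairs(class_name: str) -> dict[str, tuple[tuple[int, int], ...]]:
    """(count, label) pairs of one prototype, keyed by range name."""
    _check_class(class_name)
    return PROTOTYPE_PAIRS[class_name]


def assign_distinct_hr(
    label_counts: list[tuple[int, int]]
) -> list[tuple[int, int, int]]:
    """Assign each (label, count) item a distinct integer heart rate.

    Greedy per item in input order: the free integer nearest the label
    (ties resolved toward the label's center from below). Deterministic.
    Returns (label, hr, count) triples in input order.
    """
    used: set[int] = set()
    out: list[tuple[int, int, int]] = []
    for label, count in label_counts:
        for dist in range(0, 1000):
            for cand in ((label - dist, label + dist) if dist else (label,)):
                if cand >= 1 and cand not in used:
                    used.add(cand)
                    out.append((label, cand, count))
                    break
            else:
                continue
            break
        else:  # pragma: no cover - unreachable for sane inputs
            raise RuntimeError("no free heart-rate slot found")
    return out


def prototype_entries(class_name: str) -> list[FrequencyRepetition]:
    """All repetition entries of one prototype (both ranges), with distinct
    placeholder heart rates and authoritative labels."""
    pairs = prototype_pairs(class_name)
    # Assign label-by-label in ascending label order so placement is stable
    # regardless of range membership.
    items = [
        (label, count)
        for rng in sorted(pairs)
        for count, label in pairs[rng]
    ]
    items_sorted = sorted(items, key=lambda it: (it[0], -it[1]))
    triples = assign_distinct_hr(items_sorted)
    return [FrequencyRepetition(hr, label, count) for label, hr, count in triples]


def prototype_profile(class_name: str) -> RepetitionProfile:
    """The prototype as a :class:`RepetitionProfile` (placeholder heart rates)."""
    return RepetitionProfile(
        recording_id=f"prototype-{class_name}", entries=prototype_entries(class_name)
    )
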