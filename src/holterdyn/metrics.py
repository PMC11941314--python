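"""Diagnostic-accuracy statistics: per-class sensitivity, specificity and
Cohen's kappa against a gold standard.

All three statistics are computed on one-vs-rest dichotomizations of the
cohort; ``unclassified`` predictions count as negative for every class
(false negative for the gold class, true negative elsewhere). A pooled
multi-class kappa is reported for convenience.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

from .errors import EmptyInputError, ValidationError

__all__ = [
    "CLASS_LABELS",
    "LabeledCohort",
    "ClassCounts",
    "EvaluationResult",
    "confusion",
    "sens_spec",
    "cohen_kappa",
    "evaluate_cohort",
]

CLASS_LABELS: tuple[str, ...] = ("normal", "chronic", "acute", "pacemaker")
_UNCLASSIFIED = "unclassified"


@dataclass
class LabeledCohort:
    """Recording ids with gold-standard and predicted class labels."""

    items: list[tuple[str, str, str]]  # (recording_id, gold, predicted)

    def __post_init__(self) -> None:
        ids = [i for i, _, _ in self.items]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate recording ids: {dupes}")

    def __len__(self) -> int:
        return len(self.items)


@dataclass(frozen=True)
class ClassCounts:
    """One-vs-rest 2x2 counts for a positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(cohort: LabeledCohort, positive_class: str) -> ClassCounts:
    """Dichotomize the cohort against one positive class.

    A prediction counts as positive iff it equals ``positive_class``;
    ``unclassified`` is therefore negative for every class.
    """
    if not len(cohort):
        raise EmptyInputError("empty cohort")
    tp = fp = tn = fn = 0
    for _, gold, pred in cohort.items:
        gold_pos = gold == positive_class
        pred_pos = pred == positive_class
        if gold_pos and pred_pos:
            tp += 1
        elif gold_pos:
            fn += 1
        elif pred_pos:
            fp += 1
        else:
            tn += 1
    return ClassCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def sens_spec(counts: ClassCounts) -> tuple[float | None, float | None]:
    """(sensitivity, specificity); a statistic with an empty denominator is
    reported as ``None`` (absent), never as 0."""
    sens = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else None
    spec = counts.tn / (counts.tn + counts.fp) if counts.tn + counts.fp else None
    return sens, spec


def _kappa_from_counts(counts: ClassCounts) -> float | None:
    n = counts.total
    p_o = (counts.tp + counts.tn) / n
    p_e = (
        (counts.tp + counts.fn) * (counts.tp + counts.fp)
        + (counts.tn + counts.fp) * (counts.tn + counts.fn)
    ) / (n * n)
    if p_e == 1.0:
        # All marginal mass in one cell: agreement is structural.
        return 1.0 if p_o == 1.0 else None
    return (p_o - p_e) / (1.0 - p_e)


def cohen_kappa(cohort: LabeledCohort, positive_class: str) -> float | None:
    """Cohen's kappa on the one-vs-rest 2x2 table for one class."""
    return _kappa_from_counts(confusion(cohort, positive_class))


def _pooled_kappa(cohort: LabeledCohort) -> float | None:
    labels = sorted(
        {g for _, g, _ in cohort.items} | {p for _, _, p in cohort.items}
    )
    n = len(cohort)
    joint = Counter((g, p) for _, g, p in cohort.items)
    gold_m = Counter(g for _, g, _ in cohort.items)
    pred_m = Counter(p for _, _, p in cohort.items)
    p_o = sum(joint[(l, l)] for l in labels) / n
    p_e = sum(gold_m[l] * pred_m[l] for l in labels) / (n * n)
    if p_e == 1.0:
        return 1.0 if p_o == 1.0 else None
    return (p_o - p_e) / (1.0 - p_e)


@dataclass
class EvaluationResult:
    """Per-class accuracy statistics plus the overall confusion matrix."""

    n: int
    per_class: dict[str, dict] = field(default_factory=dict)
    confusion_matrix: dict[str, dict[str, int]] = field(default_factory=dict)
    pooled_kappa: float | None = None

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "per_class": self.per_class,
            "confusion_matrix": self.confusion_matrix,
            "pooled_kappa": self.pooled_kappa,
        }


def evaluate_cohort(
    cohort: LabeledCohort, classes: Sequence[str] = CLASS_LABELS
) -> EvaluationResult:
    """Sensitivity, specificity and kappa for every class, plus the pooled
    class-by-class confusion matrix."""
    if not len(cohort):
        raise EmptyInputError("empty cohort")
    per_class: dict[str, dict] = {}
    for cls in classes:
        counts = confusion(cohort, cls)
        sens, spec = sens_spec(counts)
        per_class[cls] = {
            "tp": counts.tp,
            "fp": counts.fp,
            "tn": counts.tn,
            "fn": counts.fn,
            "sensitivity": sens,
            "specificity": spec,
            "kappa": _kappa_from_counts(counts),
        }
    pred_labels = list(classes) + [_UNCLASSIFIED]
    matrix = {
        g: {p: 0 for p in pred_labels} for g in classes
    }
    for _, gold, pred in cohort.items:
        matrix.setdefault(gold, {p: 0 for p in pred_labels})
        matrix[gold][pred] = matrix[gold].get(pred, 0) + 1
    return EvaluationResult(
        n=len(cohort),
        per_class=per_class,
        confusion_matrix=matrix,
        pooled_kappa=_pooled_kappa(cohort),
    )
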