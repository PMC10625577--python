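"""Confidence-threshold routing, 5% confidence binning and workload reduction.

Records whose top suggestion clears the confidence threshold are processed
automatically; the rest are queued for expert review. The minimum workload
reduction is the automatically processed fraction discounted by its accuracy.
"""

from __future__ import annotations

import dataclasses
import math
from collections.abc import Sequence
from typing import Optional

from .coder import CodeSuggestion
from .errors import DataError

__all__ = [
    "ThresholdPolicy",
    "ConfidenceBin",
    "WorkloadEstimate",
    "RoutingResult",
    "route",
    "bin_by_confidence",
    "bin_outcomes",
    "estimate_workload_reduction",
    "compute_workload",
]

N_BINS = 20  # 5%-wide bins covering [0, 100]


@dataclasses.dataclass(frozen=True)
class ThresholdPolicy:
    """Auto-coding confidence threshold (default 95%).

    A top-ranked suggestion with confidence >= threshold is auto-coded.
    Values outside [0, 1] are clamped.
    """

    threshold: float = 0.95

    def __post_init__(self) -> None:
        object.__setattr__(self, "threshold", min(1.0, max(0.0, float(self.threshold))))


@dataclasses.dataclass(frozen=True)
class ConfidenceBin:
    """One 5%-wide confidence interval [lo, hi) in percent (top bin closed)."""

    lo: float
    hi: float
    count: int
    proportion: float
    accuracy: Optional[float] = None  # percent; None when no gold or empty bin


@dataclasses.dataclass(frozen=True)
class WorkloadEstimate:
    fraction_above: float  # percent of suggestions at/above the threshold
    accuracy_above: float  # percent correct among those (NaN if none above)
    reduction: float  # percent, one decimal
    n_total: int = 0
    n_above: int = 0


@dataclasses.dataclass
class RoutingResult:
    auto_coded: list[tuple[str, CodeSuggestion]]
    review_queue: list[tuple[str, list[CodeSuggestion]]]


def _top1(suggestion_lists: Sequence[Sequence[CodeSuggestion]]) -> list[CodeSuggestion]:
    tops = []
    for lst in suggestion_lists:
        if not lst:
            raise DataError("every record needs at least a rank-1 suggestion")
        tops.append(min(lst, key=lambda s: s.rank))
    return tops


def route(
    suggestion_lists: Sequence[Sequence[CodeSuggestion]],
    policy: ThresholdPolicy = ThresholdPolicy(),
    entry_ids: Optional[Sequence[str]] = None,
) -> RoutingResult:
    """Partition records into auto-coded and expert-review queues."""
    if entry_ids is None:
        entry_ids = [str(i) for i in range(len(suggestion_lists))]
    if len(entry_ids) != len(suggestion_lists):
        raise DataError("entry_ids and suggestion lists misaligned")
    result = RoutingResult(auto_coded=[], review_queue=[])
    for entry_id, lst in zip(entry_ids, suggestion_lists):
        top = min(lst, key=lambda s: s.rank) if lst else None
        if top is None:
            raise DataError(f"record {entry_id!r} has no suggestions")
        if top.confidence >= policy.threshold:
            result.auto_coded.append((entry_id, top))
        else:
            result.review_queue.append((entry_id, sorted(lst, key=lambda s: s.rank)))
    return result


def bin_outcomes(
    confidences: Sequence[float], correct: Optional[Sequence[bool]] = None
) -> list[ConfidenceBin]:
    """Group confidences into twenty 5% bins, lower-edge inclusive, top bin
    [95, 100]. ``correct`` flags (when given) yield per-bin accuracy."""
    if correct is not None and len(correct) != len(confidences):
        raise DataError("confidences and correctness flags misaligned")
    counts = [0] * N_BINS
    hits = [0] * N_BINS
    for i, conf in enumerate(confidences):
        if not 0.0 <= conf <= 1.0:
            raise DataError(f"confidence {conf} outside [0, 1]")
        b = min(int(conf * 100.0 // 5.0), N_BINS - 1)
        counts[b] += 1
        if correct is not None and correct[i]:
            hits[b] += 1
    total = len(confidences)
    bins = []
    for b in range(N_BINS):
        accuracy = None
        if correct is not None and counts[b] > 0:
            accuracy = 100.0 * hits[b] / counts[b]
        bins.append(
            ConfidenceBin(
                lo=5.0 * b,
                hi=5.0 * (b + 1),
                count=counts[b],
                proportion=counts[b] / total if total else 0.0,
                accuracy=accuracy,
            )
        )
    return bins


def bin_by_confidence(
    suggestion_lists: Sequence[Sequence[CodeSuggestion]],
    gold: Optional[Sequence] = None,
) -> list[ConfidenceBin]:
    """Confidence bins of rank-1 suggestions; accuracy per bin when gold codes
    are supplied (compared on canonical strings)."""
    tops = _top1(suggestion_lists)
    correct = None
    if gold is not None:
        if len(gold) != len(tops):
            raise DataError("gold codes and suggestions misaligned")
        correct = [
            t.code.canonical == (g.canonical if hasattr(g, "canonical") else str(g))
            for t, g in zip(tops, gold)
        ]
    return bin_outcomes([t.confidence for t in tops], correct)


def estimate_workload_reduction(fraction_above: float, accuracy_above: float) -> float:
    """Minimum workload reduction (percent, one decimal): the auto-coded
    fraction discounted by its accuracy, e.g. (57.41, 97.02) -> 55.7."""
    for name, value in (("fraction_above", fraction_above), ("accuracy_above", accuracy_above)):
        if not 0.0 <= value <= 100.0:
            raise DataError(f"{name} must be in [0, 100], got {value}")
    return round(fraction_above * accuracy_above / 100.0, 1)


def compute_workload(
    suggestion_lists: Sequence[Sequence[CodeSuggestion]],
    gold: Sequence,
    policy: ThresholdPolicy = ThresholdPolicy(),
) -> WorkloadEstimate:
    """Measure fraction-above-threshold and its accuracy, then the reduction."""
    tops = _top1(suggestion_lists)
    if len(gold) != len(tops):
        raise DataError("gold codes and suggestions misaligned")
    n_total = len(tops)
    above = [
        (t, g) for t, g in zip(tops, gold) if t.confidence >= policy.threshold
    ]
    n_above = len(above)
    fraction_above = 100.0 * n_above / n_total if n_total else 0.0
    if n_above:
        n_correct = sum(
            1
            for t, g in above
            if t.code.canonical == (g.canonical if hasattr(g, "canonical") else str(g))
        )
        accuracy_above = 100.0 * n_correct / n_above
        reduction = estimate_workload_reduction(fraction_above, accuracy_above)
    else:
        accuracy_above = math.nan
        reduction = 0.0
    return WorkloadEstimate(
        fraction_above=fraction_above,
        accuracy_above=accuracy_above,
        reduction=reduction,
        n_total=n_total,
        n_above=n_above,
    )
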