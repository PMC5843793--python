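"""Evaluation statistics for parser performance and pattern coverage.

Three families of quantities:

* **Parser performance** — sensitivity ``TP/(TP+FN)`` and specificity
  ``TN/(TN+FP)`` of the keyword-based extraction against manual review.
* **Coverage precision** — the normal-approximation margin of error of a
  coverage proportion, ``d = z * sqrt(p(1-p)/TP)`` with the true-positive
  count as denominator, and its inversion to a required sample size
  ``n = z^2 p(1-p) / d^2`` (round to nearest; ``ceil=True`` for the
  conservative variant).
* **Annotation summaries** — per-category tallies, the coverage rate
  ``(existing + new) / (existing + new + nonrepresentable)`` (CDEs that
  are not time-related at all are a parser fault, excluded from both
  sides), and three-way interannotator agreement with majority-vote
  consensus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable, Iterable, Mapping, Optional

from .errors import AnnotationError, TeoCdeError, UndefinedStatisticError

__all__ = [
    "ConfusionCounts",
    "CoverageCounts",
    "AgreementSummary",
    "CIParams",
    "sensitivity",
    "specificity",
    "margin_of_error",
    "required_sample_size",
    "coverage_rate",
    "summarize_agreement",
    "tally_categories",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal round-half-up (0.25 -> 0.3 at 1 dp), as used for the
    reported percentages."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion counts for the time-relevance decision."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise TeoCdeError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def sensitivity(cc: ConfusionCounts) -> float:
    """TP/(TP+FN): fraction of truly time-relevant CDEs retrieved."""
    if cc.tp + cc.fn == 0:
        raise UndefinedStatisticError("sensitivity undefined: tp + fn = 0")
    return cc.tp / (cc.tp + cc.fn)


def specificity(cc: ConfusionCounts) -> float:
    """TN/(TN+FP): fraction of non-temporal CDEs correctly excluded."""
    if cc.tn + cc.fp == 0:
        raise UndefinedStatisticError("specificity undefined: tn + fp = 0")
    return cc.tn / (cc.tn + cc.fp)


@dataclass(frozen=True)
class CIParams:
    """Normal-approximation CI parameters: z multiplier (1.96 = 95% CI),
    margin of error d, and the proportion p_hat, all in decimals."""

    z_value: float = 1.96
    d: float = 0.05
    p_hat: float = 0.5

    def __post_init__(self) -> None:
        if not 0 <= self.p_hat <= 1:
            raise TeoCdeError("p_hat must lie in [0, 1]")
        if self.d <= 0 or self.z_value <= 0:
            raise TeoCdeError("d and z_value must be positive")


def margin_of_error(p_hat: float, tp: int, z: float = 1.96) -> float:
    """Half-width of the normal-approximation CI for a proportion,
    ``z * sqrt(p_hat (1 - p_hat) / TP)`` with the true-positive count as
    the denominator."""
    if not 0 <= p_hat <= 1:
        raise TeoCdeError("p_hat must lie in [0, 1]")
    if tp < 1:
        raise TeoCdeError("tp must be at least 1")
    return z * math.sqrt(p_hat * (1.0 - p_hat) / tp)


def required_sample_size(
    p_hat: float, d: float, z: float = 1.96, ceil: bool = False
) -> int:
    """Sample size achieving margin ``d`` for proportion ``p_hat``:
    ``z^2 p(1-p) / d^2``, rounded to nearest (``ceil=True`` rounds up)."""
    if d <= 0:
        raise TeoCdeError("margin of error d must be positive")
    if not 0 < p_hat < 1:
        raise TeoCdeError("p_hat must lie strictly in (0, 1)")
    n = z * z * p_hat * (1.0 - p_hat) / (d * d)
    return int(math.ceil(n)) if ceil else int(math.floor(n + 0.5))


@dataclass(frozen=True)
class CoverageCounts:
    """Per-category tallies of one annotator's test set."""

    existing: int
    new: int
    not_time_related: int
    cannot_represent: int

    def __post_init__(self) -> None:
        for name in ("existing", "new", "not_time_related", "cannot_represent"):
            if getattr(self, name) < 0:
                raise TeoCdeError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.existing + self.new + self.not_time_related + self.cannot_represent


def coverage_rate(cv: CoverageCounts, denominator: str = "time_related") -> float:
    """Fraction of CDEs representable by TEO patterns.

    Default denominator counts only the genuinely time-related CDEs
    (existing + new + cannot_represent); ``denominator="all"`` divides by
    every categorized CDE instead.
    """
    num = cv.existing + cv.new
    if denominator == "time_related":
        den = num + cv.cannot_represent
    elif denominator == "all":
        den = cv.total
    else:
        raise TeoCdeError(f"unknown denominator convention {denominator!r}")
    if den == 0:
        raise UndefinedStatisticError("coverage rate undefined: empty denominator")
    return num / den


@dataclass
class AgreementSummary:
    """Three-way interannotator agreement over a test set.

    Every CDE falls in one bucket: all annotators assigned the same (or
    equivalent) pattern, exactly one disagreed (majority-vote consensus),
    or all differed (unresolvable without a domain expert).
    """

    no_difference: int
    one_difference: int
    all_different: int
    consensus: dict[str, str] = field(default_factory=dict)
    unresolved: set[str] = field(default_factory=set)

    @property
    def total(self) -> int:
        return self.no_difference + self.one_difference + self.all_different

    def percentages(self) -> dict[str, float]:
        if self.total == 0:
            raise UndefinedStatisticError("no CDEs summarized")
        return {
            "no_difference": round_half_up(100.0 * self.no_difference / self.total),
            "one_difference": round_half_up(100.0 * self.one_difference / self.total),
            "all_different": round_half_up(100.0 * self.all_different / self.total),
        }


def _assignment_key(rec) -> str:
    # pattern-bearing categories compare by pattern id; the other two by
    # their category token
    return rec.pattern_id if rec.pattern_id is not None else rec.category.value


def summarize_agreement(
    annotations: Iterable,
    expected_annotators: int = 3,
    equivalence: Optional[Callable[[str, str], bool]] = None,
) -> AgreementSummary:
    """Categorize each CDE by how its annotators' pattern assignments
    compare, under an injectable pattern-equivalence relation (default:
    literal pattern-id equality).

    With three annotators: all pairwise-equivalent -> *no difference*;
    some pair equivalent -> *one difference*, consensus = the majority
    pattern; none -> *all different*, listed unresolved.
    """
    eq = equivalence or (lambda a, b: a == b)
    grouped: dict[str, list] = {}
    order: list[str] = []
    for rec in annotations:
        if rec.public_id not in grouped:
            grouped[rec.public_id] = []
            order.append(rec.public_id)
        grouped[rec.public_id].append(rec)
    summary = AgreementSummary(0, 0, 0)
    for public_id in order:
        recs = grouped[public_id]
        if len(recs) != expected_annotators:
            raise AnnotationError(
                f"{public_id}: expected {expected_annotators} annotations, "
                f"found {len(recs)}"
            )
        keys = [_assignment_key(r) for r in recs]
        pairs = [
            (i, j)
            for i in range(len(keys))
            for j in range(i + 1, len(keys))
            if eq(keys[i], keys[j])
        ]
        n_pairs_all = len(keys) * (len(keys) - 1) // 2
        if len(pairs) == n_pairs_all:
            summary.no_difference += 1
            summary.consensus[public_id] = keys[0]
        elif pairs:
            summary.one_difference += 1
            i, j = pairs[0]
            summary.consensus[public_id] = keys[i]
        else:
            summary.all_different += 1
            summary.unresolved.add(public_id)
    return summary


def tally_categories(annotations: Iterable) -> tuple[CoverageCounts, dict[str, float]]:
    """Count one annotator's category assignments and report percentages
    of the total at one decimal (round half up)."""
    counts = {"existing_pattern": 0, "new_pattern": 0,
              "not_time_related": 0, "cannot_represent": 0}
    for rec in annotations:
        counts[rec.category.value] += 1
    cv = CoverageCounts(
        existing=counts["existing_pattern"],
        new=counts["new_pattern"],
        not_time_related=counts["not_time_related"],
        cannot_represent=counts["cannot_represent"],
    )
    if cv.total:
        pct = {k: round_half_up(100.0 * v / cv.total) for k, v in counts.items()}
    else:
        pct = {k: 0.0 for k in counts}
    return cv, pct
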