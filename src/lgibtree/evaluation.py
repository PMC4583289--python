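"""Confusion tallies, operating characteristics, the ROC-over-priors sweep,
and the unscreened-case sensitivity adjustment.

Percentages are reported to one decimal with round-half-up to match how
operating characteristics are conventionally printed; raw ratios are always
retained alongside.  A metric whose denominator is zero (e.g. PPV with no
positive calls) is reported as ``None`` with a warning, never silently 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import List, Optional, Sequence, Tuple

from .core import Cohort, LgibError
from .rules import RuleList, classify
from . import cart as _cart

__all__ = [
    "ConfusionCounts",
    "Metrics",
    "RocPoint",
    "evaluate",
    "roc_over_priors",
    "adjust_for_unscreened",
    "to_percent",
    "format_report",
    "report_to_json",
]


def to_percent(fraction: Optional[float]) -> Optional[float]:
    """A proportion as a percentage rounded half-up to one decimal."""
    if fraction is None:
        return None
    q = Decimal(repr(float(fraction) * 100)).quantize(
        Decimal("0.1"), rounding=ROUND_HALF_UP
    )
    return float(q)


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/TN/FN plus the per-clause correct/incorrect tallies.

    ``per_clause[k] = (clause_index, n_correct, n_incorrect)`` counts the
    admissions whose first matching clause was ``k`` and whether the
    clause's predicted class agreed with the gold standard;
    ``default_correct``/``default_incorrect`` tally the default row.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    per_clause: Tuple[Tuple[int, int, int], ...]
    default_correct: int
    default_incorrect: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _ratio(num: int, den: int, name: str) -> Optional[float]:
    if den == 0:
        warnings.warn(f"{name} is undefined (zero denominator)", stacklevel=3)
        return None
    return num / den


@dataclass(frozen=True)
class Metrics:
    """Sensitivity, specificity, PPV and NPV as raw proportions (``None``
    when undefined)."""

    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]

    @classmethod
    def from_counts(cls, c: ConfusionCounts) -> "Metrics":
        return cls(
            sensitivity=_ratio(c.tp, c.tp + c.fn, "sensitivity"),
            specificity=_ratio(c.tn, c.tn + c.fp, "specificity"),
            ppv=_ratio(c.tp, c.tp + c.fp, "PPV"),
            npv=_ratio(c.tn, c.tn + c.fn, "NPV"),
        )


def evaluate(rule: RuleList, cohort: Cohort) -> Tuple[ConfusionCounts, Metrics]:
    """Classify every admission and tally against the gold standard.

    Every admission must carry a label; ``tp + fp + tn + fn`` always equals
    the cohort size.
    """
    cohort.require_labels()
    tallies = {k: [0, 0] for k in range(len(rule.clauses))}
    default_tally = [0, 0]
    tp = fp = tn = fn = 0
    for a in cohort:
        predicted, k = classify(rule, a)
        gold = bool(a.lgib)
        correct = predicted is gold
        if k is None:
            default_tally[0 if correct else 1] += 1
        else:
            tallies[k][0 if correct else 1] += 1
        if predicted and gold:
            tp += 1
        elif predicted and not gold:
            fp += 1
        elif not predicted and not gold:
            tn += 1
        else:
            fn += 1
    counts = ConfusionCounts(
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        per_clause=tuple((k, c, i) for k, (c, i) in sorted(tallies.items())),
        default_correct=default_tally[0],
        default_incorrect=default_tally[1],
    )
    return counts, Metrics.from_counts(counts)


@dataclass(frozen=True)
class RocPoint:
    """One operating point of the prior-probability sweep."""

    pi: float
    sensitivity: float
    false_positive_rate: float
    rule: RuleList


def roc_over_priors(
    cohort: Cohort,
    prior_grid: Sequence[float],
    min_node: int = 7,
    folds: int = 10,
    seed: int = 0,
    do_prune: bool = True,
    holdout: Optional[Cohort] = None,
) -> List[RocPoint]:
    """Sweep the prior probability: grow, prune, flatten and evaluate a tree
    at each value of ``prior_grid``.

    By default each rule is scored on the training cohort itself
    (resubstitution), matching how derivation-cohort operating
    characteristics are reported; pass ``holdout`` to score on an
    independent cohort instead.  Points come back in grid order with their
    flattened rules attached.
    """
    if not prior_grid:
        raise LgibError("prior grid must be non-empty")
    if any(not 0.0 < p < 1.0 for p in prior_grid):
        raise LgibError("every prior must lie strictly inside (0, 1)")
    points = []
    eval_cohort = holdout if holdout is not None else cohort
    for pi in prior_grid:
        tree = _cart.grow_tree(cohort, pi=pi, min_node=min_node)
        if do_prune and not tree.root.is_leaf:
            tree = _cart.prune(tree, cohort, folds=folds, seed=seed)
        rule = _cart.flatten(tree)
        _, metrics = evaluate(rule, eval_cohort)
        points.append(
            RocPoint(
                pi=pi,
                sensitivity=metrics.sensitivity if metrics.sensitivity is not None else 0.0,
                false_positive_rate=(
                    1.0 - metrics.specificity if metrics.specificity is not None else 0.0
                ),
                rule=rule,
            )
        )
    return points


def adjust_for_unscreened(
    tp: int, fn: int, cohort_size: int, unscreened_rate: float
) -> float:
    """Sensitivity after conservatively adding unscreened LGIB cases.

    Admissions that never received a screening code were not chart reviewed;
    assuming LGIB occurs among them at ``unscreened_rate`` and that every
    such case is missed, ``unscreened_rate * cohort_size`` extra false
    negatives are added: ``tp / (tp + fn + extra)``.  Specificity is treated
    as unchanged.  Monotone decreasing in the rate.
    """
    if not 0.0 <= unscreened_rate < 1.0:
        raise LgibError("unscreened rate must be in [0, 1)")
    extra = unscreened_rate * cohort_size
    return tp / (tp + fn + extra)


# ---------------------------------------------------------------------------
# Reporting


def _fmt(x: Optional[float]) -> str:
    return "undefined" if x is None else f"{to_percent(x):.1f}%"


def format_report(rule: RuleList, counts: ConfusionCounts, metrics: Metrics) -> str:
    """Human-readable evaluation report: metrics to one decimal, the
    confusion counts, and per-clause tallies in rule order."""
    lines = []
    if rule.provenance:
        lines.append(f"rule: {rule.provenance}")
    lines.append(
        f"n = {counts.n}   TP = {counts.tp}  FP = {counts.fp}  "
        f"TN = {counts.tn}  FN = {counts.fn}"
    )
    lines.append(
        f"sensitivity = {_fmt(metrics.sensitivity)}   "
        f"specificity = {_fmt(metrics.specificity)}   "
        f"PPV = {_fmt(metrics.ppv)}   NPV = {_fmt(metrics.npv)}"
    )
    lines.append(f"{'clause':<40} {'correct':>8} {'incorrect':>10}")
    for k, c, i in counts.per_clause:
        clause = rule.clauses[k]
        if clause.is_simple:
            desc = f"IF {clause.field.value} = {clause.code}"
        else:
            desc = "IF " + " AND ".join(
                f"{'' if lit.present else 'NOT '}{lit.field.value}={lit.code}"
                for lit in clause.literals
            )
        lines.append(f"{desc:<40} {c:>8} {i:>10}")
    lines.append(
        f"{'ELSE (default)':<40} {counts.default_correct:>8} "
        f"{counts.default_incorrect:>10}"
    )
    return "\n".join(lines)


def report_to_json(counts: ConfusionCounts, metrics: Metrics) -> dict:
    return {
        "n": counts.n,
        "confusion": {"tp": counts.tp, "fp": counts.fp, "tn": counts.tn, "fn": counts.fn},
        "metrics_percent": {
            "sensitivity": to_percent(metrics.sensitivity),
            "specificity": to_percent(metrics.specificity),
            "ppv": to_percent(metrics.ppv),
            "npv": to_percent(metrics.npv),
        },
        "metrics_raw": {
            "sensitivity": metrics.sensitivity,
            "specificity": metrics.specificity,
            "ppv": metrics.ppv,
            "npv": metrics.npv,
        },
        "per_clause": [
            {"clause": k, "n_correct": c, "n_incorrect": i}
            for k, c, i in counts.per_clause
        ],
        "default": {
            "n_correct": counts.default_correct,
            "n_incorrect": counts.default_incorrect,
        },
    }
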