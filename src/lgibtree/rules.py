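"""Ordered decision-rule lists and the first-match classification engine.

The package ships three validated rules as data files:

* ``screening`` — the 36-code OR-rule used to select charts for review
  (high sensitivity by construction);
* ``table3`` — the high-specificity rule (tree grown at prior 0.20);
* ``table4`` — the balanced sensitivity/specificity rule (prior 0.70).

A :class:`RuleList` is a sequence of IF/ELSE-IF clauses evaluated strictly
first-match, with a default class when no clause fires.  Shipped clauses are
single positive (field, code) tests; clauses flattened from general trees may
be conjunctions of presence/absence literals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Tuple, Union

from .core import Admission, Field, LgibError, has_code

__all__ = [
    "Literal",
    "RuleClause",
    "RuleList",
    "classify",
    "matches",
    "screening_rule",
    "high_specificity_rule",
    "balanced_rule",
    "builtin_rule",
    "BUILTIN_RULES",
    "rule_to_json",
    "rule_from_json",
    "save_rule",
    "load_rule",
    "table1_entries",
    "derivation_cohort_stats",
]

LGIB = "LGIB"
NOT_LGIB = "Not LGIB"


def _class_to_bool(name: str) -> bool:
    if name == LGIB:
        return True
    if name == NOT_LGIB:
        return False
    raise LgibError(f"unknown class label {name!r}; expected {LGIB!r} or {NOT_LGIB!r}")


def _bool_to_class(b: bool) -> str:
    return LGIB if b else NOT_LGIB


@dataclass(frozen=True)
class Literal:
    """A single presence/absence test on one (field, code) indicator."""

    field: Field
    code: str
    present: bool = True

    def __post_init__(self):
        object.__setattr__(self, "field", Field(self.field))
        code = self.code.strip()
        if not code:
            raise LgibError("literal code must be non-empty")
        object.__setattr__(self, "code", code)

    def holds(self, a: Admission) -> bool:
        return has_code(a, self.field, self.code) is self.present


@dataclass(frozen=True)
class RuleClause:
    """A conjunction of literals mapping to a predicted class.

    Shipped rules use a single positive literal per clause; ``field`` and
    ``code`` are conveniences for that common case.
    """

    literals: Tuple[Literal, ...]
    predicted: bool

    @classmethod
    def simple(cls, f: Field, code: str, predicted: bool = True) -> "RuleClause":
        return cls((Literal(Field(f), code, True),), predicted)

    @property
    def is_simple(self) -> bool:
        return len(self.literals) == 1 and self.literals[0].present

    @property
    def field(self) -> Field:
        if not self.is_simple:
            raise LgibError("clause is not a single positive test")
        return self.literals[0].field

    @property
    def code(self) -> str:
        if not self.is_simple:
            raise LgibError("clause is not a single positive test")
        return self.literals[0].code


def matches(clause: RuleClause, a: Admission) -> bool:
    """True iff every literal of ``clause`` holds for admission ``a``."""
    return all(lit.holds(a) for lit in clause.literals)


@dataclass(frozen=True)
class RuleList:
    """Ordered first-match IF/ELSE-IF clauses with a default class.

    ``clause_counts`` optionally carries per-clause (n_correct, n_incorrect)
    tallies from the cohort the rule was derived on, aligned with
    ``clauses``; ``default_counts`` is the tally of the default row.
    """

    clauses: Tuple[RuleClause, ...]
    default: bool = False
    provenance: str = ""
    clause_counts: Optional[Tuple[Tuple[int, int], ...]] = None
    default_counts: Optional[Tuple[int, int]] = None
    metadata: Optional[dict] = None

    def __post_init__(self):
        object.__setattr__(self, "clauses", tuple(self.clauses))
        if self.clause_counts is not None:
            counts = tuple((int(c), int(i)) for c, i in self.clause_counts)
            if len(counts) != len(self.clauses):
                raise LgibError(
                    "clause_counts length does not match number of clauses"
                )
            if any(c < 0 or i < 0 for c, i in counts):
                raise LgibError("clause counts must be non-negative")
            object.__setattr__(self, "clause_counts", counts)

    def __len__(self) -> int:
        return len(self.clauses)


def classify(rule: RuleList, a: Admission) -> Tuple[bool, Optional[int]]:
    """Classify one admission.

    Returns ``(predicted_class, matched_clause_index)``; the index is
    ``None`` when the default class applies.  Evaluation is strictly
    first-match in clause order.
    """
    for i, clause in enumerate(rule.clauses):
        if matches(clause, a):
            return clause.predicted, i
    return rule.default, None


# ---------------------------------------------------------------------------
# Shipped rules


def _data_text(name: str) -> str:
    return resources.files("lgibtree.data").joinpath(name).read_text(encoding="utf-8")


@lru_cache(maxsize=None)
def _table1() -> dict:
    return json.loads(_data_text("table1_screening.json"))


def table1_entries() -> Tuple[dict, ...]:
    """The 36 screening codes with their derivation-cohort per-code tallies.

    Each entry has ``code``, ``description`` and ``principal``/``secondary``
    blocks of ``{"n": count, "p_lgib": fraction-or-None}``.
    """
    return tuple(_table1()["codes"])


def derivation_cohort_stats() -> dict:
    """Cohort-level characteristics of the derivation sample (n, screened
    count, confirmed LGIB count, secondary-diagnosis moments, procedure
    rates) used to calibrate the synthetic generator."""
    return dict(_table1()["cohort"])


@lru_cache(maxsize=None)
def screening_rule() -> RuleList:
    """The 36-code screening OR-rule: LGIB iff any screening code appears as
    a principal or secondary diagnosis.

    Order is immaterial for an OR-rule; clauses are shipped as all principal
    tests in table order, then all secondary tests.
    """
    entries = table1_entries()
    clauses = [RuleClause.simple(Field.PRINCIPAL_DX, e["code"]) for e in entries]
    clauses += [RuleClause.simple(Field.SECONDARY_DX, e["code"]) for e in entries]
    return RuleList(
        tuple(clauses),
        default=False,
        provenance=_table1()["provenance"],
    )


@lru_cache(maxsize=None)
def _rule_from_data(name: str) -> RuleList:
    return rule_from_json(json.loads(_data_text(name)))


def high_specificity_rule() -> RuleList:
    """The 11-clause high-specificity rule (prior 0.20), per-clause
    derivation tallies attached."""
    return _rule_from_data("table3_high_specificity.json")


def balanced_rule() -> RuleList:
    """The 14-clause balanced rule (prior 0.70), including the secondary
    diagnosis 280.0 (anemia from chronic blood loss) and colonoscopy
    procedure 45.23 clauses, per-clause derivation tallies attached."""
    return _rule_from_data("table4_balanced.json")


BUILTIN_RULES = {
    "table1": screening_rule,
    "screening": screening_rule,
    "table3": high_specificity_rule,
    "table4": balanced_rule,
}


def builtin_rule(name: str) -> RuleList:
    try:
        return BUILTIN_RULES[name]()
    except KeyError:
        raise LgibError(
            f"unknown builtin rule {name!r}; choose from {sorted(BUILTIN_RULES)}"
        ) from None


# ---------------------------------------------------------------------------
# JSON (de)serialization


def _clause_to_json(clause: RuleClause) -> dict:
    if clause.is_simple:
        return {
            "field": clause.field.value,
            "code": clause.code,
            "class": _bool_to_class(clause.predicted),
        }
    return {
        "tests": [
            {"field": lit.field.value, "code": lit.code, "present": lit.present}
            for lit in clause.literals
        ],
        "class": _bool_to_class(clause.predicted),
    }


def rule_to_json(rule: RuleList) -> dict:
    doc = {
        "provenance": rule.provenance,
        "default": _bool_to_class(rule.default),
        "clauses": [],
    }
    for i, clause in enumerate(rule.clauses):
        cj = _clause_to_json(clause)
        if rule.clause_counts is not None:
            cj["n_correct"], cj["n_incorrect"] = rule.clause_counts[i]
        doc["clauses"].append(cj)
    if rule.default_counts is not None:
        doc["default_counts"] = {
            "n_correct": rule.default_counts[0],
            "n_incorrect": rule.default_counts[1],
        }
    if rule.metadata:
        doc["metadata"] = dict(rule.metadata)
    return doc


def _clause_from_json(cj: dict) -> RuleClause:
    predicted = _class_to_bool(cj["class"])
    if "tests" in cj:
        lits = tuple(
            Literal(Field(t["field"]), t["code"], bool(t.get("present", True)))
            for t in cj["tests"]
        )
        return RuleClause(lits, predicted)
    return RuleClause.simple(Field(cj["field"]), cj["code"], predicted)


def rule_from_json(doc: dict) -> RuleList:
    clauses = tuple(_clause_from_json(cj) for cj in doc["clauses"])
    counts = None
    if doc["clauses"] and all("n_correct" in cj for cj in doc["clauses"]):
        counts = tuple(
            (int(cj["n_correct"]), int(cj["n_incorrect"])) for cj in doc["clauses"]
        )
    default_counts = None
    if "default_counts" in doc:
        dc = doc["default_counts"]
        default_counts = (int(dc["n_correct"]), int(dc["n_incorrect"]))
    return RuleList(
        clauses,
        default=_class_to_bool(doc.get("default", NOT_LGIB)),
        provenance=doc.get("provenance", ""),
        clause_counts=counts,
        default_counts=default_counts,
        metadata=doc.get("metadata"),
    )


def save_rule(rule: RuleList, path: Union[str, Path]) -> Path:
    path = Path(path)
    path.write_text(json.dumps(rule_to_json(rule), indent=2) + "\n", encoding="utf-8")
    return path


def load_rule(path: Union[str, Path]) -> RuleList:
    return rule_from_json(json.loads(Path(path).read_text(encoding="utf-8")))
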