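"""Synthetic admission cohorts: exact fixtures and calibrated stochastic draws.

Two generation modes serve two different purposes.

**Fixture mode** (:func:`cohort_from_rule_counts`, :func:`fixture_cohort`,
:func:`screening_fixture`) deterministically constructs a cohort on which a
given rule list reproduces a prescribed per-clause confusion tally exactly:
clause *k* contributes its ``n_correct`` truly-LGIB and ``n_incorrect``
non-LGIB admissions, each carrying clause *k*'s code in clause *k*'s field
and synthetic filler codes everywhere else, so no earlier clause can fire.
Clause match-sets are therefore disjoint by construction; only the per-clause
tallies are contractual.

**Stochastic mode** (:func:`sample_cohort` with a :class:`GeneratorConfig`)
draws seeded cohorts with the statistical structure of a general-medicine
inpatient service: a small screened subpopulation carrying LGIB-associated
codes, an overall LGIB prevalence around 4.3%, overdispersed
secondary-diagnosis counts, and background filler codes carrying no signal.

Calibration note: published per-code tallies count a patient once per code
they carry, so multi-code patients are double counted and the per-code
marginal counts alone overstate both the screened fraction and the number of
LGIB cases.  The sampler therefore factorizes the other way around: it first
draws screened status and the LGIB label, then a *bundle* of screening-code
slots from class-conditional slot weights.  This reproduces the per-code
marginal counts, the per-code conditional LGIB rates, the screened fraction
and the cohort prevalence simultaneously (see docs/methods.md).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import yaml

from .core import Admission, Cohort, Field, LgibError, MAX_LIST_CODES
from . import rules as _rules
from .rules import RuleClause, RuleList

__all__ = [
    "ClauseCounts",
    "SlotSpec",
    "GeneratorConfig",
    "FixtureError",
    "clause_counts",
    "cohort_from_rule_counts",
    "fixture_cohort",
    "screening_fixture",
    "default_generator_config",
    "config_from_rule_counts",
    "sample_cohort",
    "save_config",
    "load_config",
    "DEFAULT_FILLER_DX",
    "DEFAULT_FILLER_PROC",
]

# Synthetic filler codes, deliberately shaped unlike ICD-9-CM so they can
# never collide with a real screening or rule code.
DEFAULT_FILLER_DX: Tuple[str, ...] = tuple(f"FDX{i:03d}" for i in range(250))
DEFAULT_FILLER_PROC: Tuple[str, ...] = tuple(f"FPR{i:03d}" for i in range(40))


class FixtureError(LgibError):
    """Raised when an exact fixture cannot be constructed as specified."""


@dataclass(frozen=True)
class ClauseCounts:
    """One rule clause with its (n_correct, n_incorrect) evaluation tally."""

    clause: RuleClause
    n_correct: int
    n_incorrect: int

    def __post_init__(self):
        if self.n_correct < 0 or self.n_incorrect < 0:
            raise LgibError("clause counts must be non-negative")


def clause_counts(rule: RuleList) -> List[ClauseCounts]:
    """Per-clause tallies of ``rule`` as :class:`ClauseCounts` objects."""
    if rule.clause_counts is None:
        raise LgibError("rule carries no per-clause counts")
    return [
        ClauseCounts(cl, c, i)
        for cl, (c, i) in zip(rule.clauses, rule.clause_counts)
    ]


# ---------------------------------------------------------------------------
# Fixture mode


def _fill_fields(
    f: Optional[Field], code: Optional[str], filler: "itertools.cycle"
) -> dict:
    kwargs = {
        "principal_dx": next(filler),
        "secondary_dx": frozenset(),
        "principal_proc": None,
        "secondary_proc": frozenset(),
    }
    if f is not None:
        if f is Field.PRINCIPAL_DX:
            kwargs["principal_dx"] = code
        elif f is Field.SECONDARY_DX:
            kwargs["secondary_dx"] = frozenset((code,))
        elif f is Field.PRINCIPAL_PROC:
            kwargs["principal_proc"] = code
        else:
            kwargs["secondary_proc"] = frozenset((code,))
    return kwargs


def cohort_from_rule_counts(
    clauses: Sequence[ClauseCounts],
    default_correct: int,
    default_incorrect: int,
    filler_pool: Optional[Sequence[str]] = None,
    label: str = "fixture",
) -> Cohort:
    """Deterministically build a cohort reproducing per-clause tallies.

    Evaluating the corresponding rule list on the returned cohort yields
    exactly ``(n_correct, n_incorrect)`` at every clause and
    ``(default_correct, default_incorrect)`` at the default row.  The
    default class is assumed negative: default-row admissions are
    ``default_correct`` non-LGIB plus ``default_incorrect`` LGIB records
    carrying only filler codes.

    Raises :class:`FixtureError` when construction is impossible: a clause
    repeating an earlier clause's (field, code) test could never receive a
    first-match admission, a non-simple clause has no single code to plant,
    or the filler pool intersects a clause code.
    """
    pool = tuple(filler_pool) if filler_pool is not None else DEFAULT_FILLER_DX
    if not pool:
        raise FixtureError("filler pool is empty")
    clause_codes = set()
    for k, cc in enumerate(clauses):
        if not cc.clause.is_simple:
            raise FixtureError(
                f"clause {k + 1}: fixture construction requires a single "
                "positive (field, code) test"
            )
        clause_codes.add(cc.clause.code)
    overlap = clause_codes & set(pool)
    if overlap:
        raise FixtureError(f"filler pool overlaps clause codes: {sorted(overlap)}")

    filler = itertools.cycle(pool)
    admissions: List[Admission] = []
    seen: set = set()
    counter = itertools.count(1)

    def emit(n: int, lgib: bool, f: Optional[Field], code: Optional[str]) -> None:
        for _ in range(n):
            admissions.append(
                Admission(
                    id=f"{label}-{next(counter):05d}",
                    lgib=lgib,
                    **_fill_fields(f, code, filler),
                )
            )

    for k, cc in enumerate(clauses):
        key = (cc.clause.field, cc.clause.code)
        if key in seen:
            raise FixtureError(
                f"clause {k + 1} ({key[0].value} = {key[1]}) repeats an earlier "
                "clause's test; its admissions would be captured upstream"
            )
        seen.add(key)
        emit(cc.n_correct, cc.clause.predicted, *key)
        emit(cc.n_incorrect, not cc.clause.predicted, *key)
    emit(default_correct, False, None, None)
    emit(default_incorrect, True, None, None)
    return Cohort(tuple(admissions), label=label)


def fixture_cohort(rule: RuleList, label: Optional[str] = None) -> Cohort:
    """Fixture cohort for a rule that ships per-clause tallies."""
    if rule.default_counts is None:
        raise LgibError("rule carries no default-row counts")
    return cohort_from_rule_counts(
        clause_counts(rule),
        default_correct=rule.default_counts[0],
        default_incorrect=rule.default_counts[1],
        label=label or "fixture",
    )


def _apportion(weights: np.ndarray, total: int) -> np.ndarray:
    """Largest-remainder apportionment of ``total`` units over ``weights``."""
    weights = np.asarray(weights, dtype=float)
    if total == 0:
        return np.zeros(len(weights), dtype=int)
    if weights.sum() <= 0:
        raise LgibError("cannot apportion over all-zero weights")
    quota = weights / weights.sum() * total
    base = np.floor(quota).astype(int)
    short = total - int(base.sum())
    if short:
        order = np.argsort(-(quota - base), kind="stable")
        base[order[:short]] += 1
    return base


def screening_fixture(
    filler_pool: Optional[Sequence[str]] = None, label: str = "screening-fixture"
) -> Cohort:
    """Deterministic derivation-consistent cohort for the screening rule.

    Exactly 768 admissions carry one screening code each (297 of them LGIB),
    and 6,206 carry only filler codes.  Screened admissions are spread over
    the per-code principal/secondary slots proportionally to each slot's
    published LGIB (for cases) or non-LGIB (for non-cases) tally, by
    largest-remainder apportionment.
    """
    stats = _rules.derivation_cohort_stats()
    n_total, n_screened, n_lgib = stats["n"], stats["screened"], stats["lgib"]
    entries = _rules.table1_entries()
    slots: List[Tuple[Field, str, float, float]] = []
    for f, block in ((Field.PRINCIPAL_DX, "principal"), (Field.SECONDARY_DX, "secondary")):
        for e in entries:
            n = e[block]["n"]
            p = e[block]["p_lgib"] or 0.0
            slots.append((f, e["code"], n * p, n * (1.0 - p)))
    lgib_alloc = _apportion(np.array([s[2] for s in slots]), n_lgib)
    non_alloc = _apportion(np.array([s[3] for s in slots]), n_screened - n_lgib)

    pool = tuple(filler_pool) if filler_pool is not None else DEFAULT_FILLER_DX
    codes_used = {s[1] for s in slots}
    if codes_used & set(pool):
        raise FixtureError("filler pool overlaps screening codes")
    filler = itertools.cycle(pool)
    admissions: List[Admission] = []
    counter = itertools.count(1)
    for (f, code, _, _), n1, n0 in zip(slots, lgib_alloc, non_alloc):
        for lgib, n in ((True, int(n1)), (False, int(n0))):
            for _ in range(n):
                admissions.append(
                    Admission(
                        id=f"{label}-{next(counter):05d}",
                        lgib=lgib,
                        **_fill_fields(f, code, filler),
                    )
                )
    for _ in range(n_total - n_screened):
        admissions.append(
            Admission(
                id=f"{label}-{next(counter):05d}",
                lgib=False,
                **_fill_fields(None, None, filler),
            )
        )
    return Cohort(tuple(admissions), label=label)


# ---------------------------------------------------------------------------
# Stochastic mode


@dataclass(frozen=True)
class SlotSpec:
    """Marginal rate and conditional LGIB probability of one (field, code)
    slot, e.g. 'code 562.12 as principal diagnosis'."""

    field: Field
    code: str
    rate: float
    p_lgib: Optional[float] = None

    def __post_init__(self):
        object.__setattr__(self, "field", Field(self.field))
        if not (0.0 <= self.rate <= 1.0):
            raise LgibError(f"slot {self.code}: rate must be in [0, 1]")
        if self.p_lgib is not None and not (0.0 <= self.p_lgib <= 1.0):
            raise LgibError(f"slot {self.code}: p_lgib must be in [0, 1]")
        if self.p_lgib is None and self.rate > 0:
            raise LgibError(
                f"slot {self.code}: p_lgib may be omitted only for rate-0 slots"
            )


@dataclass(frozen=True)
class GeneratorConfig:
    """Everything the stochastic cohort sampler needs.

    ``slots`` lists the signal-bearing (field, code) indicators with their
    marginal per-admission rates and conditional LGIB probabilities, in
    priority order (principal slots first for the shipped default).
    ``screened_rate``/``lgib_rate`` set the fraction of admissions carrying
    at least one slot code and the overall LGIB prevalence; when ``None``
    they are derived from the slot marginals assuming one slot per patient.
    Remaining fields describe signal-free decoration: overdispersed
    secondary-diagnosis counts (truncated at 30), procedure coding rates,
    and the filler code pools, which must be disjoint from every slot code
    and every code in a shipped rule.
    """

    n_patients: int = 6974
    slots: Tuple[SlotSpec, ...] = ()
    screened_rate: Optional[float] = None
    lgib_rate: Optional[float] = None
    unscreened_lgib_rate: float = 0.0
    secondary_dx_mean: float = 8.0
    secondary_dx_sd: float = 4.6
    principal_proc_rate: float = 5068 / 6974
    secondary_proc_mean: float = 1.2
    secondary_proc_sd: float = 1.9
    filler_dx_pool: Tuple[str, ...] = DEFAULT_FILLER_DX
    filler_proc_pool: Tuple[str, ...] = DEFAULT_FILLER_PROC
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "slots", tuple(self.slots))
        if self.n_patients < 1:
            raise LgibError("n_patients must be >= 1")
        for name in ("screened_rate", "lgib_rate", "unscreened_lgib_rate",
                     "principal_proc_rate"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise LgibError(f"{name} must be in [0, 1], got {v}")
        if not self.filler_dx_pool:
            raise LgibError("filler_dx_pool must not be empty")
        if not self.filler_proc_pool:
            raise LgibError("filler_proc_pool must not be empty")
        reserved = {s.code for s in self.slots}
        for getter in (_rules.screening_rule, _rules.high_specificity_rule,
                       _rules.balanced_rule):
            for cl in getter().clauses:
                for lit in cl.literals:
                    reserved.add(lit.code)
        fillers = set(self.filler_dx_pool) | set(self.filler_proc_pool)
        clash = fillers & reserved
        if clash:
            raise LgibError(
                f"filler pool overlaps screening/rule codes: {sorted(clash)[:5]}"
            )
        keys = [(s.field, s.code) for s in self.slots]
        if len(set(keys)) != len(keys):
            raise LgibError("duplicate (field, code) slot in config")

    # -- derived calibration ------------------------------------------------

    @property
    def resolved_screened_rate(self) -> float:
        if self.screened_rate is not None:
            return self.screened_rate
        return min(1.0, float(sum(s.rate for s in self.slots)))

    @property
    def resolved_lgib_rate(self) -> float:
        if self.lgib_rate is not None:
            return self.lgib_rate
        return min(
            self.resolved_screened_rate,
            float(sum(s.rate * (s.p_lgib or 0.0) for s in self.slots)),
        )


def default_generator_config(seed: int = 0) -> GeneratorConfig:
    """Generator config calibrated to the derivation cohort.

    Per-slot rates are published per-code counts over n = 6,974 and
    conditional LGIB probabilities are the published percentages; cohort-level
    screened fraction (768/6,974) and prevalence (297/6,974) come from the
    cohort-characteristics table, as do the secondary-diagnosis moments
    (mean 8.0, SD 4.6), principal-procedure rate (5,068/6,974) and
    secondary-procedure moments (mean 1.2, SD 1.9).
    """
    stats = _rules.derivation_cohort_stats()
    n = stats["n"]
    slots: List[SlotSpec] = []
    for f, block in ((Field.PRINCIPAL_DX, "principal"), (Field.SECONDARY_DX, "secondary")):
        for e in _rules.table1_entries():
            slots.append(
                SlotSpec(f, e["code"], rate=e[block]["n"] / n, p_lgib=e[block]["p_lgib"])
            )
    return GeneratorConfig(
        n_patients=n,
        slots=tuple(slots),
        screened_rate=stats["screened"] / n,
        lgib_rate=stats["lgib"] / n,
        secondary_dx_mean=stats["secondary_dx_mean"],
        secondary_dx_sd=stats["secondary_dx_sd"],
        principal_proc_rate=stats["principal_proc_n"] / n,
        secondary_proc_mean=stats["secondary_proc_mean"],
        secondary_proc_sd=stats["secondary_proc_sd"],
        seed=seed,
    )


def config_from_rule_counts(rule: RuleList, seed: int = 0) -> GeneratorConfig:
    """Generator config whose cohorts stochastically reproduce a rule's
    published evaluation profile.

    Each clause becomes one slot with rate ``(n_correct + n_incorrect) / n``
    and conditional LGIB probability ``n_correct / (n_correct +
    n_incorrect)``; the default row sets the unscreened LGIB rate.  Used to
    emulate held-out validation as a stochastic property when the original
    record-level data are unavailable.
    """
    if rule.clause_counts is None or rule.default_counts is None:
        raise LgibError("rule carries no evaluation counts")
    ccs = clause_counts(rule)
    d_correct, d_incorrect = rule.default_counts
    n = sum(cc.n_correct + cc.n_incorrect for cc in ccs) + d_correct + d_incorrect
    slots = []
    for cc in ccs:
        total = cc.n_correct + cc.n_incorrect
        slots.append(
            SlotSpec(
                cc.clause.field,
                cc.clause.code,
                rate=total / n,
                p_lgib=(cc.n_correct / total) if total else None,
            )
        )
    screened = sum(s.rate for s in slots)
    lgib = sum(cc.n_correct for cc in ccs) / n
    n_default = d_correct + d_incorrect
    return GeneratorConfig(
        n_patients=n,
        slots=tuple(slots),
        screened_rate=screened,
        lgib_rate=lgib,
        unscreened_lgib_rate=(d_incorrect / n_default) if n_default else 0.0,
        seed=seed,
    )


def _count_draw(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    """Draw overdispersed non-negative counts: negative binomial matched to
    (mean, sd) when sd^2 > mean, else Poisson; truncated at the 30-slot cap."""
    if mean <= 0:
        return np.zeros(size, dtype=int)
    var = sd * sd
    if var > mean:
        k = mean * mean / (var - mean)
        p = k / (k + mean)
        draws = rng.negative_binomial(k, p, size=size)
    else:
        draws = rng.poisson(mean, size=size)
    return np.minimum(draws, MAX_LIST_CODES)


def sample_cohort(config: GeneratorConfig, seed: Optional[int] = None) -> Cohort:
    """Draw one seeded stochastic cohort.

    Per admission: screened status, then the LGIB label, then a bundle of
    1 + Poisson(λ) screening-code slots from class-conditional slot weights
    (λ calibrated so per-slot marginal rates match the config), then
    signal-free decoration (filler secondary diagnoses to an overdispersed
    target count, procedure codes).  At most one principal diagnosis slot and
    one principal procedure slot are kept per admission.  Identical seeds
    give identical cohorts.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_patients
    S = config.resolved_screened_rate
    L = config.resolved_lgib_rate
    if L > S + 1e-12:
        raise LgibError("lgib_rate cannot exceed screened_rate")
    p_l_given_s = (L / S) if S > 0 else 0.0

    rate = np.array([s.rate for s in config.slots], dtype=float)
    p = np.array([s.p_lgib or 0.0 for s in config.slots], dtype=float)
    w_case = rate * p
    w_non = rate * (1.0 - p)
    t_case, t_non = w_case.sum(), w_non.sum()
    n_case_rate, n_non_rate = L, S - L
    lam_case = max(0.0, t_case / n_case_rate - 1.0) if n_case_rate > 0 else 0.0
    lam_non = max(0.0, t_non / n_non_rate - 1.0) if n_non_rate > 0 else 0.0
    if n_case_rate == 0 and t_case > 0:
        raise LgibError("slots imply LGIB mass but lgib_rate is 0")
    probs_case = w_case / t_case if t_case > 0 else None
    probs_non = w_non / t_non if t_non > 0 else None

    screened = rng.random(n) < S
    u_label = rng.random(n)
    lgib = np.where(screened, u_label < p_l_given_s, u_label < config.unscreened_lgib_rate)
    sec_dx_target = _count_draw(
        rng, config.secondary_dx_mean, config.secondary_dx_sd, n
    )
    has_pproc = rng.random(n) < config.principal_proc_rate
    sec_proc_target = _count_draw(
        rng, config.secondary_proc_mean, config.secondary_proc_sd, n
    )
    dx_pool = np.array(config.filler_dx_pool)
    proc_pool = np.array(config.filler_proc_pool)

    admissions: List[Admission] = []
    for i in range(n):
        p_dx: Optional[str] = None
        s_dx: List[str] = []
        p_proc: Optional[str] = None
        s_proc: List[str] = []
        if screened[i]:
            probs = probs_case if lgib[i] else probs_non
            lam = lam_case if lgib[i] else lam_non
            if probs is None:
                raise LgibError(
                    "no slot has mass for the "
                    + ("LGIB" if lgib[i] else "non-LGIB")
                    + " class; check slot rates and probabilities"
                )
            support = int(np.count_nonzero(probs))
            m = min(1 + int(rng.poisson(lam)), support)
            picks = rng.choice(len(probs), size=m, replace=False, p=probs)
            for j in picks:
                slot = config.slots[int(j)]
                if slot.field is Field.PRINCIPAL_DX:
                    if p_dx is None:
                        p_dx = slot.code
                elif slot.field is Field.SECONDARY_DX:
                    s_dx.append(slot.code)
                elif slot.field is Field.PRINCIPAL_PROC:
                    if p_proc is None:
                        p_proc = slot.code
                else:
                    s_proc.append(slot.code)
        if p_dx is None:
            p_dx = str(rng.choice(dx_pool))
        extra_dx = min(
            max(int(sec_dx_target[i]) - len(s_dx), 0), MAX_LIST_CODES - len(s_dx)
        )
        if extra_dx:
            s_dx.extend(rng.choice(dx_pool, size=extra_dx, replace=False).tolist())
        if p_proc is None and has_pproc[i]:
            p_proc = str(rng.choice(proc_pool))
        extra_proc = min(
            max(int(sec_proc_target[i]) - len(s_proc), 0),
            MAX_LIST_CODES - len(s_proc),
        )
        if extra_proc:
            s_proc.extend(rng.choice(proc_pool, size=extra_proc, replace=False).tolist())
        admissions.append(
            Admission(
                id=f"syn-{i + 1:05d}",
                principal_dx=p_dx,
                secondary_dx=frozenset(s_dx),
                principal_proc=p_proc,
                secondary_proc=frozenset(s_proc),
                lgib=bool(lgib[i]),
            )
        )
    return Cohort(tuple(admissions), label=f"synthetic(seed={config.seed if seed is None else seed})")


# ---------------------------------------------------------------------------
# Config (de)serialization — YAML, of which JSON is a subset


def config_to_dict(config: GeneratorConfig) -> dict:
    return {
        "n_patients": config.n_patients,
        "slots": [
            {"field": s.field.value, "code": s.code, "rate": s.rate, "p_lgib": s.p_lgib}
            for s in config.slots
        ],
        "screened_rate": config.screened_rate,
        "lgib_rate": config.lgib_rate,
        "unscreened_lgib_rate": config.unscreened_lgib_rate,
        "secondary_dx_mean": config.secondary_dx_mean,
        "secondary_dx_sd": config.secondary_dx_sd,
        "principal_proc_rate": config.principal_proc_rate,
        "secondary_proc_mean": config.secondary_proc_mean,
        "secondary_proc_sd": config.secondary_proc_sd,
        "filler_dx_pool": list(config.filler_dx_pool),
        "filler_proc_pool": list(config.filler_proc_pool),
        "seed": config.seed,
    }


def config_from_dict(doc: dict) -> GeneratorConfig:
    doc = dict(doc)
    slots = tuple(
        SlotSpec(Field(s["field"]), s["code"], float(s["rate"]),
                 None if s.get("p_lgib") is None else float(s["p_lgib"]))
        for s in doc.pop("slots", [])
    )
    for key in ("filler_dx_pool", "filler_proc_pool"):
        if key in doc and doc[key] is not None:
            doc[key] = tuple(doc[key])
    return GeneratorConfig(slots=slots, **doc)


def save_config(config: GeneratorConfig, path: Union[str, Path]) -> Path:
    path = Path(path)
    path.write_text(
        yaml.safe_dump(config_to_dict(config), sort_keys=False), encoding="utf-8"
    )
    return path


def load_config(path: Union[str, Path]) -> GeneratorConfig:
    return config_from_dict(yaml.safe_load(Path(path).read_text(encoding="utf-8")))
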