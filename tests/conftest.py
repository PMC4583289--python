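"""Shared fixtures, hypothesis strategies, and independent oracles."""

from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings, strategies as st

import lgibtree as lt
from lgibtree.core import FIELD_ORDER, Admission, Cohort, Field, field_rank, has_code

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.function_scoped_fixture, HealthCheck.too_slow],
)
settings.load_profile("suite")


# ---------------------------------------------------------------------------
# Strategies

DX_POOL = ("100.0", "100.1", "200.5", "300.9", "455.0", "562.12", "578.1", "X1", "X2")
PROC_POOL = ("45.23", "99.1", "88.0")


@st.composite
def admissions(draw, idx=None, labeled=True):
    principal = draw(st.sampled_from(DX_POOL))
    secondary = draw(st.frozensets(st.sampled_from(DX_POOL), max_size=4))
    pproc = draw(st.one_of(st.none(), st.sampled_from(PROC_POOL)))
    sproc = draw(st.frozensets(st.sampled_from(PROC_POOL), max_size=2))
    lgib = draw(st.booleans()) if labeled else draw(st.one_of(st.none(), st.booleans()))
    return Admission(
        id=f"a{idx if idx is not None else draw(st.integers(0, 10**9))}",
        principal_dx=principal,
        secondary_dx=secondary,
        principal_proc=pproc,
        secondary_proc=sproc,
        lgib=lgib,
    )


@st.composite
def cohorts(draw, min_size=2, max_size=40, labeled=True, both_classes=False):
    n = draw(st.integers(min_size, max_size))
    adms = [draw(admissions(idx=i, labeled=labeled)) for i in range(n)]
    if both_classes:
        adms[0] = Admission(**{**_as_kwargs(adms[0]), "lgib": True})
        adms[-1] = Admission(**{**_as_kwargs(adms[-1]), "lgib": False})
    return Cohort(tuple(adms), label="generated")


def _as_kwargs(a: Admission) -> dict:
    return dict(
        id=a.id,
        principal_dx=a.principal_dx,
        secondary_dx=a.secondary_dx,
        principal_proc=a.principal_proc,
        secondary_proc=a.secondary_proc,
        lgib=a.lgib,
    )


# ---------------------------------------------------------------------------
# Independent exhaustive split-search oracle (plain Python, no shared code
# with the implementation under test).


def oracle_best_split(cohort, w_case, w_noncase, min_node):
    """Exhaustively score every (field, code) indicator and return
    ``(delta, (field, code))`` for the best admissible split, or ``None``."""
    feats = sorted(
        {(f, c) for a in cohort for f in FIELD_ORDER for c in a.codes(f)},
        key=lambda fc: (field_rank(fc[0]), fc[1]),
    )
    n1 = sum(1 for a in cohort if a.lgib)
    n0 = len(cohort) - n1
    if n1 == 0 or n0 == 0:
        return None
    W = w_case * n1 + w_noncase * n0
    p = w_case * n1 / W
    i_t = p * (1 - p)
    best = None
    for f, code in feats:
        c1 = sum(1 for a in cohort if a.lgib and has_code(a, f, code))
        c0 = sum(1 for a in cohort if not a.lgib and has_code(a, f, code))
        nL = c1 + c0
        nR = len(cohort) - nL
        if nL < min_node or nR < min_node:
            continue
        WL = w_case * c1 + w_noncase * c0
        WR = W - WL
        if WL <= 0 or WR <= 0:
            continue
        pL = w_case * c1 / WL
        pR = w_case * (n1 - c1) / WR
        delta = i_t - (WL / W) * pL * (1 - pL) - (WR / W) * pR * (1 - pR)
        if delta <= 1e-12:
            continue
        if best is None or delta > best[0] + 1e-12:
            best = (delta, (f, code))
    return best


# ---------------------------------------------------------------------------
# Shared fixtures


@pytest.fixture(scope="session")
def table3_rule():
    return lt.high_specificity_rule()


@pytest.fixture(scope="session")
def table4_rule():
    return lt.balanced_rule()


@pytest.fixture(scope="session")
def screening():
    return lt.screening_rule()


@pytest.fixture(scope="session")
def table3_fixture(table3_rule):
    return lt.fixture_cohort(table3_rule, label="t3fix")


@pytest.fixture(scope="session")
def table4_fixture(table4_rule):
    return lt.fixture_cohort(table4_rule, label="t4fix")


@pytest.fixture(scope="session")
def screening_fix():
    return lt.screening_fixture()
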