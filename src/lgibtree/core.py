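"""Domain types for coded hospital admission records.

An :class:`Admission` is one inpatient stay as it appears in a hospital
administrative database: one required principal ICD-9-CM diagnosis, up to 30
secondary diagnoses, an optional principal procedure, up to 30 secondary
procedures, and an optional gold-standard chart-review label for lower
gastrointestinal bleeding (LGIB).

Codes are opaque strings compared by exact equality after whitespace
trimming: ``"578.1"`` and ``"578.10"`` are different codes.  Secondary
diagnosis and procedure slots carry no order semantics and are stored as
sets; duplicates collapse.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterator, Optional, Sequence, Tuple, Union

__all__ = [
    "Field",
    "FIELD_ORDER",
    "MAX_LIST_CODES",
    "Admission",
    "Cohort",
    "LgibError",
    "CohortFormatError",
    "has_code",
    "read_cohort",
    "write_cohort",
]

MAX_LIST_CODES = 30

CSV_COLUMNS = (
    "id",
    "principal_dx",
    "secondary_dx",
    "principal_proc",
    "secondary_proc",
    "lgib",
)

LIST_DELIMITER = ";"


class LgibError(ValueError):
    """Base class for domain errors raised by this package."""


class CohortFormatError(LgibError):
    """Raised when a cohort CSV violates the documented dialect."""


class Field(str, Enum):
    """The four code-bearing fields of an admission record."""

    PRINCIPAL_DX = "principal_dx"
    SECONDARY_DX = "secondary_dx"
    PRINCIPAL_PROC = "principal_proc"
    SECONDARY_PROC = "secondary_proc"


#: Canonical ordering of fields, used for deterministic tie-breaking.
FIELD_ORDER: Tuple[Field, ...] = (
    Field.PRINCIPAL_DX,
    Field.SECONDARY_DX,
    Field.PRINCIPAL_PROC,
    Field.SECONDARY_PROC,
)

_FIELD_RANK = {f: i for i, f in enumerate(FIELD_ORDER)}


def field_rank(f: Field) -> int:
    """Position of ``f`` in the canonical field order."""
    return _FIELD_RANK[f]


def _clean_code(code: str) -> str:
    return code.strip()


def _clean_set(codes, what: str) -> frozenset:
    cleaned = frozenset(_clean_code(c) for c in codes if _clean_code(c))
    if len(cleaned) > MAX_LIST_CODES:
        raise LgibError(
            f"{what} holds {len(cleaned)} codes; at most {MAX_LIST_CODES} allowed"
        )
    return cleaned


@dataclass(frozen=True)
class Admission:
    """One inpatient record with coded fields and an optional LGIB label.

    ``lgib`` is tri-state: ``True``/``False`` when the chart was reviewed,
    ``None`` when no gold standard is available, so unlabeled cohorts can be
    classified before any evaluation.
    """

    id: str
    principal_dx: str
    secondary_dx: frozenset = frozenset()
    principal_proc: Optional[str] = None
    secondary_proc: frozenset = frozenset()
    lgib: Optional[bool] = None

    def __post_init__(self):
        object.__setattr__(self, "id", str(self.id).strip())
        principal = _clean_code(self.principal_dx)
        if not principal:
            raise LgibError(f"admission {self.id!r}: principal diagnosis is required")
        object.__setattr__(self, "principal_dx", principal)
        object.__setattr__(
            self, "secondary_dx", _clean_set(self.secondary_dx, "secondary_dx")
        )
        proc = self.principal_proc
        if proc is not None:
            proc = _clean_code(proc) or None
        object.__setattr__(self, "principal_proc", proc)
        object.__setattr__(
            self, "secondary_proc", _clean_set(self.secondary_proc, "secondary_proc")
        )

    def codes(self, f: Field) -> frozenset:
        """All codes stored in field ``f`` (a singleton or empty set for
        principal fields)."""
        if f is Field.PRINCIPAL_DX:
            return frozenset((self.principal_dx,))
        if f is Field.SECONDARY_DX:
            return self.secondary_dx
        if f is Field.PRINCIPAL_PROC:
            return frozenset(() if self.principal_proc is None else (self.principal_proc,))
        return self.secondary_proc

    def iter_features(self) -> Iterator[Tuple[Field, str]]:
        """Yield every (field, code) indicator this admission switches on."""
        for f in FIELD_ORDER:
            for code in self.codes(f):
                yield (f, code)


def has_code(a: Admission, f: Field, code: str) -> bool:
    """True iff admission ``a`` carries ``code`` in field ``f``.

    Exact string equality after trimming; principal fields match only their
    single code, secondary fields by set membership.
    """
    return _clean_code(code) in a.codes(f)


@dataclass(frozen=True)
class Cohort:
    """An ordered collection of admissions with a free-text label."""

    admissions: Tuple[Admission, ...]
    label: str = "cohort"

    def __post_init__(self):
        object.__setattr__(self, "admissions", tuple(self.admissions))
        if not self.admissions:
            raise LgibError("a cohort must contain at least one admission")
        ids = [a.id for a in self.admissions]
        if len(set(ids)) != len(ids):
            seen, dupes = set(), set()
            for i in ids:
                (dupes if i in seen else seen).add(i)
            raise LgibError(f"duplicate admission ids in cohort: {sorted(dupes)[:5]}")

    def __len__(self) -> int:
        return len(self.admissions)

    def __iter__(self) -> Iterator[Admission]:
        return iter(self.admissions)

    def __getitem__(self, i) -> Admission:
        return self.admissions[i]

    @property
    def n_lgib(self) -> int:
        """Number of admissions with a positive gold-standard label."""
        return sum(1 for a in self if a.lgib is True)

    def require_labels(self) -> None:
        unlabeled = [a.id for a in self if a.lgib is None]
        if unlabeled:
            raise LgibError(
                f"{len(unlabeled)} admissions lack a gold-standard label "
                f"(first: {unlabeled[0]!r})"
            )


def _parse_lgib(cell: str, where: str) -> Optional[bool]:
    cell = cell.strip()
    if cell == "":
        return None
    if cell == "1":
        return True
    if cell == "0":
        return False
    raise CohortFormatError(f"{where}: lgib cell must be '', '0' or '1', got {cell!r}")


def read_cohort(path: Union[str, Path], label: Optional[str] = None) -> Cohort:
    """Read a cohort from the package's CSV dialect.

    Comma-separated, UTF-8, required header ``id,principal_dx,secondary_dx,
    principal_proc,secondary_proc,lgib``; multi-code cells are
    ';'-delimited; empty cells mean absent fields; lgib is ``1``/``0``/empty.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise CohortFormatError(f"{path}: empty file") from None
        if tuple(h.strip() for h in header) != CSV_COLUMNS:
            raise CohortFormatError(
                f"{path}: header {header!r} does not match {list(CSV_COLUMNS)}"
            )
        admissions = []
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != len(CSV_COLUMNS):
                raise CohortFormatError(
                    f"{path}, line {lineno}: expected {len(CSV_COLUMNS)} cells, "
                    f"got {len(row)}"
                )
            rid, pdx, sdx, pproc, sproc, lg = row
            where = f"{path}, line {lineno}"
            if not pdx.strip():
                raise CohortFormatError(f"{where}: missing principal_dx")
            try:
                admissions.append(
                    Admission(
                        id=rid,
                        principal_dx=pdx,
                        secondary_dx=_split_cell(sdx),
                        principal_proc=pproc.strip() or None,
                        secondary_proc=_split_cell(sproc),
                        lgib=_parse_lgib(lg, where),
                    )
                )
            except LgibError as exc:
                raise CohortFormatError(f"{where}: {exc}") from exc
    return Cohort(tuple(admissions), label=label or path.stem)


def _split_cell(cell: str) -> frozenset:
    cell = cell.strip()
    if not cell:
        return frozenset()
    return frozenset(c.strip() for c in cell.split(LIST_DELIMITER) if c.strip())


def _join(codes: frozenset) -> str:
    return LIST_DELIMITER.join(sorted(codes))


def write_cohort(cohort: Cohort, path: Union[str, Path]) -> Path:
    """Write ``cohort`` in the CSV dialect read by :func:`read_cohort`.

    Output is deterministic (multi-code cells sorted) so identical cohorts
    produce byte-identical files.
    """
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(CSV_COLUMNS)
        for a in cohort:
            writer.writerow(
                [
                    a.id,
                    a.principal_dx,
                    _join(a.secondary_dx),
                    a.principal_proc or "",
                    _join(a.secondary_proc),
                    "" if a.lgib is None else ("1" if a.lgib else "0"),
                ]
            )
    return path
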