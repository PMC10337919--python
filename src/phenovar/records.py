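"""Per-group strain summary records and coefficient-of-variation computation.

The atom of the whole pipeline is one animal-group summary: one mouse strain,
one sex, measured for one parameter within one project, reported as the group
size ``n``, the group ``mean`` and the sample standard deviation ``sd`` — the
shape of a Mouse Phenome Database (MPD) strain-survey export row.  The
coefficient of variation, CV = SD / mean, is attached per record; records with
a non-positive mean cannot carry a meaningful CV and are flagged invalid
rather than rejected (exclusion is a downstream filtering decision).
"""

from __future__ import annotations

import dataclasses
import enum
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import pandas as pd
import yaml

__all__ = [
    "Trait",
    "StrainClass",
    "Sex",
    "StrainGroupRecord",
    "CVRecord",
    "CsvDialect",
    "ReadResult",
    "RowError",
    "CANONICAL_COLUMNS",
    "compute_cv",
    "attach_cv",
    "read_strain_summaries",
    "write_strain_summaries",
]


class Trait(str, enum.Enum):
    CLINICAL_CHEMISTRY = "clinical_chemistry"
    HEMATOLOGY = "hematology"
    IMMUNOLOGY = "immunology"
    BEHAVIOR = "behavior"
    CONTROL = "control"


class StrainClass(str, enum.Enum):
    INBRED = "inbred"
    CC_INBRED = "cc_inbred"  # Collaborative Cross derived inbred
    F1_HYBRID = "f1_hybrid"
    OTHER = "other"


class Sex(str, enum.Enum):
    FEMALE = "female"
    MALE = "male"


#: Canonical CSV header, in writing order.
CANONICAL_COLUMNS: tuple[str, ...] = (
    "project_id",
    "parameter_id",
    "trait",
    "test_id",
    "strain",
    "strain_class",
    "sex",
    "n",
    "mean",
    "sd",
    "age_weeks",
    "treated",
    "repeat_index",
    "vt_term",
)

_REQUIRED_COLUMNS = tuple(c for c in CANONICAL_COLUMNS if c not in ("test_id", "vt_term"))

_TRUTHY = {"true", "1", "yes", "t", "y"}
_FALSY = {"false", "0", "no", "f", "n", ""}


@dataclass(frozen=True)
class StrainGroupRecord:
    """Summary of one strain x sex x project x parameter animal group.

    ``n`` is the number of mice in the group, ``mean``/``sd`` the group mean
    and sample standard deviation in parameter units, ``repeat_index`` counts
    repeated measurements of the same group for the same test (0 = first).
    """

    project_id: str
    parameter_id: str
    trait: Trait
    strain: str
    strain_class: StrainClass
    sex: Sex
    n: int
    mean: float
    sd: float
    age_weeks: float
    treated: bool = False
    repeat_index: int = 0
    test_id: str | None = None
    vt_term: str | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"group size n must be >= 1, got {self.n}")
        if self.sd < 0:
            raise ValueError(f"sd must be >= 0, got {self.sd}")
        if self.age_weeks <= 0:
            raise ValueError(f"age_weeks must be > 0, got {self.age_weeks}")

    @property
    def key(self) -> tuple[str, str, str, str, int]:
        """Uniqueness key within a data collection."""
        return (self.project_id, self.parameter_id, self.strain, self.sex.value, self.repeat_index)


@dataclass(frozen=True)
class CVRecord(StrainGroupRecord):
    """A strain-group record with its coefficient of variation attached.

    ``cv_valid`` is False when the mean is non-positive, in which case ``cv``
    is SD/mean taken at face value (negative) or NaN for a zero mean.
    """

    cv: float = float("nan")
    cv_valid: bool = False


def compute_cv(record: StrainGroupRecord) -> CVRecord:
    """Attach CV = SD / mean to a record.

    A non-positive mean yields an invalid-flagged record instead of an error:
    such data sets are excluded later by the selection filters, mirroring how
    negative CVs are treated as excludable results, not as corrupt input.
    """
    if record.mean > 0:
        cv, valid = record.sd / record.mean, True
    elif record.mean < 0:
        cv, valid = record.sd / record.mean, False
    else:
        cv, valid = float("nan"), False
    return CVRecord(**dataclasses.asdict(record), cv=cv, cv_valid=valid)


@dataclass(frozen=True)
class CsvDialect:
    """Column-name mapping absorbing MPD export variants.

    ``column_map`` maps canonical names (see ``CANONICAL_COLUMNS``) to the
    header names used in the file; unmapped canonical names are looked up
    verbatim.
    """

    column_map: dict[str, str] = dataclasses.field(default_factory=dict)

    def source_name(self, canonical: str) -> str:
        return self.column_map.get(canonical, canonical)

    @classmethod
    def from_file(cls, path: str | Path) -> "CsvDialect":
        text = Path(path).read_text()
        data = yaml.safe_load(text) if str(path).endswith((".yaml", ".yml")) else json.loads(text)
        return cls(column_map=dict(data.get("column_map", data)))


class RowError(NamedTuple):
    row: int  # 1-based data row number (header excluded)
    column: str
    message: str


class ReadResult(NamedTuple):
    records: list[StrainGroupRecord]
    errors: list[RowError]


def _parse_bool(value: object) -> bool:
    s = str(value).strip().lower()
    if s in _TRUTHY:
        return True
    if s in _FALSY:
        return False
    raise ValueError(f"cannot interpret {value!r} as boolean")


def _parse_optional(value: object) -> str | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip()
    return s or None


def read_strain_summaries(path: str | Path, dialect: CsvDialect | None = None) -> ReadResult:
    """Read strain-group summaries from a CSV file.

    Every data row yields either a record or a :class:`RowError` carrying the
    1-based row number — rows are never silently dropped.  A missing required
    column raises immediately, naming the column.
    """
    dialect = dialect or CsvDialect()
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for canonical in _REQUIRED_COLUMNS:
        if dialect.source_name(canonical) not in df.columns:
            raise ValueError(f"missing required column: {dialect.source_name(canonical)!r} "
                             f"(canonical {canonical!r})")

    records: list[StrainGroupRecord] = []
    errors: list[RowError] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        # itertuples mangles non-identifier names; index positionally
        raw = {c: (row[df.columns.get_loc(dialect.source_name(c))]
                   if dialect.source_name(c) in df.columns else None)
               for c in CANONICAL_COLUMNS}
        try:
            records.append(
                StrainGroupRecord(
                    project_id=str(raw["project_id"]).strip(),
                    parameter_id=str(raw["parameter_id"]).strip(),
                    trait=Trait(str(raw["trait"]).strip()),
                    test_id=_parse_optional(raw["test_id"]),
                    strain=str(raw["strain"]).strip(),
                    strain_class=StrainClass(str(raw["strain_class"]).strip()),
                    sex=Sex(str(raw["sex"]).strip()),
                    n=int(raw["n"]),
                    mean=float(raw["mean"]),
                    sd=float(raw["sd"]),
                    age_weeks=float(raw["age_weeks"]),
                    treated=_parse_bool(raw["treated"]),
                    repeat_index=int(raw["repeat_index"] or 0),
                    vt_term=_parse_optional(raw["vt_term"]),
                )
            )
        except (ValueError, KeyError) as exc:
            errors.append(RowError(row=i, column=_offending_column(raw), message=str(exc)))
    return ReadResult(records=records, errors=errors)


def _offending_column(raw: dict[str, object]) -> str:
    for col in ("n", "mean", "sd", "age_weeks", "repeat_index"):
        try:
            float(str(raw[col]))
        except (TypeError, ValueError):
            return col
    return "row"


def write_strain_summaries(records: Iterable[StrainGroupRecord], path: str | Path,
                           dialect: CsvDialect | None = None) -> None:
    """Write records as CSV in the canonical (or dialect-mapped) header."""
    dialect = dialect or CsvDialect()
    rows = []
    for r in records:
        d = dataclasses.asdict(r)
        d.pop("cv", None)
        d.pop("cv_valid", None)
        d["trait"] = r.trait.value
        d["strain_class"] = r.strain_class.value
        d["sex"] = r.sex.value
        d["treated"] = "true" if r.treated else "false"
        d["test_id"] = r.test_id or ""
        d["vt_term"] = r.vt_term or ""
        rows.append({dialect.source_name(c): d[c] for c in CANONICAL_COLUMNS})
    header = [dialect.source_name(c) for c in CANONICAL_COLUMNS]
    pd.DataFrame(rows, columns=header).to_csv(path, index=False)


def attach_cv(records: Sequence[StrainGroupRecord]) -> list[CVRecord]:
    """Vector convenience: ``compute_cv`` over a sequence."""
    return [r if isinstance(r, CVRecord) else compute_cv(r) for r in records]
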