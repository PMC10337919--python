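"""Inclusion/exclusion rules for strain-survey data sets, with an audit trail.

The study design admits only untreated inbred strains (including Collaborative
Cross derived ones) and F1 hybrids, aged 7-26 weeks, in groups of at least
5 mice of one sex; data sets with CV >= 3 are treated as technical outliers,
non-positive means invalidate the CV, semi-quantitative behavior scores are
flagged by a configurable predicate, and repeated measurements of the same
behavior group are dropped.  Every excluded record is reported with exactly
one reason — the first failing rule in ``ExclusionReason`` order — so the
bookkeeping percentages are reproducible.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Callable, Sequence

import pandas as pd
import yaml

from .records import CVRecord, StrainClass, Trait

__all__ = [
    "ExclusionReason",
    "FilterConfig",
    "FilterOutcome",
    "apply_selection",
    "drop_repeat_measurements",
    "exclusion_rates",
    "write_exclusion_report",
]


class ExclusionReason(enum.Enum):
    """Why a record was excluded; declaration order fixes reason precedence."""

    TOO_SMALL_GROUP = "too_small_group"
    AGE_OUT_OF_RANGE = "age_out_of_range"
    TREATED = "treated"
    STRAIN_CLASS = "strain_class"
    CV_AT_OR_ABOVE_THRESHOLD = "cv_at_or_above_threshold"
    INVALID_CV = "invalid_cv"
    ZERO_DEGENERATE = "zero_degenerate"
    REPEAT_MEASUREMENT = "repeat_measurement"


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the selection rules.

    Defaults encode the study criteria: group size >= 5, age within
    [7, 26] weeks, untreated, inbred/CC-inbred/F1 strains only, CV < 3
    (the threshold itself excluded), repeats dropped for behavior.
    ``degenerate_parameters`` names behavior parameters whose scores are
    semi-quantitative (mean and/or SD 0 by construction); these are identified
    by inspection of the assay, not derivable by rule, hence configured.
    """

    min_group_size: int = 5
    age_range_weeks: tuple[float, float] = (7.0, 26.0)
    cv_exclusion_threshold: float = 3.0
    allowed_strain_classes: frozenset[StrainClass] = frozenset(
        {StrainClass.INBRED, StrainClass.CC_INBRED, StrainClass.F1_HYBRID}
    )
    exclude_treated: bool = True
    drop_repeats: bool = True
    degenerate_parameters: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.min_group_size < 1:
            raise ValueError("min_group_size must be >= 1")
        lo, hi = self.age_range_weeks
        if lo > hi:
            raise ValueError("age_range_weeks interval is empty")
        if self.cv_exclusion_threshold <= 0:
            raise ValueError("cv_exclusion_threshold must be > 0")

    def is_degenerate(self, parameter_id: str) -> bool:
        return parameter_id in self.degenerate_parameters

    # -- YAML round-trip -------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        data = {
            "min_group_size": self.min_group_size,
            "age_range_weeks": list(self.age_range_weeks),
            "cv_exclusion_threshold": self.cv_exclusion_threshold,
            "allowed_strain_classes": sorted(c.value for c in self.allowed_strain_classes),
            "exclude_treated": self.exclude_treated,
            "drop_repeats": self.drop_repeats,
            "degenerate_parameters": sorted(self.degenerate_parameters),
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FilterConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "age_range_weeks" in data:
            data["age_range_weeks"] = tuple(data["age_range_weeks"])
        if "allowed_strain_classes" in data:
            data["allowed_strain_classes"] = frozenset(
                StrainClass(c) for c in data["allowed_strain_classes"]
            )
        if "degenerate_parameters" in data:
            data["degenerate_parameters"] = frozenset(data["degenerate_parameters"])
        return cls(**data)


@dataclass
class FilterOutcome:
    """Kept records plus the (record, reason) audit trail of the excluded."""

    kept: list[CVRecord] = field(default_factory=list)
    excluded: list[tuple[CVRecord, ExclusionReason]] = field(default_factory=list)

    @property
    def n_input(self) -> int:
        return len(self.kept) + len(self.excluded)


def drop_repeat_measurements(records: Sequence[CVRecord]) -> list[CVRecord]:
    """Keep only the first measurement of each behavior group per test.

    For trait ``behavior``, only ``repeat_index == 0`` is retained within each
    (project, test, strain, sex) group; all other traits pass through.
    """
    out = []
    for r in records:
        if r.trait is Trait.BEHAVIOR and r.repeat_index != 0:
            continue
        out.append(r)
    return out


def _failing_reason(record: CVRecord, config: FilterConfig) -> ExclusionReason | None:
    lo, hi = config.age_range_weeks
    if record.n < config.min_group_size:
        return ExclusionReason.TOO_SMALL_GROUP
    if not (lo <= record.age_weeks <= hi):
        return ExclusionReason.AGE_OUT_OF_RANGE
    if config.exclude_treated and record.treated:
        return ExclusionReason.TREATED
    if record.strain_class not in config.allowed_strain_classes:
        return ExclusionReason.STRAIN_CLASS
    if record.cv_valid and record.cv >= config.cv_exclusion_threshold:
        return ExclusionReason.CV_AT_OR_ABOVE_THRESHOLD
    if not record.cv_valid:
        return ExclusionReason.INVALID_CV
    if config.is_degenerate(record.parameter_id):
        return ExclusionReason.ZERO_DEGENERATE
    if (config.drop_repeats and record.trait is Trait.BEHAVIOR
            and record.repeat_index != 0):
        return ExclusionReason.REPEAT_MEASUREMENT
    return None


def apply_selection(records: Sequence[CVRecord], config: FilterConfig | None = None) -> FilterOutcome:
    """Apply all selection rules; deterministic, single primary reason each.

    A record is kept iff it passes every rule; otherwise it is excluded with
    the first failing rule in ``ExclusionReason`` declaration order.
    """
    config = config or FilterConfig()
    outcome = FilterOutcome()
    for r in records:
        reason = _failing_reason(r, config)
        if reason is None:
            outcome.kept.append(r)
        else:
            outcome.excluded.append((r, reason))
    return outcome


def exclusion_rates(
    outcome: FilterOutcome,
    reason: ExclusionReason | str | Callable[[CVRecord], bool],
    trait: Trait | None = None,
) -> Fraction:
    """Fraction of records matching an exclusion reason or a CV-band predicate.

    The denominator is all records of the (optional) trait that entered the
    selection — kept and excluded alike, matching how outlier percentages are
    quoted against "the selected data sets".  Exact rational arithmetic; the
    caller formats.
    """
    if isinstance(reason, str):
        try:
            reason = ExclusionReason(reason)
        except ValueError as exc:
            raise ValueError(f"unknown exclusion reason: {reason!r}") from exc

    def in_trait(r: CVRecord) -> bool:
        return trait is None or r.trait is trait

    pool_kept = [r for r in outcome.kept if in_trait(r)]
    pool_excl = [(r, why) for r, why in outcome.excluded if in_trait(r)]
    total = len(pool_kept) + len(pool_excl)
    if total == 0:
        return Fraction(0)
    if isinstance(reason, ExclusionReason):
        hits = sum(1 for _, why in pool_excl if why is reason)
    else:
        hits = sum(1 for r in pool_kept if reason(r))
        hits += sum(1 for r, _ in pool_excl if reason(r))
    return Fraction(hits, total)


def write_exclusion_report(outcome: FilterOutcome, path: str | Path) -> None:
    """CSV audit trail: one row per excluded record with its reason."""
    rows = [
        {
            "project_id": r.project_id,
            "parameter_id": r.parameter_id,
            "strain": r.strain,
            "sex": r.sex.value,
            "repeat_index": r.repeat_index,
            "cv": r.cv,
            "reason": why.value,
        }
        for r, why in outcome.excluded
    ]
    cols = ["project_id", "parameter_id", "strain", "sex", "repeat_index", "cv", "reason"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
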