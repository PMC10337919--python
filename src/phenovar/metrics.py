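"""The three CV-aggregation analyses, trimmed ranges, and sex statistics.

A phenotypic parameter's variability is summarized three ways:

1. *dataset level* — the unweighted mean +/- SD of the CVs of all selected
   data sets (one data set = one strain x sex group);
2. *project level* — first a mean CV per project (for behavior: first a mean
   per parameter within the project, then the mean over parameters), then the
   unweighted mean +/- SD over project CVs;
3. *behavior parameter level* — per-parameter mean CV pooling all projects,
   then the unweighted mean over parameters (behavior tests only).

Robustness checks trim the extreme 2.5% / 5% of CVs from each tail within
each sex separately (95% / 90% ranges) or restrict to larger group sizes
(n >= 10, n >= 15).  Sex-specific variability is assessed by the CV ratio
CVf / (CVf + CVm) and a chi-squared goodness-of-fit of the higher-female vs
higher-male direction counts against 50:50.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .records import CVRecord, Sex, Trait

__all__ = [
    "Analysis",
    "CVSummary",
    "TrimmedRange",
    "SexComparison",
    "dataset_level_mean_cv",
    "project_level_mean_cv",
    "behavior_parameter_level_mean_cv",
    "trimmed_range",
    "subset_by_group_size",
    "sex_cv_ratio",
    "sex_direction_test",
]


class Analysis(str, enum.Enum):
    DATASET_LEVEL = "dataset_level"
    PROJECT_LEVEL = "project_level"
    BEHAVIOR_PARAMETER_LEVEL = "behavior_parameter_level"


@dataclass(frozen=True)
class CVSummary:
    """Mean +/- SD of CVs for one parameter/test under one aggregation."""

    parameter_or_test: str
    analysis: Analysis
    mean_cv: float
    sd_cv: float
    n_projects: int
    n_datasets: int
    n_mice: int
    mean_group_size: float
    sd_degenerate: bool = False  # single element: SD reported as 0, flagged


@dataclass(frozen=True)
class TrimmedRange:
    coverage: float
    min_cv: float
    max_cv: float
    mean_cv: float
    n_remaining: int


@dataclass(frozen=True)
class SexComparison:
    n_female_higher: int
    n_male_higher: int
    n_tied: int
    chi_squared_stat: float
    p_value: float


def _mean_sd(values: Sequence[float]) -> tuple[float, float, bool]:
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("no CV values to aggregate")
    if arr.size == 1:
        return float(arr[0]), 0.0, True
    return float(arr.mean()), float(arr.std(ddof=1)), False


def _select(records: Iterable[CVRecord], parameter_or_test: str) -> list[CVRecord]:
    """Records of one parameter, or of one behavior test (by test_id)."""
    recs = [r for r in records
            if r.parameter_id == parameter_or_test
            or (r.trait is Trait.BEHAVIOR and r.test_id == parameter_or_test)]
    return recs


def _summary(recs: Sequence[CVRecord], label: str, analysis: Analysis,
             mean_cv: float, sd_cv: float, degenerate: bool) -> CVSummary:
    n_mice = int(sum(r.n for r in recs))
    return CVSummary(
        parameter_or_test=label,
        analysis=analysis,
        mean_cv=mean_cv,
        sd_cv=sd_cv,
        n_projects=len({r.project_id for r in recs}),
        n_datasets=len(recs),
        n_mice=n_mice,
        mean_group_size=n_mice / len(recs),
        sd_degenerate=degenerate,
    )


def dataset_level_mean_cv(records: Iterable[CVRecord], parameter_or_test: str) -> CVSummary:
    """First analysis: every selected data set enters independently."""
    recs = _select(records, parameter_or_test)
    if not recs:
        raise ValueError(f"no records for {parameter_or_test!r}")
    mean, sd, degen = _mean_sd([r.cv for r in recs])
    return _summary(recs, parameter_or_test, Analysis.DATASET_LEVEL, mean, sd, degen)


def project_level_mean_cv(records: Iterable[CVRecord], parameter_or_test: str) -> CVSummary:
    """Second analysis: two-step mean, projects weighted equally.

    Per project a mean CV is formed from all its data sets; for behavior tests
    the project mean is itself the mean over that project's per-parameter mean
    CVs.  The headline value is the unweighted mean +/- sample SD across
    project CVs.
    """
    recs = _select(records, parameter_or_test)
    if not recs:
        raise ValueError(f"no records for {parameter_or_test!r}")
    behavior = all(r.trait is Trait.BEHAVIOR for r in recs)
    project_cvs = []
    for project in sorted({r.project_id for r in recs}):
        in_proj = [r for r in recs if r.project_id == project]
        if behavior:
            per_param = [
                float(np.mean([r.cv for r in in_proj if r.parameter_id == p]))
                for p in sorted({r.parameter_id for r in in_proj})
            ]
            project_cvs.append(float(np.mean(per_param)))
        else:
            project_cvs.append(float(np.mean([r.cv for r in in_proj])))
    mean, sd, degen = _mean_sd(project_cvs)
    return _summary(recs, parameter_or_test, Analysis.PROJECT_LEVEL, mean, sd, degen)


def behavior_parameter_level_mean_cv(records: Iterable[CVRecord], test: str) -> CVSummary:
    """Third analysis (behavior): per-parameter means pooling projects, then mean."""
    recs = [r for r in _select(records, test) if r.trait is Trait.BEHAVIOR]
    if not recs:
        raise ValueError(f"no behavior records for test {test!r}")
    per_param = [
        float(np.mean([r.cv for r in recs if r.parameter_id == p]))
        for p in sorted({r.parameter_id for r in recs})
    ]
    mean, sd, degen = _mean_sd(per_param)
    return _summary(recs, test, Analysis.BEHAVIOR_PARAMETER_LEVEL, mean, sd, degen)


def trimmed_range(records: Iterable[CVRecord], parameter_or_test: str | None = None,
                  coverage: float = 0.95) -> TrimmedRange:
    """Range and mean of CVs after symmetric tail deletion within each sex.

    Within each sex group separately, the ``floor(((1 - coverage)/2) * m)``
    data sets with the lowest and with the highest CVs are deleted (m = that
    sex's data-set count; stable sort by (cv, record key) so ties are
    deterministic), the survivors of both sexes are pooled, and min/max/mean
    of the remaining CVs are reported.
    """
    if not (0 < coverage <= 1):
        raise ValueError("coverage must be in (0, 1]")
    recs = list(records) if parameter_or_test is None else _select(records, parameter_or_test)
    tail = (1.0 - coverage) / 2.0
    remaining: list[CVRecord] = []
    for sex in Sex:
        group = sorted((r for r in recs if r.sex is sex), key=lambda r: (r.cv, r.key))
        m = len(group)
        k = math.floor(tail * m)
        remaining.extend(group[k: m - k] if k else group)
    if not remaining:
        raise ValueError("all records trimmed away")
    cvs = np.array([r.cv for r in remaining])
    return TrimmedRange(coverage=coverage, min_cv=float(cvs.min()),
                        max_cv=float(cvs.max()), mean_cv=float(cvs.mean()),
                        n_remaining=len(remaining))


def subset_by_group_size(records: Iterable[CVRecord], min_n: int) -> list[CVRecord]:
    """Data sets with at least ``min_n`` animals."""
    return [r for r in records if r.n >= min_n]


def sex_cv_ratio(female_mean_cv: float, male_mean_cv: float) -> float:
    """CV ratio = CVf / (CVf + CVm); 0.5 means no sex difference."""
    if female_mean_cv < 0 or male_mean_cv < 0:
        raise ValueError("mean CVs must be >= 0")
    total = female_mean_cv + male_mean_cv
    if total == 0:
        raise ValueError("both mean CVs are zero; ratio undefined")
    return female_mean_cv / total


def sex_direction_test(per_parameter_pairs: Sequence[tuple[float, float]]) -> SexComparison:
    """Chi-squared test of higher-female vs higher-male CV direction counts.

    Each pair (female mean CV, male mean CV) should be computed from projects
    that examined both sexes for that parameter.  Ties are counted but left
    out of the goodness-of-fit against 50:50 (df = 1, no continuity
    correction).
    """
    nf = sum(1 for f, m in per_parameter_pairs if f > m)
    nm = sum(1 for f, m in per_parameter_pairs if m > f)
    nt = len(per_parameter_pairs) - nf - nm
    if nf + nm < 1:
        raise ValueError("need at least one non-tied pair")
    stat, p = stats.chisquare([nf, nm])
    return SexComparison(n_female_higher=nf, n_male_higher=nm, n_tied=nt,
                         chi_squared_stat=float(stat), p_value=float(p))
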