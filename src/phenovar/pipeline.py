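"""End-to-end report assembly: filter, aggregate, trim, compare sexes, write.

Ties the stages together into the two headline outputs: a per-parameter
variability summary table (dataset-level and project-level mean CV, counts,
trimmed 95%/90% ranges, large-group subsets, sex comparison) and the k x CV
sample-size planning table.  Every number written is recomputable from the
input CSV and the configs alone; a manifest records stage counts and a
config hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from . import metrics
from .filters import FilterConfig, FilterOutcome, apply_selection, write_exclusion_report
from .metrics import Analysis, CVSummary
from .power import generate_sample_size_table
from .records import CVRecord, Sex, Trait, attach_cv, read_strain_summaries

__all__ = ["run_variability_pipeline", "run_table2", "summaries_to_frame"]


def _labels(records: Iterable[CVRecord]) -> list[str]:
    """Analysis units: parameter ids, except behavior which aggregates by test."""
    labels: set[str] = set()
    for r in records:
        if r.trait is Trait.BEHAVIOR and r.test_id:
            labels.add(r.test_id)
        else:
            labels.add(r.parameter_id)
    return sorted(labels)


def summaries_to_frame(summaries: Sequence[CVSummary]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(s) for s in summaries])


def _sex_comparison_frame(records: list[CVRecord]) -> pd.DataFrame:
    """Per-parameter female/male mean CVs and CV ratio, using only projects
    that examined both sexes for the parameter/test."""
    rows = []
    for label in _labels(records):
        recs = [r for r in records
                if (r.test_id == label if (r.trait is Trait.BEHAVIOR and r.test_id)
                    else r.parameter_id == label)]
        both_sex_projects = {
            p for p in {r.project_id for r in recs}
            if {r.sex for r in recs if r.project_id == p} == {Sex.FEMALE, Sex.MALE}
        }
        sub = [r for r in recs if r.project_id in both_sex_projects]
        if not sub:
            continue
        f = [r.cv for r in sub if r.sex is Sex.FEMALE]
        m = [r.cv for r in sub if r.sex is Sex.MALE]
        fmean, mmean = sum(f) / len(f), sum(m) / len(m)
        rows.append({
            "parameter_or_test": label,
            "female_mean_cv": fmean,
            "male_mean_cv": mmean,
            "cv_ratio": metrics.sex_cv_ratio(fmean, mmean),
        })
    return pd.DataFrame(rows, columns=["parameter_or_test", "female_mean_cv",
                                       "male_mean_cv", "cv_ratio"])


def run_variability_pipeline(
    input_csv: str | Path,
    filter_config: FilterConfig | None = None,
    analyses: set[Analysis] | None = None,
    out_dir: str | Path = "report",
    trim_coverages: Sequence[float] = (0.95, 0.90),
    group_size_subsets: Sequence[int] = (10, 15),
) -> dict[str, Path]:
    """Run the full variability analysis over an MPD-like CSV.

    Writes one summary CSV per requested analysis, trimmed-range and
    group-size-subset tables, the sex comparison, the exclusion audit, and a
    manifest of stage counts.  Returns the mapping of output names to paths.
    """
    filter_config = filter_config or FilterConfig()
    analyses = analyses or {Analysis.DATASET_LEVEL, Analysis.PROJECT_LEVEL}
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    result = read_strain_summaries(input_csv)
    cv_records = attach_cv(result.records)
    outcome: FilterOutcome = apply_selection(cv_records, filter_config)
    kept = outcome.kept
    if not kept:
        counts = {why.value: sum(1 for _, w in outcome.excluded if w is why)
                  for why in {w for _, w in outcome.excluded}}
        raise ValueError(f"no records survive filtering; exclusions: {counts}")

    labels = _labels(kept)

    for analysis in sorted(analyses, key=lambda a: a.value):
        summaries = []
        for label in labels:
            try:
                if analysis is Analysis.DATASET_LEVEL:
                    summaries.append(metrics.dataset_level_mean_cv(kept, label))
                elif analysis is Analysis.PROJECT_LEVEL:
                    summaries.append(metrics.project_level_mean_cv(kept, label))
                else:
                    summaries.append(metrics.behavior_parameter_level_mean_cv(kept, label))
            except ValueError:
                continue  # label not applicable to this analysis (non-behavior)
        path = out_dir / f"summary_{analysis.value}.csv"
        summaries_to_frame(summaries).to_csv(path, index=False)
        outputs[f"summary_{analysis.value}"] = path

    trim_rows = []
    for label in labels:
        for cov in trim_coverages:
            tr = metrics.trimmed_range(kept, label, cov)
            trim_rows.append({"parameter_or_test": label, **dataclasses.asdict(tr)})
        full = metrics.trimmed_range(kept, label, 1.0)
        trim_rows.append({"parameter_or_test": label, **dataclasses.asdict(full)})
    path = out_dir / "trimmed_ranges.csv"
    pd.DataFrame(trim_rows).to_csv(path, index=False)
    outputs["trimmed_ranges"] = path

    subset_rows = []
    for min_n in group_size_subsets:
        sub = metrics.subset_by_group_size(kept, min_n)
        for label in labels:
            try:
                s = metrics.dataset_level_mean_cv(sub, label)
            except ValueError:
                continue
            subset_rows.append({"min_group_size": min_n, **dataclasses.asdict(s)})
    path = out_dir / "group_size_subsets.csv"
    pd.DataFrame(subset_rows).to_csv(path, index=False)
    outputs["group_size_subsets"] = path

    sex_df = _sex_comparison_frame(kept)
    path = out_dir / "sex_comparison.csv"
    sex_df.to_csv(path, index=False)
    outputs["sex_comparison"] = path

    path = out_dir / "exclusions.csv"
    write_exclusion_report(outcome, path)
    outputs["exclusions"] = path

    cfg_text = json.dumps(dataclasses.asdict(filter_config), default=sorted, sort_keys=True)
    manifest = {
        "input": str(input_csv),
        "filter_config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "counts": {
            "rows_read": len(result.records) + len(result.errors),
            "rows_valid": len(result.records),
            "row_errors": len(result.errors),
            "kept": len(kept),
            "excluded": len(outcome.excluded),
            "excluded_by_reason": {
                why.value: sum(1 for _, w in outcome.excluded if w is why)
                for why in {w for _, w in outcome.excluded}
            },
        },
        "analyses": sorted(a.value for a in analyses),
        "parameters_or_tests": labels,
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    outputs["manifest"] = path
    return outputs


def run_table2(
    out_path: str | Path,
    k_grid: Sequence[float] | None = None,
    cv_grid: Sequence[float] | None = None,
    alpha: float = 0.05,
    beta: float = 0.2,
) -> Path:
    """Write the sample-size planning table as CSV (first column CV, header k).

    Byte-stable across invocations; the default grids give the full
    16-row x 19-column table.
    """
    table = generate_sample_size_table(k_grid, cv_grid, alpha=alpha, beta=beta)
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    lines = ["CV," + ",".join(f"{k:.2f}" for k in table.k_grid)]
    for i, cv in enumerate(table.cv_grid):
        lines.append(f"{cv:.2f}," + ",".join(str(int(v)) for v in table.n[i]))
    out_path.write_text("\n".join(lines) + "\n")
    return out_path
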