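"""Hierarchical generator of MPD-like strain-survey summaries with ground truth.

Emulates the structure of Mouse Phenome Database strain surveys: several
projects measure a phenotypic parameter, each project contributes many strain
x sex animal groups of 5-20 mice aged 7-26 weeks, and each group is reported
only as (n, mean, sample SD).  Individual animal values are drawn from a
positive-truncated normal (optionally lognormal, exact for high CVs) with a
strain-specific mean and a relative spread set by the parameter's true CV,
optionally inflated per project — the mechanism behind the occasional
projects with conspicuously high CVs that widen a parameter's full CV range.

Reproducibility: one global seed; each (parameter, project) pair gets its own
RNG substream via ``numpy.random.SeedSequence`` spawn keys, so adding a
project leaves every other project's records bit-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .records import Sex, StrainClass, StrainGroupRecord, Trait

__all__ = ["ParameterSpec", "SyntheticConfig", "generate_records",
           "generate_contaminated", "write_ground_truth"]


@dataclass(frozen=True)
class ParameterSpec:
    """Ground truth for one synthetic phenotypic parameter."""

    parameter_id: str
    trait: Trait
    true_cv: float
    base_mean: float
    test_id: str | None = None
    distribution: str = "normal"  # "normal" (positive-truncated) or "lognormal"

    def __post_init__(self) -> None:
        if self.true_cv <= 0:
            raise ValueError("true_cv must be > 0")
        if self.base_mean <= 0:
            raise ValueError("base_mean must be > 0")
        if self.distribution not in ("normal", "lognormal"):
            raise ValueError("distribution must be 'normal' or 'lognormal'")


def _default_parameters() -> tuple[ParameterSpec, ...]:
    # Archetypes spanning the realistic CV spectrum: tightly regulated
    # electrolytes (~0.03), ordinary clinical chemistry (~0.15), immunology
    # (~0.3), behavior (~0.5, lognormal to keep the target CV exact).
    return (
        ParameterSpec("electrolyte_like", Trait.CLINICAL_CHEMISTRY, 0.03, 145.0),
        ParameterSpec("clinchem_like", Trait.CLINICAL_CHEMISTRY, 0.15, 100.0),
        ParameterSpec("immunology_like", Trait.IMMUNOLOGY, 0.30, 25.0),
        ParameterSpec("behavior_like", Trait.BEHAVIOR, 0.50, 60.0,
                      test_id="open_field_like", distribution="lognormal"),
    )


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative settings mirroring the strain-survey cohort structure."""

    seed: int = 0
    parameters: tuple[ParameterSpec, ...] = field(default_factory=_default_parameters)
    n_projects_per_parameter: int | tuple[int, int] = (2, 8)
    strains_per_project: tuple[int, int] = (1, 72)
    group_size_range: tuple[int, int] = (5, 20)
    age_weeks_range: tuple[float, float] = (7.0, 26.0)
    between_strain_cv: float = 0.10  # spread of strain means around base_mean
    project_cv_inflation: tuple[float, ...] = (1.0,)  # factors sampled per project
    outlier_project_fraction: float = 0.0
    outlier_inflation: float = 3.0
    sex_cv_shift: float = 0.0  # female CV multiplied by (1 + shift)

    def __post_init__(self) -> None:
        if not self.parameters:
            raise ValueError("at least one parameter required")
        for lo, hi in (self.strains_per_project, self.group_size_range):
            if lo < 1 or hi < lo:
                raise ValueError("ranges must be non-empty with lo >= 1")
        if not (0 <= self.outlier_project_fraction <= 1):
            raise ValueError("outlier_project_fraction must be in [0, 1]")
        if self.outlier_inflation <= 1 and self.outlier_project_fraction > 0:
            raise ValueError("outlier_inflation must be > 1")

    def n_projects(self, rng: np.random.Generator) -> int:
        if isinstance(self.n_projects_per_parameter, int):
            return self.n_projects_per_parameter
        lo, hi = self.n_projects_per_parameter
        return int(rng.integers(lo, hi + 1))


def _draw_group_values(rng: np.random.Generator, m: int, mu: float, cv: float,
                       distribution: str) -> np.ndarray:
    """m animal values with mean mu and relative spread cv, strictly positive."""
    if distribution == "lognormal":
        sigma2 = np.log1p(cv * cv)
        mu_log = np.log(mu) - sigma2 / 2.0  # E = mu, CV = cv exactly
        return rng.lognormal(mu_log, np.sqrt(sigma2), size=m)
    a = (0.0 - mu) / (mu * cv)  # truncate at zero, in standard units
    u = rng.random(m)
    lo = stats.norm.cdf(a)
    return mu + mu * cv * stats.norm.ppf(lo + u * (1.0 - lo))


def generate_records(config: SyntheticConfig) -> list[StrainGroupRecord]:
    """Generate summaries for every parameter x project x strain x sex group."""
    records, _ = generate_contaminated(config)
    return records


def generate_contaminated(config: SyntheticConfig) -> tuple[list[StrainGroupRecord], set[str]]:
    """As :func:`generate_records`, returning the outlier-project labels too.

    With ``outlier_project_fraction`` f over P projects, exactly
    ``round(f * P)`` projects (chosen reproducibly per parameter) have their
    CV multiplied by ``outlier_inflation`` — the high-CV-project contamination
    pattern.  With f = 0 the output is plain clean data and the label set is
    empty.
    """
    records: list[StrainGroupRecord] = []
    outliers: set[str] = set()
    strain_classes = (StrainClass.INBRED, StrainClass.INBRED, StrainClass.INBRED,
                      StrainClass.CC_INBRED, StrainClass.F1_HYBRID)
    for p_idx, param in enumerate(config.parameters):
        meta_rng = np.random.default_rng(
            np.random.SeedSequence(config.seed, spawn_key=(p_idx, 0xFFFF)))
        n_proj = config.n_projects(meta_rng)
        n_out = round(config.outlier_project_fraction * n_proj)
        out_idx = set(meta_rng.permutation(n_proj)[:n_out].tolist())
        for j in range(n_proj):
            rng = np.random.default_rng(
                np.random.SeedSequence(config.seed, spawn_key=(p_idx, j)))
            project_id = f"project_{j:02d}"
            inflation = float(rng.choice(config.project_cv_inflation))
            if j in out_idx:
                inflation *= config.outlier_inflation
                outliers.add(project_id)
            age = float(rng.uniform(*config.age_weeks_range))
            n_strains = int(rng.integers(config.strains_per_project[0],
                                         config.strains_per_project[1] + 1))
            for s in range(n_strains):
                strain = f"STRAIN_{s:03d}"
                strain_class = strain_classes[int(rng.integers(len(strain_classes)))]
                mu = float(param.base_mean *
                           np.exp(rng.normal(0.0, config.between_strain_cv)))
                for sex in (Sex.FEMALE, Sex.MALE):
                    cv = param.true_cv * inflation
                    if sex is Sex.FEMALE:
                        cv *= 1.0 + config.sex_cv_shift
                    m = int(rng.integers(config.group_size_range[0],
                                         config.group_size_range[1] + 1))
                    values = _draw_group_values(rng, m, mu, cv, param.distribution)
                    records.append(StrainGroupRecord(
                        project_id=project_id,
                        parameter_id=param.parameter_id,
                        trait=param.trait,
                        test_id=param.test_id,
                        strain=strain,
                        strain_class=strain_class,
                        sex=sex,
                        n=m,
                        mean=float(values.mean()),
                        sd=float(values.std(ddof=1)) if m > 1 else 0.0,
                        age_weeks=age,
                    ))
    return records, outliers


def write_ground_truth(config: SyntheticConfig, outliers: set[str],
                       path: str | Path) -> None:
    """Sidecar JSON with the generating truth (per-parameter CV, outliers)."""
    data = {
        "seed": config.seed,
        "parameters": [
            {"parameter_id": p.parameter_id, "trait": p.trait.value,
             "true_cv": p.true_cv, "base_mean": p.base_mean,
             "distribution": p.distribution}
            for p in config.parameters
        ],
        "outlier_projects": sorted(outliers),
        "outlier_inflation": config.outlier_inflation if outliers else None,
    }
    Path(path).write_text(json.dumps(data, indent=2))
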