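# Methods

## Scope and model

`phenovar` analyzes the *relative* variability of phenotypic parameters in
laboratory-mouse strain surveys, as archived in resources like the Mouse
Phenome Database (MPD).  The atom of the analysis is a **data set**: the
summary (group size n, mean, sample SD) of one animal group — one strain, one
sex, one project, one parameter, n ≥ 5 mice.  Relative variability is the
coefficient of variation, CV = SD / mean, a dimensionless quantity comparable
across assays and units.  Raw animal values are never needed; everything is
computed from per-group summaries.

## Selection filters

A data set enters the analysis when all rules pass, checked in a fixed order
so each exclusion has exactly one primary reason:

1. group size n ≥ 5 (`min_group_size`),
2. age within the closed interval [7, 26] weeks (`age_range_weeks`),
3. untreated animals (`exclude_treated`),
4. strain class in {inbred, CC-derived inbred, F1 hybrid},
5. CV < 3 (`cv_exclusion_threshold`; the boundary CV = 3.0 is excluded as a
   technical outlier, 2.999 is kept),
6. CV computable (mean > 0; negative or zero means invalidate the CV),
7. not a configured semi-quantitative ("zero-degenerate") behavior parameter —
   these are recognized by inspection of the assay, not derivable by rule, so
   they are named in the config (`degenerate_parameters`),
8. first measurement of a behavior group for its test (`repeat_index == 0`).

The rule *order* is a package choice: the source criteria name the categories
but not a precedence, and deterministic single-reason bookkeeping requires
one.  `exclusion_rates` uses exact rational arithmetic (`fractions.Fraction`)
with the full selected pool (kept + excluded) as denominator.

## The three aggregation analyses

For each parameter (behavior: each test, which pools 1–27 related
parameters measured on the same mice):

- **dataset level** — unweighted mean ± sample SD (n−1) over the CVs of all
  selected data sets.  Weighted toward projects contributing many strains.
- **project level** — two-step: a mean CV per project first (behavior: a mean
  per parameter within the project, then the mean of those), then the
  unweighted mean ± SD across project CVs.  Weighted toward projects equally;
  divergence between the two levels signals between-project heterogeneity.
- **behavior parameter level** — per-parameter mean CV pooling all projects,
  then the unweighted mean over parameters (behavior only).

Single-element aggregates report SD = 0 with a `sd_degenerate` flag rather
than NaN.

## Trimmed ranges and subsets

The 95% / 90% ranges delete `floor(tail_fraction × m)` data sets from each
end of the CV-sorted list *within each sex separately* (m = that sex's count,
tail fraction 2.5% / 5%), then pool survivors and report min / max / mean CV.
Floor rounding means small groups lose nothing spuriously; ties break by a
stable sort on (cv, record key) so trimming is deterministic.  Group-size
subsets simply restrict to data sets with n ≥ 10 or n ≥ 15.

## Sex-specific variability

Per parameter, female and male mean CVs are computed from projects that
examined both sexes, summarized as the CV ratio CVf / (CVf + CVm) (0.5 = no
sex difference).  Across parameters, the counts with higher female vs higher
male CV are tested against 50:50 by a chi-squared goodness-of-fit (df = 1, no
continuity correction — the plain test, since no correction was specified
for it); ties are tallied but excluded from the statistic.

## Sample-size solver

For a two-sided two-sample t-test with equal group sizes and equal variances,
writing the test-group mean as μ₁ = k·μ₀ gives the standardized effect size

    Δ = (μ₁ − μ₀)/σ = (k − 1)/CV,   CV = σ/μ₀ (control group),

so planning needs only k and CV.  Power at n per group uses the noncentral t
distribution with df = 2n − 2 and noncentrality δ = Δ·√(n/2):
power = P(|T′| > t₁₋α/₂,df), evaluated with `scipy.stats.nct` (accurate far
below the 1e−8 level at which integer decisions could flip).  The minimum
sample size is the **smallest integer n ≥ 2 with power ≥ 1 − β**, found by
starting from the closed-form normal approximation and walking the integer
lattice with exact power in both directions — never by rounding a continuous
root.  n = 2 (df = 2) is the statistical floor; the package flags results
below 3 as inadvisable in practice given within-strain variability, without
baking that into the solver.  Because |Δ| is equal for k and 2 − k, sample
sizes are symmetric around k = 1.  The default grid (k = 1.10…2.00 step
0.05; CV = 0.03, 0.05, 0.10…0.60 step 0.05, 0.70, 0.80, 0.90) is a 16 × 19
table; a Monte-Carlo t-test simulator (`mc_power_oracle`) provides an
independent check of the analytic power in the tests.

Unequal group sizes, unequal variances (the test group's implied CV is
CV/k), nonparametric power, and multiplicity adjustment are out of scope.

## Synthetic strain surveys

The generator emulates the survey structure so the pipeline is testable
without any download: parameters (archetypes for electrolytes ~CV 0.03,
clinical chemistry ~0.15, immunology ~0.30, behavior ~0.50) × projects (2–8
by default, drawable up to 32) × strains (1–72) × both sexes; one age per
project in [7, 26] weeks; group sizes uniform on 5–20.  Animal values are
drawn from a normal distribution truncated to the positive half-line with a
strain-specific mean (lognormal spread of 0.10 across strains) and SD =
mean × true CV; for high-CV parameters (≳0.5) a lognormal option keeps the
target CV exact where truncation would distort it.  Only (n, sample mean,
sample SD with n−1) are emitted.  Ground truth is the generating CV of the
untruncated distribution; tests compare recovered means against a
Monte-Carlo oracle of the expected *sample* CV at the drawn group sizes, so
small-sample bias is handled by simulation, not by a hand-waved constant.

Contamination mimics the observation that wide CV ranges are often driven by
one or a few projects: a chosen fraction of projects (exactly
`round(fraction × P)`, labels returned) has its CV multiplied by an
inflation factor (> 1, default 3).

Reproducibility: one global seed; every (parameter, project) pair derives
its own `numpy.random.SeedSequence` substream via spawn keys, so adding a
project leaves all other projects' records bit-identical.

What the simulator does *not* emulate: real per-assay distributions,
measurement error structure, litter/cage effects, strain-by-sex interactions
beyond an optional multiplicative female CV shift, or missingness patterns.
Passing recovery tests therefore demonstrates the correctness of the
pipeline's arithmetic and bookkeeping on MPD-shaped data, not fidelity to
any particular real assay.

## Problem sizes in the test suite

The suite favors configurations that exercise every code path at modest
scale: recovery runs use 240–500 data sets, contamination checks 200
replicates of ~400-record surveys, and the Monte-Carlo power comparisons
100 000 simulated t-tests per point at 21 (n, Δ) points.  These sizes put
Monte-Carlo standard errors well below the effect sizes being verified while
keeping the default `pytest` run in the tens of seconds.

## Numerical conventions

- Sample SD (n−1) throughout, both over animals (simulator) and over CVs
  (aggregation); the `sd` column of an input CSV is taken at face value.
- CV of a record with mean ≤ 0 is flagged invalid rather than erroring;
  exclusion is a filtering decision.
- Human-readable report tables round CVs to 2 decimals; machine CSVs keep
  full precision.  The sample-size table CSV is byte-stable across runs.
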