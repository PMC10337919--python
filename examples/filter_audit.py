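"""Selection filtering with a per-record exclusion audit trail.

Records must come from untreated inbred/CC-inbred/F1 groups of >= 5 mice
aged 7-26 weeks; CVs at or above 3 are technical outliers; non-positive
means invalidate the CV.  Each excluded record gets exactly one reason (the
first failing rule), so exclusion percentages are exactly reproducible.
"""

from fractions import Fraction

from phenovar import (
    ExclusionReason, Sex, StrainClass, StrainGroupRecord, Trait,
    apply_selection, compute_cv, exclusion_rates,
)


def group(strain, n=10, mean=100.0, sd=15.0, age=12.0, treated=False):
    return compute_cv(StrainGroupRecord(
        project_id="proj_A", parameter_id="glucose", trait=Trait.CLINICAL_CHEMISTRY,
        strain=strain, strain_class=StrainClass.INBRED, sex=Sex.FEMALE,
        n=n, mean=mean, sd=sd, age_weeks=age, treated=treated))


records = [
    group("C57BL/6J"),                      # kept
    group("DBA/2J", n=4),                   # too few animals
    group("A/J", age=30.0),                 # aged out of the 7-26 wk window
    group("BALB/cJ", treated=True),         # treatment study
    group("CAST/EiJ", mean=10.0, sd=31.0),  # CV = 3.1 >= 3: technical outlier
    group("PWK/PhJ", mean=-2.0, sd=1.0),    # negative mean: CV invalid
    group("NOD/ShiLtJ"),                    # kept
]

outcome = apply_selection(records)
print(f"kept {len(outcome.kept)} of {outcome.n_input} data sets")
for record, reason in outcome.excluded:
    print(f"  excluded {record.strain:<10} -> {reason.value}")

rate = exclusion_rates(outcome, ExclusionReason.CV_AT_OR_ABOVE_THRESHOLD)
print(f"CV-outlier rate: {rate} = {float(rate):.1%} of the selected data sets")
assert rate == Fraction(1, 7)
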