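import pytest
from hypothesis import settings

from phenovar import Sex, StrainClass, StrainGroupRecord, Trait, compute_cv

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def make_record():
    """Factory for strain-group records with sensible defaults."""

    def _make(**kwargs):
        base = dict(
            project_id="project_00",
            parameter_id="glucose",
            trait=Trait.CLINICAL_CHEMISTRY,
            strain="C57BL/6J",
            strain_class=StrainClass.INBRED,
            sex=Sex.FEMALE,
            n=10,
            mean=100.0,
            sd=15.0,
            age_weeks=12.0,
        )
        base.update(kwargs)
        return StrainGroupRecord(**base)

    return _make


@pytest.fixture
def make_cv_record(make_record):
    """Factory for CV-attached records; pass cv= to set sd = cv * mean."""

    def _make(cv=None, **kwargs):
        if cv is not None:
            kwargs.setdefault("mean", 100.0)
            kwargs["sd"] = cv * kwargs["mean"]
        return compute_cv(make_record(**kwargs))

    return _make
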