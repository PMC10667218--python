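import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from hydrometal.datagen import GeneratorConfig, reference_survey
from hydrometal.records import SampleRecord
from hydrometal.risk import ExposureProfile
from hydrometal.standards import StandardsTable


@pytest.fixture
def standards() -> StandardsTable:
    return StandardsTable.default()


@pytest.fixture
def standards_csf() -> StandardsTable:
    return StandardsTable.default(with_example_csf=True)


@pytest.fixture
def profile() -> ExposureProfile:
    return ExposureProfile()


@pytest.fixture
def survey() -> list[SampleRecord]:
    return reference_survey()


@pytest.fixture
def spring_vector(survey) -> SampleRecord:
    """The Hassar spring sample with all five metals at 0.009 mg/L."""
    return next(
        r for r in survey
        if r.river == "hassar" and r.season == "spring" and r.sample_id == "S4"
    )


@pytest.fixture
def small_config() -> GeneratorConfig:
    return GeneratorConfig(seed=42)


def make_record(conc: dict[str, float], **kw) -> SampleRecord:
    base = dict(sample_id="X", river="r", season="s", lon=0.0, lat=0.0,
                replicate=1)
    base.update(kw)
    return SampleRecord(conc=conc, **base)
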