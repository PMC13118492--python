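import pytest

from residuerisk import (
    CooccurrenceModel,
    MonitoringDataset,
    PesticideRef,
    ReferenceTable,
    SampleRecord,
    generate_dataset,
)
from residuerisk.synthetic import PROVINCE_SIZES, default_survey_specs, synthetic_reference_table


@pytest.fixture
def refs_small() -> ReferenceTable:
    return ReferenceTable(
        [
            PesticideRef("metalaxyl", "fungicide", True, mrl=0.01, adi=0.08,
                         arfd=0.5, loq=0.01),
            PesticideRef("flonicamid", "insecticide", True, mrl=0.5, adi=0.025,
                         arfd=0.025, loq=0.01),
            PesticideRef("acetamiprid", "insecticide", True, mrl=0.3, adi=0.025,
                         arfd=0.025, loq=0.01),
            PesticideRef("chlorpyrifos", "insecticide", False, mrl=0.01,
                         adi=None, arfd=None, loq=0.01),
        ]
    )


@pytest.fixture
def dataset_small(refs_small) -> MonitoringDataset:
    samples = [
        SampleRecord("S1", "Manisa", {"metalaxyl": 0.343, "flonicamid": 0.02}),
        SampleRecord("S2", "Manisa", {}),
        SampleRecord("S3", "Izmir", {"flonicamid": 0.048}),
    ]
    return MonitoringDataset(samples=samples, panel=refs_small.analytes)


@pytest.fixture(scope="session")
def survey_dataset() -> MonitoringDataset:
    """A full synthetic survey with the emulated roster and co-occurrence."""
    return generate_dataset(
        default_survey_specs(), PROVINCE_SIZES, CooccurrenceModel(1.0), seed=42
    )


@pytest.fixture(scope="session")
def survey_refs() -> ReferenceTable:
    return synthetic_reference_table()
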