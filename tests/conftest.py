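import pytest

from ctdna_monitor.io import build_timelines
from ctdna_monitor.reference import SURGERY_PATIENTS, reference_cohort
from ctdna_monitor.validation import PUBLISHED_CUTOFFS


@pytest.fixture(scope="session")
def ref():
    return reference_cohort()


@pytest.fixture(scope="session")
def timelines(ref):
    return build_timelines(ref.samples, ref.events)


@pytest.fixture(scope="session")
def surgery_timelines(timelines):
    return {pid: timelines[pid] for pid in SURGERY_PATIENTS}


@pytest.fixture
def braf_cutoffs():
    return PUBLISHED_CUTOFFS["BRAF_V600E"]


@pytest.fixture
def kras_cutoffs():
    return PUBLISHED_CUTOFFS["KRAS_G12G13"]
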