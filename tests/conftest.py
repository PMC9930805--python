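import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")

from dentage.calibration import reference_model
from dentage.staging import FDI_TEETH, StageRecord, ToothStage


@pytest.fixture
def male_model():
    return reference_model("male")


@pytest.fixture
def female_model():
    return reference_model("female")


@pytest.fixture
def rng():
    return np.random.default_rng(20230212)


def make_record(nolla=None, demirjian=None, sex="male", ca=10.0, subject="S1"):
    """Build a StageRecord from 7-vectors of Nolla values / Demirjian letters."""
    nolla = nolla if nolla is not None else [None] * 7
    demirjian = demirjian if demirjian is not None else [None] * 7
    stages = tuple(
        ToothStage(t, demirjian=d, nolla=v)
        for t, d, v in zip(FDI_TEETH, demirjian, nolla)
    )
    return StageRecord(subject_id=subject, sex=sex, ca_years=ca, stages=stages)


@pytest.fixture
def record_factory():
    return make_record
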