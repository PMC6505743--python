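from datetime import datetime, timedelta

import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")

from mewsaudit import (
    Arm,
    ElementKind,
    RecordingSource,
    VitalRecording,
    build_default_table,
    generate_cohort,
    paper_like_config,
)


@pytest.fixture(scope="session")
def table():
    return build_default_table()


@pytest.fixture(scope="session")
def small_cohort():
    """A small but full two-arm synthetic cohort, shared across tests."""
    config = paper_like_config(n_per_arm=25, seed=11)
    stays, recordings, truth = generate_cohort(config)
    return config, stays, recordings, truth


def make_recording(
    pid="P1",
    minutes=0,
    element=ElementKind.HEART_RATE,
    value=80.0,
    oxygen=False,
    source=RecordingSource.CONVENTIONAL,
    arm=Arm.CONTROL,
    base=datetime(2012, 3, 1, 8, 0),
):
    return VitalRecording(
        patient_id=pid,
        timestamp=base + timedelta(minutes=minutes),
        element=element,
        value=value,
        oxygen_therapy=oxygen,
        source=source,
        period=arm,
    )
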