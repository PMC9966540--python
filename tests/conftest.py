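import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, database=None)
settings.load_profile("deterministic")

from pupilkit import (
    CohortParams,
    PupilTrace,
    RunConfig,
    run_pipeline,
    simulate_cohort,
)


def make_trace(
    diameters,
    valid=None,
    rate=30.0,
    condition="mesopic",
    subject_id="T01",
    visit="screening",
    eye="right",
    repeat_index=1,
    onset=3.0,
    duration=10.0,
):
    """Build a trace directly from a diameter array (NaN = missing sample)."""
    d = np.asarray(diameters, dtype=float)
    if valid is None:
        valid = np.ones(d.size, dtype=bool)
    lux = {"mesopic": 4.0, "photopic": 300.0}[condition]
    return PupilTrace(
        subject_id=subject_id,
        visit=visit,
        eye=eye,
        condition=condition,
        repeat_index=repeat_index,
        lux=lux,
        sampling_rate=rate,
        stimulus_onset=onset,
        stimulus_duration=duration,
        t=np.arange(d.size) / rate,
        diameter=d,
        device_valid=np.asarray(valid, dtype=bool),
    )


def full_length(rate=30.0, onset=3.0, duration=10.0):
    return int(round((onset + duration) * rate))


@pytest.fixture
def trace_factory():
    return make_trace


@pytest.fixture(scope="session")
def small_cohort():
    """A compact right-eye cohort reused by pipeline-level tests."""
    cp = CohortParams(n_subjects=10, eyes=("right",), seed=7)
    return simulate_cohort(cp)


@pytest.fixture(scope="session")
def small_bundle(small_cohort):
    return run_pipeline(small_cohort.traces, RunConfig(seed=7))


@pytest.fixture(scope="session")
def study_bundle():
    """Right-eye cohort at the full study size, shared by recovery tests."""
    cp = CohortParams(n_subjects=43, eyes=("right",), seed=20)
    cohort = simulate_cohort(cp)
    return run_pipeline(cohort.traces, RunConfig(seed=20))
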