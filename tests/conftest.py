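import numpy as np
import pytest

from gapsurv import (
    Cohort,
    MCMCSettings,
    PriorSpec,
    SubjectRecord,
    SyntheticParams,
    generate_cohort,
)


def make_record(sid, arm, times, inds, age=60.0, gender=1):
    return SubjectRecord(
        subject_id=sid, arm=arm, age=age, gender=gender,
        event_times=tuple(times), event_indicators=tuple(inds),
    )


@pytest.fixture
def toy_cohort():
    """Five subjects, two complete, mixed censoring."""
    recs = (
        make_record("a", 0, (10.0, 15.0, 22.0), (1, 1, 1)),
        make_record("b", 0, (8.0, 12.0, 30.0), (1, 1, 0)),
        make_record("c", 1, (5.0, 20.0, 25.0), (1, 1, 1), age=50.0, gender=0),
        make_record("d", 1, (7.0, 7.0, 7.0), (1, 0, 0)),
        make_record("e", 0, (3.0, 3.0, 3.0), (0, 0, 0), age=70.0),
    )
    return Cohort(records=recs)


@pytest.fixture(scope="session")
def default_cohort():
    """Default-preset synthetic cohort: 43 vs 31 subjects, complete case."""
    cohort, manifest = generate_cohort(SyntheticParams(seed=2024))
    return cohort, manifest


@pytest.fixture
def fast_mcmc():
    return MCMCSettings(chains=2, iterations=1500, burn_in=500, seed=99)


@pytest.fixture
def vague_prior():
    return PriorSpec()


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
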