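import numpy as np
import pytest

from myoracle import (
    DigitStatus,
    DigitStatusTrace,
    FailureEvent,
    FailureKind,
    PredictionTrace,
    Session,
    SimConfig,
    TaskTimeline,
    generate_session,
)
from myoracle.session import N_CHANNELS, N_DIGITS


def make_session(
    tasks: list[TaskTimeline],
    failures: list[FailureEvent] | None = None,
    sample_rate: float = 10.0,
    subject_id: str = "T1",
) -> Session:
    """Minimal valid session with silent traces, for tests that only need
    timelines and failure instants."""
    n = int(round(tasks[-1].t_end * sample_rate)) + 1
    return Session(
        prediction=PredictionTrace(
            sample_rate=sample_rate, values=np.zeros((N_CHANNELS, n))
        ),
        digit_status=DigitStatusTrace(
            sample_rate=sample_rate,
            statuses=np.full((N_DIGITS, n), int(DigitStatus.OPEN), dtype=np.int8),
        ),
        tasks=tasks,
        failures=failures or [],
        buttons=[],
        subject_id=subject_id,
    )


def spurious_close(time: float, channel: int = 1) -> FailureEvent:
    return FailureEvent(time=time, channel=channel, kind=FailureKind.SPURIOUS_CLOSE)


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """A cheap simulator configuration for unit tests."""
    return SimConfig(
        seed=42,
        n_tasks=6,
        sample_rate=50.0,
        zone_duration_means=(4.0, 5.0, 7.0),
    )


@pytest.fixture(scope="session")
def small_session(small_cfg):
    return generate_session(small_cfg)


@pytest.fixture(scope="session")
def default_session():
    """One session under the default study conditions (20 tasks)."""
    return generate_session(SimConfig(seed=11))
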