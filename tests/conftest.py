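import pytest

from gaitdose import (
    GaitGenConfig,
    SubjectProfile,
    TrialContext,
    generate_gait_events,
)


@pytest.fixture
def subject() -> SubjectProfile:
    return SubjectProfile("S01", 1.70, "left")


@pytest.fixture
def symmetric_config() -> GaitGenConfig:
    """Jitter-free 1.0 s cycles, 60% stance both legs, 10 m at 1 m/s."""
    return GaitGenConfig(
        cycle_time=1.0,
        stance_fraction_affected=0.6,
        stance_fraction_unaffected=0.6,
        walking_speed=1.0,
        walkway_distance=10.0,
        timing_jitter_sd=0.0,
        phase_offset=0.5,
        seed=0,
    )


@pytest.fixture
def symmetric_trial(subject, symmetric_config):
    return generate_gait_events(subject, symmetric_config)


@pytest.fixture
def symmetric_context(symmetric_trial) -> TrialContext:
    return TrialContext(
        walkway_distance=10.0,
        walk_duration=symmetric_trial.duration,
        height=1.70,
        affected_side="left",
    )
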