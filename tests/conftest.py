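import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def small_config():
    """A minimal valid single-track study: 3-digit numbers, parity check."""
    from studyid import BlockLayout, CheckAlgorithm, StudyConfig

    return StudyConfig(
        study_name="DEMO",
        layout=BlockLayout.parse("N,V,X"),
        k=3,
        tracks=(("", 10),),
        visit="1",
        check_algorithm=CheckAlgorithm.PARITY,
        seed=11,
    )


@pytest.fixture
def tracked_config():
    """Two explicit tracks with track codes rendered into the ID."""
    from studyid import BlockLayout, CheckAlgorithm, StudyConfig

    return StudyConfig(
        study_name="TRK",
        layout=BlockLayout.parse("T,N,V,X"),
        k=3,
        tracks=(("1", 6), ("2", 4)),
        visit="1",
        check_algorithm=CheckAlgorithm.PARITY,
        seed=5,
    )
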