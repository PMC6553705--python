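import datetime as dt

import pytest

from netwell.data_model import StudyConfig
from netwell.synthetic_cohort import GeneratorConfig


@pytest.fixture
def study() -> StudyConfig:
    return StudyConfig(
        study_start=dt.date(2016, 8, 15),
        n_weeks=22,
        roster=frozenset({"P0000", "P0001", "P0002"}),
    )


@pytest.fixture
def tiny_generator() -> GeneratorConfig:
    """Small cohort for fast end-to-end tests."""
    return GeneratorConfig(n_participants=8, n_external=10, n_weeks=4, seed=11)
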