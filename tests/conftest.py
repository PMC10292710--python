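"""Shared fixtures: embedded study data and fast ANN training settings."""

import pytest

from rarecast.data import load_annual_fixture, load_event_fixture
from rarecast.hybrid import TrainingConfig


@pytest.fixture(scope="session")
def study_counts():
    """Annual counts 1966-2019."""
    return load_annual_fixture()


@pytest.fixture(scope="session")
def study_counts_with_2020():
    """Annual counts 1966-2020."""
    return load_annual_fixture(include_2020=True)


@pytest.fixture(scope="session")
def study_events():
    """Embedded event-time series."""
    return load_event_fixture()


@pytest.fixture()
def fast_ann_config():
    """Short training runs for tests that exercise plumbing, not accuracy."""
    return TrainingConfig(max_iterations=800, seed=0)
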