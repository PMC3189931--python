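import numpy as np
import pytest

from hiersynth import (
    Dataset,
    McmcSettings,
    StudyRecord,
    get_scenario,
)


@pytest.fixture(scope="session")
def sc1():
    return get_scenario(1)


@pytest.fixture(scope="session")
def sc4():
    return get_scenario(4)


@pytest.fixture(scope="session")
def tiny_settings():
    """Fast settings for shape/determinism tests (not for inference quality)."""
    return McmcSettings(n_chains=2, burn_in=300, n_keep=200, thin=2, seed=0)


@pytest.fixture(scope="session")
def small_dataset():
    """Hand-written 2 RCT + 2 NRS dataset used for oracle checks."""
    studies = [
        StudyRecord("randomised", 0, 200, 200, 10, 8, 75.0, 75.0),
        StudyRecord("randomised", 1, 300, 300, 12, 11, 78.0, 78.0),
        StudyRecord("nonrandomised", 0, 250, 250, 9, 14, 76.0, 82.0),
        StudyRecord("nonrandomised", 1, 150, 150, 7, 9, 77.0, 80.0),
    ]
    return Dataset(scenario=None, studies=studies)


@pytest.fixture(scope="session")
def rct_only_dataset():
    studies = [
        StudyRecord("randomised", j, n, n, rc, rt, 75.0, 75.0)
        for j, (n, rc, rt) in enumerate([(400, 18, 14), (250, 9, 8), (320, 15, 12)])
    ]
    return Dataset(scenario=None, studies=studies)
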