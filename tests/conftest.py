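import numpy as np
import pandas as pd
import pytest

from vigil.config import SimConfig, TaskSpec
from vigil.data import EpochSet
from vigil.scoring import label_epochs
from vigil.synthetic import simulate_behavior, simulate_eeg


def micro_config(seed: int = 0, **overrides) -> SimConfig:
    """A few-second configuration for unit tests: 4 + 2 participants,
    8 channels, short sessions."""
    params = dict(
        n_participants_exp1=4,
        n_participants_exp2=2,
        tasks=(
            TaskSpec("atc", 1, 48, 1, 0.25, (2.0, 2.0)),
            TaskSpec("oddball", 1, 24, 1, 0.25, (2.0, 2.0)),
            TaskSpec("line", 2, 48, 1, 0.25, (1.3, 1.7)),
        ),
        n_exp2_single_session=0,
        n_channels=8,
        seed=seed,
    )
    params.update(overrides)
    return SimConfig(**params)


@pytest.fixture(scope="session")
def micro_cfg() -> SimConfig:
    return micro_config(seed=7)


@pytest.fixture(scope="session")
def micro_trials(micro_cfg) -> pd.DataFrame:
    return simulate_behavior(micro_cfg)


@pytest.fixture(scope="session")
def micro_epochs(micro_cfg, micro_trials) -> EpochSet:
    return label_epochs(simulate_eeg(micro_cfg, micro_trials))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(123)
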