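import numpy as np
import pytest

from algafeed import (
    GroupSummary,
    TankRecord,
    TrialSimConfig,
    simulate_trial,
)


@pytest.fixture(scope="session")
def table2_weight_gain_summaries() -> list[GroupSummary]:
    """Published weight-gain row: per-diet mean +/- SE over 3 tanks."""
    return [
        GroupSummary("reference", 106.6, 13.1, 3),
        GroupSummary("33NS", 160.6, 21.4, 3),
        GroupSummary("66NS", 135.8, 4.6, 3),
        GroupSummary("100NS", 172.9, 8.4, 3),
    ]


@pytest.fixture(scope="session")
def noiseless_trial() -> tuple[TrialSimConfig, list[TankRecord]]:
    cfg = TrialSimConfig(
        w0_sd=0.0,
        growth_noise_sd=0.0,
        feed_noise_sd=0.0,
        mortality_rate=0.0,
        seed=123,
    )
    return cfg, simulate_trial(cfg)


@pytest.fixture(scope="session")
def noisy_trial() -> list[TankRecord]:
    return simulate_trial(TrialSimConfig(seed=2024))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(99)
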