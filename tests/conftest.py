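import numpy as np
import pytest

from paglucose.synth import DatasetConfig, NoiseModel, simulate_dataset


def quiet_noise(seed: int = 0) -> NoiseModel:
    """All stochastic components off: deterministic clean spectra."""
    return NoiseModel(
        floor_uv=0.0,
        floor_sd_uv=0.0,
        round_jitter_rel=0.0,
        shift_bins_max=0.0,
        round_shift_sd_bins=0.0,
        seed=seed,
    )


@pytest.fixture(scope="session")
def default_dataset():
    """One default 2-day x 12-class x 3-round simulated campaign."""
    return simulate_dataset(DatasetConfig())


@pytest.fixture(scope="session")
def noiseless_dataset():
    return simulate_dataset(DatasetConfig(noise=quiet_noise()))
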