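import numpy as np
import pytest

from ecgplace import CohortConfig, FeatureConfig, generate_cohort


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Small noiseless cohort spanning all three subject classes."""
    cfg = CohortConfig(n_per_class=10, noise_sd=0.0, baseline_drift_amp=0.0,
                       seed=101)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def noisy_cohort():
    """Small cohort at the default noise level."""
    cfg = CohortConfig(n_per_class=10, seed=202)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def raw_amplitude_config():
    """Feature config reading landmark amplitudes from the raw (mV) beat."""
    return FeatureConfig(amplitudes_from_normalized=False)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
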