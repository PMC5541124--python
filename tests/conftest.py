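import pytest
from hypothesis import settings

from isoreg import GeneratorConfig, generate_experiment

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_config():
    """A fast, noisy, decoy-carrying configuration for generic round trips."""
    return GeneratorConfig(n_proteins=60, seed=11)


@pytest.fixture(scope="session")
def small_experiment(small_config):
    return generate_experiment(small_config)


@pytest.fixture(scope="session")
def noiseless_config():
    """No noise, no regulation, no decoys: every log2 ratio is exactly zero."""
    return GeneratorConfig(
        n_proteins=25, noise_sd=0.0, frac_up_vehicle=0.0, frac_down_vehicle=0.0,
        decoy_fraction=0.0, seed=3)
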