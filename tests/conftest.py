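import pytest
from hypothesis import settings

from interarray.pipeline import analyze
from interarray.simulate import SimulationConfig, generate_experiment

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Small noise-free study: every planted effect is exact."""
    config = SimulationConfig(seed=7, n_genes=400, noise_sd_log2=0.0)
    return generate_experiment(config)


@pytest.fixture(scope="session")
def noiseless_result(noiseless_dataset):
    ds = noiseless_dataset
    return analyze(ds.tables, ds.design, ds.annotation)


@pytest.fixture(scope="session")
def noisy_dataset():
    """Realistic replicate noise at the study's design size."""
    config = SimulationConfig(seed=11, n_genes=2000, noise_sd_log2=0.25)
    return generate_experiment(config)


@pytest.fixture(scope="session")
def noisy_result(noisy_dataset):
    ds = noisy_dataset
    return analyze(ds.tables, ds.design, ds.annotation)
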