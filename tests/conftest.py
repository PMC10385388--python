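import numpy as np
import pytest

from mhcgt.synthetic import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """7 species × 4 phases × 10 records (N=280), default archetypes."""
    return generate_dataset(GeneratorConfig(samples_per_class_phase=10, seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
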