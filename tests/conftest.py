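import numpy as np
import pytest

from valleycall import simulate as sim


@pytest.fixture(scope="session")
def small_truth():
    """A compact planted genome shared by read-only tests."""
    truth = sim.generate_genome(11, chrom_length=300_000)
    planted = sim.plant_enhancers(truth, seed=12, n_per_condition=10)
    return truth, planted


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
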