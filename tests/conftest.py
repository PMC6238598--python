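import pytest

from lincterm import make_genome
from lincterm.synthetic import SimulationConfig


@pytest.fixture(scope="session")
def config():
    return SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def fixture_genome(config):
    return make_genome(config)


@pytest.fixture(scope="session")
def small_config():
    """One small chromosome — cheap enough for exhaustive-alignment oracles."""
    return SimulationConfig(seed=13, n_chroms=1, chrom_length=60_000,
                            n_mrna=4, n_linc=2)


@pytest.fixture(scope="session")
def small_genome(small_config):
    return make_genome(small_config)
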