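import pytest

from mosscharter.synthetic_data import (
    SyntheticConfig,
    generate_cohort,
    generate_reference,
)


@pytest.fixture(scope="session")
def default_config():
    return SyntheticConfig(seed=7)


@pytest.fixture(scope="session")
def reference(default_config):
    return generate_reference(default_config)


@pytest.fixture(scope="session")
def cohort(default_config, reference):
    genome, genes, spikeins = reference
    return generate_cohort(default_config, genome, genes, spikeins)
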