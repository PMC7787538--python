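import random

import pytest

from sddp.synthetic import GeneratorConfig, gen_corpus, load_worked_examples


@pytest.fixture(scope="session")
def worked():
    return load_worked_examples()


@pytest.fixture(scope="session")
def default_config():
    return GeneratorConfig(seed=1)


@pytest.fixture(scope="session")
def synthetic_corpus(default_config):
    """200-abstract corpus with ground truth at the default study conditions."""
    return gen_corpus(default_config)


@pytest.fixture()
def rng():
    return random.Random(12345)
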