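import pytest

from mitocomp.presets import daozhenensis_like, expansivus_like
from mitocomp.synthetic import generate


@pytest.fixture(scope="session")
def dao_genome():
    """One daozhenensis-like synthetic genome with its ground truth."""
    return generate(daozhenensis_like(seed=1))


@pytest.fixture(scope="session")
def exp_genome():
    return generate(expansivus_like(seed=1))
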