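import numpy as np
import pytest

from funnelmap import Mapper, MapParams, make_reference


@pytest.fixture(scope="session")
def small_ref():
    """A 50 kb random reference shared by fast pipeline-level tests."""
    name, seq, _ = make_reference(50_000, seed=1234, name="chrS")
    return name, seq


@pytest.fixture(scope="session")
def small_mapper(small_ref):
    return Mapper([small_ref], MapParams())


@pytest.fixture
def rng():
    return np.random.default_rng(99)


def random_dna(rng, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))
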