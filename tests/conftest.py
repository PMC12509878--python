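import numpy as np
import pytest
from hypothesis import settings as _hyp_settings

_hyp_settings.register_profile("deterministic", derandomize=True, deadline=None)
_hyp_settings.load_profile("deterministic")

from ncmap.index import IndexParams, build_index
from ncmap.seqcore import ConversionScheme
from ncmap.simulator import random_genome

BASES = "ACGT"


def random_seq(rng, n):
    return "".join(rng.choice(list(BASES), size=n))


@pytest.fixture(scope="session")
def ct_scheme():
    return ConversionScheme.from_name("CT")


@pytest.fixture(scope="session")
def tc_scheme():
    return ConversionScheme.from_name("TC")


@pytest.fixture(scope="session")
def small_refs():
    """A 100 kb single-contig synthetic genome with repeat families."""
    return random_genome(100_000, seed=7)


@pytest.fixture(scope="session")
def small_index(small_refs, ct_scheme):
    return build_index(small_refs, ct_scheme, IndexParams())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
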