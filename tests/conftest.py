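import numpy as np
import pytest

from pindex import make_polyploid_fixture


@pytest.fixture(scope="session")
def biased_bundle(tmp_path_factory):
    """Small biased tetraploid bundle with shattered blocks, on disk."""
    out = tmp_path_factory.mktemp("biased_bundle")
    return make_polyploid_fixture(
        out,
        scenario="biased",
        n_chromosomes=4,
        genes_per_chromosome=500,
        seed=3,
        n_segments=4,
    )


@pytest.fixture(scope="session")
def balanced_bundle(tmp_path_factory):
    out = tmp_path_factory.mktemp("balanced_bundle")
    return make_polyploid_fixture(
        out,
        scenario="balanced",
        n_chromosomes=4,
        genes_per_chromosome=800,
        seed=5,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
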