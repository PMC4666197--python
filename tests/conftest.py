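import numpy as np
import pytest

from tcrseek import (
    JunctionModel,
    generate_fixture_germline,
    merge_references,
    simulate_repertoire,
)


@pytest.fixture(scope="session")
def ref():
    """Small two-chain fixture reference shared across the suite."""
    return merge_references(
        generate_fixture_germline(6, 1, 4, "alpha", seed=101),
        generate_fixture_germline(6, 2, 4, "beta", seed=102),
    )


@pytest.fixture(scope="session")
def junction_model():
    return JunctionModel.default()


@pytest.fixture(scope="session")
def beta_repertoire(ref, junction_model):
    rng = np.random.default_rng(7)
    return simulate_repertoire(ref, "beta", 300, junction_model, rng)


@pytest.fixture(scope="session")
def alpha_repertoire(ref, junction_model):
    rng = np.random.default_rng(8)
    return simulate_repertoire(ref, "alpha", 200, junction_model, rng)
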