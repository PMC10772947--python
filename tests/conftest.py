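import numpy as np
import pytest

from allophase.presets import build_preset


@pytest.fixture(scope="session")
def wheat_bundle():
    """One wheat-like simulated complex shared across read-only tests."""
    return build_preset("wheat", seed=0)


@pytest.fixture(scope="session")
def strawberry_bundle():
    return build_preset("strawberry", seed=0)


@pytest.fixture(scope="session")
def wheat_synteny(wheat_bundle):
    from allophase.pipeline import run_synteny_channel
    return run_synteny_channel(wheat_bundle.complexes, wheat_bundle.outgroup)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
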