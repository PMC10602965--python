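import numpy as np
import pytest
from hypothesis import settings

from npgsim.substrate import CahnHilliardParams, generate_npg_field

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def npg_field_20nm():
    """A 20 nm nanoporous field shared across tests (generation is the
    slowest fixture; 256 px keeps ~10 characteristic lengths per side)."""
    return generate_npg_field(seed=7, target_length_nm=20.0, size_px=256)


@pytest.fixture(scope="session")
def ch_params():
    return CahnHilliardParams(seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
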