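import pytest

import sithv2 as s
from sithv2 import simulator as sim


@pytest.fixture(scope="session")
def temperate_forcing():
    """Two synthetic years of temperate forcing, fixed seed."""
    return s.generate_forcing(s.REGIMES["temperate"], 2, seed=3)


@pytest.fixture(scope="session")
def loam_grass(temperate_forcing):
    """Loam/grassland parameters with climatology traits filled."""
    return sim.derive_traits(temperate_forcing, s.make_site_params("loam", "grassland"))


@pytest.fixture(scope="session")
def equilibrated(temperate_forcing, loam_grass):
    """State after a 20-cycle spin-up on the first forcing year."""
    return sim.spin_up(temperate_forcing.iloc[:365], loam_grass, 20).state
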