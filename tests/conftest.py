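import numpy as np
import pytest

import receptome as rc


@pytest.fixture(scope="session")
def geom60():
    return rc.make_sphere_geometry(60, seed=1)


@pytest.fixture(scope="session")
def geom100():
    return rc.make_sphere_geometry(100, seed=1)


@pytest.fixture(scope="session")
def planted_panel(geom100):
    """Single-axis panel at the study's noise level, plus its truth."""
    return rc.simulate_density_panel(
        geom100, n_molecules=19, n_axes=1, noise_sd=0.1, seed=7
    )


@pytest.fixture(scope="session")
def blocks60():
    """Planted 3-block signed matrix at the generator defaults."""
    return rc.simulate_signed_blocks(
        60, 3, w_in=0.8, w_out=-0.4, noise_sd=0.05, seed=11
    )
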