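import numpy as np
import pytest

from prevpool.simulator import (
    GenerativeParams,
    attach_poststrat_weights,
    draw_population,
    make_fixture,
    sample_sources,
)


@pytest.fixture(scope="session")
def small_table():
    """A small simulated two-source table: n1=200, n2=2000, 50% linked."""
    return make_fixture(seed=20200406, N=20_000, n1=200, n2=2000, overlap=0.5)


@pytest.fixture(scope="session")
def medium_table():
    """A larger table with full overlap (every survey subject in the EHR)."""
    params = GenerativeParams(N=50_000, n1=400, n2=5000, overlap=1.0,
                              target_p1=0.30, target_p2=0.35,
                              seed=11).calibrated()
    rng = np.random.default_rng(11)
    pop = draw_population(params, rng)
    return attach_poststrat_weights(sample_sources(pop, params, rng), pop)
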