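import numpy as np
import pytest

import torporna as tp


@pytest.fixture(scope="session")
def default_profile():
    """Representative 12-day cycle at 1-minute resolution."""
    return tp.build_profile(tp.default_cycle_spec())


@pytest.fixture(scope="session")
def coarse_profile():
    """Same cycle at 10-minute resolution, for cheap simulations."""
    return tp.build_profile(tp.default_cycle_spec(), grid_spacing_min=10.0)


@pytest.fixture(scope="session")
def small_population():
    """60-transcript population (50 bulk + 10 protected) for fast runs."""
    spec = tp.PopulationSpec(n_bulk=50, n_protected=10, seed=11)
    return tp.sample_population(spec, tp.ProtectionMechanism.temp_protection())


@pytest.fixture()
def rng():
    return np.random.default_rng(202409)
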