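import numpy as np
import pytest

from pmfm import (
    Connectome,
    LinearCoefficients,
    SimulationConfig,
    SpatialMap,
    SyntheticSpec,
    generate_connectome,
    generate_spatial_maps,
    simulate_bold,
)


@pytest.fixture(scope="session")
def small_spec():
    return SyntheticSpec(n_regions=10, density=0.35, map_correlation=0.4, n_genes=40, seed=0)


@pytest.fixture(scope="session")
def small_sc(small_spec):
    return generate_connectome(small_spec)


@pytest.fixture(scope="session")
def small_maps(small_spec):
    return generate_spatial_maps(small_spec)


@pytest.fixture(scope="session")
def quiet_coeffs():
    """Near-critical stable operating point used for short test simulations."""
    from pmfm import recovery_coefficients

    return recovery_coefficients()


@pytest.fixture(scope="session")
def short_config():
    """3-minute protocol with a 1-minute burn-in (166 output frames)."""
    return SimulationConfig(dt=0.01, t_total=180.0, t_burn=60.0, tr=0.72, seed=0)


@pytest.fixture(scope="session")
def short_bold(quiet_coeffs, small_sc, small_maps, short_config):
    return simulate_bold(quiet_coeffs, small_sc, small_maps, config=short_config)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
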