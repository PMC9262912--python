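import pytest

from greenfeedback.experiments import build_experiment_set
from greenfeedback.grids import Season, climatological_lai_mask, regular_grid
from greenfeedback.lai import LaiScenario, generate_lai_scenario
from greenfeedback.simulator import SimParams, default_forcing


@pytest.fixture(scope="session")
def small_grid():
    return regular_grid(8, 8)


@pytest.fixture(scope="session")
def smooth_lai(small_grid):
    """Noise-free LAI record with the default seasonal trends, 8 years."""
    lat, lon = small_grid
    sc = LaiScenario(seed=2, noise_cell_sd=0.0, noise_shared_sd=0.0)
    return generate_lai_scenario(sc, lat, lon, years=(2000, 2007))


@pytest.fixture(scope="session")
def noisy_lai(small_grid):
    lat, lon = small_grid
    return generate_lai_scenario(LaiScenario(seed=7), lat, lon, years=(2000, 2011))


@pytest.fixture(scope="session")
def wet_forcing(small_grid):
    lat, _ = small_grid
    return default_forcing(lat, dry_band=None)


@pytest.fixture(scope="session")
def params():
    return SimParams()


@pytest.fixture(scope="session")
def quiet_params():
    """Circulation internal variability switched off."""
    return SimParams(ar1_sd=0.0)


@pytest.fixture(scope="session")
def small_experiment(small_grid, noisy_lai, params):
    """5-member MAM+JJA experiment set on the 8x8 grid, 12-year record."""
    lat, _ = small_grid
    forcing = default_forcing(lat)
    return build_experiment_set(
        noisy_lai, forcing, params, seeds=[11, 12, 13, 14, 15],
        seasons=[Season.MAM, Season.JJA],
    )


@pytest.fixture(scope="session")
def small_mask(noisy_lai):
    return climatological_lai_mask(noisy_lai)
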