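import numpy as np
import pytest

from pwsfire import (
    GridDef,
    LagConfig,
    estimate_pws_map,
    make_truth,
    simulate_climate,
    simulate_lfmc,
    standard_fixture,
)


@pytest.fixture(scope="session")
def small_grid():
    return GridDef(8, 8)


@pytest.fixture(scope="session")
def small_loop(small_grid):
    """Tiny noise-free closed loop: climate, truth, LFMC and estimated PWS."""
    truth = make_truth(small_grid, seed=11)
    climate = simulate_climate(small_grid, range(2015, 2021), seed=12)
    lfmc = simulate_lfmc(climate, truth, noise_sd=0.0, seed=13)
    pws_map = estimate_pws_map(lfmc, climate.dfmc, LagConfig())
    return {"truth": truth, "climate": climate, "lfmc": lfmc, "pws": pws_map}


@pytest.fixture(scope="session")
def std_fixture():
    """Standard 64x64 fixture with noise calibrated to median fit r2 ~ 0.3."""
    return standard_fixture(seed=42)


@pytest.fixture(scope="session")
def std_pws(std_fixture):
    fx = std_fixture
    return estimate_pws_map(fx.lfmc, fx.climate.dfmc, fx.cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
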