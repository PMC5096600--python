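import pytest
from hypothesis import HealthCheck, settings

import oasim as oa

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def two_layer():
    """Two-layer demonstration scenario (10 then 20 cm^-1 over 0.05 cm each)."""
    return oa.preset("fig3a")


@pytest.fixture(scope="session")
def small_grid():
    """Reduced cylindrical grid: enough resolution for property checks,
    cheap enough to solve many times."""
    return oa.CylindricalGrid(L_rho=0.3, N_rho=1500, N_phi=180, L_z=0.15, N_z=150)


@pytest.fixture(scope="session")
def small_oracle_grid():
    return oa.CartesianGrid(L_x=0.6, L_y=0.6, L_z=0.15, N_x=200, N_y=200, N_z=75)


@pytest.fixture(scope="session")
def ff_signal(two_layer):
    """Far-field fig3a signal at z_D = -4 cm on the default grid."""
    cfg = two_layer
    det = oa.DetectionPoint(0.0, -4.0)
    return oa.solve(cfg.stack, cfg.beam, cfg.const, det, grid=cfg.grid, foil=cfg.foil)


@pytest.fixture(scope="session")
def nf_signal(two_layer):
    """Near-field fig3a signal at z_D = -0.04 cm on the default grid."""
    cfg = two_layer
    det = oa.DetectionPoint(0.0, -0.04)
    return oa.solve(cfg.stack, cfg.beam, cfg.const, det, grid=cfg.grid, foil=cfg.foil)


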