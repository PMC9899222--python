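import pytest
from hypothesis import HealthCheck, settings

import radonroom as rr
from radonroom.flow import SolverSettings

settings.register_profile(
    "deterministic", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("deterministic")

#: effective generation rate calibrated from the published ACH=0.3
#: analytical steady value (221.60 Bq/m3, C_out = 10 Bq/m3)
G_CALIBRATED = rr.calibrate_generation(221.60, 0.3, 10.0)


@pytest.fixture(scope="session")
def default_geom():
    return rr.build_room(None)


@pytest.fixture(scope="session")
def coarse_grid(default_geom):
    """5 cells/m closed-scenario grid (15 x 20 x 14)."""
    return rr.generate_grid(default_geom, 5)


@pytest.fixture(scope="session")
def coarse_flow(default_geom, coarse_grid):
    vent = rr.VentilationSpec(ach=1.0, room_volume=default_geom.volume,
                              vent_area=default_geom.vent_area)
    return rr.solve_flow(coarse_grid, vent)


@pytest.fixture(scope="session")
def coarse_radon(coarse_grid, coarse_flow):
    """Volumetric-source solve with the calibrated generation rate."""
    return rr.solve_radon(coarse_grid, coarse_flow, rr.SourceSpec(),
                          source_mode="volumetric",
                          generation_bq_m3_h=G_CALIBRATED)


def _room_run(scenario: str):
    geom = rr.build_room({"scenario": scenario})
    grid = rr.generate_grid(geom, 10)  # 30 x 40 x 28
    vent = rr.VentilationSpec(ach=1.0, room_volume=geom.volume,
                              vent_area=geom.vent_area)
    flow = rr.solve_flow(grid, vent, settings=SolverSettings())
    radon = rr.solve_radon(grid, flow, rr.SourceSpec(),
                           source_mode="volumetric",
                           generation_bq_m3_h=G_CALIBRATED)
    return grid, flow, radon


@pytest.fixture(scope="session")
def room_run_closed():
    """Production-resolution closed-door run at ACH = 1."""
    return _room_run("closed")


@pytest.fixture(scope="session")
def room_run_open():
    """Production-resolution open-door run at ACH = 1."""
    return _room_run("open")
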