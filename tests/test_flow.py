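import numpy as np
import pytest

import radonroom as rr
from radonroom.flow import (FlowSolverError, SolverSettings,
                            bcs_for_room, divergence, lid_driven_cavity,
                            solve_flow)
from radonroom.room import box_grid

#: Ghia, Ghia & Shin (1982) Re=100 cavity centreline reference values
GHIA_RE100 = {"u_center": -0.20581, "u_min": -0.21090,
              "v_max": 0.17527, "v_min": -0.24533}


class TestQuiescentAndErrors:
    def test_zero_inlet_speed_gives_zero_field(self, coarse_grid,
                                               default_geom):
        vent = rr.VentilationSpec(ach=0.0, room_volume=default_geom.volume,
                                  vent_area=default_geom.vent_area)
        field = solve_flow(coarse_grid, vent)
        assert field.converged
        assert field.speed().max() == 0.0
        assert np.all(field.p == 0.0)

    def test_nonconvergence_raises_with_history(self, coarse_grid,
                                                default_geom):
        vent = rr.VentilationSpec(ach=1.0, room_volume=default_geom.volume,
                                  vent_area=default_geom.vent_area)
        with pytest.raises(FlowSolverError, match="residual"):
            solve_flow(coarse_grid, vent,
                       settings=SolverSettings(max_iterations=3))

    def test_missing_openings_rejected(self):
        grid = box_grid(1.0, 1.0, 1.0, (4, 4, 4))
        vent = rr.VentilationSpec(ach=1.0, room_volume=1.0, vent_area=0.1)
        with pytest.raises(FlowSolverError, match="inlet"):
            bcs_for_room(grid, vent)

    def test_invalid_settings_rejected(self):
        with pytest.raises(FlowSolverError):
            SolverSettings(closure="LES")
        with pytest.raises(FlowSolverError):
            SolverSettings(alpha_u=1.5)


class TestContinuity:
    def test_converged_room_flow_is_divergence_free(self, coarse_grid,
                                                    coarse_flow):
        cc = rr.check_continuity(coarse_flow, coarse_grid)
        assert cc["max_scaled"] < 1e-6

    def test_global_mass_balance(self, coarse_flow):
        assert coarse_flow.mass_balance["relative_imbalance"] < 1e-6

    def test_uniform_unidirectional_field_is_divergence_free(self):
        grid = box_grid(1.0, 1.0, 1.0, (6, 6, 6))
        u = np.full((7, 6, 6), 0.3)
        v = np.zeros((6, 7, 6))
        w = np.zeros((6, 6, 7))
        np.testing.assert_allclose(divergence(grid, u, v, w), 0.0,
                                   atol=1e-15)

    def test_perturbed_field_reports_divergence(self, coarse_grid,
                                                coarse_flow):
        # finite-difference oracle: adding q to one face changes that
        # cell's divergence by exactly q and its neighbour's by -q
        u = coarse_flow.u.copy()
        dy, dz = coarse_grid.dy, coarse_grid.dz
        base = divergence(coarse_grid, u, coarse_flow.v, coarse_flow.w)
        u[5, 5, 5] += 1.0e-3
        pert = divergence(coarse_grid, u, coarse_flow.v, coarse_flow.w)
        # face i=5 is the low-x face of cell 5 and the high-x face of
        # cell 4: extra inflow for 5, extra outflow for 4
        assert pert[5, 5, 5] - base[5, 5, 5] == pytest.approx(
            -1.0e-3 * dy * dz, rel=1e-9)
        assert pert[4, 5, 5] - base[4, 5, 5] == pytest.approx(
            1.0e-3 * dy * dz, rel=1e-9)
        cc = rr.check_continuity(
            rr.FlowField(u=u, v=coarse_flow.v, w=coarse_flow.w,
                         p=coarse_flow.p, rho=coarse_flow.rho,
                         mu=coarse_flow.mu, mu_t=0.0), coarse_grid)
        assert cc["max_scaled"] > 1e-6


class TestMirrorSymmetry:
    def test_symmetric_room_gives_x_mirror_symmetric_flow(self):
        # window centred on the y=Ly wall, door centred on y=0: geometry,
        # boundary conditions and scheme are all symmetric under x -> Lx-x
        # (patch widths chosen to snap symmetrically at 5 cells/m)
        geom = rr.build_room({
            "window": {"wall": "y1", "center": [1.5, 1.4], "width": 1.0},
            "door": {"wall": "y0", "center": [1.5, 1.1], "width": 1.0},
            "scenario": "open"})
        grid = rr.generate_grid(geom, 5)
        vent = rr.VentilationSpec(ach=1.0, room_volume=geom.volume,
                                  vent_area=geom.vent_area)
        f = solve_flow(grid, vent)
        vmax = max(np.abs(f.u).max(), np.abs(f.v).max())
        # u is antisymmetric, v symmetric under the mirror
        assert np.abs(f.u + f.u[::-1]).max() < 5e-3 * vmax
        assert np.abs(f.v - f.v[::-1]).max() < 5e-3 * vmax


@pytest.fixture(scope="module")
def cavity():
    return lid_driven_cavity(n=48, reynolds=100.0)


class TestCavityBenchmark:
    def test_centreline_velocities_match_published_benchmark(self, cavity):
        grid, field = cavity
        nx, ny, nz = grid.shape
        y = (np.arange(ny) + 0.5) * grid.dy
        u_cl = field.u[nx // 2, :, nz // 2]
        x = (np.arange(nx) + 0.5) * grid.dx
        v_cl = field.v[:, ny // 2, nz // 2]
        assert np.interp(0.5, y, u_cl) == pytest.approx(
            GHIA_RE100["u_center"], rel=0.05)
        assert u_cl.min() == pytest.approx(GHIA_RE100["u_min"], rel=0.05)
        assert v_cl.max() == pytest.approx(GHIA_RE100["v_max"], rel=0.05)
        assert v_cl.min() == pytest.approx(GHIA_RE100["v_min"], rel=0.05)

    def test_spanwise_invariance(self, cavity):
        grid, field = cavity
        # free-slip span walls keep the solution two-dimensional
        assert np.abs(field.w).max() < 1e-8
        assert np.abs(field.u[:, :, 0] - field.u[:, :, -1]).max() < 1e-8


class TestGridConvergence:
    def test_monitor_point_velocity_plateaus_under_refinement(
            self, default_geom):
        speeds = []
        for res in ((12, 16, 12), (18, 24, 17)):
            grid = rr.generate_grid(default_geom, res)
            vent = rr.VentilationSpec(ach=1.0,
                                      room_volume=default_geom.volume,
                                      vent_area=default_geom.vent_area)
            f = solve_flow(grid, vent)
            pt = f.speed()[grid.nx // 2, grid.ny // 2, grid.nz // 2]
            speeds.append(pt)
        # mid-room speed changes modestly between successive grids,
        # mirroring the plateau of a mesh-convergence study
        assert abs(speeds[1] - speeds[0]) / abs(speeds[1]) < 0.15


class TestKEpsilonClosure:
    def test_room_flow_converges_and_conserves_mass(self, coarse_grid,
                                                    default_geom):
        vent = rr.VentilationSpec(ach=1.0, room_volume=default_geom.volume,
                                  vent_area=default_geom.vent_area)
        f = solve_flow(coarse_grid, vent,
                       settings=SolverSettings(closure="k_epsilon",
                                               max_iterations=20000))
        assert f.converged
        assert f.mass_balance["relative_imbalance"] < 1e-6
        assert np.all(f.k >= 0) and np.all(f.eps > 0)
        assert np.min(f.mu_t) >= 0
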