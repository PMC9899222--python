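import numpy as np
import pytest

import radonroom as rr
from radonroom.room import box_grid
from radonroom.transport import (TransportError, layer_mean, per_second,
                                 sample_at, volume_average)

G_CALIBRATED = rr.calibrate_generation(221.60, 0.3, 10.0)


class TestGenerationRate:
    def test_all_surfaces_of_reference_room(self, default_geom):
        areas = {w: default_geom.wall_area(w) for w in
                 ("x0", "x1", "y0", "y1", "z0", "z1")}
        assert sum(areas.values()) == pytest.approx(63.2)
        g = rr.volumetric_generation_rate(
            {w: 3.1 for w in areas}, areas, default_geom.volume)
        assert g == pytest.approx(5.83, abs=0.01)

    def test_zero_exhalation(self):
        assert rr.volumetric_generation_rate({"floor": 0.0}, {"floor": 12.0},
                                             33.6) == 0.0

    def test_floor_only(self):
        g = rr.volumetric_generation_rate({"floor": 3.1}, {"floor": 12.0},
                                          33.6)
        assert g == pytest.approx(1.107, abs=0.002)

    def test_per_second_conversion(self):
        assert per_second(3600.0) == pytest.approx(1.0)


class TestVolumeAverage:
    def test_uniform_field(self, coarse_grid):
        f = np.full(coarse_grid.shape, 42.0)
        assert volume_average(f, coarse_grid) == pytest.approx(42.0)

    def test_half_and_half(self, coarse_grid):
        f = np.zeros(coarse_grid.shape)
        # equal volumes at 0 and 2c average to c (even cell split in y)
        f[:, :10] = 2 * 13.0
        f[:, 10:] = 0.0
        assert volume_average(f, coarse_grid) == pytest.approx(13.0)

    def test_linear_in_z_gives_midpoint(self, coarse_grid):
        _, _, z = coarse_grid.cell_centers
        f = np.broadcast_to(5.0 + 3.0 * z, coarse_grid.shape)
        mid = 5.0 + 3.0 * coarse_grid.geom.lz / 2
        assert volume_average(f, coarse_grid) == pytest.approx(mid, rel=1e-12)


class TestSampleAt:
    def test_uniform_field_everywhere(self, coarse_grid):
        f = np.full(coarse_grid.shape, 7.0)
        pts = [(0.01, 0.01, 0.01), (1.5, 2.0, 1.4), (2.99, 3.99, 2.79)]
        np.testing.assert_allclose(sample_at(f, coarse_grid, pts), 7.0)

    def test_cell_center_is_exact(self, coarse_grid):
        rng = np.random.default_rng(5)
        f = rng.random(coarse_grid.shape)
        x, y, z = coarse_grid.cell_centers
        pt = (x[3], y[4], z[5])
        assert sample_at(f, coarse_grid, [pt])[0] == pytest.approx(
            f[3, 4, 5], rel=1e-12)

    def test_trilinear_reproduces_linear_fields(self, coarse_grid):
        x, y, z = coarse_grid.cell_centers
        xx, yy, zz = np.meshgrid(x, y, z, indexing="ij")
        f = 1.0 + 2.0 * xx - 0.5 * yy + 3.0 * zz
        pts = [(1.23, 2.34, 1.11), (0.77, 3.05, 0.63)]
        expect = [1.0 + 2.0 * p[0] - 0.5 * p[1] + 3.0 * p[2] for p in pts]
        np.testing.assert_allclose(sample_at(f, coarse_grid, pts), expect,
                                   rtol=1e-12)

    def test_outside_room_rejected(self, coarse_grid):
        with pytest.raises(TransportError, match="outside"):
            sample_at(np.zeros(coarse_grid.shape), coarse_grid,
                      [(5.0, 1.0, 1.0)])


class TestSolveRadon:
    def test_no_source_inlet_dominated(self, coarse_grid, coarse_flow):
        # ventilation-only: the room equilibrates to the outdoor level, the
        # small radioactive-decay deficit scaling with lambda_Rn/ACH
        src = rr.SourceSpec(exhalation_bq_m2_h=0.0, outdoor_bq_m3=10.0)
        geom = coarse_grid.geom
        vent = rr.VentilationSpec(ach=4.3, room_volume=geom.volume,
                                  vent_area=geom.vent_area)
        flow = rr.solve_flow(coarse_grid, vent)
        rad = rr.solve_radon(coarse_grid, flow, src)
        assert abs(rad.volume_average - 10.0) / 10.0 < 0.005
        assert rad.min > 0

    def test_strong_mixing_limit_matches_wellmixed(self, coarse_grid,
                                                   coarse_flow):
        rad = rr.solve_radon(coarse_grid, coarse_flow, rr.SourceSpec(),
                             source_mode="volumetric",
                             generation_bq_m3_h=G_CALIBRATED,
                             diffusion_override=1.2e-5 * 1e6)
        box = rr.WellMixedParams(generation=G_CALIBRATED, ach=1.0,
                                 outdoor=10.0)
        expect = rr.wellmixed_steady(box)
        assert abs(rad.volume_average - expect) / expect < 0.02

    def test_activity_balance_closes(self, coarse_radon):
        assert coarse_radon.balance["relative_residual"] < 1e-4

    def test_positivity(self, coarse_grid, coarse_flow):
        rad = rr.solve_radon(coarse_grid, coarse_flow, rr.SourceSpec())
        assert rad.min >= 0.0

    def test_floor_layer_exceeds_average_with_wall_sources(
            self, coarse_grid, coarse_flow):
        rad = rr.solve_radon(coarse_grid, coarse_flow, rr.SourceSpec(),
                             source_mode="boundary_flux")
        assert layer_mean(rad, coarse_grid, 0.3) > rad.volume_average

    def test_unknown_source_mode_rejected(self, coarse_grid, coarse_flow):
        with pytest.raises(TransportError):
            rr.solve_radon(coarse_grid, coarse_flow, rr.SourceSpec(),
                           source_mode="magic")


class TestManufacturedConvergence:
    def test_l2_error_first_order_under_refinement(self):
        from radonroom.synthetic import manufactured_case

        errors = {}
        for n in (16, 32):
            grid = box_grid(1.0, 1.0, 1.0, (n, n, n))
            errors[n] = manufactured_case(grid).l2_error()
        assert errors[16] / errors[32] >= 1.8

    def test_constant_field_zero_velocity_source_is_decay(self):
        from radonroom.synthetic import manufactured_case

        grid = box_grid(1.0, 1.0, 1.0, (8, 8, 8))
        mc = manufactured_case(grid, amplitude=0.0, c_amp=0.0, c_mean=30.0)
        xc, yc, zc = grid.cell_centers
        src = mc.cell_source()
        np.testing.assert_allclose(src, mc.decay * 30.0, rtol=1e-12)
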