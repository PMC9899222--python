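import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import radonroom as rr
from radonroom.compare import (ComparisonError, MeasurementSet,
                               load_detector_printed_averages,
                               measurement_set_from_table)


class TestMetrics:
    def test_sweep_table_percentage_differences(self):
        # recomputed from the printed analytical/numerical pairs
        assert rr.percentage_difference(74.59, 70.21) == pytest.approx(
            5.87, abs=0.005)
        assert rr.percentage_difference(25.11, 20.17) == pytest.approx(
            19.67, abs=0.005)

    def test_identical_values_give_zero(self):
        assert rr.percentage_difference(42.0, 42.0) == 0.0
        assert rr.relative_deviation(42.0, 42.0) == 0.0

    def test_breathing_zone_deviations(self):
        # AlphaGUARD / RAD7 vs prediction at 1.0 m, open scenario
        assert rr.relative_deviation(77.0, 82.0) == pytest.approx(6.1,
                                                                  abs=0.05)
        assert rr.relative_deviation(81.0, 82.0) == pytest.approx(1.2,
                                                                  abs=0.05)

    def test_sign_conventions_differ(self):
        # percentage difference is signed, relative deviation absolute
        assert rr.percentage_difference(50.0, 60.0) < 0
        assert rr.relative_deviation(60.0, 50.0) > 0

    @given(a=st.floats(1.0, 300.0), n=st.floats(0.1, 300.0),
           c=st.floats(0.01, 100.0))
    def test_scale_invariance(self, a, n, c):
        assert rr.percentage_difference(c * a, c * n) == pytest.approx(
            rr.percentage_difference(a, n), rel=1e-9)
        assert rr.relative_deviation(c * n, c * a) == pytest.approx(
            rr.relative_deviation(n, a), rel=1e-9)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ComparisonError):
            rr.percentage_difference(0.0, 1.0)
        with pytest.raises(ComparisonError):
            rr.relative_deviation(1.0, 0.0)


class TestFixtures:
    def test_sweep_table_contents(self):
        table = rr.load_ventilation_sweep_table()
        assert len(table) == 6
        row = table[np.isclose(table["ach_per_h"], 1.0)].iloc[0]
        assert row["numerical_closed_bq_m3"] == 70.21
        assert row["numerical_open_bq_m3"] == 66.25
        assert row["analytical_bq_m3"] == 74.59

    def test_detector_tables_shape(self):
        df = rr.load_detector_tables()
        # 5 devices x 5 points x (2-3 heights) minus missing cells
        assert set(df["device"]) == {"AlphaGUARD", "RAD7", "Raduet", "NRPB",
                                     "Simulation"}
        sim = rr.load_detector_tables(device="Simulation")
        assert len(sim) == 30  # 5 points x 3 heights x 2 scenarios
        assert df["concentration_bq_m3"].min() > 0

    def test_printed_average_consistent_with_cells(self):
        # breathing-zone predicted row, open door: printed average 82
        sim = rr.load_detector_tables(scenario="open", device="Simulation")
        z100 = sim[np.isclose(sim["z_m"], 1.0)]
        assert sorted(z100["concentration_bq_m3"]) == [50, 52, 57, 98, 154]
        printed = load_detector_printed_averages()
        row = printed[(printed["device"] == "Simulation")
                      & (printed["scenario"] == "open")
                      & np.isclose(printed["z_m"], 1.0)]
        assert abs(z100["concentration_bq_m3"].mean()
                   - float(row["average_bq_m3"].iloc[0])) < 0.5

    def test_measurement_set_from_table(self):
        mset = measurement_set_from_table("open", "AlphaGUARD", z_m=1.0)
        assert len(mset.records) == 5
        assert mset.values.mean() == pytest.approx(77.2, abs=0.05)


class TestBuildTable2:
    def test_calibrated_parameters_reproduce_analytical_column(self):
        params = rr.calibrated_params_from_sweep_table()
        table = rr.load_ventilation_sweep_table()
        report = rr.build_table2(
            table["ach_per_h"],
            {"open": table["numerical_open_bq_m3"].tolist(),
             "closed": table["numerical_closed_bq_m3"].tolist()},
            params)
        np.testing.assert_allclose(report.table["analytical_bq_m3"],
                                   table["analytical_bq_m3"], atol=0.01)

    def test_single_row_and_self_comparison(self):
        params = rr.calibrated_params_from_sweep_table()
        analytical = rr.wellmixed_steady(
            rr.WellMixedParams(generation=params.generation, ach=1.0,
                               outdoor=10.0))
        report = rr.build_table2([1.0], {"closed": [analytical]}, params)
        assert len(report.table) == 1
        assert report.table["diff_closed_pct"].iloc[0] == pytest.approx(
            0.0, abs=1e-12)

    def test_mismatched_lengths_rejected(self):
        params = rr.calibrated_params_from_sweep_table()
        with pytest.raises(ComparisonError):
            rr.build_table2([1.0, 2.0], {"closed": [70.0]}, params)


class TestDetectorComparison:
    def test_zero_noise_self_consistency(self, coarse_grid, coarse_radon):
        from radonroom.synthetic import NoiseModel, synthetic_measurements

        pts = [(1.0, 1.0, 1.0), (2.0, 3.0, 2.0), (0.5, 0.5, 0.5)]
        mset = synthetic_measurements(coarse_radon, coarse_grid, pts,
                                      NoiseModel(sigma=0.0, seed=1))
        report = rr.build_detector_comparison(coarse_radon, coarse_grid, mset)
        np.testing.assert_allclose(report.table["relative_deviation_pct"],
                                   0.0, atol=1e-10)

    def test_permutation_invariance(self, coarse_grid, coarse_radon):
        mset = measurement_set_from_table("closed", "RAD7")
        shuffled = MeasurementSet(
            device=mset.device,
            records=mset.records.sample(frac=1.0, random_state=3),
            scenario=mset.scenario, ach=mset.ach)
        r1 = rr.build_detector_comparison(coarse_radon, coarse_grid, mset)
        r2 = rr.build_detector_comparison(coarse_radon, coarse_grid, shuffled)
        assert (r1.summary["mean_relative_deviation_pct"]
                == pytest.approx(r2.summary["mean_relative_deviation_pct"]))

    def test_empty_measurements_rejected(self):
        with pytest.raises(ComparisonError):
            MeasurementSet(device="RAD7", records=pd.DataFrame(
                columns=["x_m", "y_m", "z_m", "concentration_bq_m3"]))
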