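"""Comparison of analytical, numerical and measured radon concentrations.

Two distinct metrics are deliberately kept apart:

* ``percentage_difference`` — the signed (analytical - numerical) /
  analytical x 100 used when benchmarking the finite-volume averages
  against the well-mixed model across ventilation rates;
* ``relative_deviation`` — the absolute |measured - predicted| /
  predicted x 100 used when validating predictions against detector
  readings.

The module also ships, as fixtures, the published ventilation-sweep table
and the detector intercomparison tables (active AlphaGUARD/RAD7 monitors
and passive Raduet/NRPB track detectors at five plan positions and three
heights), and rebuilds both comparisons from package output.
"""

from __future__ import annotations

import importlib.resources as resources
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .boxmodel import WellMixedParams, wellmixed_steady

KNOWN_DEVICES = ("AlphaGUARD", "RAD7", "Raduet", "NRPB", "Simulation",
                 "synthetic")

#: detector plan positions (x, y) in metres; heights are 0.2/1.0/1.8 m
DETECTOR_POINTS = {
    "A": (2.9, 0.1),
    "B": (0.1, 0.1),
    "C": (0.1, 3.9),
    "D": (2.9, 3.9),
    "Center": (1.5, 2.0),
}
DETECTOR_HEIGHTS = (0.2, 1.0, 1.8)


class ComparisonError(ValueError):
    """Raised for invalid comparison inputs."""


def percentage_difference(analytical: float, numerical: float) -> float:
    """Signed percentage difference (analytical - numerical)/analytical."""
    analytical = np.asarray(analytical, dtype=float)
    if np.any(analytical <= 0):
        raise ComparisonError("analytical reference must be positive")
    out = (analytical - np.asarray(numerical, dtype=float)) / analytical * 100.0
    return float(out) if out.ndim == 0 else out


def relative_deviation(measured: float, predicted: float) -> float:
    """Absolute relative deviation |measured - predicted|/predicted, %."""
    predicted = np.asarray(predicted, dtype=float)
    if np.any(predicted <= 0):
        raise ComparisonError("predicted reference must be positive")
    out = np.abs(np.asarray(measured, dtype=float) - predicted) / predicted * 100.0
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class MeasurementSet:
    """Detector readings at labelled positions inside the room.

    ``records`` columns: point, x_m, y_m, z_m, concentration_bq_m3.
    """

    device: str
    records: pd.DataFrame
    scenario: str = "closed"
    ach: float = 1.0

    def __post_init__(self) -> None:
        required = {"x_m", "y_m", "z_m", "concentration_bq_m3"}
        missing = required - set(self.records.columns)
        if missing:
            raise ComparisonError(f"records missing column(s) {sorted(missing)}")
        if len(self.records) == 0:
            raise ComparisonError("measurement set is empty")
        if (self.records["concentration_bq_m3"] < 0).any():
            raise ComparisonError("concentrations must be non-negative")

    @property
    def points(self) -> np.ndarray:
        return self.records[["x_m", "y_m", "z_m"]].to_numpy(dtype=float)

    @property
    def values(self) -> np.ndarray:
        return self.records["concentration_bq_m3"].to_numpy(dtype=float)


@dataclass(frozen=True)
class ComparisonReport:
    """A reproducible comparison table plus summary statistics."""

    kind: str
    table: pd.DataFrame
    summary: dict = dc_field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def to_text(self) -> str:
        lines = [f"[{self.kind}]", self.table.to_string(index=False)]
        for k, v in self.summary.items():
            lines.append(f"{k}: {v:.4g}" if isinstance(v, float) else f"{k}: {v}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# fixtures


def _load_fixture(name: str) -> pd.DataFrame:
    with resources.files("radonroom.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_ventilation_sweep_table() -> pd.DataFrame:
    """Published ventilation-sweep comparison (six ACH values)."""
    return _load_fixture("table2_ventilation_sweep.csv")


def load_detector_tables(scenario: str | None = None,
                         device: str | None = None) -> pd.DataFrame:
    """Published detector intercomparison records (both scenarios)."""
    df = _load_fixture("detector_tables.csv")
    if scenario is not None:
        df = df[df["scenario"] == scenario]
    if device is not None:
        df = df[df["device"] == device]
    return df.reset_index(drop=True)


def load_detector_printed_averages() -> pd.DataFrame:
    """Row averages as printed in the published tables (may differ from the
    arithmetic mean of the printed cells by rounding)."""
    return _load_fixture("detector_table_averages.csv")


def measurement_set_from_table(scenario: str, device: str,
                               z_m: float | None = None) -> MeasurementSet:
    """One device's fixture records as a :class:`MeasurementSet`."""
    df = load_detector_tables(scenario=scenario, device=device)
    if z_m is not None:
        df = df[np.isclose(df["z_m"], z_m)].reset_index(drop=True)
    if len(df) == 0:
        raise ComparisonError(
            f"no fixture records for device={device!r}, scenario={scenario!r}")
    return MeasurementSet(device=device, records=df, scenario=scenario,
                          ach=float(df["ach_per_h"].iloc[0]))


# ---------------------------------------------------------------------------
# report builders


def build_table2(ach_list, numerical: dict[str, list] | pd.DataFrame,
                 params: WellMixedParams) -> ComparisonReport:
    """Ventilation-sweep comparison: analytical column vs numerical averages.

    ``numerical`` maps scenario name -> volume-averaged concentrations
    aligned with ``ach_list`` (a DataFrame with scenario columns works
    too).  ``params`` supplies the calibrated generation rate and outdoor
    concentration; its ``ach`` field is overridden per row.
    """
    ach = [float(a) for a in ach_list]
    if isinstance(numerical, pd.DataFrame):
        numerical = {c: numerical[c].tolist() for c in numerical.columns}
    for scen, vals in numerical.items():
        if len(vals) != len(ach):
            raise ComparisonError(
                f"numerical column {scen!r} has {len(vals)} entries for "
                f"{len(ach)} ACH values")
    rows = []
    for i, a in enumerate(ach):
        p = WellMixedParams(generation=params.generation, ach=a,
                            outdoor=params.outdoor, lambda_rn=params.lambda_rn,
                            include_outdoor_inflow=params.include_outdoor_inflow)
        analytical = wellmixed_steady(p)
        row = {"ach_per_h": a, "analytical_bq_m3": analytical}
        for scen, vals in numerical.items():
            row[f"numerical_{scen}_bq_m3"] = float(vals[i])
            row[f"diff_{scen}_pct"] = percentage_difference(analytical,
                                                            float(vals[i]))
        rows.append(row)
    table = pd.DataFrame(rows)
    diff_cols = [c for c in table.columns if c.startswith("diff_")]
    summary = {f"max_abs_{c}": float(table[c].abs().max()) for c in diff_cols}
    return ComparisonReport(kind="ventilation_sweep", table=table,
                            summary=summary)


def build_detector_comparison(field, grid,
                              measurements: MeasurementSet) -> ComparisonReport:
    """Sample a concentration field at the measurement points and report
    per-point and per-height relative deviations."""
    from .transport import sample_at  # local import to avoid a cycle

    if len(measurements.records) == 0:
        raise ComparisonError("measurement set is empty")
    predicted = sample_at(field, grid, measurements.points)
    table = measurements.records.copy().reset_index(drop=True)
    table["predicted_bq_m3"] = predicted
    table["relative_deviation_pct"] = relative_deviation(
        measurements.values, predicted)
    by_height = (table.groupby("z_m")
                 .agg(observed_mean=("concentration_bq_m3", "mean"),
                      predicted_mean=("predicted_bq_m3", "mean"))
                 .reset_index())
    by_height["relative_deviation_pct"] = relative_deviation(
        by_height["observed_mean"].to_numpy(),
        by_height["predicted_mean"].to_numpy())
    summary = {
        "device": measurements.device,
        "scenario": measurements.scenario,
        "mean_relative_deviation_pct": float(
            table["relative_deviation_pct"].mean()),
        "max_relative_deviation_pct": float(
            table["relative_deviation_pct"].max()),
        "by_height": by_height,
    }
    return ComparisonReport(kind="detector_comparison", table=table,
                            summary=summary)


def calibrated_params_from_sweep_table(
        table: pd.DataFrame | None = None,
        calibration_ach: float = 0.3,
        outdoor: float = 10.0) -> WellMixedParams:
    """Well-mixed parameters with G calibrated from one row of the
    published ventilation sweep (default: the ACH = 0.3 analytical value)."""
    from .boxmodel import calibrate_generation

    if table is None:
        table = load_ventilation_sweep_table()
    row = table[np.isclose(table["ach_per_h"], calibration_ach)]
    if len(row) != 1:
        raise ComparisonError(
            f"calibration ACH {calibration_ach} not found in sweep table")
    c_ss = float(row["analytical_bq_m3"].iloc[0])
    g = calibrate_generation(c_ss, calibration_ach, outdoor=outdoor)
    return WellMixedParams(generation=g, ach=calibration_ach, outdoor=outdoor)
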