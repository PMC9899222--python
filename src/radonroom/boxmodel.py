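"""Well-mixed (single-zone) radon balance and inhalation dose.

The lumped model treats the room as one perfectly mixed volume:

    dC/dt = G + lambda_V * C_out - (lambda_V + lambda_Rn) * C,

with generation rate G (Bq m^-3 h^-1), ventilation rate lambda_V (the ACH,
h^-1), radon decay constant lambda_Rn and outdoor concentration C_out.  Its
steady state C_ss = (G + lambda_V C_out) / (lambda_V + lambda_Rn) and the
exponential approach from any initial value C_0 are exact closed forms.
The classical textbook form without the outdoor-inflow term
(C_ss = G / (lambda_V + lambda_Rn)) is retained behind a flag.

The annual effective dose from inhaled radon progeny is

    AED [mSv yr^-1] = C_Rn * F * t * K * 1e-6,

with equilibrium factor F (0.4 indoors per UNSCEAR), annual occupancy t
(h yr^-1) and the ICRP-115 dose coefficient K = 12 nSv per Bq h m^-3.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

#: radon-222 decay constant, s^-1 and h^-1
LAMBDA_RN_PER_S = 2.1e-6
LAMBDA_RN_PER_H = LAMBDA_RN_PER_S * 3600.0  # 7.56e-3


class BoxModelError(ValueError):
    """Raised for infeasible well-mixed-model parameterisations."""


@dataclass(frozen=True)
class WellMixedParams:
    """Parameters of the single-zone balance.

    ``generation`` is the volumetric source G in Bq m^-3 h^-1; use
    :func:`generation_from_exhalation` to derive it from per-surface
    exhalation rates, or :func:`calibrate_generation` to back it out of an
    observed steady concentration.
    """

    generation: float                 # Bq m^-3 h^-1
    ach: float                        # ventilation rate lambda_V, h^-1
    outdoor: float = 10.0             # C_out, Bq m^-3
    initial: float = 0.0              # C_0, Bq m^-3
    lambda_rn: float = LAMBDA_RN_PER_H  # h^-1
    include_outdoor_inflow: bool = True

    def __post_init__(self) -> None:
        if self.generation < 0 or self.outdoor < 0 or self.initial < 0:
            raise BoxModelError("concentrations and generation must be >= 0")
        if self.ach < 0 or self.lambda_rn < 0:
            raise BoxModelError("rates must be non-negative")
        if self.lambda_total <= 0:
            raise BoxModelError("total removal rate lambda_V + lambda_Rn "
                                "must be positive")

    @property
    def lambda_total(self) -> float:
        return self.ach + self.lambda_rn


@dataclass(frozen=True)
class DoseParams:
    """Annual-effective-dose coefficients."""

    equilibrium_factor: float = 0.4   # F, dimensionless
    occupancy_h: float = 2000.0       # t, h yr^-1
    coefficient_nsv: float = 12.0     # K, nSv per Bq h m^-3

    def __post_init__(self) -> None:
        if not (0 < self.equilibrium_factor <= 1):
            raise BoxModelError("equilibrium factor must lie in (0, 1]")
        if not (0 <= self.occupancy_h <= 8760):
            raise BoxModelError("occupancy must lie in [0, 8760] h/yr")
        if self.coefficient_nsv <= 0:
            raise BoxModelError("dose coefficient must be positive")


def wellmixed_steady(p: WellMixedParams) -> float:
    """Steady-state concentration of the well-mixed balance, Bq m^-3."""
    if p.include_outdoor_inflow:
        return (p.generation + p.ach * p.outdoor) / p.lambda_total
    return p.generation / p.lambda_total


def wellmixed_timeseries(p: WellMixedParams, times_h) -> np.ndarray:
    """Exact transient C(t) = C_ss + (C_0 - C_ss) exp(-lambda_total t)."""
    t = np.asarray(times_h, dtype=float)
    if np.any(t < 0):
        raise BoxModelError("times must be non-negative")
    c_ss = wellmixed_steady(p)
    return c_ss + (p.initial - c_ss) * np.exp(-p.lambda_total * t)


def calibrate_generation(c_ss_observed: float, ach: float,
                         outdoor: float = 10.0,
                         lambda_rn: float = LAMBDA_RN_PER_H) -> float:
    """Invert the steady balance for the effective generation rate G.

    G = C_ss (lambda_V + lambda_Rn) - lambda_V C_out.  The observation must
    be at least the outdoor-supported floor lambda_V C_out / lambda_total,
    otherwise no non-negative source can explain it.
    """
    lam = ach + lambda_rn
    if lam <= 0:
        raise BoxModelError("total removal rate must be positive")
    floor = ach * outdoor / lam
    g = c_ss_observed * lam - ach * outdoor
    if g < -1e-9 * max(1.0, abs(c_ss_observed) * lam):
        raise BoxModelError(
            f"observed steady concentration {c_ss_observed} Bq/m3 is below "
            f"the outdoor-supported floor {floor:.3f} Bq/m3; no non-negative "
            "generation rate can produce it")
    return max(g, 0.0)


def generation_from_exhalation(exhalation_by_surface: dict[str, float],
                               area_by_surface: dict[str, float],
                               volume: float) -> float:
    """Volumetric generation G = sum_i E_i A_i / V, in Bq m^-3 h^-1.

    ``exhalation_by_surface`` holds E_i in Bq m^-2 h^-1 keyed like
    ``area_by_surface`` (any consistent surface naming).
    """
    if volume <= 0:
        raise BoxModelError("volume must be positive")
    missing = set(exhalation_by_surface) - set(area_by_surface)
    if missing:
        raise BoxModelError(f"no area given for surface(s) {sorted(missing)}")
    total = sum(exhalation_by_surface[s] * area_by_surface[s]
                for s in exhalation_by_surface)
    return total / volume


def annual_effective_dose(concentration: float,
                          d: DoseParams = DoseParams()) -> float:
    """Annual effective dose in mSv yr^-1 from a mean concentration."""
    if concentration < 0:
        raise BoxModelError("concentration must be non-negative")
    nsv = concentration * d.equilibrium_factor * d.occupancy_h * d.coefficient_nsv
    return nsv * 1e-6  # nSv -> mSv


def steady_concentration_table(g: float, ach_values,
                               outdoor: float = 10.0,
                               lambda_rn: float = LAMBDA_RN_PER_H,
                               dose: DoseParams | None = None):
    """Steady concentrations (and optionally doses) over an ACH list.

    Returns a list of dicts suitable for a DataFrame / CSV mirroring the
    analytical column of the ventilation-sweep comparison table.
    """
    rows = []
    for ach in ach_values:
        p = WellMixedParams(generation=g, ach=float(ach), outdoor=outdoor,
                            lambda_rn=lambda_rn)
        c = wellmixed_steady(p)
        row = {"ach_per_h": float(ach), "steady_bq_m3": c}
        if dose is not None:
            row["aed_msv_per_yr"] = annual_effective_dose(c, dose)
        rows.append(row)
    return rows


def with_generation(p: WellMixedParams, g: float) -> WellMixedParams:
    return replace(p, generation=g)
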