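"""Ventilation kinematics and humid-air properties.

The air-change rate (ACH, h^-1) sets the mean inlet speed through the
window opening,

    U_in = ACH * V_room / (A_vent * 3600)   [m s^-1],

the natural-ventilation balance used throughout.  Humid-air density comes
from an ideal-gas mixture of dry air and water vapour with a Magnus-type
saturation-pressure correlation; dynamic viscosity uses Sutherland's law
for dry air (the RH effect on viscosity is below 1% and is neglected).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

R_DRY = 287.058    # J kg^-1 K^-1, specific gas constant of dry air
R_VAPOUR = 461.495  # J kg^-1 K^-1, water vapour
STANDARD_PRESSURE = 101325.0  # Pa


class AirDomainError(ValueError):
    """Raised for physically out-of-range air/ventilation inputs."""


@dataclass(frozen=True)
class AirProperties:
    """Thermodynamic state of the room air."""

    temperature_c: float
    relative_humidity: float
    pressure_pa: float
    density: float            # kg m^-3
    dynamic_viscosity: float  # Pa s

    @property
    def kinematic_viscosity(self) -> float:
        return self.dynamic_viscosity / self.density


@dataclass(frozen=True)
class VentilationSpec:
    """Air-change rate and the inlet speed it implies."""

    ach: float          # h^-1
    room_volume: float  # m^3
    vent_area: float    # m^2

    def __post_init__(self) -> None:
        if self.ach < 0:
            raise AirDomainError("ACH must be non-negative")
        if self.vent_area <= 0:
            raise AirDomainError("ventilation area must be positive")
        if self.room_volume <= 0:
            raise AirDomainError("room volume must be positive")

    @property
    def inlet_speed(self) -> float:
        """Mean inlet speed U_in (m s^-1)."""
        return inlet_velocity(self.ach, self.room_volume, self.vent_area)

    @property
    def volumetric_flow(self) -> float:
        """Ventilation flow rate Q (m^3 s^-1)."""
        return self.ach * self.room_volume / 3600.0


def inlet_velocity(ach: float, room_volume: float, vent_area: float) -> float:
    """Inlet speed (m s^-1) from the air-change rate.

    U = ACH * V_room / A_vent evaluates in m h^-1 and is returned in SI.
    The default room (V = 33.6 m^3, window 0.96 m^2) at 1 ACH gives
    0.0097 m s^-1.
    """
    if vent_area <= 0:
        raise AirDomainError("vent_area must be positive")
    if room_volume <= 0:
        raise AirDomainError("room_volume must be positive")
    if ach < 0:
        raise AirDomainError("ach must be non-negative")
    return ach * room_volume / (vent_area * 3600.0)


def saturation_vapour_pressure(temperature_c: float) -> float:
    """Magnus-type (Alduchov–Eskridge) saturation pressure over water, Pa."""
    t = float(temperature_c)
    return 610.94 * float(np.exp(17.625 * t / (t + 243.04)))


def dry_air_viscosity(temperature_c: float) -> float:
    """Sutherland's law for dry air, Pa s."""
    t = float(temperature_c) + 273.15
    t0, mu0, s = 273.15, 1.716e-5, 110.4
    return mu0 * (t / t0) ** 1.5 * (t0 + s) / (t + s)


def air_properties(temperature_c: float = 24.0,
                   relative_humidity: float = 0.5,
                   pressure_pa: float = STANDARD_PRESSURE) -> AirProperties:
    """Humid-air density and viscosity at the given state.

    Density is the ideal-gas mixture of dry air (partial pressure P - e)
    and vapour (partial pressure e = RH * e_sat(T)); it decreases
    monotonically with RH at fixed T, P because vapour is lighter than dry
    air.
    """
    if not (0.0 <= relative_humidity <= 1.0):
        raise AirDomainError(
            f"relative humidity must lie in [0, 1], got {relative_humidity}")
    if not (-20.0 <= temperature_c <= 60.0):
        raise AirDomainError(
            f"temperature {temperature_c} degC outside the supported "
            "-20..60 degC range")
    if pressure_pa <= 0:
        raise AirDomainError("pressure must be positive")
    t_k = temperature_c + 273.15
    e = relative_humidity * saturation_vapour_pressure(temperature_c)
    rho = (pressure_pa - e) / (R_DRY * t_k) + e / (R_VAPOUR * t_k)
    return AirProperties(
        temperature_c=temperature_c,
        relative_humidity=relative_humidity,
        pressure_pa=pressure_pa,
        density=rho,
        dynamic_viscosity=dry_air_viscosity(temperature_c),
    )


def reynolds_number(speed: float, length_scale: float,
                    air: AirProperties) -> float:
    """Re = rho * U * L / mu for a given speed and length scale."""
    if speed < 0 or length_scale < 0:
        raise AirDomainError("speed and length scale must be non-negative")
    return air.density * speed * length_scale / air.dynamic_viscosity


def hydraulic_diameter(width: float, height: float) -> float:
    """Hydraulic diameter 4A/P of a rectangular opening."""
    return 4.0 * width * height / (2.0 * (width + height))
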