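"""Coolant heat balance and condensation safety for incubator operation.

The winding dissipates I^2 R; in the worst case all of it is carried away by
the cooling water, whose steady-state temperature rise is P / (mdot c_p).
Because the water-cooled enclosure sits inside a warm humid incubator, its
surfaces must stay above the dew point of the incubator air or moisture
condenses on the enclosure and the dish.  The dew point uses the Magnus
relation with the Sonntag 1990 constants (a = 17.62, b = 243.12 degC),
accurate to ~0.1 degC over 0-60 degC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "CoolantSpec",
    "IncubatorAir",
    "ThermalReport",
    "dissipated_power",
    "coolant_temperature_rise",
    "dew_point",
    "condensation_safe",
    "thermal_report",
]

_MAGNUS_A = 17.62
_MAGNUS_B = 243.12  # degC


@dataclass(frozen=True)
class CoolantSpec:
    """Cooling water: flow (L/min), inlet temperature (degC) and physical
    properties (defaults: water near room temperature)."""

    flow_rate: float
    inlet_temp: float = 37.0
    specific_heat: float = 4181.3  # J/(kg K)
    density: float = 997.0  # kg/m^3

    def __post_init__(self) -> None:
        if self.flow_rate <= 0:
            raise ValueError(f"flow_rate must be > 0 L/min, got {self.flow_rate}")
        if not 1000.0 <= self.specific_heat <= 10000.0:
            raise ValueError(f"specific_heat {self.specific_heat} J/(kg K) not physical")
        if not 500.0 <= self.density <= 2000.0:
            raise ValueError(f"density {self.density} kg/m^3 not physical")

    @property
    def mass_flow(self) -> float:
        """Mass flow, kg/s (L/min -> kg/s)."""
        return self.flow_rate * self.density / 60000.0


@dataclass(frozen=True)
class IncubatorAir:
    """Incubator air state: temperature (degC), relative humidity (%, (0,100])."""

    temperature: float
    relative_humidity: float

    def __post_init__(self) -> None:
        if not 0.0 < self.relative_humidity <= 100.0:
            raise ValueError(
                f"relative_humidity must be in (0, 100], got {self.relative_humidity}"
            )


@dataclass(frozen=True)
class ThermalReport:
    """Steady-state thermal/condensation summary."""

    power: float  # W
    coolant_dT: float  # K
    dew_point: float  # degC
    coolant_surface_temp: float  # degC
    condensation_safe: bool

    def to_dict(self) -> dict:
        return {
            "power_w": self.power,
            "coolant_dT_K": self.coolant_dT,
            "dew_point_c": self.dew_point,
            "coolant_surface_temp_c": self.coolant_surface_temp,
            "condensation_safe": self.condensation_safe,
        }


def dissipated_power(i: float, R: float) -> float:
    """Ohmic power i^2 R, W."""
    if R <= 0:
        raise ValueError(f"R must be > 0, got {R}")
    return i * i * R


def coolant_temperature_rise(power: float, coolant: CoolantSpec) -> float:
    """Steady-state coolant temperature rise, K: P / (mdot c_p), assuming in
    the worst case that all dissipated power enters the water."""
    if power < 0:
        raise ValueError(f"power must be >= 0, got {power}")
    return power / (coolant.mass_flow * coolant.specific_heat)


def dew_point(air: IncubatorAir) -> float:
    """Dew-point temperature, degC, via the Magnus relation:
    Td = b g / (a - g), g = ln(RH/100) + a T / (b + T)."""
    g = math.log(air.relative_humidity / 100.0) + _MAGNUS_A * air.temperature / (
        _MAGNUS_B + air.temperature
    )
    return _MAGNUS_B * g / (_MAGNUS_A - g)


def condensation_safe(
    coolant_surface_temp: float, air: IncubatorAir, margin: float = 0.0
) -> bool:
    """True iff the coldest wetted surface stays above the air dew point by
    at least ``margin`` (degC)."""
    return coolant_surface_temp > dew_point(air) + margin


def thermal_report(
    current: float,
    R: float,
    coolant: CoolantSpec,
    air: IncubatorAir,
    margin: float = 0.0,
) -> ThermalReport:
    """Assemble the steady-state report.  The coldest enclosure surface is
    taken at the coolant inlet temperature (the water only warms from
    there), which is the conservative choice for the condensation verdict.
    Pure function: identical inputs give an identical report."""
    P = dissipated_power(current, R)
    dT = coolant_temperature_rise(P, coolant)
    Td = dew_point(air)
    return ThermalReport(
        power=P,
        coolant_dT=dT,
        dew_point=Td,
        coolant_surface_temp=coolant.inlet_temp,
        condensation_safe=condensation_safe(coolant.inlet_temp, air, margin),
    )
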