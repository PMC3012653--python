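"""Boundary unit conversions between lab-friendly units and SI.

The internal unit system is strictly SI (m, s, K, kg, Pa.s); everything a
user types in nm, mm, Celsius, g/cm3, mPa.s, ug/mL or cm2 is converted once
at the boundary.  Only the pairs that actually occur at that boundary are
supported -- this is deliberately a closed table, not a general unit system.
"""

from __future__ import annotations


class UnitError(ValueError):
    """Raised for an unknown unit or a conversion between incompatible units."""


# unit -> (dimension, scale, offset); SI value = value * scale + offset
_UNITS: dict[str, tuple[str, float, float]] = {
    # length
    "m": ("length", 1.0, 0.0),
    "cm": ("length", 1e-2, 0.0),
    "mm": ("length", 1e-3, 0.0),
    "um": ("length", 1e-6, 0.0),
    "nm": ("length", 1e-9, 0.0),
    # temperature
    "K": ("temperature", 1.0, 0.0),
    "degC": ("temperature", 1.0, 273.15),
    # mass density / mass concentration
    "kg/m^3": ("density", 1.0, 0.0),
    "g/cm^3": ("density", 1e3, 0.0),
    "g/mL": ("density", 1e3, 0.0),
    "mg/mL": ("density", 1.0, 0.0),
    "ug/mL": ("density", 1e-3, 0.0),
    # dynamic viscosity
    "Pa.s": ("viscosity", 1.0, 0.0),
    "mPa.s": ("viscosity", 1e-3, 0.0),
    # area
    "m^2": ("area", 1.0, 0.0),
    "cm^2": ("area", 1e-4, 0.0),
    # volume
    "m^3": ("volume", 1.0, 0.0),
    "mL": ("volume", 1e-6, 0.0),
    "uL": ("volume", 1e-9, 0.0),
    # number concentration
    "1/m^3": ("number_concentration", 1.0, 0.0),
    "1/mL": ("number_concentration", 1e6, 0.0),
    # time
    "s": ("time", 1.0, 0.0),
    "min": ("time", 60.0, 0.0),
    "h": ("time", 3600.0, 0.0),
}

_ALIASES = {
    "°C": "degC",
    "C": "degC",
    "celsius": "degC",
    "µg/mL": "ug/mL",
    "μg/mL": "ug/mL",
    "ug_per_mL": "ug/mL",
    "particles/mL": "1/mL",
    "particles_per_mL": "1/mL",
    "µm": "um",
    "g/cc": "g/cm^3",
    "mPas": "mPa.s",
    "cP": "mPa.s",
    "hr": "h",
}


def _lookup(unit: str) -> tuple[str, float, float]:
    key = _ALIASES.get(unit, unit)
    try:
        return _UNITS[key]
    except KeyError:
        raise UnitError(f"unknown unit {unit!r}") from None


def convert_units(value: float, from_unit: str, to_unit: str) -> float:
    """Convert ``value`` from one supported unit to another.

    Conversions are exact linear (plus Celsius offset) maps through SI and
    round-trip bit-identically for scale-only pairs.

    Raises
    ------
    UnitError
        If either unit is unknown or the two units measure different things.
    """
    dim_from, scale_from, off_from = _lookup(from_unit)
    dim_to, scale_to, off_to = _lookup(to_unit)
    if dim_from != dim_to:
        raise UnitError(
            f"cannot convert {from_unit!r} ({dim_from}) to {to_unit!r} ({dim_to})"
        )
    if (scale_from, off_from) == (scale_to, off_to):
        return value
    si = value * scale_from + off_from
    return (si - off_to) / scale_to


def celsius_to_kelvin(t_c: float) -> float:
    return convert_units(t_c, "degC", "K")
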