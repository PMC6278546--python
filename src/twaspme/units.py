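"""Unit-tagged quantity parsing for run configuration files.

All internal computation is SI (m, s, mol·m⁻³).  Config files may tag
values with common laboratory units ("10 mm", "0.641 umol/m3",
"8.8 mm2/s"); bare numbers are taken to be SI already.
"""

from __future__ import annotations

import re

__all__ = ["UnitError", "parse_quantity"]


class UnitError(ValueError):
    """Raised for an unknown unit tag or a malformed quantity string."""


# conversion factor to SI, per dimension
_FACTORS: dict[str, dict[str, float]] = {
    "length": {"m": 1.0, "cm": 1e-2, "mm": 1e-3, "um": 1e-6, "µm": 1e-6},
    "time": {"s": 1.0, "min": 60.0, "h": 3600.0},
    "diffusivity": {"m2/s": 1.0, "mm2/s": 1e-6, "cm2/s": 1e-4},
    "concentration": {
        "mol/m3": 1.0,
        "mmol/m3": 1e-3,
        "umol/m3": 1e-6,
        "µmol/m3": 1e-6,
        "nmol/m3": 1e-9,
    },
    "speed": {"m/s": 1.0},
}

# mass-per-volume concentration tags need a molar mass to become molar
_MASS_CONC = {"g/m3": 1.0, "mg/m3": 1e-3, "ug/m3": 1e-6, "µg/m3": 1e-6}

_QUANTITY_RE = re.compile(r"^\s*([-+0-9.eE]+)\s*([^\s]+)?\s*$")


def parse_quantity(
    value: float | int | str,
    dimension: str,
    *,
    molar_mass: float | None = None,
) -> float:
    """Convert a config value to SI.

    Parameters
    ----------
    value
        A bare number (assumed SI) or a string like ``"10 mm"``.
    dimension
        One of ``length``, ``time``, ``diffusivity``, ``concentration``,
        ``speed``.
    molar_mass
        g·mol⁻¹; required only to convert mass-per-volume concentrations
        (µg·m⁻³) to molar ones.
    """
    if isinstance(value, (int, float)):
        return float(value)
    if not isinstance(value, str):
        raise UnitError(f"cannot parse quantity from {value!r}")
    m = _QUANTITY_RE.match(value)
    if m is None:
        raise UnitError(f"malformed quantity {value!r}")
    number, unit = m.groups()
    try:
        x = float(number)
    except ValueError as exc:
        raise UnitError(f"malformed number in {value!r}") from exc
    if unit is None:
        return x
    if dimension not in _FACTORS:
        raise UnitError(f"unknown dimension {dimension!r}")
    table = _FACTORS[dimension]
    if unit in table:
        return x * table[unit]
    if dimension == "concentration" and unit in _MASS_CONC:
        if molar_mass is None:
            raise UnitError(
                f"{value!r}: mass concentration needs the analyte molar mass"
            )
        # (g·m⁻³) / (g·mol⁻¹) = mol·m⁻³
        return x * _MASS_CONC[unit] / molar_mass
    raise UnitError(f"unknown {dimension} unit {unit!r} in {value!r}")
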