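"""Gas–liquid equilibrium for dissolved CO2 and O2.

Henry's law with a van 't Hoff temperature correction links headspace partial
pressures to dissolved concentrations::

    H(T) = H_298.15 * exp[B * (1/T - 1/298.15)]        [mol/(kg bar)]
    C    = H(T) * P                                     [mol/kg]

where ``B = -Delta_sol H / R`` (K).  Dissolved amounts are computed on the
molal (mol/kg) scale and converted to molar (µM) via the density of pure
water, itself a frozen quadratic fit to a standard 0–50 °C density table.
Salinity/ionic-strength corrections to H and fugacity corrections are
deliberately out of scope: the target systems are dilute acidic freshwater
cultures and the corrections are smaller than the other uncertainties.

Dissolved-O2 values used in compensation-point work default to the canonical
published values for the four (O2 %, temperature) study conditions rather
than being recomputed ("canonical" mode); ``mode="physics"`` recomputes them from
Henry's law (the two differ by up to ~8%; see docs/methods.md).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

__all__ = [
    "GasSolubility",
    "EnvConditions",
    "CO2",
    "O2",
    "STANDARD_PRESSURE_PA",
    "T_REF_K",
    "henry_constant",
    "water_density",
    "dissolved_concentration",
    "partial_pressure",
    "dissolved_o2",
]

STANDARD_PRESSURE_PA = 101_325.0
T_REF_K = 298.15
_T_MIN_K, _T_MAX_K = 273.15, 333.15

PA_PER_BAR = 1e5
UBAR_PER_BAR = 1e6


def _load_json(name: str) -> dict:
    with resources.files("ccmgasex.data").joinpath(name).open() as fh:
        return json.load(fh)


@dataclass(frozen=True)
class GasSolubility:
    """Henry's-law description of one gas.

    Parameters
    ----------
    gas_name : str
        ``"CO2"`` or ``"O2"`` for the packaged gases.
    H298 : float
        Henry constant at 298.15 K, mol/(kg·bar).
    B : float
        van 't Hoff temperature-dependence constant, −Δ_sol H / R, in K.
    """

    gas_name: str
    H298: float
    B: float

    def __post_init__(self) -> None:
        if self.H298 <= 0:
            raise ValueError(f"H298 must be positive, got {self.H298}")


def _packaged_gases() -> dict[str, GasSolubility]:
    raw = _load_json("gas_solubility.json")
    return {name: GasSolubility(name, v["H298"], v["B"]) for name, v in raw.items()}


_GASES = _packaged_gases()
CO2: GasSolubility = _GASES["CO2"]
O2: GasSolubility = _GASES["O2"]


def as_kelvin(temperature: float, unit: str = "K") -> float:
    """Normalize a temperature given in ``unit`` ("K" or "C") to kelvin."""
    if unit == "K":
        return float(temperature)
    if unit == "C":
        return float(temperature) + 273.15
    raise ValueError(f"unit must be 'K' or 'C', got {unit!r}")


@dataclass(frozen=True)
class EnvConditions:
    """Chamber headspace conditions.

    ``temperature`` is stored in kelvin; pass ``unit="C"`` to supply Celsius.
    """

    temperature: float
    total_pressure: float = STANDARD_PRESSURE_PA
    o2_fraction: float = 0.21
    co2_ppm: float = 400.0
    unit: str = field(default="K", repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "temperature", as_kelvin(self.temperature, self.unit))
        object.__setattr__(self, "unit", "K")
        _check_temperature(self.temperature)
        if not 0.0 <= self.o2_fraction <= 1.0:
            raise ValueError(f"o2_fraction must be in [0, 1], got {self.o2_fraction}")
        if self.co2_ppm < 0:
            raise ValueError(f"co2_ppm must be >= 0, got {self.co2_ppm}")

    @property
    def temperature_c(self) -> float:
        return self.temperature - 273.15


def _check_temperature(t_k: float) -> None:
    if t_k < _T_MIN_K:
        raise ValueError(f"temperature {t_k} K below supported minimum {_T_MIN_K} K")
    if t_k > _T_MAX_K:
        raise ValueError(f"temperature {t_k} K above supported maximum {_T_MAX_K} K")


def henry_constant(gas: GasSolubility, temperature: float, unit: str = "K") -> float:
    """Temperature-adjusted Henry constant, mol/(kg·bar).

    Equals ``gas.H298`` exactly at 298.15 K and decreases with temperature
    (gases are less soluble in warm water).
    """
    t_k = as_kelvin(temperature, unit)
    _check_temperature(t_k)
    return gas.H298 * np.exp(gas.B * (1.0 / t_k - 1.0 / T_REF_K))


_density_cfg = _load_json("water_density.json")
_DENSITY_COEFFS = np.asarray(_density_cfg["quadratic_coefficients"], dtype=float)
_DENSITY_RANGE_C = tuple(_density_cfg["valid_range_c"])


def water_density(temperature_c: float) -> float:
    """Pure-water density in kg/L from the frozen quadratic, valid 0–50 °C."""
    t = np.asarray(temperature_c, dtype=float)
    if np.any(t < _DENSITY_RANGE_C[0]) or np.any(t > _DENSITY_RANGE_C[1]):
        raise ValueError(
            f"temperature {temperature_c} degC outside density fit range {_DENSITY_RANGE_C}"
        )
    out = np.polyval(_DENSITY_COEFFS, t)
    return float(out) if out.ndim == 0 else out


def dissolved_concentration(
    gas: GasSolubility, mole_fraction, env: EnvConditions
) -> float:
    """Equilibrium dissolved concentration in µM for a headspace mole fraction.

    ``C = H(T) * P`` on the mol/kg scale, then mol/kg → mol/L via water
    density.  ``mole_fraction`` may be an array.
    """
    x = np.asarray(mole_fraction, dtype=float)
    if np.any(x < 0) or np.any(x > 1):
        raise ValueError("mole_fraction must lie in [0, 1]")
    p_bar = x * env.total_pressure / PA_PER_BAR
    molal = henry_constant(gas, env.temperature) * p_bar  # mol/kg
    molar = molal * water_density(env.temperature_c)  # mol/L
    out = molar * 1e6  # µM
    return float(out) if out.ndim == 0 else out


def partial_pressure(
    gas: GasSolubility, concentration_uM, temperature: float, unit: str = "K"
) -> float:
    """Equilibrium partial pressure (µbar) over a dissolved concentration (µM).

    Exact inverse of :func:`dissolved_concentration`; round-trips to relative
    1e-12.
    """
    c = np.asarray(concentration_uM, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be >= 0")
    t_k = as_kelvin(temperature, unit)
    molal = c * 1e-6 / water_density(t_k - 273.15)  # mol/kg
    p_bar = molal / henry_constant(gas, t_k)
    out = p_bar * UBAR_PER_BAR
    return float(out) if out.ndim == 0 else out


_DISSOLVED_O2_TABLE = {
    (cond["o2_percent"], cond["temperature_c"]): cond["o_uM"]
    for cond in _load_json("thermophile_kinetics.json")["dissolved_o2_uM"]
}


def dissolved_o2(o2_percent: float, temperature_c: float, mode: str = "canonical") -> float:
    """Dissolved O2 (µM) for a headspace O2 percentage at a given temperature.

    mode="canonical" returns the canonical published values for the four study
    conditions (2/21/40% at 40 °C, 21% at 30 °C) and raises for any other
    condition; mode="physics" recomputes any condition from Henry's law.
    """
    if mode == "physics":
        env = EnvConditions(temperature_c, unit="C", o2_fraction=o2_percent / 100.0)
        return dissolved_concentration(O2, o2_percent / 100.0, env)
    if mode != "canonical":
        raise ValueError(f"mode must be 'canonical' or 'physics', got {mode!r}")
    key = (round(o2_percent), round(temperature_c))
    try:
        return _DISSOLVED_O2_TABLE[key]
    except KeyError:
        raise KeyError(
            f"no canonical dissolved-O2 value for {o2_percent}% O2 at "
            f"{temperature_c} degC; use mode='physics' to compute one"
        ) from None
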