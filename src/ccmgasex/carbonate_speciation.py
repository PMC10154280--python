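"""Freshwater dissolved-inorganic-carbon speciation across pH.

For water in equilibrium with a fixed headspace pCO2, the dissolved CO2
concentration is pH independent (Henry's law) while the ionic pools follow
the dissociation equilibria::

    CO2(aq) = K0 * pCO2
    HCO3-   = CO2(aq) * K1 / [H+]
    CO3--   = HCO3-   * K2 / [H+]

Activity coefficients are taken as 1 (pure-water assumption), pH is the
free-scale hydrogen-ion exponent, and all constants live on the mol/kg
scale with a water-density conversion to µM at output.

Two dissociation-constant sets are packaged:

``"lueker00"`` (default)
    Lueker et al. (2000) evaluated at salinity 0.  These are marine-
    calibrated constants, and zero salinity is an extrapolation — but it is
    what general-purpose carbonate-chemistry packages produce when driven
    with S = 0, and it is the set under which bicarbonate comprises about
    half of the Ci pool at pH 6 and 40 °C, the behaviour this package's
    pH-comparison analyses are built around (pK1(40 °C) ≈ 6.00).
``"plummer82"``
    Plummer & Busenberg (1982), the standard true-freshwater formulation
    (pK1(25 °C) ≈ 6.35); recommended when freshwater accuracy matters more
    than consistency with marine-package output.  Under it bicarbonate is
    nearer one third of the pool at pH 6 and 40 °C.

The "accessible Ci" construct formalizes the pH 2 vs pH 6 uptake
experiment: a cell that can take up only CO2 sees the same substrate pool
at both pH values, while a bicarbonate-capable cell roughly doubles its
pool at pH 6.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import henry_phase
from .henry_phase import CO2

__all__ = [
    "CarbonateConstants",
    "DICState",
    "UptakeModel",
    "FORMULATIONS",
    "DEFAULT_FORMULATION",
    "carbonate_constants",
    "speciate_from_pco2",
    "bicarbonate_fraction",
    "accessible_ci",
]

_T_MIN_K, _T_MAX_K = 273.15, 333.15
DEFAULT_FORMULATION = "lueker00"


def _pk_lueker00(t_k: float) -> tuple[float, float]:
    # Lueker et al. 2000 at S = 0, total scale == free scale at S = 0
    pk1 = 3633.86 / t_k - 61.2172 + 9.6777 * np.log(t_k)
    pk2 = 471.78 / t_k + 25.929 - 3.16967 * np.log(t_k)
    return pk1, pk2


def _pk_plummer82(t_k: float) -> tuple[float, float]:
    # Plummer & Busenberg 1982, pure water, mol/kg
    lg = np.log10(t_k)
    pk1 = -(-356.3094 - 0.06091964 * t_k + 21834.37 / t_k
            + 126.8339 * lg - 1684915.0 / t_k**2)
    pk2 = -(-107.8871 - 0.03252849 * t_k + 5151.79 / t_k
            + 38.92561 * lg - 563713.9 / t_k**2)
    return pk1, pk2


FORMULATIONS = {"lueker00": _pk_lueker00, "plummer82": _pk_plummer82}


@dataclass(frozen=True)
class CarbonateConstants:
    """CO2 solubility and dissociation constants at one temperature (mol/kg)."""

    K0: float  # mol/(kg bar), from Henry's law
    K1: float  # mol/kg
    K2: float  # mol/kg
    temperature_k: float
    formulation: str

    def __post_init__(self) -> None:
        if not self.K1 > self.K2 > 0:
            raise ValueError("expected K1 > K2 > 0")

    @property
    def pK1(self) -> float:
        return -np.log10(self.K1)

    @property
    def pK2(self) -> float:
        return -np.log10(self.K2)


@dataclass(frozen=True)
class DICState:
    """Dissolved inorganic carbon pools (µM) at one pH and temperature."""

    temperature_k: float
    pH: float
    co2_aq_uM: float
    hco3_uM: float
    co3_uM: float

    @property
    def dic_uM(self) -> float:
        return self.co2_aq_uM + self.hco3_uM + self.co3_uM


@dataclass(frozen=True)
class UptakeModel:
    """Which Ci species a cell can import: CO2 always, bicarbonate optionally."""

    beta_bicarbonate: int = 0

    def __post_init__(self) -> None:
        if self.beta_bicarbonate not in (0, 1):
            raise ValueError("beta_bicarbonate must be 0 or 1")


def carbonate_constants(
    temperature_k: float, formulation: str = DEFAULT_FORMULATION
) -> CarbonateConstants:
    """Evaluate a packaged dissociation-constant formulation at a temperature."""
    if not _T_MIN_K <= temperature_k <= _T_MAX_K:
        raise ValueError(
            f"temperature {temperature_k} K outside [{_T_MIN_K}, {_T_MAX_K}] K"
        )
    try:
        pk1, pk2 = FORMULATIONS[formulation](temperature_k)
    except KeyError:
        raise ValueError(
            f"unknown formulation {formulation!r}; available: {sorted(FORMULATIONS)}"
        ) from None
    k0 = henry_phase.henry_constant(CO2, temperature_k)
    return CarbonateConstants(k0, 10.0 ** -pk1, 10.0 ** -pk2,
                              temperature_k, formulation)


def speciate_from_pco2(
    pco2_ppm: float,
    ph: float,
    temperature_c: float,
    formulation: str = DEFAULT_FORMULATION,
    total_pressure_pa: float = henry_phase.STANDARD_PRESSURE_PA,
) -> DICState:
    """DIC pools for water under a fixed headspace pCO2.

    CO2(aq) comes from Henry's law and is therefore identical across pH;
    the ionic pools follow from the dissociation constants.  Output in µM
    (mol/kg converted through water density).
    """
    if pco2_ppm < 0:
        raise ValueError("pco2_ppm must be >= 0")
    if not 0.0 < ph < 14.0:
        raise ValueError("pH must lie in (0, 14)")
    t_k = temperature_c + 273.15
    consts = carbonate_constants(t_k, formulation)
    p_bar = pco2_ppm * 1e-6 * total_pressure_pa / 1e5
    h = 10.0 ** -ph
    co2_molal = consts.K0 * p_bar
    hco3_molal = co2_molal * consts.K1 / h
    co3_molal = hco3_molal * consts.K2 / h
    to_uM = henry_phase.water_density(temperature_c) * 1e6
    return DICState(t_k, ph, co2_molal * to_uM, hco3_molal * to_uM,
                    co3_molal * to_uM)


def bicarbonate_fraction(
    ph: float, temperature_c: float, formulation: str = DEFAULT_FORMULATION
) -> float:
    """Fraction of the DIC pool present as bicarbonate at fixed pCO2.

    Independent of the pCO2 itself; strictly increasing in pH over the
    acidic-to-neutral range.
    """
    state = speciate_from_pco2(400.0, ph, temperature_c, formulation)
    return state.hco3_uM / state.dic_uM


def accessible_ci(state: DICState, uptake: UptakeModel) -> float:
    """The Ci pool (µM) a cell can draw on under an uptake model.

    CO2 is always accessible; bicarbonate only for beta = 1; carbonate
    never (no known uptake route at these pH values).
    """
    return state.co2_aq_uM + uptake.beta_bicarbonate * state.hco3_uM
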