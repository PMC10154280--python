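"""Rubisco kinetic parameter sets and their temperature adjustment.

Published kinetics for the thermophilic red-algal rubiscos (CO2/O2
specificity S_c/o, Michaelis constants K_c and K_o) are referenced to 25 °C.
Gas exchange on thermoacidophile cultures is measured at 30–40 °C, so each
parameter is shifted with a Q10 power law::

    Parameter(T) = Parameter(25 degC) * Q10 ** ((T - 25) / 10)

with two phase conventions that matter for correctness:

* S_c/o uses liquid-phase (molar/molar) Q10 values, listed per decade base:
  Q10(25 °C) applies over 25→35 °C and Q10(35 °C) above 35 °C, giving a
  piecewise product for, e.g., 40 °C: ``0.60 * 0.62**0.5``.
* K_c and K_o have their Q10 defined on partial-pressure units (µbar and
  mbar).  The µM value at 25 °C is therefore converted to partial pressure
  with Henry's law at 25 °C, scaled by Q10**((T-25)/10), and converted back
  to µM with Henry's law at T — the round trip through the gas phase is what
  makes the adjusted liquid-phase constants temperature consistent.

The module also houses the two pieces of bench arithmetic that feed the
modelling: carboxylation rate from the coupled NADH spectrophotometric assay
and chlorophyll-a quantification in methanol extracts.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from importlib import resources
from typing import NamedTuple, Sequence

from . import henry_phase
from .henry_phase import CO2, O2, GasSolubility

__all__ = [
    "RubiscoKinetics",
    "Q10Set",
    "AdjustedKinetics",
    "load_reference_kinetics",
    "load_q10",
    "rl_vcmax_ratio",
    "adjust_specificity",
    "adjust_michaelis",
    "adjust_kinetics",
    "vcmax_from_nadh_assay",
    "chlorophyll_a_methanol",
]

T_REF_C = 25.0
_T_MAX_C = 45.0


@dataclass(frozen=True)
class RubiscoKinetics:
    """One species' rubisco parameter set at the 25 °C reference.

    ``Sc_o`` is the liquid-phase (molar/molar) CO2/O2 specificity; ``Kc_uM``
    and ``Ko_uM`` are Michaelis constants for dissolved CO2 and O2.
    """

    species: str
    Sc_o: float
    Kc_uM: float
    Ko_uM: float
    T_ref_C: float = T_REF_C

    def __post_init__(self) -> None:
        for name in ("Sc_o", "Kc_uM", "Ko_uM"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class Q10Set:
    """Q10 temperature coefficients with their phase/base conventions."""

    q10_sco_25: float = 0.60  # liquid phase, decade starting at 25 degC
    q10_sco_35: float = 0.62  # liquid phase, decade starting at 35 degC
    q10_kc_ubar: float = 2.24  # Kc in ubar
    q10_ko_mbar: float = 1.63  # Ko in mbar

    def __post_init__(self) -> None:
        for name in ("q10_sco_25", "q10_sco_35", "q10_kc_ubar", "q10_ko_mbar"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class AdjustedKinetics:
    """A kinetic set adjusted to an assay temperature, in both phases."""

    species: str
    temperature_c: float
    Sc_o_T: float
    Kc_uM_T: float
    Ko_uM_T: float
    Kc_ubar_T: float
    Ko_mbar_T: float


def _fixture() -> dict:
    with resources.files("ccmgasex.data").joinpath("thermophile_kinetics.json").open() as fh:
        return json.load(fh)


def load_reference_kinetics() -> list[RubiscoKinetics]:
    """The packaged thermophilic red-algal kinetic sets (25 °C reference)."""
    return [RubiscoKinetics(**row) for row in _fixture()["kinetics"]]


def load_q10() -> Q10Set:
    """The packaged Q10 coefficient set."""
    return Q10Set(**_fixture()["q10"])


def rl_vcmax_ratio(temperature_c: float) -> float:
    """Packaged day-respiration ratio R_L/V_cmax for a study temperature."""
    table = _fixture()["rl_vcmax_ratio"]
    key = str(round(temperature_c))
    if key not in table:
        raise KeyError(
            f"no packaged R_L/V_cmax ratio at {temperature_c} degC "
            f"(available: {sorted(table)})"
        )
    return table[key]


def kinetics_from_json(path) -> list[RubiscoKinetics]:
    """Read kinetic sets from a JSON list of records."""
    with open(path) as fh:
        return [RubiscoKinetics(**row) for row in json.load(fh)]


def _check_adjust_temperature(temperature_c: float) -> None:
    if temperature_c < T_REF_C:
        raise ValueError(
            f"adjustment below the {T_REF_C} degC reference is unsupported "
            f"(got {temperature_c} degC); the Q10 rules are defined upward only"
        )
    if temperature_c > _T_MAX_C:
        raise ValueError(
            f"temperature {temperature_c} degC above supported maximum {_T_MAX_C}"
        )


def adjust_specificity(
    Sc_o: float, temperature_c: float, q10s: Q10Set | None = None
) -> float:
    """Adjust liquid-phase S_c/o from 25 °C to ``temperature_c``.

    The two listed Q10 values are applied piecewise by decade: Q10(25 °C)
    over 25–35 °C, Q10(35 °C) beyond, each with exponent (span/10).
    """
    q10s = q10s or Q10Set()
    _check_adjust_temperature(temperature_c)
    span_25 = min(temperature_c, 35.0) - 25.0
    span_35 = max(temperature_c - 35.0, 0.0)
    return Sc_o * q10s.q10_sco_25 ** (span_25 / 10.0) * q10s.q10_sco_35 ** (span_35 / 10.0)


class MichaelisAdjustment(NamedTuple):
    liquid_uM: float
    partial_pressure_ubar: float


def adjust_michaelis(
    K_uM: float, gas: GasSolubility, temperature_c: float, q10: float
) -> MichaelisAdjustment:
    """Adjust a Michaelis constant through its partial-pressure Q10.

    Sequence: µM → partial pressure at 25 °C (Henry), Q10 scaling with
    exponent (T−25)/10, partial pressure → µM at T (Henry).  Returns both
    the liquid (µM) and the partial-pressure (µbar) form at T.
    """
    if K_uM <= 0:
        raise ValueError("K must be positive")
    _check_adjust_temperature(temperature_c)
    pp25_ubar = henry_phase.partial_pressure(gas, K_uM, T_REF_C, unit="C")
    ppT_ubar = pp25_ubar * q10 ** ((temperature_c - T_REF_C) / 10.0)
    molal = henry_phase.henry_constant(gas, temperature_c, unit="C") * ppT_ubar * 1e-6
    k_uM_T = molal * henry_phase.water_density(temperature_c) * 1e6
    return MichaelisAdjustment(k_uM_T, ppT_ubar)


def adjust_kinetics(
    kin: RubiscoKinetics, temperature_c: float, q10s: Q10Set | None = None
) -> AdjustedKinetics:
    """Adjust a full kinetic set to ``temperature_c``."""
    q10s = q10s or Q10Set()
    sco_T = adjust_specificity(kin.Sc_o, temperature_c, q10s)
    kc = adjust_michaelis(kin.Kc_uM, CO2, temperature_c, q10s.q10_kc_ubar)
    ko = adjust_michaelis(kin.Ko_uM, O2, temperature_c, q10s.q10_ko_mbar)
    return AdjustedKinetics(
        species=kin.species,
        temperature_c=temperature_c,
        Sc_o_T=sco_T,
        Kc_uM_T=kc.liquid_uM,
        Ko_uM_T=ko.liquid_uM,
        Kc_ubar_T=kc.partial_pressure_ubar,
        Ko_mbar_T=ko.partial_pressure_ubar / 1e3,
    )


NADH_EXTINCTION_MM_CM = 6.22  # Abs340 per mM per cm
NADH_PER_CARBOXYLATION = 4.0


def vcmax_from_nadh_assay(
    abs_slope: float,
    cuvette_volume_ml: float,
    chl_mass_ug: float,
    path_cm: float = 1.0,
    epsilon: float = NADH_EXTINCTION_MM_CM,
    stoichiometry: float = NADH_PER_CARBOXYLATION,
) -> float:
    """Carboxylation rate from the coupled NADH assay.

    ``abs_slope`` is the magnitude of the RuBP-dependent Abs340 decline per
    second.  Beer–Lambert gives mM NADH/s, the coupling stoichiometry (4 NADH
    per carboxylation) converts to carboxylations, and the result is scaled
    by cuvette volume and chlorophyll mass to pmol CO2 · µg Chl a⁻¹ · s⁻¹.
    """
    if abs_slope < 0:
        raise ValueError("abs_slope is a magnitude and must be >= 0")
    if chl_mass_ug <= 0 or cuvette_volume_ml <= 0 or path_cm <= 0:
        raise ValueError("path, volume and chlorophyll mass must be positive")
    nadh_mM_per_s = abs_slope / (epsilon * path_cm)
    # mM * mL = umol, so mM/s * mL = umol/s
    co2_umol_per_s = nadh_mM_per_s * cuvette_volume_ml / stoichiometry
    return co2_umol_per_s * 1e6 / chl_mass_ug  # pmol / ug / s


def chlorophyll_a_methanol(
    a_peak: float, a720: float, coefficient: float, dilution: float = 1.0
) -> float:
    """Chlorophyll a (µg/mL) from a methanol extract's absorbances.

    ``coefficient * (a_peak - a720) * dilution`` with a 720 nm turbidity
    correction; a negative corrected absorbance yields 0 with a warning.
    """
    if a720 < 0 or a_peak < 0:
        raise ValueError("absorbances must be >= 0")
    corrected = a_peak - a720
    if corrected < 0:
        warnings.warn(
            "turbidity-corrected absorbance is negative; returning 0 ug/mL",
            stacklevel=2,
        )
        return 0.0
    return coefficient * corrected * dilution


def adjust_many(
    kinetics: Sequence[RubiscoKinetics],
    temperature_c: float,
    q10s: Q10Set | None = None,
) -> list[AdjustedKinetics]:
    """Adjust a collection of kinetic sets to one temperature."""
    return [adjust_kinetics(k, temperature_c, q10s) for k in kinetics]
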