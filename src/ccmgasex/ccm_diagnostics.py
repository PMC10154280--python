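"""Compensation-point modelling and CCM diagnostics.

The CO2 compensation point Γ_CO2 (dissolved CO2, µM, at which net carbon
assimilation is zero) follows from rubisco kinetics in the absence of a CCM
or RuBP limitation.  With r = R_L/V_cmax (day respiration relative to the
maximal carboxylation rate) and O the chloroplastic dissolved O2 (µM):

    Gamma_CO2 = [ (0.5/S_c/o + Kc*r/Ko) / (1 - r) ] * O + Kc*r / (1 - r)

Γ is exactly linear in O; the coefficient of O (the "oxygen-response slope")
is the diagnostic of interest because an operating CCM suppresses rubisco
oxygenation and flattens the measured slope below anything the kinetics
permit.  This module evaluates Γ over all crosses of published kinetic
parameter sets, extracts the slope range, runs the hypothetical
generous-kinetics scenario (doubled best specificity, halved best Kc), and
classifies measured values against calculated ranges.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import rubisco_kinetics as rk
from .rubisco_kinetics import AdjustedKinetics, Q10Set, RubiscoKinetics

__all__ = [
    "GammaInputs",
    "GammaResult",
    "GammaGrid",
    "RangeComparison",
    "gamma_co2",
    "gamma_grid",
    "hypothetical_gamma",
    "oxygen_slope",
    "classify_measurement",
]

PM_PER_UM = 1e6  # µM/µM -> pM/µM


@dataclass(frozen=True)
class GammaInputs:
    """Symbols of the compensation-point equation at one temperature."""

    Sc_o_T: float
    Kc_uM_T: float
    Ko_uM_T: float
    rl_ratio: float
    O_uM: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.rl_ratio < 1.0:
            raise ValueError(
                f"rl_ratio must be in [0, 1); got {self.rl_ratio} "
                "(r = 1 makes the compensation point singular)"
            )
        for name in ("Kc_uM_T", "Ko_uM_T", "O_uM"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class GammaResult:
    """Evaluated compensation point and its linear-in-O decomposition."""

    gamma_uM: float
    slope_term: float  # µM CO2 per µM O2
    intercept_term: float  # µM CO2


def gamma_co2(inputs: GammaInputs) -> GammaResult:
    """Evaluate the compensation-point equation.

    Returns Γ together with its analytic slope and intercept in O, which
    satisfy ``gamma_uM == slope_term * O_uM + intercept_term`` exactly.
    """
    r = inputs.rl_ratio
    slope = (0.5 / inputs.Sc_o_T + inputs.Kc_uM_T * r / inputs.Ko_uM_T) / (1.0 - r)
    intercept = inputs.Kc_uM_T * r / (1.0 - r)
    return GammaResult(slope * inputs.O_uM + intercept, slope, intercept)


@dataclass(frozen=True)
class GammaGrid:
    """Γ over every (S_c/o source, K_c source) cross at each O level.

    ``rows`` has one record per combination × O level with provenance
    columns; slopes are per-combination OLS fits across the O levels
    (equal to the analytic coefficient, since Γ is linear in O).
    """

    rows: pd.DataFrame
    slope_min_pM_per_uM: float
    slope_max_pM_per_uM: float
    gamma_bounds_uM: pd.DataFrame  # per O level: min/max over combinations

    @property
    def slope_range(self) -> tuple[float, float]:
        return (self.slope_min_pM_per_uM, self.slope_max_pM_per_uM)


def _adjusted(kinetics: Sequence[RubiscoKinetics], temperature_c: float,
              q10s: Q10Set | None) -> list[AdjustedKinetics]:
    return rk.adjust_many(kinetics, temperature_c, q10s)


def gamma_grid(
    kinetics: Sequence[RubiscoKinetics],
    temperature_c: float,
    o_levels_uM: Sequence[float],
    rl_ratio: float,
    q10s: Q10Set | None = None,
) -> GammaGrid:
    """Evaluate Γ for all S_c/o × K_c crosses at each dissolved-O2 level.

    The shared K_o (identical across the packaged sets) is temperature
    adjusted once.  Every pairing of a specificity source with a Kc source
    is formed — the parameters are published independently, so crosses, not
    just species-matched triplets, bound the feasible range.
    """
    if not kinetics or not list(o_levels_uM):
        raise ValueError("kinetics and o_levels_uM must be nonempty")
    adj = _adjusted(kinetics, temperature_c, q10s)
    o = np.asarray(list(o_levels_uM), dtype=float)

    records = []
    slopes = {}
    for a_s in adj:  # specificity source
        for a_k in adj:  # Kc source
            combo = f"Sc/o:{a_s.species}|Kc:{a_k.species}"
            res0 = None
            for o_uM in o:
                res = gamma_co2(GammaInputs(a_s.Sc_o_T, a_k.Kc_uM_T,
                                            a_k.Ko_uM_T, rl_ratio, o_uM))
                res0 = res
                records.append({
                    "combination": combo,
                    "sco_species": a_s.species,
                    "kc_species": a_k.species,
                    "Sc_o_T": a_s.Sc_o_T,
                    "Kc_uM_T": a_k.Kc_uM_T,
                    "Ko_uM_T": a_k.Ko_uM_T,
                    "O_uM": o_uM,
                    "gamma_uM": res.gamma_uM,
                    "slope_term_uM_per_uM": res.slope_term,
                    "intercept_term_uM": res.intercept_term,
                })
            if len(o) >= 2:
                gammas = [r["gamma_uM"] for r in records[-len(o):]]
                fit = stats.linregress(o, gammas)
                slopes[combo] = fit.slope
            else:
                slopes[combo] = res0.slope_term
    rows = pd.DataFrame.from_records(records)
    rows["slope_pM_per_uM"] = rows["combination"].map(slopes) * PM_PER_UM
    bounds = rows.groupby("O_uM")["gamma_uM"].agg(["min", "max"]).reset_index()
    slope_vals = np.array(list(slopes.values())) * PM_PER_UM
    return GammaGrid(rows, float(slope_vals.min()), float(slope_vals.max()), bounds)


def hypothetical_gamma(
    kinetics: Sequence[RubiscoKinetics],
    temperature_c: float,
    rl_ratio: float,
    O_uM: float,
    sco_multiplier: float = 2.0,
    kc_multiplier: float = 0.5,
    q10s: Q10Set | None = None,
) -> GammaResult:
    """Γ under deliberately generous hypothetical kinetics.

    Takes the extrema AFTER temperature adjustment — the maximum adjusted
    S_c/o and minimum adjusted K_c — applies the multipliers (defaults:
    doubled specificity, halved K_c), and evaluates Γ with the adjusted
    shared K_o.  Answers "could any plausible rubisco explain the measured
    compensation point without a CCM?"
    """
    if not kinetics:
        raise ValueError("kinetics must be nonempty")
    adj = _adjusted(kinetics, temperature_c, q10s)
    sco = max(a.Sc_o_T for a in adj) * sco_multiplier
    kc = min(a.Kc_uM_T for a in adj) * kc_multiplier
    ko = adj[0].Ko_uM_T
    return gamma_co2(GammaInputs(sco, kc, ko, rl_ratio, O_uM))


@dataclass(frozen=True)
class OxygenSlope:
    slope_pM_per_uM: float
    se_pM_per_uM: float


def oxygen_slope(gamma_by_o2: Sequence[tuple[float, float]]) -> OxygenSlope:
    """OLS slope (pM CO2 / µM O2) of Γ against dissolved O2, with its SE."""
    pairs = np.asarray(list(gamma_by_o2), dtype=float)
    if pairs.ndim != 2 or len(np.unique(pairs[:, 0])) < 2:
        raise ValueError("need Gamma observations at >= 2 distinct O2 levels")
    fit = stats.linregress(pairs[:, 0], pairs[:, 1])
    se = 0.0 if np.isnan(fit.stderr) else fit.stderr
    return OxygenSlope(fit.slope * PM_PER_UM, se * PM_PER_UM)


@dataclass(frozen=True)
class RangeComparison:
    """A measured value ± halfwidth against a calculated [min, max] range."""

    measured: float
    halfwidth: float
    calculated_min: float
    calculated_max: float
    verdict: str  # below | within | above


def classify_measurement(
    measured: float, halfwidth: float, calculated_range: tuple[float, float]
) -> RangeComparison:
    """Interval comparison of a measurement with a calculated range.

    "below" when the whole measured interval sits under the range, "above"
    when it sits over it, "within" when the intervals touch or overlap.
    """
    lo, hi = calculated_range
    if lo > hi:
        raise ValueError(f"calculated range must satisfy min <= max, got {lo} > {hi}")
    if halfwidth < 0:
        raise ValueError("halfwidth must be >= 0")
    if measured + halfwidth < lo:
        verdict = "below"
    elif measured - halfwidth > hi:
        verdict = "above"
    else:
        verdict = "within"
    return RangeComparison(measured, halfwidth, lo, hi, verdict)
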