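"""Synthetic gas-exchange datasets with known ground truth.

No raw instrument export is publicly deposited for the study system this
package models, so every pipeline stage is exercised against generated
data whose true parameters are known and carried in metadata.

The CO2-response generator uses an *offset* Michaelis–Menten model::

    A(C) = (A_max + R_L) * C / (K_m + C) - R_L + eps,   eps ~ N(0, sd^2)

which saturates at A_max, respires R_L in the dark limit, and crosses zero
at the closed-form compensation point ``Gamma = K_m * R_L / A_max`` — so a
single curve gives the Michaelis–Menten fit, the low-CO2 compensation-point
fit, and the Kok-style respiration a meaningful target each.  The light-
response generator is exactly linear (slope φ, intercept −R_L) through the
Kok window and saturates smoothly above a breakpoint.  The oxygen-response
generator draws replicate Γ-vs-O2 lines either from a stated slope or from
the rubisco-kinetics grid (optionally attenuated, emulating a CCM's
suppression of oxygen sensitivity), and the pH-experiment generator drives
the response model with the accessible-Ci pool so that bicarbonate-capable
uptake (beta = 1) halves the apparent headspace-ppm K_m at pH 6.

Noise is additive, homoscedastic Gaussian (default 5% of A_max — a package
choice, not an instrument claim).  Replicate ``i`` of a dataset seeded with
``seed`` uses the stream ``SeedSequence(entropy=(seed, i))``, so adding
replicates never reshuffles earlier ones and identical configurations are
byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import carbonate_speciation as spec
from . import ccm_diagnostics as diag
from . import rubisco_kinetics as rk
from .gasex_pipeline import SUBSAMPLE_FLOW_UMOL_S, ResponseCurve

__all__ = [
    "SyntheticConfig",
    "simulate_co2_response",
    "simulate_light_response",
    "simulate_oxygen_response",
    "simulate_ph_experiment",
    "curves_to_records",
    "write_dataset",
]

CO2_GRID_PPM = (10.0, 25.0, 50.0, 75.0, 100.0, 150.0, 200.0,
                300.0, 400.0, 700.0, 1000.0, 1500.0)
LIGHT_GRID = (10.0, 15.0, 20.0, 25.0, 30.0, 50.0, 100.0,
              250.0, 500.0, 1000.0, 2000.0)


@dataclass(frozen=True)
class SyntheticConfig:
    """Ground-truth parameters, noise model, and seed for data generation.

    Defaults are the study conditions at 40 °C: A_max 35 pmol µg Chl a⁻¹
    s⁻¹, R_L = 0.13 · A_max, an apparent K_m of 200 ppm headspace CO2,
    dissolved-O2 levels 20/209/398 µM, and a measured-scale oxygen-response
    slope of 5425 pM/µM with Γ ≈ 1.1 µM at 21% O2.
    """

    km_true_ppm: float = 200.0
    amax_true: float = 35.0
    rl_true: float = 0.13 * 35.0
    noise_sd: float = 0.05 * 35.0
    driver_grid: tuple = CO2_GRID_PPM
    light_grid: tuple = LIGHT_GRID
    phi_true: float = 0.05  # low-light slope, per µmol m-2 s-1 incident
    light_break: float = 100.0
    n_replicates: int = 3
    seed: int = 0
    temperature_c: float = 40.0
    o2_levels_uM: tuple = (20.0, 209.0, 398.0)
    slope_true_pM_per_uM: float = 5425.0
    intercept_true_uM: float = 0.0
    noise_sd_gamma_uM: float = 0.05
    uptake: spec.UptakeModel = field(default_factory=spec.UptakeModel)
    ph_pair: tuple = (2.0, 6.0)

    def __post_init__(self) -> None:
        if self.km_true_ppm <= 0 or self.amax_true <= 0:
            raise ValueError("km_true_ppm and amax_true must be positive")
        if self.rl_true < 0 or self.noise_sd < 0 or self.noise_sd_gamma_uM < 0:
            raise ValueError("rl_true and noise sds must be >= 0")

    @property
    def gamma_true_ppm(self) -> float:
        """Closed-form compensation point of the offset model (ppm)."""
        return self.km_true_ppm * self.rl_true / self.amax_true


def _rng(cfg: SyntheticConfig, replicate: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=(cfg.seed, replicate)))


def _offset_mm(c, amax, rl, km):
    return (amax + rl) * c / (km + c) - rl


def simulate_co2_response(cfg: SyntheticConfig) -> list[ResponseCurve]:
    """Replicate CO2-response curves from the offset Michaelis–Menten model."""
    truth = {
        "km_true_ppm": cfg.km_true_ppm,
        "amax_true": cfg.amax_true,
        "rl_true": cfg.rl_true,
        "gamma_true_ppm": cfg.gamma_true_ppm,
        "noise_sd": cfg.noise_sd,
    }
    curves = []
    x = np.asarray(cfg.driver_grid, dtype=float)
    for rep in range(cfg.n_replicates):
        eps = _rng(cfg, rep).normal(0.0, cfg.noise_sd, size=x.shape) if cfg.noise_sd else 0.0
        a = _offset_mm(x, cfg.amax_true, cfg.rl_true, cfg.km_true_ppm) + eps
        meta = {"replicate": rep, "temperature_c": cfg.temperature_c,
                "ground_truth": truth}
        curves.append(ResponseCurve("headspace_co2_ppm", x, a, meta))
    return curves


def _light_model(i, cfg: SyntheticConfig):
    """Exactly linear (φ·I − R_L) up to the breakpoint, then C1-smooth
    exponential saturation toward A_max."""
    i = np.asarray(i, dtype=float)
    a_break = cfg.phi_true * cfg.light_break - cfg.rl_true
    span = cfg.amax_true - a_break
    sat = cfg.amax_true - span * np.exp(-cfg.phi_true * (i - cfg.light_break) / span)
    return np.where(i <= cfg.light_break, cfg.phi_true * i - cfg.rl_true, sat)


def simulate_light_response(cfg: SyntheticConfig) -> list[ResponseCurve]:
    """Replicate light-response curves with an exact Kok segment."""
    truth = {"phi_true": cfg.phi_true, "rl_true": cfg.rl_true,
             "amax_true": cfg.amax_true, "noise_sd": cfg.noise_sd}
    x = np.asarray(cfg.light_grid, dtype=float)
    curves = []
    for rep in range(cfg.n_replicates):
        eps = _rng(cfg, rep).normal(0.0, cfg.noise_sd, size=x.shape) if cfg.noise_sd else 0.0
        a = _light_model(x, cfg) + eps
        meta = {"replicate": rep, "temperature_c": cfg.temperature_c,
                "ground_truth": truth}
        curves.append(ResponseCurve("incident_light", x, a, meta))
    return curves


def simulate_oxygen_response(
    cfg: SyntheticConfig,
    kinetics: list[rk.RubiscoKinetics] | None = None,
    attenuation: float = 1.0,
    rl_ratio: float | None = None,
) -> pd.DataFrame:
    """Replicate (O2, Γ) tables with a known linear oxygen response.

    Without ``kinetics`` the line is ``slope_true · O + intercept_true``.
    With ``kinetics`` each replicate takes the (slope, intercept) of one
    rubisco-parameter combination from the modelled grid (assigned
    round-robin), scaled by ``attenuation`` ∈ (0, 1] on the slope — an
    attenuation below 1 emulates a CCM damping the oxygen sensitivity.
    Ground truth is stored in ``df.attrs["ground_truth"]``.
    """
    if not 0.0 < attenuation <= 1.0:
        raise ValueError("attenuation must lie in (0, 1]")
    o = np.asarray(cfg.o2_levels_uM, dtype=float)
    if kinetics is not None:
        if rl_ratio is None:
            rl_ratio = rk.rl_vcmax_ratio(cfg.temperature_c)
        grid = diag.gamma_grid(kinetics, cfg.temperature_c, o, rl_ratio)
        combos = (grid.rows.drop_duplicates("combination")
                  [["combination", "slope_term_uM_per_uM", "intercept_term_uM"]]
                  .reset_index(drop=True))
        lines = [(row.slope_term_uM_per_uM * attenuation, row.intercept_term_uM,
                  row.combination) for row in combos.itertuples()]
    else:
        lines = [(cfg.slope_true_pM_per_uM / 1e6 * attenuation,
                  cfg.intercept_true_uM, "configured")]

    records = []
    truth_lines = []
    for rep in range(cfg.n_replicates):
        slope, intercept, combo = lines[rep % len(lines)]
        truth_lines.append({"replicate": rep, "slope_uM_per_uM": slope,
                            "intercept_uM": intercept, "combination": combo})
        eps = (_rng(cfg, rep).normal(0.0, cfg.noise_sd_gamma_uM, size=o.shape)
               if cfg.noise_sd_gamma_uM else np.zeros_like(o))
        for o_uM, e in zip(o, eps):
            records.append({"replicate": rep, "o2_uM": o_uM,
                            "gamma_uM": slope * o_uM + intercept + e})
    df = pd.DataFrame.from_records(records)
    df.attrs["ground_truth"] = {"lines": truth_lines, "attenuation": attenuation}
    return df


def simulate_ph_experiment(cfg: SyntheticConfig) -> dict[float, list[ResponseCurve]]:
    """Paired CO2-response curve sets at pH 2 and pH 6.

    The response model runs on the *accessible-Ci* pool: each headspace ppm
    value is speciated at the record's pH and reduced to CO2(aq) plus
    (for beta = 1) bicarbonate.  The true K_m is anchored in accessible-Ci
    units so that it corresponds to ``km_true_ppm`` at low pH; with
    bicarbonate-capable uptake the apparent headspace-ppm K_m at pH 6 is
    smaller by the factor by which the accessible pool grows.
    """
    ph_lo, ph_hi = cfg.ph_pair
    x = np.asarray(cfg.driver_grid, dtype=float)

    def accessible(ppm, ph):
        states = [spec.speciate_from_pco2(p, ph, cfg.temperature_c) for p in np.atleast_1d(ppm)]
        return np.array([spec.accessible_ci(s, cfg.uptake) for s in states])

    # anchor: km_true_ppm is the apparent ppm Km at the low-pH condition
    km_acc_uM = accessible(cfg.km_true_ppm, ph_lo)[0]
    pool_ratio = float(accessible(1000.0, ph_hi)[0] / accessible(1000.0, ph_lo)[0])
    truth = {
        "km_true_ppm_low_ph": cfg.km_true_ppm,
        "km_acc_uM": km_acc_uM,
        "beta_bicarbonate": cfg.uptake.beta_bicarbonate,
        "accessible_pool_ratio_ph_hi_over_lo": pool_ratio,
        "expected_km_ppm_ratio_hi_over_lo": 1.0 / pool_ratio,
        "amax_true": cfg.amax_true,
        "rl_true": cfg.rl_true,
    }
    out: dict[float, list[ResponseCurve]] = {}
    for k, ph in enumerate((ph_lo, ph_hi)):
        curves = []
        s = accessible(x, ph)
        for rep in range(cfg.n_replicates):
            # distinct streams per (pH, replicate)
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=(cfg.seed, k, rep)))
            eps = rng.normal(0.0, cfg.noise_sd, size=x.shape) if cfg.noise_sd else 0.0
            a = _offset_mm(s, cfg.amax_true, cfg.rl_true, km_acc_uM) + eps
            meta = {"replicate": rep, "ph": ph,
                    "temperature_c": cfg.temperature_c, "ground_truth": truth}
            curves.append(ResponseCurve("headspace_co2_ppm", x, a, meta))
        out[ph] = curves
    return out


def curves_to_records(curves: list[ResponseCurve], sample_id: str = "synthetic",
                      o2_percent: float = 21.0, ph: float = 2.0,
                      flow_umol_s: float = 400.0) -> pd.DataFrame:
    """Render curves in the instrument-export CSV dialect.

    ΔC is written as zero so the headspace correction is the identity and
    the reference-chamber column carries the driver for CO2 curves.
    """
    rows = []
    for curve in curves:
        meta = curve.metadata
        for xv, av in zip(curve.x, curve.a):
            rows.append({
                "sample_id": sample_id,
                "replicate": meta.get("replicate", 0),
                "temperature_c": meta.get("temperature_c", np.nan),
                "o2_percent": o2_percent,
                "ph": meta.get("ph", ph),
                "reference_co2_ppm": xv if curve.driver == "headspace_co2_ppm" else 400.0,
                "delta_co2_ppm": 0.0,
                "flow_umol_s": flow_umol_s,
                "subsample_flow_umol_s": SUBSAMPLE_FLOW_UMOL_S,
                "incident_light": xv if curve.driver == "incident_light" else 2000.0,
                "assimilation": av,
            })
    return pd.DataFrame.from_records(rows)


def write_dataset(curves: list[ResponseCurve], csv_path, truth_path=None, **kwargs) -> None:
    """Write curves as CSV plus a sidecar JSON of ground truth."""
    df = curves_to_records(curves, **kwargs)
    df.to_csv(csv_path, index=False)
    if truth_path is not None:
        truth = curves[0].metadata.get("ground_truth", {}) if curves else {}
        with open(truth_path, "w") as fh:
            json.dump(truth, fh, indent=2)
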