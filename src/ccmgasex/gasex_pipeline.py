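"""Data reduction for aquatic-chamber gas-exchange experiments.

Raw instrument records carry the reference-chamber CO2, the reference-minus-
sample difference ΔC, and the sample/subsample flow rates.  The headspace
CO2 above the liquid sample is recovered with the subsample correction
ΔC_sub = (µ_i / µ_i_sub) · ΔC applied below the sample-chamber value, with
negative results clamped to zero (and flagged).  Curves of assimilation
against headspace CO2, dissolved CO2, or incident light then feed three
fits:

* a two-parameter Michaelis–Menten fit, A = A_max · C / (K_m + C), with
  linearized 95% confidence intervals — the whole-cell CO2 affinity;
* a linear fit to the low-CO2 points (≤ 100 ppm by default) whose
  x-intercept is the CO2 compensation point Γ;
* a Kok fit: a line through the low-light points (10–30 µmol m⁻² s⁻¹
  incident) whose extrapolated intercept magnitude is the day respiration
  R_L.

Two replicate-level analyses sit on top: the oxygen-response slope of Γ
(mean ± 2 SE over replicates) and the pH 2 vs pH 6 Welch-test comparison
that asks whether apparent K_m halves when bicarbonate becomes available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import henry_phase
from .henry_phase import CO2, EnvConditions

__all__ = [
    "ResponseCurve",
    "MMFitResult",
    "CompPointFit",
    "KokFit",
    "CSV_COLUMNS",
    "SUBSAMPLE_FLOW_UMOL_S",
    "read_records",
    "headspace_co2",
    "to_dissolved",
    "fit_michaelis_menten",
    "fit_compensation_point",
    "fit_kok",
    "oxygen_response_analysis",
    "ph_comparison_tests",
]

SUBSAMPLE_FLOW_UMOL_S = 233.0  # instrument constant

CSV_COLUMNS = [
    "sample_id", "replicate", "temperature_c", "o2_percent", "ph",
    "reference_co2_ppm", "delta_co2_ppm", "flow_umol_s",
    "subsample_flow_umol_s", "incident_light", "assimilation",
]


class FitError(RuntimeError):
    """A fit failed to converge or was degenerate; carries diagnostics."""


class InsufficientDataError(ValueError):
    """Too few points for the requested fit."""


@dataclass(frozen=True)
class ResponseCurve:
    """An ordered set of (driver, assimilation) observations for one replicate.

    ``driver`` names the x-axis: ``headspace_co2_ppm``, ``dissolved_co2_uM``
    or ``incident_light``.  Assimilation is in pmol CO2 · µg Chl a⁻¹ · s⁻¹.
    """

    driver: str
    x: np.ndarray
    a: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        a = np.asarray(self.a, dtype=float)
        if x.shape != a.shape or x.ndim != 1:
            raise ValueError("x and a must be 1-D arrays of equal length")
        if np.any(x < 0):
            raise ValueError("driver values must be nonnegative")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "a", a)

    def __len__(self) -> int:
        return len(self.x)


def read_records(path) -> pd.DataFrame:
    """Read the instrument-export CSV dialect, checking the schema."""
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"input CSV missing columns: {missing}")
    return df


def headspace_co2(records: pd.DataFrame) -> pd.DataFrame:
    """Headspace CO2 (ppm) from reference CO2, ΔC and the two flows.

    sample chamber = reference − ΔC; headspace = sample − (µ_i/µ_i_sub)·ΔC.
    Negative results are clamped to 0 and flagged in ``headspace_clamped``;
    the clamp count is stored in ``df.attrs["n_clamped"]``.
    """
    df = records.copy()
    flows = df[["flow_umol_s", "subsample_flow_umol_s"]].to_numpy(dtype=float)
    if np.any(flows <= 0):
        raise ValueError("flow rates must be positive")
    delta = df["delta_co2_ppm"].to_numpy(dtype=float)
    sample = df["reference_co2_ppm"].to_numpy(dtype=float) - delta
    raw = sample - flows[:, 0] / flows[:, 1] * delta
    clamped = raw < 0
    df["headspace_co2_ppm"] = np.where(clamped, 0.0, raw)
    df["headspace_clamped"] = clamped
    df.attrs["n_clamped"] = int(clamped.sum())
    return df


def to_dissolved(curve: ResponseCurve, temperature_c: float) -> ResponseCurve:
    """Map a headspace-ppm curve to dissolved CO2 (µM) via Henry's law."""
    if curve.driver != "headspace_co2_ppm":
        raise ValueError(f"expected a headspace_co2_ppm curve, got {curve.driver}")
    env = EnvConditions(temperature_c, unit="C")
    x_uM = henry_phase.dissolved_concentration(CO2, curve.x * 1e-6, env)
    meta = dict(curve.metadata, temperature_c=temperature_c)
    return ResponseCurve("dissolved_co2_uM", x_uM, curve.a, meta)


@dataclass(frozen=True)
class MMFitResult:
    """Two-parameter Michaelis–Menten fit with linearized 95% CIs."""

    km: float
    amax: float
    ci_km: float  # 95% half-interval
    ci_amax: float
    n_points_used: int
    driver: str


def fit_michaelis_menten(
    curve: ResponseCurve, max_driver: float | None = None
) -> MMFitResult:
    """Fit A = A_max · C / (K_m + C) by nonlinear least squares.

    ``max_driver`` applies a strict ``x < max_driver`` cutoff first (used to
    exclude the supersaturating points of pH 6 curves).  Confidence
    half-intervals come from the parameter covariance at the optimum with a
    t(n−2) critical value.
    """
    mask = np.ones(len(curve), dtype=bool) if max_driver is None else curve.x < max_driver
    x, a = curve.x[mask], curve.a[mask]
    if len(x) < 3:
        raise InsufficientDataError(
            f"Michaelis-Menten fit needs >= 3 points, got {len(x)}"
        )

    def mm(c, amax, km):
        return amax * c / (km + c)

    amax0 = max(a.max(), 1e-6)
    km0 = max(np.median(x), 1e-6)
    try:
        popt, pcov = optimize.curve_fit(
            mm, x, a, p0=(amax0, km0), maxfev=20000,
            bounds=((0, 0), (np.inf, np.inf)),
        )
    except RuntimeError as exc:
        raise FitError(f"Michaelis-Menten fit did not converge: {exc}") from exc
    se = np.sqrt(np.diag(pcov))
    dof = max(len(x) - 2, 1)
    tcrit = stats.t.ppf(0.975, dof)
    return MMFitResult(
        km=popt[1], amax=popt[0],
        ci_km=tcrit * se[1], ci_amax=tcrit * se[0],
        n_points_used=int(len(x)), driver=curve.driver,
    )


@dataclass(frozen=True)
class CompPointFit:
    """Linear low-CO2 fit; gamma is the x-intercept (−intercept/slope)."""

    gamma: float
    slope: float
    intercept: float
    n_points_used: int
    driver: str


def fit_compensation_point(
    curve: ResponseCurve, threshold: float = 100.0
) -> CompPointFit:
    """Compensation point from an OLS line through points with x ≤ threshold.

    The default 100 ppm window keeps the response in its near-linear range.
    A nonpositive fitted slope means the subset carries no crossing
    information and raises :class:`FitError`.
    """
    mask = curve.x <= threshold
    x, a = curve.x[mask], curve.a[mask]
    if len(np.unique(x)) < 2:
        raise InsufficientDataError(
            f"compensation-point fit needs >= 2 distinct points <= {threshold}"
        )
    fit = stats.linregress(x, a)
    if fit.slope <= 0:
        raise FitError(
            f"degenerate compensation-point fit: slope {fit.slope:.4g} <= 0"
        )
    return CompPointFit(
        gamma=-fit.intercept / fit.slope,
        slope=fit.slope, intercept=fit.intercept,
        n_points_used=int(len(x)), driver=curve.driver,
    )


KOK_WINDOW = (10.0, 30.0)  # µmol m-2 s-1 incident


@dataclass(frozen=True)
class KokFit:
    """Kok-method respiration estimate from the low-light linear segment."""

    rl: float  # positive magnitude of the extrapolated intercept
    slope: float  # quantum-efficiency proxy
    window: tuple[float, float]
    n_points_used: int


def fit_kok(
    curve: ResponseCurve, window: tuple[float, float] = KOK_WINDOW
) -> KokFit:
    """Day respiration R_L as −intercept of an OLS line on the light window."""
    lo, hi = window
    mask = (curve.x >= lo) & (curve.x <= hi)
    x, a = curve.x[mask], curve.a[mask]
    if len(np.unique(x)) < 2:
        raise InsufficientDataError(
            f"Kok fit needs >= 2 distinct points inside {window}"
        )
    fit = stats.linregress(x, a)
    return KokFit(rl=-fit.intercept, slope=fit.slope, window=(lo, hi),
                  n_points_used=int(len(x)))


@dataclass(frozen=True)
class OxygenResponseResult:
    slope_mean_pM_per_uM: float
    slope_2se_pM_per_uM: float
    per_replicate: pd.DataFrame
    n_replicates: int
    se_defined: bool
    balanced: bool


def oxygen_response_analysis(comp_points: pd.DataFrame) -> OxygenResponseResult:
    """Measured oxygen-response slope of Γ, aggregated over replicates.

    ``comp_points`` needs columns ``replicate``, ``o2_uM``, ``gamma_uM``.
    Each replicate contributes one OLS slope across its O2 levels; the
    result is their mean ± 2·SE (in pM CO2 / µM O2).  An unbalanced design
    (replicates seeing different O2 sets) is tolerated with a warning flag.
    """
    required = {"replicate", "o2_uM", "gamma_uM"}
    if not required.issubset(comp_points.columns):
        raise ValueError(f"comp_points must have columns {sorted(required)}")
    if comp_points["o2_uM"].nunique() < 2:
        raise InsufficientDataError("need >= 2 distinct O2 levels")

    rows = []
    level_sets = set()
    for rep, grp in comp_points.groupby("replicate"):
        if grp["o2_uM"].nunique() < 2:
            raise InsufficientDataError(
                f"replicate {rep} has < 2 distinct O2 levels"
            )
        fit = stats.linregress(grp["o2_uM"], grp["gamma_uM"])
        rows.append({"replicate": rep, "slope_pM_per_uM": fit.slope * 1e6})
        level_sets.add(tuple(sorted(grp["o2_uM"].unique())))
    per_rep = pd.DataFrame(rows)
    slopes = per_rep["slope_pM_per_uM"].to_numpy()
    n = len(slopes)
    se_defined = n >= 2
    se = float(np.std(slopes, ddof=1) / np.sqrt(n)) if se_defined else float("nan")
    return OxygenResponseResult(
        slope_mean_pM_per_uM=float(np.mean(slopes)),
        slope_2se_pM_per_uM=2.0 * se,
        per_replicate=per_rep,
        n_replicates=n,
        se_defined=se_defined,
        balanced=len(level_sets) <= 1,
    )


@dataclass(frozen=True)
class WelchTest:
    statistic: float
    df: float
    pvalue: float
    alternative: str


@dataclass(frozen=True)
class PhComparisonReport:
    """The two one-sided Welch tests of the pH 2 vs pH 6 design."""

    half_mean: WelchTest  # H1: mean(pH6) < 0.5 * mean(pH2)
    greater: WelchTest  # H1: mean(pH2) > mean(pH6)


def ph_comparison_tests(
    params_ph2: Sequence[float], params_ph6: Sequence[float]
) -> PhComparisonReport:
    """Welch t-tests for one parameter measured at pH 2 and pH 6.

    The "half-mean" test scales the pH 2 sample by 0.5 (scaling its variance
    by 0.25) and tests one-sided whether the pH 6 mean falls below it — the
    direction expected if bicarbonate uptake doubled the accessible Ci pool
    at pH 6.  The "greater" test is the plain one-sided pH 2 > pH 6
    comparison.
    """
    a2 = np.asarray(params_ph2, dtype=float)
    a6 = np.asarray(params_ph6, dtype=float)
    if len(a2) < 2 or len(a6) < 2:
        raise InsufficientDataError("need >= 2 replicates per pH group")

    res_half = stats.ttest_ind(a6, 0.5 * a2, equal_var=False, alternative="less")
    res_greater = stats.ttest_ind(a2, a6, equal_var=False, alternative="greater")
    return PhComparisonReport(
        half_mean=WelchTest(float(res_half.statistic), float(res_half.df),
                            float(res_half.pvalue), "mean(pH6) < mean(pH2)/2"),
        greater=WelchTest(float(res_greater.statistic), float(res_greater.df),
                          float(res_greater.pvalue), "mean(pH2) > mean(pH6)"),
    )


def curves_from_records(df: pd.DataFrame, driver: str = "headspace_co2_ppm") -> list[ResponseCurve]:
    """Split a processed record table into per-(sample, replicate) curves."""
    if driver == "headspace_co2_ppm" and "headspace_co2_ppm" not in df.columns:
        df = headspace_co2(df)
    xcol = driver if driver != "incident_light" else "incident_light"
    curves = []
    for (sid, rep), grp in df.groupby(["sample_id", "replicate"]):
        meta = {
            "sample_id": sid,
            "replicate": int(rep),
            "temperature_c": float(grp["temperature_c"].iloc[0]),
            "o2_percent": float(grp["o2_percent"].iloc[0]),
            "ph": float(grp["ph"].iloc[0]),
        }
        curves.append(ResponseCurve(driver, grp[xcol].to_numpy(dtype=float),
                                    grp["assimilation"].to_numpy(dtype=float), meta))
    return curves
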