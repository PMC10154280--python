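# Methods

This note documents the models, parameter choices, numerical decisions and
known limitations of `ccmgasex`.

## Compensation-point model

Net assimilation of a rubisco-limited cell vanishes at

Γ_CO2 = [(0.5/S_c/o + K_c·r/K_o)/(1 − r)]·O + K_c·r/(1 − r),  r = R_L/V_cmax,

all concentrations dissolved (µM).  Assumptions: steady state, no CCM, no
RuBP limitation, 0.5 CO₂ released per oxygenation, and V_cmax well
approximated by the cellular maximal assimilation rate A_max (which is why
the respiration term enters as a ratio r supplied directly rather than an
absolute R_L — the packaged values are r = 0.13 at 40 °C and 0.07 at
30 °C, from light-response measurements on the study organism).  Γ is
exactly linear in O; `gamma_grid` nevertheless computes the per-combination
oxygen slope both analytically and by OLS across the O levels and
cross-asserts them, because the OLS route is the one a measured dataset
must use.

The packaged kinetic sets are the published 25 °C values for three
thermophilic red algae (S_c/o 224.6, 238.1, 166; K_c 6.7, 6.6, 3.3 µM) with
a single K_o (374 µM) — only one species has a published K_o, and that
value is shared across all combinations.  The grid forms all 3 × 3
specificity × K_c crosses rather than only the species-matched triplets:
the parameters are reported independently, and because the slope separates
into a specificity term and a K_c term the extrema are the same either way.

## Temperature adjustment

Parameters shift from the 25 °C reference by Q10 power laws,
P(T) = P(25 °C)·Q10^((T−25)/10).  Two conventions matter:

* **S_c/o** (liquid phase): two Q10 values are published with different
  base temperatures, 0.60 at 25 °C and 0.62 at 35 °C.  They are applied
  piecewise by decade — 0.60 over 25→35 °C, 0.62 above — so 40 °C uses
  0.60 · 0.62^0.5.  The published modelled slope range is reproduced to
  better than 1 % under this reading (7007 and 11,182 recomputed against
  7046 and 11,153 printed); we know of no other reading that does, but the
  original calculation chain is not published, so the piecewise rule is
  documented here as this package's interpretation.
* **K_c, K_o**: their Q10 values (2.24, 1.63) are defined on
  partial-pressure units (µbar, mbar).  The µM constant is converted to
  partial pressure with Henry's law at 25 °C, scaled, and converted back
  at T; both forms are returned and their mutual consistency is asserted
  at relative 1e-9.

Adjustment below 25 °C is refused: the decade rules are stated upward only.

## Gas solubility and dissolved O₂

Henry constants (CO₂: 0.035 mol kg⁻¹ bar⁻¹, B = 2400 K; O₂: 0.0012,
B = 1700 K) follow H(T) = H₂₉₈·exp[B(1/T − 1/298.15)].  Partial pressure is
mole fraction × total pressure (101,325 Pa default), ignoring water-vapour
displacement and fugacity.  Dissolved amounts are computed in mol/kg and
converted to µM through the density of pure water — a quadratic in
temperature fit once to an 11-point 0–50 °C standard table and frozen
(coefficients in `data/water_density.json`); the density step changes
results by under 1 % but keeps the unit chain honest.  Salinity corrections
are deliberately omitted (dilute acidic freshwater media).

Direct computation gives dissolved O₂ of ≈18.5/193/387 µM for 2/21/40 % O₂
at 40 °C and ≈232 µM for 21 % at 30 °C, whereas the canonical values used
in the original Γ calculations are 20/209/398/251 µM.  The published
provenance of those values is not stated and they are not exactly
reproduced by the published Henry constants.  `dissolved_o2` therefore
defaults to the canonical table (`mode="canonical"`) so that Γ-range results
match the published framework, with `mode="physics"` recomputing any
condition from Henry's law.  The difference propagates to Γ at the few-
percent level.

## Hypothetical-kinetics scenario

`hypothetical_gamma` answers "could any plausible rubisco explain a low
measured compensation point?": it doubles the *temperature-adjusted*
maximum S_c/o and halves the adjusted minimum K_c (extrema taken after
adjustment, which matters because adjustment reorders nothing but rescales
unevenly between phases), then evaluates Γ.  At 40 °C, r = 0.13, O =
209 µM this gives 1.29 µM ≈ 1.3 µM at two significant figures — still above
compensation points measured on the study organism, which is the argument
that even hypothetically generous kinetics cannot replace a CCM.

## Carbonate speciation

Pools follow the open-system convention: CO₂(aq) fixed by Henry's law
(hence identical across pH), HCO₃⁻ = CO₂(aq)·K1/[H⁺], CO₃²⁻ =
HCO₃⁻·K2/[H⁺].  Activity coefficients are 1, pH is the free hydrogen-ion
exponent, constants are mol/kg with a density conversion to µM at output.

Two dissociation-constant sets ship:

* `lueker00` (default): the Lueker et al. (2000) seawater-calibrated
  constants evaluated at salinity 0.  Zero salinity extrapolates these
  constants outside their calibration range, but it is what general-purpose
  carbonate packages return for S = 0 input, and it is the set under which
  bicarbonate comprises ≈0.50 of the Ci pool at pH 6 and 40 °C
  (pK1(40 °C) ≈ 6.00) — the behaviour the bicarbonate-uptake analyses in
  this package are calibrated against.
* `plummer82`: Plummer & Busenberg (1982), the standard true-freshwater
  thermodynamic formulation (pK1 = 6.35 at 25 °C, 6.30 at 40 °C).  Under
  it bicarbonate is ≈1/3 of the pool at pH 6/40 °C.  This set is
  recommended whenever freshwater accuracy, rather than consistency with
  marine-package output, is the goal, and it is the set cross-checked in
  the tests against an independently computed oracle (Harned & Davis /
  Harned & Scholes dissociation constants with Weiss solubility; agreement
  within 5 % on HCO₃⁻ at pH 7.5–8).

The divergence between the two sets is itself a caution: "half the pool at
pH 6" versus "a third of the pool" is a constant-set artefact, while the
qualitative contrast driving the uptake experiment — bicarbonate negligible
at pH 2, substantial at pH 6, CO₂(aq) unchanged — holds under both.

"Accessible Ci" is CO₂(aq) + β·HCO₃⁻ with β ∈ {0, 1}; carbonate is never
accessible.  β = 1 roughly doubles the accessible pool at pH 6 relative to
pH 2, which halves the apparent headspace-ppm K_m — the observable the
pH-comparison tests target.

## Gas-exchange pipeline

* **Headspace correction**: headspace = (reference − ΔC) − (µᵢ/µᵢ_sub)·ΔC
  with ΔC = reference − sample chamber (positive when cells consume CO₂)
  and µᵢ_sub = 233 µmol s⁻¹ as the instrument constant.  Negative results
  are clamped to zero, flagged per record, and counted.
* **Michaelis–Menten fit**: scipy nonlinear least squares of
  A = A_max·C/(K_m + C), positivity-bounded, with 95 % confidence
  half-intervals from the linearized covariance at the optimum and a
  t(n−2) critical value (not profile likelihood).  An optional strict
  `x < max_driver` cutoff (e.g., < 700 ppm) excludes supersaturating
  points.
* **Compensation point**: OLS on points with driver ≤ 100 ppm (inclusive);
  Γ = −intercept/slope; a nonpositive slope raises rather than returning a
  meaningless intercept.  Because the window is a secant through a convex
  response, Γ̂ carries a curvature bias of order (window/K_m)² — about 5 %
  at the default synthetic parameters — vanishing as the window shrinks;
  fitting in ppm and converting versus converting then fitting agree to
  0.5 % over the window (the Henry mapping is linear in concentration).
* **Kok respiration**: OLS on incident light 10–30 µmol m⁻² s⁻¹
  (incident, not absorbed, units); R_L = −intercept.
* **Oxygen response**: one OLS slope per replicate across its O₂ levels,
  aggregated as mean ± 2·SE over replicates; a single replicate yields a
  slope with an undefined-SE flag; unbalanced designs are tolerated and
  flagged.  A ±2·SE band with few replicates under-covers relative to the
  normal 95 % (e.g., ~90 % at 6 replicates), which the tests account for.
* **pH comparison**: two one-sided Welch tests per parameter — the
  "half-mean" test compares the pH 6 sample against the pH 2 sample scaled
  by 0.5 (scaling the variance by 0.25) with alternative
  mean(pH6) < mean(pH2)/2, and the plain greater test pH 2 > pH 6.  The
  half-mean construction (scaling one sample rather than testing a ratio)
  is one of several defensible formalizations of "the pH 6 means are half
  the pH 2 means"; it is exact under the scaled null and is documented
  here as this package's choice.

## Synthetic data

The generator stands in for raw instrument exports (none are publicly
deposited for the motivating study) and encodes the study conditions as
defaults: 40 °C, A_max = 35 pmol µg Chl a⁻¹ s⁻¹, r = R_L/A_max = 0.13,
apparent K_m = 200 ppm headspace, O₂ levels 20/209/398 µM, measured-scale
oxygen slope 5425 pM/µM, 3 replicates, additive homoscedastic Gaussian
noise with sd = 5 % of A_max (a package choice, not an instrument claim).

* CO₂ response: offset Michaelis–Menten,
  A(C) = (A_max + R_L)·C/(K_m + C) − R_L, chosen so one curve gives the MM
  fit, the compensation-point fit (closed-form Γ = K_m·R_L/A_max) and a
  respiration offset meaningful targets simultaneously.
* Light response: exactly linear (φ·I − R_L) through the Kok window, then
  C¹-smooth exponential saturation toward A_max above a breakpoint —
  exact-linearity in the window is what makes noise-free Kok recovery
  exact rather than approximate.
* Oxygen response: replicate Γ(O) lines either from a configured slope or
  from the kinetics grid (combinations assigned round-robin across
  replicates), with an attenuation factor in (0, 1] on the slope emulating
  a CCM's damping of oxygen sensitivity.
* pH experiment: the response model is driven by the accessible-Ci pool at
  each record's pH, so β = 1 produces the halved apparent K_m at pH 6 and
  β = 0 produces identical curves, up to noise.

Seeding: replicate i of a dataset seeded s draws from
`SeedSequence(entropy=(s, i))` (pH experiments add a pH index), so outputs
are byte-reproducible and earlier replicates are unchanged when the
replicate count grows.

What the generator does *not* emulate: instrument drift and matching
artefacts, heteroscedastic or autocorrelated noise, chamber equilibration
dynamics, light-absorption variation between samples, and biological
replicate-to-replicate parameter variation.  Passing recovery tests on this
generator therefore demonstrate correctness of the estimators under the
stated statistical model, not robustness to real instrument pathology.

## Problem sizes and numerics

The Monte-Carlo checks use 500 simulated curves for confidence-interval
coverage and 1000 replicate sets for slope-recovery rates, sizes at which
the binomial uncertainty on a ~0.9 coverage estimate is ~1 %.  Parameter
grids: the 3 × 3 × 3 kinetics grid for the modelled slope range, a
12-point ppm grid for CO₂ responses and an 11-point grid for light
responses.  Degenerate inputs fail loudly: fewer than 3 points for an MM
fit, fewer than 2 distinct O₂ levels for a slope, r ≥ 1, nonpositive
flows, out-of-range temperatures.  Tie-break conventions: compensation
window inclusive (≤), MM cutoff strict (<), Kok window inclusive on both
edges.

## Known limitations

* The S_c/o piecewise-decade Q10 rule and the half-mean test construction
  are interpretations of under-specified published procedure (see above);
  both are flagged where implemented.
* The canonical dissolved-O₂ table cannot be derived from the packaged
  Henry constants; physics mode and canonical mode differ by up to ~8 %.
* Speciation beyond pH ~8 (borate, ion pairing, activity corrections) is
  out of scope; the module targets the acidic-to-neutral range.
* Gas-phase (µbar) compensation points for leaves, instrument acquisition
  logic (averaging, analyzer matching), and mechanistic CCM simulation are
  out of scope.
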