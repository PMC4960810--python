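# Methods

This note documents the models, numerical choices and limitations behind
`prodrugpk`, in the package's own terms.

## Plasma model

Plasma kinetics after an IV bolus are described by the standard mammillary
two-compartment model, parameterised by clearance CL (L/h/kg), central
volume V1 (L/kg), inter-compartment clearance Q (L/h/kg) and peripheral
volume V2 (L/kg). The micro rate constants are k10 = CL/V1, k12 = Q/V1,
k21 = Q/V2, giving a bi-exponential unit-dose response with exponents
alpha > beta > 0 (roots of x² − (k10+k12+k21)x + k10·k21) and coefficients
A = (alpha−k21)/(V1(alpha−beta)), B = (k21−beta)/(V1(alpha−beta)). The
macro constants are always derived from the micro parameters, never
user-supplied, so A, B ≥ 0 and the exponent ordering hold by construction.
Multi-dose curves are sums of time-shifted single-dose curves
(superposition), which presumes dose-linear kinetics; dose instants
evaluate as right limits (post-dose concentration). All quantities are per
kg body weight; no absolute body-weight scaling is performed.

`ode_reference` integrates the equivalent amount-balance ODE system with
LSODA (default rtol 1e-10) and is used purely as a cross-check of the
analytic path; the two agree to better than 1e-6 relative across random
parameter sets in the test suite.

**Default parameters** (packaged config, version 1.0): CL = 17.7 L/h/kg,
V1 = 23.4 L/kg, Q = 22.9 L/kg/h, V2 = 58.1 L/kg. These are the package's
own reconstruction from the reported non-compartmental estimates for the
prodrug (CL 17.7 L/h/kg, Vss 81.5 L/kg, terminal t½ 4.6 h, Cmax ≈ 141 ng/mL
at 3.3 mg/kg): V1 = dose/C(0⁺), V2 = Vss − V1, and Q solved so the slow
exponent equals ln2/4.6 h⁻¹. They are package defaults consistent with
those summary values, not published micro-parameters.

## Non-compartmental analysis

* AUC uses the linear trapezoid by default (lin-up/log-down optional; the
  method is recorded in the result). AUC(0–t) runs from the first sample to
  the last quantifiable point, with no back-extrapolation to t = 0; the
  0 → 5 min segment of the nine-point design is therefore not included,
  matching how a 24-h exposure is computed from the observed grid.
* λz is estimated by log-linear OLS. Automatic selection evaluates the last
  k quantifiable points for k = 3 … all points strictly after Tmax (Tmax
  excluded), keeps the maximal adjusted R², and breaks ties (within 1e-12)
  toward more points. A non-declining terminal phase raises a "no valid
  fit" error; `run_nca` then returns an AUC-only result with the
  extrapolation-dependent fields marked unavailable.
* AUC(0–∞) extrapolates from the *observed* last quantifiable concentration
  (C_last/λz); AUMC adds C_last·t_last/λz + C_last/λz². MRT = AUMC/AUC,
  CL = Dose/AUC(0–∞), Vz = CL/λz, Vss = CL·MRT.
* Units are explicit: dose in mg/kg over AUC in h·ng/mL yields CL in L/h/kg
  through the exact factor 10⁶ ng/mg ÷ 10⁶ mL/L (leaving ×10³ for mL → L),
  never a silent magnitude assumption. Tumor profiles (ng/g tissue) get
  exposure metrics only; clearance/volume fields stay NaN because a
  plasma-volume interpretation does not apply and no tissue-density
  conversion is attempted.
* BLQ policy: pre-Tmax BLQ values are set to zero, BLQ points at or after
  Tmax are excluded, so t_last is the last quantifiable sample. Flagged
  values are retained by the generators and resolved here, exercising the
  common case of an unquantifiable 24-h plasma sample.

## Tumor drug link (synthetic data only)

Tumor drug content is generated from plasma via a first-order link
dCt/dt = k_in·Cp(t) − k_out·Ct, Ct(0) = 0, solved by an exponential
integrator that is exact for piecewise-linear Cp. The defaults
(k_in = 2.7 h⁻¹, k_out = 4.0 h⁻¹, stored in the versioned default config)
were calibrated to the study's qualitative anchors: peak tumor
concentration ≈ 50 ng/g at ~15–25 min and a >10-fold decline by 24 h.

*Limitation:* with a plasma driver whose terminal half-life is 4.6 h, a
first-order link cannot simultaneously put the peak at 15 min and hold
~2 ng/g at 24 h (the observed 24-h tumor residual implies slower tissue
elimination than any single first-order k_out compatible with the early
peak). The defaults honour the peak-time and fold-decline anchors; the
absolute 24-h trough is lower than observed in vivo. Whether tumor drug
formation is flow- or enzyme-limited is unknown; this link is a stand-in,
not a mechanistic claim.

## Growth-inhibition model

dT/dt = [kg − Imax·C(t)/(IC50 + C(t))]·T, T(0) = T0, with C(t) the plasma
prodrug concentration. Imax is a rate (1/day), so Imax > kg permits
regression during exposure; growth is unbounded exponential (no logistic
cap) because ~3-week untreated courses show no plateau. Since the equation
is linear in log T, the solver evaluates the exact solution
T = T0·exp(kg·t − Imax·H(t)) with H(t) = ∫C/(IC50+C) ds computed by
trapezoidal quadrature on a 0.05-h grid refined at dose instants;
quadrature error is far below data noise and burden positivity is
automatic. Driving the effect with tumor drug content instead of plasma is
possible by supplying a different driver profile upstream; plasma is the
default because regimen simulations are defined on plasma kinetics.

**Defaults** (config v1.0): T0 = 100 mm³, kg = 0.25 day⁻¹, Imax = 1.5
day⁻¹, IC50 = 15 ng/mL — chosen so an untreated tumor grows ~190-fold in
three weeks while the 3.3 mg/kg ×3 regimen roughly halts net growth during
treatment, matching the qualitative behaviour of the emulated study arms.

**Estimation.** Weighted least squares on burden means, weights
1/max(SD, floor)² with floor = 1 mm³ (so zero-SD points cannot dominate),
minimised by Nelder–Mead in log-parameter space from multiple seeded starts
(default 16; the truth-initialised recovery experiments use 2–4 since the
objective there is locally well-behaved). Box bounds, when given, are
enforced by a quadratic log-space penalty. With only drug-free arms, Imax
and IC50 enter the likelihood nowhere; they are flagged unidentifiable and
held at their initial values while T0 and kg are fitted. With a single dose
level they are still nearly confounded post-treatment (only
Imax·H(∞; IC50) is identified), so the recovery experiments and the
recommended design fit jointly across untreated + 3.3/10/20 mg/kg arms,
which separates the two through the nonlinearity of H in dose.

Daily (24 h) dose spacing is the default regimen convention; any spacing
can be configured through explicit dose-event lists.

## Calibration

Unweighted OLS of counts/s on concentration (weighted optional), requiring
≥ 2 distinct standards; the five-point design 0–1500 µM is the reference
layout. Inversion subtracts a per-series scalar background (baseline flux
is treated as constant over time) and the intercept, divides by the slope,
and clamps negative results to zero with a BLQ flag. Standards are retained
on the curve object for audit. Molar ↔ mass conversion (1 µM =
M ng/mL for molar mass M g/mol) requires an explicit molar mass; no
compound constant is built in. No spectral unmixing is performed: the
prodrug's fluorescence at the product's emission wavelengths is negligible,
so a single-channel model suffices.

## Statistics

Pearson correlation with the two-sided t-transform p-value (n−2 df);
paired two-tailed t-test on natural-log-transformed positive values, with
the geometric-mean ratio reported as fold change and zero within-pair
variance flagged as degenerate rather than producing a spurious statistic;
fold ratios of group mean AUCs. Natural logs are used throughout (t and p
are base-invariant). No multiple-testing correction is applied, and the
log-paired t mechanics are not extended to a full TOST bioequivalence
procedure.

## Synthetic data: what it does and does not emulate

Noise is multiplicative log-normal with σ² = ln(1+CV²), mean-preserving, so
empirical CVs match nominal ones and all quantities stay positive. Default
CVs — concentration 0.3, counts 0.2, burden 0.15, LLOQ 1 ng/mL — are of the
order of the between-animal scatter the emulated study reports (e.g. plasma
Cmax SE ≈ 20 % of the mean at n = 4); with LLOQ 1 ng/mL the 24-h plasma
sample falls below the limit, as in vivo. Identical (design, parameters,
seed) yield bit-identical outputs.

Not emulated: between-subject *parameter* variability (noise is residual
only, so all subjects share one true curve), assay-specific error
structure, enzyme-expression heterogeneity between tumors, pixel-level
imaging, survival endpoints. Passing tests therefore demonstrate
correctness of the estimators under the stated noise model, not robustness
to model misspecification in real animals.

## Problem sizes in the shipped experiments

The packaged experiments use: 100 random parameter sets for
analytic-vs-ODE agreement; 800-point dense profiles (to five terminal
half-lives) for NCA recovery; 200 replicate four-arm studies (8 days × 5
subjects per arm, 10 % burden CV, 2 optimiser starts) for PD recovery;
2000 subjects for the noise-CV calibration check; and 10 000 simulated
null datasets (n = 4) for the type-I-error check of the log-paired t-test.
These sizes give Monte-Carlo error comfortably below the tolerances they
are checked against.
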