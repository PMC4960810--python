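# prodrugpk

PK/PD analysis toolkit for preclinical studies of a fluorescent anticancer
prodrug system: the prodrug CNOB is activated in tumor tissue by an
engineered bacterial nitroreductase into the cytotoxic, natively fluorescent
product MCHB, which can be quantified non-invasively from live-animal
imaging. The package implements the analysis chain such a study needs —
from photon counts to dose-regimen predictions — together with a
seed-deterministic synthetic study generator so every stage is testable
without animal data.

It is written for pharmacometricians and imaging scientists running (or
re-analysing) small-animal prodrug studies, in the Model/Results style of
statsmodels: models are built from data, `fit()` returns a results object
with estimates, diagnostics and a `summary()`.

## What it computes

**Standard-curve calibration** (`StandardCurveModel`). ROI photon flux is
linear in MCHB concentration; an OLS (optionally weighted) line through
in-vitro standards, `counts/s = slope · C + intercept`, is fitted and
inverted (with background subtraction and zero-clamping) to convert imaging
series into concentration profiles.

**Non-compartmental analysis** (`NCA`). For an IV-bolus profile C(t):
Cmax/Tmax, trapezoidal AUC(0–t) (linear or lin-up/log-down), terminal slope
λz by log-linear regression with automatic point selection (max adjusted R²
over the last k ≥ 3 post-Tmax points, ties to more points), and

    AUC(0–∞) = AUC(0–t) + C_last/λz,       t½ = ln 2 / λz,
    CL = Dose/AUC(0–∞),  Vz = CL/λz,  MRT = AUMC/AUC,  Vss = CL·MRT,

with exact mg/kg ÷ h·ng/mL → L/h/kg unit bookkeeping and explicit policies
for below-LLOQ samples.

**Two-compartment IV simulation** (`simulate_2cmt_bolus`). Parameterised by
(CL, V1, Q, V2) per kg; the bi-exponential macro constants are derived, and
multi-dose curves are built by superposition (linear kinetics). An
independent ODE integration (`ode_reference`) cross-checks the analytic
path.

**Tumor growth inhibition** (`TumorGrowthModel`). An inhibitory-Emax effect
of plasma drug on net exponential growth,

    dT/dt = [kg − Imax · C(t)/(IC50 + C(t))] · T,

fitted to tumor-burden series by weighted least squares with multistart
Nelder–Mead, plus `compare_regimens` to rank dosing schedules by predicted
terminal burden.

**Statistics** (`pearson`, `log_paired_ttest`, `auc_fold_ratio`) for
method-agreement and exposure comparisons.

**Synthetic studies** (`generate_plasma_profiles`, `generate_tumor_profile`,
`generate_imaging_series`, `generate_tumor_growth`) reproducing the study
design the toolkit targets (3.3 mg/kg IV bolus, nine samples from 5 min to
24 h, n = 4; three-week growth courses under daily ×3 regimens, n = 5) with
mean-preserving log-normal noise and known ground truth.

## Worked example

```python
import numpy as np, prodrugpk as pp

cfg = pp.load_default_config()           # packaged study conditions
times = np.array(pp.synthetic.PAPER_SAMPLING_TIMES_H)
profile = pp.simulate_2cmt_bolus(cfg.pk, pp.DoseRegimen.single(3.3), times)
print(pp.run_nca(profile, 3.3).summary())
```

prints

```
Non-compartmental analysis: subject=sim matrix=plasma analyte=CNOB
dose=3.3 mg/kg, AUC method=linear
                Cmax        122.21
                Tmax      0.083333 h
             AUC_0-t        184.03 h*conc
           AUC_0-inf        187.38 h*conc
            lambda_z       0.15069 1/h
               t_1/2        4.5997 h
                  CL        17.611 L/h/kg
                  Vz        116.87 L/kg
                 Vss        81.209 L/kg
                 MRT        4.6112 h
   %AUC extrapolated        1.7879 %
```

i.e. NCA on the default two-compartment curve sampled at the nine study
time points returns the clearance (~17.6 L/h/kg), steady-state volume
(~81 L/kg) and terminal half-life (4.6 h) that the default parameters encode
— the Cmax of 122 ng/mL is the 5-min sample, below the true back-extrapolated
C(0⁺) of 141 ng/mL.

The same pipeline is available from the shell:

```bash
prodrugpk full-run --seed 11 --out out/   # simulate -> NCA -> PD fit -> regimens
prodrugpk nca --input out/plasma.csv --dose 3.3 --out out/nca.csv
prodrugpk compare-regimens --out out/regimens.csv
```

All artifacts are CSV/JSON and embed the seed and configuration hash;
re-running with the same seed reproduces them byte for byte.

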