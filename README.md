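# mvcal

Full-spectrum multivariate calibration for simultaneously quantifying
spectrally overlapping analytes by UV-Vis spectrophotometry — the classic
"three drugs, one cuvette" problem. When the absorption bands of analytes
such as theophylline (λmax ≈ 275 nm), montelukast (≈ 276 nm) and loratadine
(≈ 251 nm) overlap, no single wavelength resolves them; an inverse model
built on the whole spectrum does, with no physical separation step.

The package is for analytical chemists and chemometricians who want the
complete first-order calibration workflow as tested, scriptable code:
calibration-set design, model fitting, factor selection, validation
statistics and net-analyte-signal figures of merit.

## What it computes

Given calibration spectra **X** (n samples × p wavelengths, AU) and
reference concentrations **c** (mg/L) for one analyte at a time, each model
produces a regression vector **b** with ĉ = **r**ᵀ**b** (+ centering terms)
for an unknown spectrum **r**:

- **PLS1** — partial least squares via NIPALS, deflating X only;
- **PCR** — regression of c on the leading principal-component scores of
  centered X;
- **HLA** — hybrid linear analysis: subtract the analyte's own contribution
  **c s**ₖᵀ from X, model the residual interference space by truncated SVD,
  and quantify through the net analyte signal **s**ₖ\* (the part of the
  unit-concentration pure spectrum **s**ₖ orthogonal to the interferences).

Around the models:

- face-centered **central composite designs** (2ᵏ + 2k + 1 runs, three
  levels) for calibration/validation sets;
- **leave-one-out cross-validation**: PRESS(A), SEP_CV(A), R²_CV(A) and the
  optimal factor count (minimum PRESS, or the Haaland–Thomas F-ratio rule);
- **prediction statistics**: RE%, mean |RE|, RMSEP, SEP, REP%, R²,
  recovery%;
- **figures of merit**: SEL = ‖**s**ₖ\*‖/‖**s**ₖ‖, SEN = ‖**s**ₖ\*‖,
  analytical sensitivity γ = SEN/‖ε‖ and LOD = 3‖ε‖/SEN = 3γ⁻¹, with ‖ε‖
  estimated from the NAS projections of blank spectra;
- a **synthetic three-drug simulator** (Gaussian-band pure spectra with the
  overlap structure above, Beer–Lambert mixing, instrument noise, optional
  plasma-like background) so the whole pipeline is testable without data
  downloads;
- the **published worked example**: the printed design, prediction,
  figures-of-merit and recovery tables of a three-drug determination study
  are embedded (misprints flagged, never corrected) and every
  desk-checkable number is recomputed by `mvcal reproduce-reference`.

## Worked example

```python
import numpy as np
from mvcal import (DesignSpec, central_composite_design, default_three_drug_spec,
                   make_pure_spectra, simulate_mixtures, simulate_blanks,
                   loo_press_curve, fit_pls1, predict, prediction_stats,
                   figures_of_merit)

spec = default_three_drug_spec(noise_sd=0.002, seed=42)
pure = make_pure_spectra(spec)
cal = central_composite_design(DesignSpec(n_factors=3, low=2, high=14, center=8))
val = central_composite_design(DesignSpec(n_factors=3, low=3, high=11, center=7))
X_cal = simulate_mixtures(cal, pure, spec)
X_val = simulate_mixtures(val, pure, spec, replicate=1)
blanks = simulate_blanks(50, spec)

y = cal.runs[:, 0]                      # theophylline, mg/L
cv = loo_press_curve(X_cal, y, "PLS1", A_max=6)
print("A_opt =", cv.A_opt, " PRESS =", np.round(cv.press, 4))
model = fit_pls1(X_cal, y, cv.A_opt, analyte="THEO")
stats = prediction_stats(predict(model, X_val), val.runs[:, 0])
print(f"RMSEP = {stats.rmsep:.4f} mg/L   REP = {stats.rep_percent:.2f}%   "
      f"R2 = {stats.r_squared:.5f}")
fom = figures_of_merit(model, pure.absorbance[0], blanks)
print(f"SEL = {fom.sel:.3f}   SEN = {fom.sen:.4f} AU/(mg/L)   "
      f"gamma^-1 = {fom.gamma_inv:.5f} mg/L   LOD = {fom.lod:.4f} mg/L")
```

prints

```
A_opt = 3  PRESS = [2.212003e+02 8.464150e+01 2.600000e-03 3.200000e-03 3.300000e-03
 3.400000e-03]
RMSEP = 0.0129 mg/L   REP = 0.18%   R2 = 0.99999
SEL = 0.362   SEN = 0.1470 AU/(mg/L)   gamma^-1 = 0.01292 mg/L   LOD = 0.0388 mg/L
```

PRESS collapses by five orders of magnitude at A = 3 — the true chemical
rank of a three-component system — and stays flat beyond it, so minimum
PRESS selects 3 factors. At 0.002 AU instrument noise the validation-set
errors are a fraction of a percent; the selectivity of 0.36 says roughly a
third of the theophylline signal survives the overlap with the other two
drugs, and concentration differences below ~0.013 mg/L are indistinguishable
from noise (γ⁻¹), giving a detection limit of about 0.04 mg/L.

The same pipeline runs from the shell:

```bash
mvcal simulate --noise 0.002 --seed 7 -o sim/
mvcal crossval --method pls1 --amax 6 --analyte THEO \
      -X sim/spectra.csv -y sim/concentrations.csv -o cv.json
mvcal fit --method pls1 --factors 3 --analyte THEO \
      -X sim/spectra.csv -y sim/concentrations.csv -o model.json
mvcal fom -m model.json --pure sim/pure_spectra.csv --blanks sim/blanks.csv -o fom.json
mvcal run --seed 7 -o runout/        # end-to-end with summary.json
```

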