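# Methods

## The calibration problem

The package treats first-order (vector-per-sample) inverse calibration
under the Beer–Lambert assumption: an absorbance spectrum of a mixture is a
non-negative linear combination of unit-concentration pure-component
spectra plus instrument noise and, optionally, a smooth matrix background.
Each analyte is calibrated separately against the full spectrum, so
interferents need not be known or modelled explicitly — they only need to
vary across the calibration set, which is what the central composite design
guarantees.

All three regression methods assume linearity of response, a shared uniform
wavelength grid, and errors concentrated in the spectra rather than the
reference concentrations. None of them handles wavelength shifts,
stray-light nonlinearity or detector saturation; the working window should
exclude saturated regions before fitting (`restrict_window`).

## Models

**PLS1 (NIPALS).** For a single response the NIPALS component step is
non-iterative: w = Xᵀy/‖Xᵀy‖, t = Xw, p = Xᵀt/tᵀt, q = yᵀt/tᵀt, then X is
deflated by t pᵀ (y is not deflated; its residual structure is carried by
the per-component loadings q). The composite regression vector is
b = W(PᵀW)⁻¹q. X and y are mean-centered; no column scaling is applied,
since absorbance shares units across channels.

**PCR.** Truncated SVD of centered X; y is regressed on the first A scores.
Because the scores are orthogonal, the per-component coefficients are
independent and the A-factor model is nested in the (A+1)-factor model —
which is what makes the leave-one-out curves cheap (one SVD per fold).

**HLA.** With s_k the analyte's unit-concentration spectrum (supplied, or
estimated as Xᵀy/yᵀy), the analyte's contribution y s_kᵀ is removed from X
and the top-A right singular vectors of the residual matrix span the
interference space. The net analyte signal s_k* is s_k minus its projection
onto that space, and b = s_k*/(s_k*ᵀ s_k*), so prediction is a scalar
projection. HLA is uncentered by default — it operates on raw Beer–Lambert
signals, and an all-zero blank then predicts exactly 0 mg/L — with a
`centered=True` opt-in. When s_k is estimated from the calibration set
itself, the estimate is contaminated by interferents in proportion to the
design correlations, but the contamination lies inside the interference
space and cancels exactly on noiseless data (the calibration coefficient of
the analyte term is yᵀy/yᵀy = 1); the tests exercise both routes.

On noiseless K-component data of full rank, PLS1(A=K), PCR(A=K),
HLA(A=K−1) and classical least squares with known pure spectra coincide;
this method-equivalence property is the package's main correctness oracle.

## Factor selection

Leave-one-out cross-validation is used throughout: with 15-sample
calibration designs it is cheap, and it needs no fold-assignment
convention. PRESS(A) = Σᵢ(ĉ₋ᵢ(A) − cᵢ)², SEP_CV = √(PRESS/n),
R²_CV = 1 − PRESS/SS_tot. `A_max` may not exceed n − 2 so every fold
supports the largest model. Two selection rules are exposed:

- `min_press` (default): argmin PRESS, ties broken toward smaller A;
- `f_ratio`: the smallest A with PRESS(A) ≤ F(0.75; n, n) · min PRESS
  (Haaland–Thomas). Minimum PRESS alone can chase noise into very high
  factor counts on small sample sets, and published factor counts in this
  field sometimes reflect such curves; the parsimony rule is the remedy.

## Prediction statistics

RMSEP uses denominator m − 1 by default, with m available as a parameter —
published worked examples in this area are internally consistent with
neither choice once predictions are rounded, so the package exposes both
and asserts neither against printed RMSEP values. SEP is always
√(Σ(ĉ−c)²/m). REP% = 100·RMSEP/c̄, so REP·c̄/100 ≡ RMSEP holds exactly by
construction. The mean relative error reported for prediction tables is the
mean of *absolute* per-sample RE% — recomputation of the embedded reference
tables confirms that only the absolute-value reading reproduces all nine
printed summary values (signed means are near zero).

## Figures of merit

SEL = ‖s_k*‖/‖s_k‖, SEN = ‖s_k*‖, γ = SEN/‖ε‖, LOD = 3‖ε‖/SEN ≡ 3γ⁻¹.
For PLS1/PCR the NAS vector is recovered from the regression vector as
s_k* = b/‖b‖², so SEN = 1/‖b‖; HLA carries its NAS explicitly. The noise
norm ‖ε‖ is the sample SD over ≥3 blanks of the signed scalar projection
r_blankᵀ s_k*/‖s_k*‖; the algebraically identical alternative (SD of
predicted blank concentrations × SEN) is not separately implemented. The
LOD expression is implemented in the 3‖ε‖/‖s_k*‖ form, the only reading
consistent with LOD = 3γ⁻¹ across every column of the embedded
figures-of-merit table. Jointly rescaling all spectra by a factor c scales
SEN and ‖ε‖ by c and leaves SEL, γ and LOD invariant (tested).

Degenerate cases: ‖s_k*‖/‖s_k‖ < 1e-10 raises (analyte inside the
interference space — HLA cannot quantify it); zero blank noise flags
infinite γ with a warning and reports LOD = 0.

## Experimental design

The face-centered central composite design (α = 1) is used: 2ᵏ factorial
vertices at {low, high}, 2k axial runs on the cube faces, one center run —
15 runs at three levels for k = 3, with each factor at low/center/high in
exactly 5/5/5 runs. Only three concentration levels appear in the embedded
reference design, which is what fixes α = 1 rather than a rotatable
scaling. Run order is canonical (factorial block, axial pairs, center);
the printed order of the reference table is preserved separately in
`reference_tables` for exact reproduction.

## Wavelength windows

Windows are half-open, [low, high): restricting a 1-nm grid to [225, 390)
keeps 165 points, matching the stated point count of the reference
measurements, whereas an inclusive window would keep 166. The half-open
convention is this package's choice — the measurement description does not
disambiguate — and is documented on `restrict_window`, which is idempotent
and preserves sample order.

## Synthetic data

The simulator emulates the *structure* the analysis relies on, not any
specific instrument: three Gaussian-band pure spectra peaking at 275, 276
and 251 nm with pairwise cosine similarity ≥ 0.5 (severe overlap), linear
mixing over the 2–14 mg/L working range, iid Gaussian channel noise
(default 0.002 AU — a typical benchtop UV-Vis noise floor, producing
validation errors on the same percent scale as published prediction
tables; no published noise magnitude exists for the reference instrument),
an optional proportional-noise mode, and a plasma-like background
(exponentially decaying baseline, per-sample log-normal amplitude) as a
deliberate stand-in for a deproteinized biological matrix.

What passing tests on this generator show: the estimators are correct and
well-behaved under the stated model (linearity, additive noise, smooth
background). What they do not show: robustness to band-shape misspecification,
wavelength registration errors, nonlinear detector response, or real plasma
chemistry — the generator has none of these.

All randomness derives from one integer seed; stream and replicate indices
offset the generator deterministically, so every dataset is reproducible
bit-for-bit.

## Numerical conventions

- SVD singular-vector signs are fixed (largest-magnitude element positive)
  so fitted models are identical across runs and platforms.
- Uniform-grid detection on CSV load tolerates 1e-9 relative step jitter.
- Spectra CSVs are written with %.17g and read with round-trip float
  parsing, so write→read is lossless for float64.
- Negative predicted concentrations are reported as-is (blanks legitimately
  predict slightly below zero); reference concentrations must be ≥ 0.
- PRESS ties select the smaller factor count.

## Problem sizes

The test suite and the acceptance script use 15-run designs on a 165-point
grid, 20 replicates for noisy parameter-recovery measurements, and 1000
blanks for noise-estimator calibration; the full suite runs in a few
seconds on one CPU.

## Known limitations

- PLS2, wavelength selection, outlier diagnostics beyond residuals, and
  IUPAC multivariate detection-limit intervals are out of scope.
- The embedded reference tables' factor counts, absolute SEN/SEL/γ values
  and recovery predictions depend on the original measured spectra and are
  reported/flagged but not recomputed — no digitized spectra exist to
  recompute them from.
- LOO is the only cross-validation flavor; for much larger calibration sets
  a k-fold scheme would be preferable.
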