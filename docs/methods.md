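# Methods

## Scope and data model

The package analyses absorbance FTIR spectra of dried microbial (fungal)
biomass on a uniform descending wavenumber grid, together with a GC
reference table of summed fatty-acid parameters — SAT, MUFA and PUFA as
percentage by weight of total fatty acids, closed to 100 % with minor
components. The default grid is 4000 → 500 cm⁻¹ at 2 cm⁻¹ spacing: IR
instruments with ~6 cm⁻¹ optical resolution digitize more finely, and
2 cm⁻¹ makes the nine-point derivative window span 16 cm⁻¹, comparable to
a lipid band width.

## Quality test

Instrument-vendor quality tests are proprietary, so the three admission
statistics are defined explicitly (windows follow common practice for
mid-IR biomass spectra) and documented as a reimplementation, not a clone:

* **max absorbance** over 2100–1600 cm⁻¹ (ester carbonyl + amide bands),
  threshold > 0.35 — rejects films too thin to quantify;
* **noise**: RMS of the first difference over the signal-free
  2100–2000 cm⁻¹ window, divided by √2 so it estimates the per-point
  noise sd; threshold < 1.5·10⁻⁵ absorbance;
* **water vapor**: peak-to-peak of the first difference over
  1847–1837 cm⁻¹, where sharp rotational lines sit on a flat background;
  threshold < 3·10⁻⁴.

First differences make both statistics insensitive to smooth baselines but
sensitive to point-to-point roughness; any sharp spectral structure inside
the windows would inflate them, which is exactly their purpose.

## Preprocessing

Order of operations: technical-replicate averaging → Savitzky-Golay
second derivative → EMSC. Averaging groups by (sample, run, well) and
takes the pointwise mean of surviving replicates. Derivatives use a
nine-point, cubic Savitzky-Golay filter (the chemometrics default for
second derivatives; window and order configurable), differentiate with
respect to wavenumber (units absorbance·cm²) so results are
spacing-independent, and evaluate the boundary-window polynomial at the
edges so the grid length is preserved. Second derivatives resolve
overlapping lipid bands and annihilate linear baselines; the cubic fit
over a 16 cm⁻¹ window biases the derivative of a band of width σ by
O((window/σ)²), about 0.7 % of peak for σ = 50 cm⁻¹ and 10 % for
σ = 12 cm⁻¹ — acceptable because calibration only needs a reproducible,
approximately linear transform, not an exact derivative.

EMSC fits each spectrum on the 3050–700 cm⁻¹ region as
a + b·m(ν) + d₁P₁(u) + d₂P₂(u), with m the set mean (stored with the
model so prediction-time spectra are corrected against the same
reference), Pₖ Legendre polynomials on the region mapped to [−1, 1], and
returns (x − a − ΣdₖPₖ)/b. The quadratic ("basic") EMSC model is the
default; the order is configurable. Fits with b ≤ 0 are flagged rather
than silently divided. EMSC is applied after derivation, following the
stated stage order of the workflow; since both operations are linear this
mainly affects which distortions the polynomial terms absorb.

## Lipid markers

Markers are computed on EMSC-corrected absorbance-domain spectra (peak
areas and maxima are conventionally read from absorbance, not derivative,
spectra; the functions accept any SpectraSet, so the choice is
configurable). Band areas are trapezoidal integrals against wavenumber
with an optional local-linear baseline — the chord between the band's
endpoint absorbances — which is the default, as is common for isolated
bands. The unsaturation index is the olefinic (3020–2993 cm⁻¹) over CH₂
(2946–2902 cm⁻¹) area ratio; it is scale-invariant and flagged undefined
(NaN) when the CH₂ area is non-positive. The C=O marker is the absorbance
at the grid point nearest 1740 cm⁻¹ after chord subtraction across
±20 cm⁻¹. The olefinic peak position is the argmax over the
3030–2993 cm⁻¹ search window at grid resolution, ties broken toward
higher wavenumber; saturation-related shifts are conventionally reported
in whole wavenumbers, so no sub-grid interpolation is applied by default.

## PCA and PLS calibration

PCA is a mean-centred SVD of the 3200–2800 cm⁻¹ (fatty-acid region)
sub-matrix; component signs are fixed by making each loading's
largest-magnitude element positive, so results are deterministic.
Explained-variance ratios derive from the squared singular values. When
PCA is run on EMSC output (which starts at 3050 cm⁻¹) the region clips to
the available grid; the 3200–3050 cm⁻¹ stretch is essentially featureless.

Calibration is one univariate PLS1 model per target (SAT, MUFA, PUFA) —
separate models can choose different factor counts, which a single
multi-response PLS2 model could not. The NIPALS extraction, deflation and
regression-vector assembly are implemented directly (and cross-checked in
the test suite against scikit-learn's PLS and against ordinary least
squares at full rank). "Full cross-validation" means leave-one-out over
the averaged samples; leave-group-out by an arbitrary grouping is
available because replicate-structured designs otherwise leak between
folds. The factor count is the smallest one whose RMSECV is within 2 % of
the curve minimum (margin rule); an F-ratio test on PRESS values is
selectable. R² is reported as the squared Pearson correlation between
held-out predictions and reference values, with one guard: when that
correlation is negative the reported R² is 0. Under leave-one-out a
no-signal model predicts the training-fold mean (n·ȳ − yᵢ)/(n − 1), which
is perfectly *anti*-correlated with yᵢ; squaring alone would report that
artifact as skill, and the guard makes a permutation null correctly read
as ≈ 0 while leaving genuine calibrations untouched.

Fitted models carry their preprocessing provenance (grid size,
Savitzky-Golay settings, EMSC region and order) and refuse to predict
spectra whose declared provenance differs. Serialization is plain JSON.

## Synthetic-study generator

The generator emulates the screening design: 5 strains × 5 media
(glucose, sucrose, canola / olive / sunflower oil) × 3 runs × 2 wells ×
3 technical replicates = 450 spectra over 150 biological samples.
Compositions are base (SAT 30, MUFA 40, PUFA 30) plus zero-sum strain and
medium offsets — oil media push toward MUFA and higher lipid load,
carbohydrate media toward PUFA, olive being the most saturated oil — plus
iid biological noise (sd 2 % per component, then re-closed to 100 %).
Technical replicates share a composition and differ only in artifact
draws. The pure spectrum is a sum of Gaussian bands whose amplitudes are
linear in (SAT, MUFA, PUFA, total lipid); the olefinic band (default
centre 3008 cm⁻¹, σ 6) responds only to unsaturated fatty acids and the
ester C=O band (1740 cm⁻¹) only to total lipid, so the markers have exact
ground truth. Gaussian shapes (rather than Voigt) keep band areas and
derivatives analytically integrable for test oracles.

Recorded spectra are a + b·pure + c₁P₁ + c₂P₂ + vapor + noise: offset
a ~ U(−0.02, 0.02), scatter b ~ U(0.9, 1.1), Legendre baseline terms
U(±2·10⁻³), a fixed comb of 15 water-vapor lines in 1900–1300 cm⁻¹
(σ 1.2 cm⁻¹, two lines inside the QC window) with per-spectrum amplitude
U(0, 1.2·10⁻⁴), and iid noise of sd 8·10⁻⁶ absorbance. These defaults
sit below the QC thresholds the way accepted instrument spectra do —
real campaigns discard the failures before analysis — while giving EMSC
genuine distortions to remove. GC reference values are the true
compositions plus iid measurement noise (sd 1 % of total fat, the
dominant error floor of the calibration) and an optional per-run bias
that reproduces day-effect clustering when enabled (off by default).

What the generator does **not** emulate: Mie-type wavelength-dependent
scattering, instrument line-shape convolution, band-position or width
variation with composition, correlated (pink) detector noise, atmospheric
CO₂, and any nonlinearity between composition and absorbance. Passing
tests therefore demonstrate that the analysis chain recovers a known
forward model under realistic additive/multiplicative distortions — not
that a real instrument campaign would reach the same figures of merit.

## Problem sizes and determinism

All stochastic stages draw from numpy Generators seeded from one master
seed via SeedSequence spawning, so studies, pipelines and reports are
bit-reproducible. The shipped study size (450 spectra × 1751 points,
LOO over 150 samples at up to 15 factors) runs the whole chain in well
under a minute; tests use the same sizes or smaller.

## Known limitations

* EMSC has no interference-spectrum or multi-reference extensions.
* No variable selection (iPLS, jackknifing) and no PLS2.
* The quality-test statistics are stated substitutes for the instrument
  vendor's unpublished formulas; thresholds are taken at face value.
* JCAMP-DX support is read-only and limited to single-block AFFN XYDATA.
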