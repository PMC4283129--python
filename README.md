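# ftirlip

FTIR-based screening of microbial fatty-acid profiles.

High-throughput FTIR spectroscopy can estimate the lipid composition of
fungal biomass directly from dried-cell films, replacing (or triaging ahead
of) slow gas-chromatography reference analysis. `ftirlip` implements the
full chemometric chain such a screen needs:

* **quality control** of raw absorbance spectra (signal level, noise,
  water-vapor contamination),
* **preprocessing** — technical-replicate averaging, nine-point
  Savitzky-Golay second derivatives, and extended multiplicative signal
  correction (EMSC) on the 3050–700 cm⁻¹ region,
* **univariate lipid markers** — the unsaturation index (olefinic C=CH
  band area 3020–2993 cm⁻¹ over the CH₂ band area 2946–2902 cm⁻¹), the
  ester C=O absorbance at 1740 cm⁻¹ (total-lipid proxy) and the olefinic
  peak-maximum position (3010/3008/3006 cm⁻¹ shifts track saturation),
* **multivariate analysis** — PCA of the fatty-acid region
  (3200–2800 cm⁻¹) and PLS1 calibration of SAT/MUFA/PUFA (% of total
  fatty acids, from GC) on the preprocessed spectra, with leave-one-out
  cross-validation, RMSECV-based factor selection and R² reporting,
* a **synthetic-study generator** that emulates the whole experimental
  design — 5 strains × 5 media × 3 runs × 2 wells × 3 technical
  replicates = 450 spectra over 150 biological samples, with Gaussian
  lipid bands driven by the true composition plus multiplicative scatter,
  polynomial baselines, water-vapor combs and detector noise — so every
  stage is testable end to end without any instrument data.

## The model

Calibration is univariate PLS (PLS1, NIPALS). With centred spectra **X**
(n × p) and centred reference values **y**, each factor extracts the weight
vector **w** ∝ **Xᵀy**, scores **t** = **Xw**, loadings **p** = **Xᵀt**/**tᵀt**,
q = **yᵀt**/**tᵀt**, then deflates both blocks; the regression vector is
**b** = **W**(**PᵀW**)⁻¹**q**. Model size is chosen from the leave-one-out
RMSECV curve

RMSECV(f) = √( 1/n · Σᵢ (ŷ₋ᵢ(f) − yᵢ)² )

as the smallest factor count within 2 % of the curve minimum (a
Haaland–Thomas style F-test rule is available). R² is the squared Pearson
correlation between held-out predictions and the reference.

EMSC models each spectrum as a + b·m(ν) + Σ dₖ·Pₖ(ν) — a reference
spectrum m plus Legendre baseline polynomials — and returns
(x − a − Σ dₖPₖ)/b, removing additive, multiplicative and smooth baseline
distortions in one least-squares step.

## Worked example

```python
from ftirlip import (StudyDesign, average_technical_replicates, calibrate,
                     emsc, filter_set, generate_study,
                     savgol_second_derivative)

study = generate_study(StudyDesign(seed=1))
passing, report = filter_set(study.spectra)
averaged = average_technical_replicates(passing)
corrected = emsc(savgol_second_derivative(averaged)).corrected
results, table = calibrate(corrected, study.reference, max_factors=15)
print(table.to_string(index=False))
print(results["MUFA"].summary())
```

prints

```
Fatty acid   RMSECV       R2  Factors
       SAT 1.003442 0.948292        3
      MUFA 1.087137 0.985111        3
      PUFA 1.072522 0.984111        3

PLS1 calibration: MUFA
========================================
samples:            150
variables:          1176
factors:            3  (rule: margin)
cross-validation:   loo
RMSECV:             1.087 % of total fat
R^2 (CV):           0.985
```

450 generated spectra pass the quality test and average to 150 samples;
each fatty-acid parameter is then recovered from the spectra with a
cross-validated error of about 1 % of total fat — the floor set by the
generator's simulated GC measurement noise — using 3 PLS factors.

The same chain is available from the shell:

```
ftirlip run --seed 1 --out runs/demo
ftirlip simulate --seed 1 --out-dir data/
ftirlip qc --spectra data/spectra.tsv --report qc.csv --out passed.tsv
```

`ftirlip run` writes every intermediate artifact (QC report, averaged and
preprocessed spectra, EMSC parameters, marker table, PCA scores,
calibration report, serialized models) plus a manifest with per-stage
counts and checksums; rerunning the same config and seed reproduces the
outputs byte for byte.

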