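# oxiraman

Raman, THz-Raman and SERS quantification of oxidative damage in nucleotide
pools.

Reactive oxygen species preferentially oxidize guanine, producing
8-oxo-7,8-dihydro(-2'-deoxy)guanosine (8-oxo-(d)G) and its triphosphates —
the dominant pre-mutagenic lesion in the cellular dNTP/NTP pool.  `oxiraman`
implements three complementary spectroscopic assays that quantify the
oxidized fraction *C* (in %) of a nucleotide mixture, together with a
synthetic-spectrum generator that emulates the statistical structure of the
measurements so that every stage is testable end to end:

1. **Fingerprint calibration.**  Spectra are baseline-corrected, normalized
   to the phosphate-backbone band at ν<sub>PO</sub> = 1123 cm⁻¹, and the
   1400–1650 cm⁻¹ window is deconvolved with six bounded Gaussians.  The
   integrated intensities *I* of the oxidation markers
   ν<sub>A</sub> = 1535 cm⁻¹ and ν<sub>B</sub> = 1607 cm⁻¹ follow
   *I*ᵢ = *m*ᵢ·*C* + *I*⁰, and the intercept — accidental 8-oxo
   contamination *C*⁰ of the nominally pure stock — is subtracted so the
   calibration passes through the origin.  Inverse prediction carries
   first-order propagated uncertainty; the detection limit is
   LOD = *k*·σ<sub>res</sub>/*m* (*k* = 3.3 by default).  The 620 cm⁻¹
   C5–N7–C8 marker provides the same workflow for 8-oxo-dATP/dATP.
2. **THz tetrad shift.**  Guanosine nucleotides self-assemble into G-tetrads
   whose collective modes give a broad band below ~100 cm⁻¹; C8 oxidation
   blocks the Hoogsteen H-bonds and shifts it by >30 cm⁻¹.  In mixtures the
   main-band frequency follows
   ν(*C*) = ν<sub>8-oxo</sub> + (ν₀ − ν<sub>8-oxo</sub>)·e^(−*C*/R), which is
   fitted and inverted with uncertainty; |dν/d*C*| is maximal at *C* = 0, so
   this observable is most sensitive exactly at trace contamination levels.
3. **SERS chemometrics.**  Nucleoside (dG / 8-oxo-dG) spectra acquired on
   silver colloid are cropped to 400–1800 cm⁻¹, unit-vector normalized
   (removing the enhancement gain) and regressed on *C* by a 3-component
   PLS1 (NIPALS, authored in-repo), with leave-one-out predicted-vs-actual
   diagnostics.

## Worked example

```python
from oxiraman import (SyntheticDatasetSpec, generate_mixture_series,
                      calibrate_mixture_series, preprocess_fingerprint)
from oxiraman.pipeline import marker_areas

spec = SyntheticDatasetSpec(seed=7)          # 0-16 %, 3 replicates, 1 % noise
_, spectra = generate_mixture_series(spec)
result = calibrate_mixture_series(spectra, [s.fraction_pct for s in spectra])
print(result.averaged.summary())

unknown = generate_mixture_series(
    SyntheticDatasetSpec(concentrations=(5.0,), replicates=1, seed=99)
)[1][0]
areas = marker_areas(preprocess_fingerprint(unknown))
a, se = areas[1535.0]
est = result.curves[1535.0].predict(a, se)
print(f"predicted C = {est.value:.2f} +/- {est.uncertainty:.2f} %")
```

prints

```
Calibration curve [average(1535 cm-1, 1607 cm-1)]  I = m*C
  n points             : 18  (C in [0, 16] %)
  slope m              : 0.008405 +/- 0.000067  per %
  intercept I0         : 0.000000 +/- 0.000000
  residual SD          : 0.002840
  C0-corrected         : True
  LOD (k=3.3)          : 1.115 %

predicted C = 4.97 +/- 0.50 %
```

The averaged dual-marker slope is ≈0.008–0.009 per %, the corrected
intercept is zero by construction, the detection limit at this noise level
is ≈1 %, and a held-out 5 % mixture is recovered within its stated
uncertainty.

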