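# myotex

Quantitative analysis of fish fillet texture from muscle histology and
FT-IR microspectroscopy of connective tissue.

Soft fillets of farmed Atlantic salmon are downgraded at processing, and
softness is associated with a visible tissue phenotype: myocytes (muscle
fibre cells) detach from one another, enlarging the pericellular
(intercellular) space, while the endomysial connective tissue loses
sulfated glycosaminoglycan (GAG) content. `myotex` implements the two
measurement chains that quantify this phenotype, together with a
synthetic-data generator that provides ground truth for validating every
stage:

* **Histomorphometry** — marker-controlled watershed segmentation of
  myocytes in HE-like cross-section images, six per-cell features (area,
  nucleus count, eccentricity, convexity, cell-to-cell distance,
  pericellular area), 200-cell-per-specimen sampling, binning of fish into
  five instrumental-firmness classes over the 6.6–20.9 N breaking-force
  span, one-way ANOVA across classes, and the quadratic ("curvilinear")
  regression of group-mean pericellular fraction *f* on group-mean
  breaking force *F*:

  *f* = b₀ + b₁·F + b₂·F², fit by OLS with model F-test and R².

* **Spectroscopy** — for endomysial absorbance spectra on the 750–3998 cm⁻¹
  grid (4 cm⁻¹ interval): Savitzky–Golay second derivative, extended
  multiplicative signal correction (EMSC)

  z = a + b·m + d₁·x + d₂·x² + e,  corrected = (z − a − d₁·x − d₂·x²)/b,

  restriction to the 800–1000 cm⁻¹ sulfated-GAG fingerprint window,
  unstandardized PCA, and detection of wavenumbers where the hard-texture
  group mean exceeds the soft one (the GAG bands at 850, 925 and
  1314 cm⁻¹).

The spectral steps and the firmness regression are scikit-learn-style
estimators (`SavitzkyGolaySecondDerivative`, `EMSCCorrection`,
`RegionSelector`, `UnstandardizedPCA`, `QuadraticTextureRegression`) that
compose in sklearn pipelines; module-level functions wrap them for
`SpectraSet` containers with a processing log.

## Worked example

```python
import numpy as np
from myotex import synthgen, segment, morpho, spectra

# a synthetic cross-section: 50 myocytes, moderate detachment
image, truth = synthgen.generate_tissue_image(n_cells=50, detachment=0.15, seed=1)
labels = segment.segment_myocytes(image)
nuclei = segment.detect_nuclei(image, labels)
table = morpho.cell_feature_table(labels, nuclei, fish_id="fish_01")
_, fraction = morpho.pericellular_area_map(labels)
print(f"segmented {labels.n_cells} cells; pericellular fraction {fraction:.3f} "
      f"(truth {truth.pericellular_fraction:.3f})")

# endomysial spectra: derivative -> EMSC -> differential peaks
sset = synthgen.generate_spectra_set(n_per_group=30, seed=1)
corrected = spectra.emsc_correct(spectra.sg_second_derivative(sset)).corrected
sub = spectra.select_region(corrected, 800, 1400)
means = spectra.group_mean_spectra(sub)
peaks = spectra.differential_peaks(means["hard"], means["soft"],
                                   sub.wavenumbers, n_peaks=3)
print("hard-vs-soft differential peaks (cm^-1):", peaks)
```

prints

```
segmented 50 cells; pericellular fraction 0.219 (truth 0.238)
hard-vs-soft differential peaks (cm^-1): [ 850.  926. 1314.]
```

The automatic segmentation recovers all 50 cells and estimates the
extracellular fraction within 0.02 of the generator's ground truth, and the
peak caller localises the three GAG bands to the grid (925 cm⁻¹ falls
between the 922/926 grid points, so 926 is the expected reading).

A `myotex` console script exposes the same chains from the shell:
`myotex simulate tissue|cohort|spectra`, `myotex segment`,
`myotex features`, `myotex stats`, `myotex spectra` (see `--help`).

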