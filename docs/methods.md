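# Methods

## Scope and rationale

`myotex` quantifies the tissue-level correlates of fillet firmness in
farmed salmon: enlargement of the pericellular (intercellular) space
between myocytes, and depletion of sulfated glycosaminoglycans (GAGs) in
the endomysium. Because no raw study images or spectra are publicly
deposited, the package pairs each measurement chain with a synthetic
generator whose ground truth is known exactly; all accuracy claims in the
test suite are made against that truth.

## Synthetic tissue sections

A cross-section is a Voronoi mosaic of `n_cells` seeds placed on a
jittered square grid (jitter ±30 % of the spacing, Poisson-disk-like, so
cell sizes stay comparable). Myocyte detachment is modelled by contracting
each Voronoi cell toward its seed by a factor
`detachment · (1 + U(−0.2, 0.2))`; vacated pixels become label 0
(pericellular space). The contraction is applied geometrically: a pixel
stays in its cell iff its preimage under the scaling lies in the same
Voronoi region, so cells remain convex and connected. Removing a fraction
`d` of each linear dimension removes `1 − (1−d)²` of the area, which is how
`generate_cohort` inverts a target pericellular fraction `f` to
`d = 1 − sqrt(1−f)`.

Ground truth `pericellular_fraction` is the label-0 share of the convex
hull of all cell pixels — the same tissue-region definition the
measurement side uses, so recovery tests compare like with like.

Each cell receives 1–4 nuclei at peripheral positions (3 px to ~40 % of
the inradius from the edge, pairwise ≥ 6 px apart), matching the
peripheral nucleus position of healthy myocytes. Rendering uses a bright
background (0.92 of full scale), mid-gray cell bodies (0.60 ± 0.03
per-cell shade), a ~2 px darker membrane ring (0.35) and dark nuclei
(0.10, radius 3 px), followed by Gaussian blur (σ 0.6 px) and additive
noise (sd 0.01). These levels give the four structures distinct intensity
modes even after blurring; they are not calibrated to any particular stain.
Defaults (50 cells on 512², 1 µm/px) put the mean cell diameter near
80 px, comfortably above the 10 px floor below which the generator refuses
to run ("overcrowded").

## Simulated cohorts

Breaking forces are drawn uniformly over 6.6–20.9 N (the span of the
instrumental firmness measurements), or — with `group_stratified=True` —
as `n_fish/5` draws inside each of the five class intervals, mirroring a
selection design that guarantees every texture group is represented. The
per-fish pericellular fraction follows the quadratic relation
`f = c0 + c1·F + c2·F²` plus Gaussian noise (default sd 0.01), clipped to
[0, 0.5]. Default coefficients (0.5556, −0.04521, 0.000983) put the curve
at 0.30 for 6.6 N and 0.04 for 20.9 N with its minimum at 23 N, i.e.
decreasing and convex over the whole span — the qualitative shape of the
soft-texture phenotype. A relation whose noiseless value leaves [0, 0.5]
everywhere on the span is rejected ("infeasible relation").

## Segmentation

Images are converted to luminance, Gaussian-smoothed (σ 1 px) and min-max
normalized. The tissue foreground is everything darker than the Otsu
threshold (cells, membranes, nuclei; the bright background and
pericellular space are excluded), hole-filled. Markers are proposed
automatically: a second Otsu split *within* the foreground separates the
brighter cell bodies from membrane rings and nuclei; eroding the
foreground by 2 px first removes thin bright bridges between near-abutting
cells that blurring pulls just under the background threshold (without
this, adjacent cells occasionally share a marker). Connected components of
that core mask, minus fragments below `min_area_px/4`, are the markers. A
user-supplied seed set (one interior point per cell) overrides the
proposal, standing in for the interactive correction of a semi-automatic
workflow. Watershed then floods the negated intensity within the
foreground mask.

Regions below `min_area_px` (default 100 px — far below any real myocyte
cross-section at ~1 µm/px) are dropped. Cells touching the image frame are
kept for pericellular accounting but flagged and excluded from feature
sampling, because truncation biases shape features; only cells whose
frame contact exceeds 80 % of their boundary are dropped outright.
Labels are renumbered 1..K. The stage is deterministic for a fixed image;
permuting seed order permutes label identities but leaves the partition
intact up to watershed tie-breaking on plateaus (tested at ≥ 99.9 % pixel
agreement).

Nuclei are detected as dark blobs: pixels below 0.22 of the *absolute*
intensity range (not min-max normalized, so a section without dark blobs
yields nothing), cleaned of components under 4 px; centroids falling in
label-0 space are discarded and the rest inherit their cell's label.

## Morphometry

Area, eccentricity (moment-matched ellipse) and convexity (solidity) come
from `skimage.measure.regionprops`. Pericellular area is defined per cell
by assigning every extracellular pixel inside the tissue region (convex
hull of all cell pixels) to its nearest cell via the Euclidean distance
transform; this conserves the total extracellular area exactly and gives
both a per-cell feature and a global fraction (both are reported, since
either reading of "pericellular area" is defensible). Cell-to-cell
distance is the nearest-neighbour boundary gap: minimum pixel-centre
distance between boundary pixels of different cells, minus 1 px
(edge-to-edge rather than centre-to-centre), clipped at zero — abutting
cells read 0 µm, a 5 px gap reads 5 µm at 1 µm/px. With a single cell the
distance is undefined and reported as NaN. Specimen summaries are
mean ± sd over the sampled cells (200 per specimen when available; fewer,
with a warning, otherwise); the sd of a single cell or of a constant
feature is 0 by convention.

## Firmness statistics

The five class intervals (soft 6.6–7.5, low 8.6–9.5, medium 9.7–12.5,
high 13.1–16.7, hard 17.7–20.9 N) are closed; forces in the gaps between
them go to the nearest boundary, ties toward the softer class, so the
mapping is total on the calibrated span; forces outside 6.6–20.9 N are
"unclassified". The gap rule is a package choice — the classes were
originally defined only for the fish actually measured, and a total
function is needed for simulated cohorts.

The "curvilinear" relation is realized as quadratic OLS of group-mean
pericellular fraction on group-mean force (5 points), with the model
F-test; a log-linear form is available behind `form="loglinear"` for
sensitivity analysis, and the same fit can be run on per-fish values
(n = 15) since either aggregation level is defensible. ANOVA is one-way
fixed-effects at the specimen level (one value per fish), not the cell
level, to avoid pseudo-replication; the cell-level option is deliberately
not offered. All-zero within-group variance yields an undefined F,
reported as NaN with a warning rather than an error.

## Spectroscopy

The instrument grid is anchored at 750 cm⁻¹ and ascends in 4 cm⁻¹ steps to
3998 cm⁻¹ (813 points; 4000 is not on the grid because the span is not
divisible by the interval). Synthetic endomysium spectra are sums of
Gaussian bands — amide A/I/II/III, C–H stretch, a carbohydrate C–O band,
and the three sulfated-GAG bands at 850, 925, 1314 cm⁻¹ whose amplitudes
are multiplied by 1.6–1.8 in the hard group — distorted per spectrum by
`b·signal + a + d₁·x + d₂·x²` with b ∈ U(0.7, 1.3), a ∈ U(−0.05, 0.05),
d₁, d₂ ∈ U(−0.02, 0.02) on the [−1, 1]-rescaled axis, plus Gaussian noise
(sd 0.001 absorbance units, the order of a well-averaged FT-IR
measurement).

Processing order is second derivative first, then EMSC, with the set mean
of the derivative spectra as reference. The Savitzky–Golay filter defaults
to an 11-point window and polynomial order 3 (a standard choice for 4 cm⁻¹
FT-IR data; both configurable), scaled by the grid step so units are
absorbance/(cm⁻¹)², with polynomial edge handling (exact for global
quadratics). EMSC fixes the baseline polynomial at order 2 — constant,
linear and quadratic terms covering wavenumber-independent and -dependent
additive effects — on the [−1, 1]-rescaled axis for conditioning; the
per-spectrum least-squares solve is checked in the tests against an
independent normal-equations oracle, and correction is idempotent against
a fixed reference because the residual is orthogonal to the design.
Spectra with |b| < 1e-8 cannot be corrected stably and are flagged and
passed through. PCA centres columns but never scales them (derivative
amplitudes carry the signal), with a deterministic sign convention
(largest-magnitude loading element positive) so score plots reproduce.

Differential peaks are local maxima of |mean_hard| − |mean_soft| on the
corrected second-derivative spectra (absolute values because
differentiation inverts band signs), filtered by prominence — default 3×
the median absolute deviation of the difference trace, falling back to 5 %
of the largest excursion when the trace is zero almost everywhere. Second
derivatives of Gaussian bands have flanking side lobes; `n_peaks` keeps
the most prominent maxima when only band centres are wanted. Note 925 cm⁻¹
is not a grid point on the 750-anchored grid, so its band reads at
926 cm⁻¹, within one grid step. The 800–1000 cm⁻¹ fingerprint window on
this grid holds the 50 points 802–998 (a 4 cm⁻¹ grid containing 800 would
hold 51); PCA is run on the window-restricted corrected spectra by
default.

## What the generators do and do not emulate

The tissue generator reproduces the *measurable structure* — cell mosaic,
controlled intercellular spacing, peripheral nuclei, intensity contrast
between structures — not HE colour, staining variability, sectioning
artefacts, fibre-type heterogeneity or out-of-plane effects. The spectra
generator reproduces the EMSC distortion family and band-level group
differences, not water-vapour/CO₂ lines, detector nonlinearity or
scattering signatures beyond a quadratic baseline. Passing tests therefore
demonstrate that the algorithms recover known structure under the stated
noise model; they do not certify performance on real micrographs or
measured spectra, where marker proposal and peak prominence thresholds
would need re-tuning.

## Problem sizes and numerical choices

Test and acceptance runs use 512² sections with 50 cells (the reference
condition), a 1200² section with 300 cells for the 200-cell sampling
protocol, 15-fish cohorts, and 30 spectra per group — sizes chosen so the
whole validation chain exercises every stage at realistic cell counts.
Null-calibration checks use 200–500 simulations. All randomness flows from
explicit integer seeds through local `numpy.random.Generator` instances;
fixed seeds give bit-identical outputs. Tolerances: exact identities are
asserted at 1e-8–1e-10; discrete-raster oracles (ellipse eccentricity,
hull-based convexity) at ±0.02; end-to-end pericellular-fraction recovery
at ±0.05 against truth.

## Known limitations

* The watershed stage assumes cells darker than background with brighter
  interiors than membranes; inverted-contrast stains require preprocessing.
* The pericellular partition attributes shared gaps to the nearest cell
  only; a membrane-to-membrane midline split would differ at the pixel
  scale.
* Nucleus detection is intensity-thresholded, not shape-aware; heavily
  overlapping nuclei merge.
* The quadratic regression on five group means has one residual degree of
  freedom; its F-test p-value is accordingly coarse (the per-fish fit is
  available for a better-powered test).
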