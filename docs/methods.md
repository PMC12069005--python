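# Methods

This note documents the models and algorithms implemented in
`oculovasc`, the design choices made where the problem was genuinely
open, and what the synthetic-data validation does and does not
demonstrate about real images.

## Peripapillary vessel counting (`ringscan`)

A peripapillary ring scan samples a 3.4 mm circle around the optic nerve
head; every retinal vessel crossing the ring attenuates the beam and
casts a vertical shadow on the bright outer-retina/RPE band.  The
counter works on the *shadow profile*: the band (selected automatically
as a band around the brightest row, or given explicitly) is averaged per
column and divided by a circular median-filtered baseline (window 51
columns — wide enough that isolated shadows do not drag the baseline,
narrow enough to track slow illumination drift).  Columns whose ratio
falls below `threshold_frac` (default 0.85) form candidate shadows;
maximal circular runs are merged across the wrap point.  Runs narrower
than `min_width_px` (default 3 px ≈ 20 µm at the 6.8 µm/px transverse
pitch) are tallied separately as thin ciliary vessels and excluded from
the count.  Eyes are classified *high* when the count is ≥ 18, *low*
otherwise.

Normalizing by a local baseline makes detection invariant to global
intensity rescaling and to rotation of the scan; both invariances are
tested.  The run-length rule is a deliberately simple, reproducible
stand-in for interactive segmentation tools; its two parameters are
explicit and configurable.

## UWF vessel-tree metrics (`uwf`)

**Regions of interest.**  The standard analysis region is the union of a
fovea-centred ellipse (major semi-axis 12 mm along the disc–fovea axis,
minor semi-axis 8.5 mm) and a posterior annulus from the optic-disc edge
to 5.2 mm around the disc centre, always excluding the disc itself.
Posterior annulus and mid-periphery (the remainder) partition the
standard region by construction.  All radii are configurable; the exact
outer contour that a particular grading platform uses is not published,
so the ellipse is a documented choice, not a claim of equivalence.

**Fractal dimension.**  The sandbox estimator samples seed pixels
uniformly from structure pixels around which the largest box still fits
inside the region (chessboard distance transform, image border counted
as boundary).  For each box side `R = 2r+1` in a geometric series the
mean structure mass ⟨M(R)⟩ is computed via an integral image; the
dimension is the least-squares slope of log ⟨M⟩ against log R.  Mass
scales as `M ∝ R^D`, so the 1-px line, the filled plane and the
Sierpiński carpet give exactly 1, 2 and log 8/log 3 — these analytic
fixtures, plus an independent grid box-count estimator, anchor the
tests.  Defaults: 500 seeds, radii 2…64 further capped so the box side
does not exceed ~¼ of the region extent; larger boxes sense the region
boundary rather than the structure's scaling and bias the slope low
(measured −0.06 on a 243-px carpet when boxes up to 129 px are allowed).

**Width gradient and intercept.**  Vessel caliber is sampled at regular
arclength intervals (default 0.25 mm) along the centerline: at each
sample the width is the edge-to-edge extent of the binary map along the
local normal (bilinear interpolation at 0.2 px steps, 0.5 level).
`RobustWidthModel` then fits `width = WI + WG·d` with an M-estimator
using the Tukey bisquare loss (tuning constant 4.685, iterated to a
relative coefficient change below 1e-8).  Distance is arclength from the
first centerline point, which generators place at the disc edge, so WI
estimates caliber at the disc.  When the data are exactly linear the
M-estimator's scale is zero and the estimating equations are singular;
the model detects this and returns the (identical) least-squares
solution.  Validation: exact recovery on noiseless tapers, agreement
with a brute-force least-trimmed-squares oracle under 20% contamination,
and mean absolute errors < 0.3 µm/mm (WG) and < 5 µm (WI) across 100
noisy profiles (caliber noise SD 2 µm).

**Tortuosity density.**  The path is smoothed with a short moving
average (window 5 samples), split at sign changes of the discrete
curvature (cross product of successive segments, with a relative
tolerance so numerically straight paths produce no inflections), and
scored as `((n−1)/n)·(1/L)·Σ (arc/chord − 1)` with lengths in mm.  A
straight path and a single arc (no inflection) score exactly 0; the
score grows with the number of inflection-separated curves and is
divided by total length, so uniform scaling of a path divides the score
by the scale factor.  Tests compare against direct quadrature evaluation
of the formula on analytic sinusoids.

**Aggregation.**  Per-vessel metrics carry a quadrant (ST/SN/IT/IN) and
class; temporal averages {ST, IT}, nasal {SN, IN}, global all four,
separately for arterioles and venules.  A scope with no vessels yields a
missing value, never zero.

## Lesion zoning and phenotyping (`lesions`)

Lesions live in fovea-centred fundus coordinates (mm).  Zones are
concentric: central within `central_r` (default 10 mm), mid-peripheral
within `mid_r` (default 15 mm), far-peripheral beyond; boundary circles
belong to the inner zone.  The published grid's exact radii are defined
in an external grading protocol, so they are configuration with
documented defaults — downstream statistics consume the zoning logic,
not specific radii.  Hemispheres split at the vertical line through the
fovea; left-eye coordinates are mirrored so temporal keeps one sign, and
the tie at x = 0 goes temporal.  Phenotyping is hierarchical: any
hemorrhage → hemorrhage group, otherwise microaneurysms → microaneurysm
group, otherwise negative.  Both operations are order-invariant and
idempotent.

## Choroidal vascularity index (`cvi`)

Per B-scan, the choroid is the set of pixels strictly between the inner
(Bruch's membrane) and outer (choroidal–scleral interface) boundary
polylines; crossing boundaries raise an error naming the first offending
A-scan.  Binarization proceeds as: Gaussian smoothing (σ = 0.5 px);
min–max rescaling to 8 bit within the choroid mask (making everything
downstream invariant to affine intensity changes); for each scale
`r ∈ {4, 8, 16, 32}` px, a local Otsu threshold over the (2r+1)-square
neighborhood restricted to the mask, marking sub-threshold (dark) pixels
whose Euclidean distance from the mask boundary exceeds `r`; union of
marked pixels across scales; one morphological opening (3×3 cross)
followed by removal of components smaller than `min_region_px`
(default 10).  The result is the luminal area (LA); the stroma (SA) is
its complement within the mask, so LA + SA equals the mask exactly.

One guard is added to the multi-scale Otsu loop: a window contributes
dark pixels only when its local dynamic range exceeds
`local_contrast_min` (default 0.4) of the 8-bit range.  Otsu assumes a
bimodal window; in a window containing only stroma it splits the noise
and marks half the tissue dark, which inflated recovered CVI by ~0.05 at
low luminal fractions.  The gate is computed on the rescaled image, so
it shares Otsu's affine invariance.  With it, recovered global CVI is
within ±0.01 of the planted fraction across 0.2–0.5, with and without
noise.

CVI of any region is `|LA ∩ region| / |choroid ∩ region|`.  The en-face
map keeps one row per B-scan at its fundus y (no interpolation between
scans) and per-column luminal/total counts; ETDRS sectors (circle
diameters 1 / 3 / 6 mm, quadrants split by the ±45° diagonals) pool
counts over their footprint rather than averaging sector means, so
rings and the global value weight cells by choroidal area.  A sector
with no populated cells reports a missing value.

## Statistics (`stats`)

Both eyes of a participant enter the analysis, so observations are
clustered.  Group contrasts are estimated by GEE with an exchangeable
working correlation (statsmodels backend), CTRL as the reference level,
age and sex as covariates, and robust sandwich standard errors; gaussian
identity for continuous outcomes, binomial logit for binary ones.  With
cluster size 1 or an independence working structure the estimates
coincide with ordinary least squares (tested to 1e-6), and the logistic
group log-OR on a flat 2×2 equals the closed-form log odds ratio.
Simulation at the operating conditions used throughout (100 participants
per group, ρ = 0.5) shows the planted effect recovered within ±0.1 over
200 replicates, type-I error 5.2% and CI coverage 94.8% over 5000
replicates — no small-sample correction is applied, and none appears
needed at ~200 clusters.

Supporting pieces: descriptive tables report frequencies and percentages
(one decimal, ties rounded half-up) or mean/SD/range; group tests use
Pearson's chi-squared, switching to Fisher's exact test when an expected
cell is ≤ 5, and the Wilcoxon rank-sum test for continuous variables
(exact enumeration at small n); extreme values are imputed to their
group mean using leave-one-out moments (|v − mean₋ᵥ| > k·SD₋ᵥ, default
k = 3, flags decided in a single pass on the original data) with an
audit log of every replacement; Benjamini–Hochberg FDR adjustment is
applied within configurable outcome families (one family per results
table); marginal R² is the squared Pearson correlation between the
linear predictor and the observed outcome.

## Synthetic data (`synth`)

Every generator is a pure function of its seed (bit-reproducibility is
tested) and returns the rendered artifact together with a ground-truth
record measured from the artifact itself.

* **Ring scans**: bright band over a dark background; each planted
  vessel multiplies the band and everything below it by an attenuation
  factor (default 0.45) over its column interval.  Intervals are packed
  circularly with a minimum gap, so wrap-spanning shadows occur
  naturally.  Noise is Gaussian with SD = band/snr.
* **Vessel scenes**: centerlines start at the disc edge and run into
  their quadrant as a straight line, single arc or k-period sinusoid;
  the local full width is `WI + WG·d` µm at arclength d, rendered by
  stamping discs without anti-aliasing so the binary truth is exact.
* **Fractal fixtures**: line, filled square and Sierpiński carpet at
  3^depth px with analytic dimensions.
* **Choroid volumes**: smooth non-crossing boundary polylines, bright
  stroma, dark elliptical lumina (intensity stroma − contrast, default
  contrast 80 over noise SD 10).  Lumina are placed sequentially —
  overlap is permitted but the rendered union is tracked incrementally
  and the final ellipse is shrunk so the realized fraction lands within
  ±0.005 of the request (strict non-overlap packing jams near fraction
  0.5 and cannot reach the supported ceiling of 0.8).  Every lumen lies
  at least 5 px inside the mask, inside the smallest distance gate of
  the default binarization scales, so the planted truth is recoverable
  by construction.
* **Cohorts**: two eyes per participant share a participant-level
  random effect sized so that Var(b)/(Var(b)+Var(ε)) = ρ; binary
  outcomes use the logistic analogue (random-effect variance
  ρ/(1−ρ)·π²/3).  Age and sex distributions default to the study
  cohort's (DS 39 ± 7 y, 37.5% female; controls 36 ± 9 y, 52.9%
  female).  At ρ = 0 the generator reduces to i.i.d. regression data.

**What passing tests do not show.**  The generators emulate the
*geometry and contrast structure* the estimators rely on, not real
optics: no speckle, no projection distortion of the ultra-widefield
lens, no eyelash/eyelid artifacts or media opacities, no
vessel-segmentation errors (centerlines and maps are inputs by
contract), and boundary polylines are exact rather than
operator-corrected.  Recovery results therefore validate the
measurement chain given its inputs; they say nothing about upstream
segmentation quality on clinical images.  Scanner noise characteristics
are not published for this protocol, so SNR defaults were chosen once
for test stability, not realism.

## Problem sizes and numerical choices

Test and acceptance runs use deliberately small renderings chosen as a
balance of statistical resolution and runtime: choroid volumes of 2–4
B-scans × 256 A-scans (the generator defaults to the clinical 25 × 768),
vessel scenes of 1200–1400 px, 50 ring scans for counting, 200
replicates for GEE effect recovery and 1000 for calibration.  Ties and
degenerate inputs are handled explicitly throughout: boundary pixels of
ETDRS sectors belong to the sector whose angular interval is closed on
the counter-clockwise edge, zone boundary circles belong to the inner
zone, constant outcomes and degenerate regressor sets raise errors
rather than returning numbers, and empty aggregation scopes yield
missing values.

## Known limitations

* The run-length shadow detector is not claimed to be equivalent to the
  interactive OCT segmentation software it stands in for, nor the CVI
  binarizer to the original unpublished plugins; both are fixed,
  parameter-explicit implementations of the described procedures.
* Pixel scales are taken as isotropic from metadata; no stereographic
  correction of ultra-widefield projection is applied, so far-peripheral
  distances in scene space are nominal.
* The ETDRS map interpolates nothing between B-scans; sparse volumes
  leave sectors partially sampled (pooling handles this, but sector
  estimates from very few B-scans are noisy).
* GEE small-sample behavior below ~30 clusters is not corrected;
  calibration was verified at 120–200 clusters.
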