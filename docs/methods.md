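# Methods

This note documents the models, conventions and numerical choices behind
`octa_intereye`, in the order data flows through the package.

## Measurement substrate

All image operations assume an 8-bit grayscale en-face angiogram of one
capillary plexus, square, fovea-centered, with a physical pixel pitch in
mm/px. The default substrate is 500×500 px at 0.012 mm/px (a 6×6 mm field);
native scan sampling is device-dependent and not standardized, so the size
is configurable and every physical quantity is computed through the pitch.
Test and analysis drivers often use 250 px at 0.024 mm/px — the same 6-mm
field at half sampling — purely because the measurement chain is
resolution-robust and the smaller images make the examples quick.

## Binarization

The vessel/background decision is a single global threshold per image,

    threshold = mean + std_coeff · sd,

with `std_coeff = 0.5` for all perfused vessels and `1.3` for the large
arcade vessels only. Conventions that the formula leaves open, fixed here
so that masks are bit-reproducible:

* `sd` is the **population** standard deviation (ddof = 0) over all pixels.
* A pixel is vessel iff its value is **strictly greater** than the
  threshold (a constant image therefore yields an empty mask).
* The statistics are computed over the whole image — no windowing, no
  preprocessing, FAZ included.

The big-vessel mask may be dilated by a disc (default radius 0) so the
exclusion region covers the full vessel caliber. For the SCP, capillary
metrics remove the big-vessel mask from numerator **and** denominator:
"area measured" is what remains after exclusion, so density reflects the
microcirculation rather than being depressed wherever an arcade crosses a
sector. For the DCP, bright superficial vessels cast projection artifacts
onto the deep slab; lacking a manual artifact trace, the SCP big-vessel
footprint is used as the exclusion region (configurable off).

## ETDRS grid

Standard macular grid diameters (1/3/6 mm) centered on the FAZ center
(annotated directly or taken as the centroid of the FAZ boundary trace).
Pixel-center coordinates, 0-based, x = column; half-open radial bins
[0, 0.5), [0.5, 1.5), [1.5, 3.0] mm make the central subfield, inner ring
and outer ring an exact partition of the 6-mm disc. Reported sectors are
the inner ring, outer ring and the full 6-mm disc ("total", including the
central subfield); the rings are not subdivided into quadrants. A grid
whose disc extends past the image border is clipped with a warning and
flagged in the per-eye QC output.

## Vessel density

`vd_S = (capillary pixels in S) / (pixels in S not excluded)`, stored as a
fraction in [0, 1] (rendered as a percentage only in prose). A sector left
without measured area raises an error naming the sector rather than
emitting a silent 0/0.

## Fractal dimension

Box counting with square boxes anchored at the top-left corner, on the
dyadic ladder {2, 4, …, size//4} by default; `N(s)` counts boxes containing
at least one foreground pixel and the FD is the negative slope of the OLS
fit of `log N(s)` on `log s`, with the fit R² reported. No automatic
linear-range selection is applied, and grid-offset averaging exists behind
a flag but is off by default (the raw raster convention). FD is computed on
the big-vessel-excluded capillary map over the full image; restriction to
the 6-mm disc is available via the `restrict` argument. Absolute FD values
are convention-dependent (ladder, anchoring, field), so cross-package
comparisons should use the same convention; within this package the
defaults recover log8/log3 on the Sierpinski carpet, 2 on a filled square
and 1 on a line within the documented tolerances, and synthetic SCP-like
meshes land near 1.78.

## FAZ metrics

The canonical FAZ representation is the traced boundary polygon
(pixel-center vertices, implicit closure), mirroring manual tracing;
self-intersecting traces are rejected. Area is the shoelace area × pitch²,
perimeter the closed polyline length × pitch, circularity `4πA/P²`.
Circularity is scale-invariant, which also makes it robust to axial-length
magnification differences that bias FAZA and FAZP. A filled-mask input path
extracts the boundary by marching squares at level 0.5 and then applies the
same computation; note that the stair-stepped boundary of a pixelated disc
inflates the perimeter, so mask-derived circularity of a perfect disc lands
near 0.9, not 1 — a property of raw digitized traces, not a defect.

## Intereye statistics

Per patient and metric, `δ_abs = |R − L|` and the asymmetry index
`AI = |R − L| / ((R + L)/2) × 100` (undefined for non-positive two-eye
means; bounded by 200 for non-negative metrics). Pairing requires both
eyes for the same metric; unpaired eyes are excluded and logged, and a
patient whose two eyes carry different stage labels is rejected (the
cohort design is same-stage-both-eyes).

## Cohort statistics

* **Kruskal–Wallis** (tie-corrected H, χ² reference) across DR stages on
  the per-patient asymmetry measures; an all-tied input reports H = 0,
  p = 1 by convention (no rank variation, no evidence).
* **Wilcoxon signed-rank** for paired comparisons (inner vs outer ring
  asymmetry); zeros dropped, average ranks for ties, exact null
  distribution for n ≤ 25 without tied magnitudes, otherwise the normal
  approximation with continuity correction.
* **Linear mixed model** per response metric: fixed effects DR stage
  (treatment-coded, reference "no_dr"), side (reference "right"), age,
  HbA1c, sex (0 = female, 1 = male), and the stage × side interaction;
  random intercept per patient; REML estimation. Wald 95% CIs and t-based
  p-values use denominator df = n_obs − rank(X); the Wald F-tests for the
  stage and interaction terms use the same denominator df. (With two eyes
  per patient and the study-scale group sizes these df are large, so the
  difference from finer df approximations is far inside the reported
  precision; a cross-check against lme4's REML fit is part of the test
  suite.) Rows with missing covariates are dropped with a log entry, and a
  rank-deficient design raises an error naming the collinear term.
* **Branching**: if the stage F-test rejects at α = 0.05, each stage is
  contrasted against "no_dr" (averaged over sides when the interaction is
  not significant, per side when it is); if the interaction F-test rejects,
  left-vs-right contrasts are reported within each stage, otherwise only
  the single side main effect. No multiplicity correction is applied —
  p-values are descriptive.
* Summary tables report mean ± SD per stage × side and median (Q1; Q3) of
  AI and δ_abs per stage, with linear-interpolation quantiles.

## Synthetic data

**Images.** One synthetic eye is built from: a FAZ polygon (72 radial
spokes, radius `faz_mean_radius · (1 + irregularity · u)` with
u ~ Uniform(−1, 1) smoothed by a 5-point circular moving average —
irregularity maps monotonically to circularity); arcade vessels (smooth
random curves radiating from the field border, steered around the fovea,
dilated to `big_vessel_width`, drawn until they cover `big_vessel_fraction`
of the field, default 0.035 — a stable macrovessel content keeps the
1.3-sd threshold on the arcade class across eyes); and a capillary mesh of
correlated random-walk strokes accumulated until a target coverage
fraction of the 6-mm disc (outside FAZ and arcades) is reached, with
adaptive stroke batching so the realized coverage lands within ~3·10⁻⁴ of
the target — fine enough to plant intereye deficits of 0.009. Intensities
(background 25, capillary 80, arcade 230, Gaussian noise SD 5, clipped and
quantized to 8 bits) are chosen so the two global thresholds separate the
three tissue classes with > 3σ margin over the supported coverage range.
The left eye shares all parameters except an optional additive coverage
deficit and FAZ-irregularity override. All randomness flows from one seed
through numpy seed sequences split per eye, so outputs are bit-identical
under a fixed seed.

What the generator does **not** emulate: OCT speckle and flow-decorrelation
noise, motion and segmentation artifacts, projection artifacts in the DCP,
vessel-caliber heterogeneity and true branching topology. Passing tests
therefore demonstrate that the measurement chain is correct on images whose
ground truth is known — not that the specific threshold constants are
optimal on clinical scans.

**Metrics-level cohorts.** Per-eye responses are drawn from the additive
model `grand_mean + stage_effect + (side_effect + interaction[stage])·
I(left) + covariate terms + patient intercept + residual`, two rows per
patient, with demographics emulating the study population (age
~ N(57.2, 13.1²), HbA1c ~ N(7.34, 1.32²), 66% male — realism only, their
default effects are zero). Defaults emulate SCP vessel density: grand mean
0.218, stage offsets (0, +0.009, 0, −0.005, −0.006), left-eye effect
−0.009, between-patient SD 0.015, within-eye SD 0.008, 34 patients per
stage. These are the conditions under which the parameter-recovery and
calibration results in `scripts/acceptance.py` are computed.

## Numerical and engineering choices

* CSV outputs round floats to 6 decimals and use a fixed float format, so
  re-runs are byte-identical across platforms.
* The mixed-model optimizer falls back from L-BFGS to Powell when a
  boundary fit (patient variance → 0) breaks the gradient path.
* Problem sizes in the drivers and acceptance script (20-patient image
  cohorts at 250 px, 200 replicate cohorts for coverage/branch-rate
  estimates, 1000 replicates for rank-test calibration) were chosen to
  estimate each quantity within its documented tolerance band.

## Known limitations

* The box-counting convention (ladder, anchoring) shifts absolute FD by
  more than typical between-group differences; only within-convention
  comparisons are meaningful.
* DCP projection-artifact exclusion by the SCP arcade footprint is an
  approximation of a manual process.
* Satterthwaite/Kenward–Roger denominator df are not implemented; at
  small cohort sizes (few patients per stage) the reported p-values are
  anti-conservative relative to those corrections.
* The FAZ is measured on the SCP only, and FAZ metrics inherit whatever
  magnification error the trace carries (circularity excepted).
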