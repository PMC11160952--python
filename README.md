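# octa-intereye

Quantification of OCTA en-face angiograms and statistical analysis of
right-vs-left eye microvascular asymmetry in diabetic retinopathy (DR).

Optical coherence tomography angiography (OCTA) produces en-face maps of
perfused retinal capillaries. In diabetic patients the microvasculature
deteriorates before clinical lesions appear, and — because the left common
carotid artery experiences different hemodynamic stress than the right —
the two eyes of the same patient may not be affected equally. This package
implements the measurement chain and the paired-organ statistics needed to
ask that question on fovea-centered 6×6 mm scans of the superficial (SCP)
and deep (DCP) capillary plexus:

* **Binarization** — global threshold `t = mean + c·sd` over the image's
  pixel values, with `c = 0.5` for all perfused vessels and `c = 1.3` for
  the bright arcade ("big") vessels, which are excluded from capillary
  metrics.
* **Vessel density (VD)** — fraction of the measured area occupied by
  flow-positive capillary pixels, per ETDRS sector (inner ring 1–3 mm,
  outer ring 3–6 mm, 6-mm total) centered on the foveal avascular zone.
* **Fractal dimension (FD)** — box-counting slope of `log N(s)` vs `log s`
  on the binarized, big-vessel-excluded map; a global index of branching
  complexity.
* **FAZ metrics** — area (FAZA, mm²), perimeter (FAZP, mm) and circularity
  `FAZC = 4πA/P²` of the traced foveal avascular zone boundary.
* **Intereye statistics** — per patient, the absolute difference
  `δ_abs = |R − L|` and the asymmetry index `AI = |R − L| / ((R+L)/2) × 100`;
  across the cohort, Kruskal–Wallis tests over DR stages, Wilcoxon
  signed-rank tests between ETDRS rings, and linear mixed models
  `metric ~ stage + side + age + HbA1c + sex + stage×side + (1 | patient)`
  (REML) with F-tests and stage-vs-no-DR / per-stage side contrasts.

Clinical image sets cannot be redistributed, so the package ships a
synthetic-data module that generates paired-eye angiograms with known
ground truth (planted capillary coverage, arcade vessels, FAZ geometry)
and metrics-level cohorts with configurable stage, side, interaction and
random-intercept structure. Every stage of the chain is validated against
these ground truths and against closed-form oracles.

## Worked example

Simulate a 20-patient paired-eye image cohort with a planted −0.009
left-eye capillary deficit in the SCP, quantify it, and fit the cohort
statistics:

```bash
python analysis/01_simulate_cohort.py
python analysis/02_quantify_images.py
```

which prints (seed 7):

```
eyes quantified: 40
mean SCP VD right 0.2177 vs left 0.2092 (planted deficit -0.009)
mixed-model side estimate -0.0085 [-0.0094; -0.0077], p=4.41e-18
```

The measured right-eye SCP vessel density (≈0.218) sits at the planted
capillary fraction, the left eyes are lower by the planted deficit, and the
mixed model attributes the difference to the side term with a tight CI.
`analysis/03_intereye_summaries.py` writes the stage × side summary tables
and the median (Q1; Q3) asymmetry tables, and
`analysis/04_cohort_models.py` repeats the mixed-model analysis at full
study scale (34 patients per stage) on a metrics-level cohort:

```
side (left vs right) estimate -0.0095 [-0.0133; -0.0058], planted -0.009
patient SD 0.0156 (planted 0.015); residual SD 0.0078 (planted 0.008)
```

The same machinery is scriptable through the CLI:

```bash
octa-intereye simulate --out cohort --n-patients 10 --seed 1
octa-intereye stats --metrics cohort/analysis/metrics.csv --out stats.json
```

## Layout

```
src/octa_intereye/   library: synthetic data, segmentation, ETDRS grid,
                     density, fractal, FAZ, intereye, cohort stats, pipeline
analysis/            numbered narrative drivers over the library
tests/               pytest suite (unit, property, acceptance)
scripts/acceptance.py
docs/methods.md      models, conventions, parameters, limitations
```
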