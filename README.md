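# cinephase

Left-ventricle (LV) analysis for **rat cardiac cine MRI**: from per-phase 3D
segmentation masks to an automated ejection-fraction estimate, with the
statistics needed to benchmark a segmentation pipeline against reference
values.

Preclinical cardiac studies image the rat LV as short-axis cine series —
11–13 three-dimensional volumes, 8 ms apart, covering one cardiac cycle on a
12 × 86 × 98 grid at 0.5 × 0.5 × 1.5 mm. The study endpoint is the ejection
fraction

```
EF = 100 · (EDV − ESV) / EDV
```

where EDV and ESV are the cavity volumes at end-diastole (ED, maximal
volume) and end-systole (ES, minimal volume). Identifying *which* phases are
ED and ES is normally manual; `cinephase` automates it:

1. compute a scalar **cycle metric** per phase from the masks — cavity
   volume (µL), the area of the short-axis slice whose area varies most over
   the cycle (mm²), or Lewiner marching-cubes surface area (mm²);
2. fit the metric-vs-phase curve with a fourth-degree polynomial or a
   **Gaussian process** (constant × RBF kernel, hyperparameters by marginal
   likelihood);
3. take the fitted curve's global maximum/minimum, snap each to the nearest
   acquired phase, and compute EF from the segmentation-derived volumes at
   those phases (never from the fitted ordinate).

Around this core the package provides, for building and benchmarking the
segmentation stage itself:

- probability-map post-processing (thresholding, per-slice hole filling,
  morphological opening);
- training objectives as pure numpy functions: ε-smoothed two-sided soft
  Dice loss, a U-Net-style border weight map
  `w_c + w0·exp(−(d1+d2)²/(2σ²))`, the weighted soft Dice loss, BCE and the
  hybrid loss;
- MRI noise models (Gaussian, Rician, Rayleigh, mixed) calibrated to a
  target SNR = mean foreground signal / noise sd, and the six-transform
  augmentation suite with ×10 dataset inflation;
- agreement statistics: mean absolute EF difference (MD), Bland–Altman bias
  and limits of agreement with 95% CIs, proportional-bias screening, and a
  paired TOST equivalence test with a 2% EF margin;
- a **synthetic cine generator** (ellipsoidal cavity + myocardial shell,
  configurable EF in the study's 41–67% range) whose ground truth is
  measured on the voxel grid, so every stage is testable without
  proprietary data.

## Worked example

Generate a synthetic series with a known 55% EF, then recover it fully
automatically from the masks:

```bash
$ cinephase synth --ef 55 --phases 13 --seed 7 --out demo_series
wrote series with true EF 55.02% (ED phase 0, ES phase 4) to demo_series

$ cinephase auto-ef --in demo_series/masks.nii.gz --metric slice_area \
      --fit gp --seed 0 --out demo_ef.json
EF 55.02% (EDV 500.2 uL at phase 0, ESV 225.0 uL at phase 4)
```

The generator wrote `truth.json` with the voxel-grid ground truth (EDV
500.25 µL, ESV 225.0 µL, ED phase 0, ES phase 4); the automated pipeline
selected exactly those phases, so the recovered EF matches the truth to
machine precision. The same fit is available as a model object:

```python
from cinephase import read_cine_nifti, cycle_curve, CycleCurveModel, FitSpec

series = read_cine_nifti("demo_series/masks.nii.gz", is_mask=True)
result = CycleCurveModel(cycle_curve(series, "slice_area"),
                         FitSpec(method="gp", seed=0)).fit()
print(result.summary())
```

```
Cardiac cycle phase selection
=================================
metric:           slice_area
fit method:       gp
phases observed:  13
diastole phase:   0 (value 58.00)
systole phase:    4 (value 26.50)
fit RMSE:         0.0001905
```

`result.plot()` draws the observed points, the fitted curve and the selected
phases; `estimate_ef`/`auto_ef` turn a selection into an `EFEstimate`.

Other entry points: `cinephase metrics` (per-phase curves as CSV),
`cinephase corrupt` / `cinephase augment` (noise and augmentation),
`cinephase agree` (Bland–Altman/MD/TOST report from a CSV of paired EFs),
`cinephase benchmark` and `cinephase noise-robustness` (the scripted
experiments; see `cinephase.pipeline`).

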