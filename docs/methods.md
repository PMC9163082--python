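# Methods

This note documents the models, conventions and numerical choices behind
`cinephase`, and what the synthetic experiments do and do not demonstrate.

## Geometry and units

Arrays are indexed `(z, y, x)`; spacing is `(dz, dy, dx)` in millimetres,
default `(1.5, 0.5, 0.5)` on the standard 12 × 86 × 98 grid. Volumes are
foreground voxel count × voxel volume with no partial-volume correction
(1 mm³ = 1 µL); all coordinates are 0-based. 4D NIfTI files are stored in
the on-disk `(x, y, z, t)` layout and reordered to phase-major `(t, z, y,
x)` on load; a directory of per-phase 3D files is ordered by the numeric
index in the file names. Pre-processing resizes with trilinear
interpolation for intensities and nearest-neighbour for masks (so labels
stay binary) and normalises either min–max to [0, 1] (the default —
compatible with sigmoid-output probability maps) or to z-scores; a constant
image returns all zeros with a warning.

## Automated phase selection

The cycle curve is one scalar per phase: cavity volume, surface area, or
the area of the short-axis slice whose area has the highest across-phase
variance (ties broken toward the smallest slice index, with a warning).
Surface area is the total triangle area of the Lewiner marching-cubes
iso-surface at level 0.5 with physical spacing. The binary field is
pre-smoothed with a 0.8-voxel Gaussian before extraction: on a voxelised
sphere of radius 10 the raw binary mesh overestimates the analytic area by
≈8.5% (staircase artefact) while the smoothed field is accurate to well
under 5% across radii 6–14; structures too small to survive the smoothing
(e.g. a single voxel) fall back to the raw binary field. The volume is
zero-padded by one voxel so boundary-touching masks still produce closed
surfaces.

Two curve models are fitted on the integer phase index (temporal spacing is
uniform, so using milliseconds would not move any extremum):

- **poly4** — degree-4 least squares (`numpy.polynomial`);
- **gp** — Gaussian-process regression (scikit-learn) with a constant ×
  RBF kernel, length-scale bounds [0.1, 100] phases, observation noise as a
  diagonal jitter `alpha = 1e-6` (fraction of the standardised value
  variance), and 5 seeded restarts of the marginal-likelihood optimiser.
  Values are standardised to zero mean/unit variance before fitting and
  de-standardised after, which makes phase selection exactly invariant to
  affine rescaling `y → a·y + b (a > 0)` of the metric.

The fitted mean is evaluated on a dense grid (≥ 10 points per phase,
default 501) over the acquired window only — no periodic extension. The
diastole is the dense-grid global maximum and the systole the global
minimum, each snapped to the nearest acquired phase; EF always uses the
mask-derived volumes at the snapped phases, never the fitted ordinate, so
both fitting methods are anchored in actual data points. If the fitted
curve is monotone over the window (no extremum pair — a fit failure, not a
data failure, since cycles are cyclic) selection falls back to the raw-data
argmax/argmin with a warning; if both extremes snap to the same phase the
cycle is reported as degenerate. A mis-selection with ESV > EDV yields a
negative EF with a warning rather than a clamped value, so failures stay
visible downstream.

The fitting core follows the model/results idiom: `CycleCurveModel(curve,
spec).fit()` returns a `PhaseSelectionResult` with the dense fitted curve,
residual diagnostics, the (lazily computed) phase selection, `summary()`
and `plot()`.

## Synthetic cine generator

The phantom is an LV cavity modelled as a z-truncated ellipsoid inside a
concentric myocardial shell (default wall 2 mm) on the study grid, with
intensities background 50 / cavity 300 / myocardium 180 (arbitrary units —
chosen to give a well-defined foreground mean for SNR scaling and three
separable intensity populations for the reference threshold backend). The
long axis is fixed per series at 1.5× the end-diastolic in-plane radius
(capped by the slab, spanning ~9 of 12 slices so apical/basal slices stay
partial); contraction is purely radial, as in short-axis cine physiology.
This makes every covered slice share the same relative area swing, so the
largest (mid) slices carry the largest absolute across-phase variance — the
premise of the slice-area metric — and the variance profile is unimodal
with its peak in the central third of the slab. A seeded in-plane centre
jitter (±2 mm) and a fixed 0.37-slice axial offset (base/apex asymmetry)
avoid degenerate symmetric ties.

Per-phase target volumes follow one of two one-cycle shapes with the
maximum EDV at phase 0 and the minimum ESV = EDV·(1 − EF/100) at the
systolic phase (default 35% into the window):

- **cosine** — half-cosine descent to ESV, then ascent recovering 93% of
  the EDV−ESV span by the end of the window;
- **skewed** — a fast 4% early decline off the end-diastolic peak, a
  gently tilted (2%) diastolic plateau, and a narrow raised-cosine systolic
  dip.

The curve constants are set by a resolvability rule: the per-phase
decrement at the extremes must exceed the grid's quantisation floor
(~0.25 mm² per in-plane voxel at the metric slice, ~0.375 µL per voxel in
volume), otherwise the phantom's own extreme phases would not be
expressible in its binary masks and no selection method could recover them.
For the same reason the rasteriser matches each target volume to 0.2%
(documented error bound 5%) by iterating the in-plane scale. Ground truth
(EDV, ESV, EF, extreme phases) is measured on the voxelised masks, not the
analytic ellipsoid, so a pipeline fed the ground-truth masks recovers EF
exactly.

**What the phantom does not emulate:** myocardial texture, papillary
muscles, trabeculation, through-plane motion, partial-volume intensity
blending, infarct remodelling, or operator variability in manual
segmentation. Passing the synthetic experiments therefore demonstrates the
correctness of the *pipeline* (metrics, fitting, selection, statistics) and
its noise behaviour, not segmentation performance on real rat hearts.

## Post-processing

Probability maps are thresholded at 0.5 (sigmoid-symmetric default), holes
are filled per 2D slice (LV cavity holes are in-plane in short-axis data),
and thin protrusions are shaved by a binary opening with a radius-r
Chebyshev ball (the full (2r+1)³ box, default r = 1). The box element —
rather than a 6-connected Euclidean ball — is chosen so that opening
preserves compact blocky bodies exactly (a 6-connected element clips
corners of even a solid cube). Hole filling runs *before* the opening: a
one-voxel interior hole would otherwise hollow out the erosion entirely.
The erosion treats out-of-volume as foreground so a solid spanning the
whole array survives; the whole chain is idempotent. An opening of a
voxelised ellipsoid still removes a few thin apical voxels — which is why
the pipeline's ground-truth oracle backend returns final reference masks
directly rather than feeding them through the probability chain.

## Losses and weight maps

The soft Dice loss is the two-sided ε-smoothed form (ε = 1 by default):
`1 − (Σtp+ε)/(Σ(t+p)+ε) − (Σ(1−t)(1−p)+ε)/(Σ(2−t−p)+ε)`. It can be
slightly negative on small arrays because ε pads numerator and denominator;
it vanishes as `O(ε/N)` for perfect predictions. The weight map is
`w_c + w0·exp(−(d1+d2)²/(2σ²))` with defaults w0 = 2, σ = 1: `w_c` gives
each class the inverse of its frequency, normalised so the map-wide mean is
1 (making the weighted loss scale-comparable to the unweighted one), and
d1/d2 are Euclidean distances in voxel units from the border rings of the
nearest and second-nearest foreground components, measured on background
voxels (a voxel adjacent to a component has d = 0; with a single LV
component d2 := d1). The weighted soft Dice loss multiplies each voxel's
contribution to every sum by its weight, which reduces exactly to the
unweighted loss for unit weights; doubling w0 strictly increases the loss
of a border-adjacent error while leaving a far-field error almost
untouched (the residual coupling through the denominators is orders of
magnitude smaller). BCE clips probabilities to [1e−7, 1−1e−7] so all
losses stay finite; the hybrid loss is BCE + unit-weight soft Dice.

## Noise and augmentation

SNR is defined as mean foreground intensity / noise sd (the magnitude-MRI
convention); σ = µ/SNR is computed from the supplied foreground mask or the
whole image. Gaussian noise is additive; Rician noise re-magnitudes with
two independent Gaussian channels `sqrt((I+n1)² + n2²)` (zero-signal voxels
then follow a Rayleigh law with mean σ·√(π/2)); Rayleigh noise is additive
and mean-centred with its scale set so sd = σ (keeping mean intensity
comparable across scenarios); the mixed scenario draws one distribution per
image. Augmentation samples a non-empty random subset of {elastic, shift,
rotation, scaling, blur, gamma}; geometric transforms are in-plane only and
applied identically to image (trilinear) and mask (nearest, re-binarised);
blur (σ ∈ [0.5, 1.5], in-plane) and gamma (γ ~ N(1, 0.1), applied on the
[0, 1]-normalised image and mapped back to the original range) touch the
image alone. Unstated ranges default to ±10% in-plane shifts, scaling
[0.9, 1.1] about the centre, and elastic fields of 8-voxel amplitude
smoothed over 4 voxels. Dataset inflation returns the originals plus
factor−1 seeded augmentations per pair, deterministic via spawned seed
sequences.

## Agreement statistics

Differences are estimated − reference. Bland–Altman reports bias,
1.96·sd limits of agreement, the bias CI `t(0.975, n−1)·sd/√n` and the
classical `t·sd·√(3/n)` approximation for each limit's CI; proportional
bias is screened by regressing differences on pair means (flagged at
p < 0.05). The equivalence test is a paired TOST with a 2% EF margin — a
deliberate, labelled simplification of a mixed-model equivalence contrast
(random effects for animal and operator are out of scope); with zero
variance the decision is exact on |bias| vs the margin. Single-pair sd is
reported as 0 with a warning rather than NaN so batch pipelines keep
running.

## Experiment sizing

The bundled experiments are sized for a desktop run: the EF-recovery
experiment uses 50 series on the full 12 × 86 × 98 grid (≈10 s); the unit
and property tests use a reduced 10 × 40 × 44 grid with 300 µL EDV, which
preserves every behaviour of interest at ~5× lower cost. The
noise-robustness comparisons average ≥10 seeds when asserting ordering
(Dice under heavier noise) because single-seed orderings are noisy.

## Known limitations

- Phase-selection accuracy is quantisation-limited: on curves whose
  extremes differ by less than one voxel (area) between adjacent phases,
  the selected phase can legitimately land on a neighbour; the residual
  ~2% miss rate of the GP + slice-area experiment is of this kind and
  changes EF by well under 2 points.
- The GP uses a stationary RBF kernel; strongly asymmetric cycles are
  followed through the dense mean, not through a cycle-aware kernel.
- The weight map assumes in-plane isotropy (distances in voxel units).
- The reference threshold backend presumes the cavity is the brightest
  intensity population; it is a pipeline test fixture, not a segmentation
  method.
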