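# Methods

## Measurement model

The tear meniscus is modelled as a thin band of fluid pooled along the lower
eyelid margin. Under gravity the tangent at the band's lowest point is
horizontal, so the meniscus height is well defined as a *vertical* chord
there. On a binary mask the measurement is:

1. **Largest component.** Segmentation may emit stray blobs; only the
   largest 8-connected component is measured. When two components tie on
   area, the one whose lowest pixel has the larger row index wins — the
   meniscus is the bottom structure in an ocular photograph. (Remaining ties
   fall back to first-labelled order, which is raster order.)
2. **Lowest point.** The maximum-row foreground pixel. A flat bottom row is
   expected (the tangent argument), so among bottom-row pixels the
   lower-median column is taken: deterministic, central, and insensitive to
   single-pixel jitter at the ends of the row.
3. **Vertical chord.** The contiguous run of foreground pixels in the lowest
   point's column, counted inclusively. The run *containing* the point is
   used rather than all foreground pixels in the column, so a disjoint
   reflection artifact higher in the column cannot inflate the reading.
4. **Calibration and label.** `TMH_mm = chord_px * mm_per_px` exactly;
   `dry_eye = TMH_mm < threshold` with strict inequality (a meniscus of
   exactly the criterion height is not dry). The default threshold is
   0.20 mm, the usual clinical screening criterion.

Measurements are integer-pixel throughout. Sub-pixel interpolation is a
non-goal: the quantity is defined on a mask, and the phantom studies below
show the discretization cost is at most one pixel.

An alternative geometry found in the literature drops a vertical from the
corneal centre; it misreads tilted eyelids whose lowest point is not under
the cornea. The lowest-point construction used here has no such failure
mode, which is why the phantom generator exposes tilt as a parameter.

## Phantom generator

The generator emulates the geometry of an infrared ocular-surface
photograph, not its appearance. In the untilted frame:

* **Eyelid margin**: `margin_row(col) = c − a·(col − b)²` with `a > 0`; the
  apex `(c, b)` is the on-screen lowest point and the arms curve upward,
  like a lower lid. Rows grow downward everywhere in the package.
* **Band**: pixels with `margin − t(col) < row ≤ margin`, where
  `t(col) = t₀·(1 + m·sin(2π(col − b)/W))` is the local vertical thickness:
  nominal `t₀` at the apex, sinusoidally modulated by `m ∈ [0, 1)` along the
  eyelid with one period across the image width.
* **Tilt**: the whole geometry is rotated about the image centre by
  `tilt_deg`. Rasterization inverts the rotation per pixel centre and
  applies the analytic band test — no image resampling, so masks are exact.
* **Rendering**: background 0.15, corneal ellipse 0.05, band 0.85, plus a
  linear horizontal illumination ramp and additive Gaussian noise, clipped
  to [0, 1]. Noise corrupts only the image; the mask is always the noiseless
  band raster.

**Ground truth** is defined on the noiseless rasterized mask: an internal
direct scan (independent of the measurement module) reads the lowest-point
vertical chord and multiplies by the calibration. This makes the ground
truth exact at pixel precision; tests verify it agrees with a 4×
supersampled rasterization of the same continuous geometry to within one
pixel.

Defaults: 128×128 px at 0.01 mm/px (so a 0.20 mm meniscus spans 20 px —
topographer calibration is not published, so this is a stand-in, not a
device constant), apex near (96, 64), curvature `a ∈ [0.002, 0.005]` px⁻¹.

### Cohorts

`generate_cohort` draws band thickness from a two-component mixture:
U(0.08, 0.18) mm with probability `dry_eye_fraction` (dry), U(0.215, 0.40) mm
otherwise (normal). Tilt is U(−10°, 10°), noise SD 0.02, illumination ramp
U(0, 0.1). Because tilt slides the measured lowest point away from the apex
into modulated-thickness territory (and inflates the vertical chord by
1/cos tilt), the modulation amplitude is bounded per sample so that every
possible vertical chord stays on its component's side of the 0.20 mm
criterion, with one rasterization pixel of safety. Near-criterion menisci
are therefore rendered nearly uniform while clearly-dry/normal bands modulate
up to 30 %. The labelled prevalence then equals `dry_eye_fraction` in
expectation, while the label itself is always derived from the rasterized
ground truth.

What the phantoms deliberately do **not** emulate: Placido-ring reflections,
eyelashes, specular highlights, partial blinks, upper-eyelid meniscus, and
realistic tear-film texture. Passing on phantoms therefore demonstrates the
correctness of the geometry, the harness contracts and the metric suite —
not clinical-grade segmentation robustness.

## Segmenters

**Classical baseline.** Otsu threshold estimated on the lower half of the
frame (the meniscus lives there; bright upper-field structure would skew a
global estimate), applied to the whole frame, followed by 3×3 binary opening
and largest-component retention. Pure function of its inputs; uniform or
empty results yield an empty mask rather than an error.

**Trainable segmenter.** A fully convolutional pixel classifier written
directly in numpy: 5×5 convolution (8 channels, edge padding) → ReLU → 1×1
convolution → sigmoid, 217 parameters, He-initialised, inputs centred at
0.5. Loss is pixelwise binary cross-entropy. The optimizer is minibatch SGD
with momentum 0.9, weight decay 5·10⁻⁴ applied to the gradient, initial
learning rate 10⁻³ and a step schedule
`lr(epoch) = lr₀ · 0.2^⌊epoch/40⌋` (exact, asserted in tests). After every
epoch the validation mean per-image IoU is recorded; the harness returns the
parameters of the *first* epoch attaining the peak, not the final epoch. A
non-finite loss aborts with a diagnostic.

IoU on an image where both the reference and the predicted mask are empty is
defined as 1.0 (and 0.0 when exactly one is empty); otherwise degenerate
all-background tasks would divide 0 by 0.

The tiny architecture is a deliberate trade: on high-contrast phantoms it
reaches validation mean IoU ≈ 0.94 in 30 epochs on one CPU in about half a
minute, which is enough to exercise every harness contract (schedule,
checkpointing, determinism, serialization). It is not a clinical-grade
instance segmenter and makes no multi-scale or instance-level claims.

## Evaluation suite

* **IoU** `|A∩B|/|A∪B|` per image; the aggregate is the unweighted mean of
  per-image values (the same statistic the training harness tracks).
* **Confusion matrix** at the operating threshold, positive class = dry eye;
  sensitivity, specificity and Youden `J = se + sp − 1` with explicit
  undefined-metric errors when a class is absent. `J` is mathematically
  bounded in [−1, 1], which a property test enforces on random matrices.
* **ROC/AUC**: the screening score is −TMH (lower TMH ⇒ more dry). The sweep
  visits each unique score once plus a sentinel, so ties produce diagonal
  segments and the trapezoidal area equals the tie-corrected Mann–Whitney
  statistic (asserted to 1e−9 against pairwise enumeration and
  scikit-learn). An ROC needs the continuous score: a single binary
  operating point would give a degenerate two-segment curve, so the 0.20 mm
  point is reported separately as the confusion matrix.
* **Regression agreement**: OLS of the reference (manual) TMH on the
  automatic TMH, `R² = SSR/SST`; for OLS with intercept this equals
  1 − SSE/SST, and the equivalence is asserted in tests. The automatic
  reading is the regressor because the question is how well the automatic
  value explains the reference one.
* In the end-to-end report, a predicted mask with no meniscus is scored TMH
  0 mm (maximally dry) and counted in `n_failed` rather than dropped:
  silently excluding failures would bias screening metrics optimistically.

## Pipeline and reproducibility

All randomness flows from one global seed; stages derive sub-seeds by fixed
offsets (cohort +0, split +1, training +2). Reruns with the same
configuration are byte-identical for CSV/JSON artifacts (asserted in tests).
Dataset splits use largest-remainder rounding, so (0.7, 0.2, 0.1) on 1,200
records gives exactly (840, 240, 120). Serialized coordinates are 0-based
(row, col), row increasing downward; masks are 0/255 single-channel PNGs and
any nonzero value reads back as foreground.

## Problem sizes

The validation studies use 500 random masks for the brute-force agreement
check, 200 clean phantoms spanning tilt ∈ [−15°, 15°] and thickness ∈
[0.08, 0.40] mm for ground-truth recovery, a 300-phantom cohort at 30 %
dry-eye prevalence for screening metrics, and 200 train / 50 val phantoms at
128×128 for 30 epochs for the training harness. These sizes give stable
statistics (binomial 99 % intervals for prevalence checks) while keeping the
whole suite fast on a single CPU.

## Known limitations

* Phantom realism is geometric, not photometric; see above.
* The trainable segmenter is a pixel classifier, not an instance segmenter;
  overlapping structures or multiple menisci per image are out of scope.
* Integer-pixel measurement quantizes TMH to `mm_per_px` steps; at the
  default calibration that is 0.01 mm.
* The pixel calibration of real topographer exports must be supplied by the
  user; the package default is only meaningful for phantoms.
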