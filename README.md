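# tmhkit

Automatic measurement of **tear meniscus height (TMH)** on ocular-surface
images, with a full synthetic validation harness.

The tear meniscus is the strip of tear fluid pooled along the lower eyelid
margin; its vertical height at the lowest point of the meniscus indexes tear
volume and is a standard screening metric for dry eye (TMH < 0.20 mm is the
usual criterion). In clinical practice TMH is read off corneal-topographer
photographs by hand, which is slow and subjective. `tmhkit` implements the
automatic alternative as a tested, reusable library and CLI for researchers
who want to segment the meniscus, measure its height, and quantify how well
an automatic reader agrees with a reference one.

## What it computes

Given a binary meniscus mask **M** on an image with calibration *s*
(mm/pixel):

1. keep the largest 8-connected component of **M**;
2. find the lowest point *(r\*, c\*)* — the maximum-row foreground pixel
   (gravity makes the meniscus tangent horizontal there), ties broken by the
   lower-median column;
3. the TMH is the contiguous vertical run of foreground pixels through
   *(r\*, c\*)*: `TMH = s · chord_px`, and `dry_eye = TMH < 0.20 mm`
   (strict).

Segmentation is pluggable behind one `predict(image) -> mask` contract: a
deterministic classical baseline (lower-half Otsu threshold, 3×3 opening,
largest component) and a small fully convolutional classifier (~220
parameters, plain numpy) trained by SGD with momentum 0.9, weight decay
5·10⁻⁴, learning rate 10⁻³ stepped ×0.2 every 40 epochs, checkpointed at the
epoch of peak validation mean IoU.

Evaluation covers the standard suite: per-image IoU
(`|A∩B| / |A∪B|`), the dry-eye confusion matrix with sensitivity
`TP/(TP+FN)`, specificity `TN/(TN+FP)` and Youden index
`J = sensitivity + specificity − 1`, an ROC sweep over the continuous TMH
score (AUC by trapezoid, equal to the tie-corrected rank statistic), and
ordinary-least-squares agreement of reference on automatic TMH with
`R² = SSR/SST`.

Because clinical Keratograph images cannot be redistributed, the package
ships a parametric **phantom generator**: eyelid-margin parabola, bright
meniscus band of (optionally modulated) thickness, corneal ellipse, eyelid
tilt, illumination ramp and sensor noise — with an exact rasterized
ground-truth mask and analytic TMH for every image. All validation runs on
phantoms with known truth.

## Worked example

```python
from tmhkit import PhantomSpec, generate_phantom, segment_baseline, measure_tmh, iou

spec = PhantomSpec(meniscus_thickness_mm=0.17, tilt_deg=8.0, noise_sd=0.03, seed=7)
sample = generate_phantom(spec)
pred = segment_baseline(sample.image)
m = measure_tmh(pred, sample.image.mm_per_px)
print(f"ground-truth TMH : {sample.true_tmh_mm:.2f} mm (dry eye: {sample.dry_eye_label})")
print(f"segmentation IoU : {iou(pred, sample.mask):.3f}")
print(f"measured TMH     : {m.tmh_mm:.2f} mm at pixel {m.lowest_point} (dry eye: {m.dry_eye})")
```

```
ground-truth TMH : 0.16 mm (dry eye: True)
segmentation IoU : 0.999
measured TMH     : 0.16 mm at pixel (96, 77) (dry eye: True)
```

The 0.17 mm nominal band rasterizes to 0.16 mm at the tilted lowest point;
the baseline segmenter recovers the band almost exactly (IoU 0.999), and the
measured TMH matches the generator's ground truth, below the 0.20 mm dry-eye
criterion.

### Command line

```bash
tmh simulate --n 300 --out data/ --dry-eye-fraction 0.3 --seed 1
tmh train    --manifest data/manifest.json --out model/ --seed 1
tmh segment  --model model/model.npz --images data/images --out pred/
tmh measure  --manifest data/manifest.json --masks pred/ --out measurements.csv
tmh evaluate --manifest data/manifest.json --pred pred/ --out report.json
tmh pipeline --config config.yaml          # all stages, one seed, one output dir
```

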