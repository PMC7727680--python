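# pulmoseg

Two-phase lung-field segmentation for axial chest CT slices.

Automatic lung segmentation is a prerequisite for most quantitative CT
analysis (airway measurement, density scoring, pathology follow-up). Modern
detectors such as Mask R-CNN locate the lungs reliably but produce *coarse*
masks that bound the lung fields without hugging the lung wall. `pulmoseg`
addresses both halves of the practical problem:

1. **Phase 1 — slice gate.** A classifier decides per slice whether lung is
   present at all, so abdomen or neck slices never reach segmentation. The
   gate is selected by a rigorous protocol: features are z-scored with
   training-set statistics only, each classifier family (naive Bayes, MLP,
   k-NN, random forest, linear/polynomial/RBF SVM) is tuned by random search
   with stratified 5-fold cross-validation, and the extractor/classifier
   combination with the highest held-out F1 wins.
2. **Phase 2 — Parzen-window boundary refinement.** The coarse mask is
   eroded into a seed; the seed interior and a surrounding background band
   supply samples for two kernel density estimates
   (f̂ for lung, b̂ for body); each pixel gets the membership posterior

   p(z) = f̂(z) / (f̂(z) + b̂(z)),   f̂(z) = (1/n) Σᵢ δ((z − zᵢ)/h) / h^d

   with Gaussian, uniform, or triangular kernel δ and bandwidth h. The
   region boundary then moves iteratively — 8-connected frontier pixels
   with p ≥ τ join, boundary pixels with p < τ leave — until the pixel flux
   stabilizes on the lung wall.

A seeded synthetic thoracic phantom (bright elliptical body, two dark lung
fields with vessel-like inclusions, Gaussian noise, exact constructive
ground truth, and detector-style mask corruptions) makes every stage
testable without patient data. Evaluation uses the standard pixel-level
suite: accuracy, sensitivity, Matthews correlation, Jaccard, Dice, and the
boundary Hausdorff distance, plus the Friedman rank test with Nemenyi
post-hoc marks for comparing methods across cases.

## Worked example

```python
import pulmoseg as ps

# a 256-px thoracic phantom with exact ground truth
ct, gt = ps.generate_phantom(ps.PhantomSpec(seed=42))

# emulate a detector that over-segments by 4 px
coarse = ps.corrupt_mask(gt, ps.CorruptionSpec("dilate", 4))
print(f"coarse  Dice = {ps.evaluate_masks(coarse, gt).dice:.4f}")

# refine the boundary onto the lung wall
norm = ps.normalize_intensity(ct, "minmax")
res = ps.refine_boundary(norm, coarse, ps.ParzenConfig(seed=0))
m = ps.evaluate_masks(res.mask, gt)
print(f"refined Dice = {m.dice:.4f}  HD = {m.hausdorff:.2f} px "
      f"({res.iterations_run} iterations, converged={res.converged})")
```

prints

```
coarse  Dice = 0.9100
refined Dice = 1.0000  HD = 0.00 px (5 iterations, converged=True)
```

The coarse mask overlaps the truth at Dice 0.91; five boundary iterations
recover the exact lung fields because the phantom's lung/body contrast is
far larger than its noise level, so the intensity posterior is unambiguous
at every boundary pixel. On real CT the gap narrows, but the direction —
refinement improves on the detector's mask — is the method's point.

The same pipeline is scriptable from the shell:

```sh
pulmoseg phantom --output data --n-lung 4 --n-nonlung 2 --corrupt dilate --magnitude 4
pulmoseg train-gate --output gate.joblib --n-per-class 50
pulmoseg segment --input data --coarse data --gt data --gate gate.joblib --output out
pulmoseg evaluate --pred out --gt data
pulmoseg compare --scores method_scores.csv
```

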