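# Methods

## Problem and model

Given an axial CT slice and a coarse binary lung mask from any detector,
the package estimates the true lung-field boundary. The underlying model is
intensity-based and nonparametric: lung parenchyma and surrounding soft
tissue occupy distinct intensity ranges, so the densities of the two
classes can be estimated from spatial samples and each pixel assigned the
posterior probability of belonging to the lung.

**Membership estimation.** With foreground samples {zᵢ} from the seed
interior and background samples from a band beyond the seed, the class
densities are Parzen-window estimates

    f̂(z) = (1/n) Σᵢ δ((z − zᵢ)/h) / h^d

for kernel δ ∈ {Gaussian, uniform, triangular} and bandwidth h, and the
pixel membership is the two-class posterior p = f̂/(f̂ + b̂), defined as
0.5 where both densities vanish (possible with compact-support kernels).
The two-class normalization is a deliberate choice: a single density says
how lung-like a pixel is but not relative to what; the posterior is
calibrated and threshold-stable.

**Kernel normalization conventions.** Two constant conventions are
implemented for the Gaussian forms. `as_printed` uses 1/((2π)^d·|C|) for
the covariance kernel and 1/(N·(2πh)^D) for the isotropic mixture;
`standard` uses the multivariate-normal constants, under which the 1-D
estimate integrates to one (verified numerically in the tests). Because
both classes share kernel and bandwidth, the constants cancel in the
posterior: the refined mask is bit-identical under either convention
(asserted by a test), so nothing downstream depends on the choice.
`as_printed` is the default.

**Boundary refinement.** The algorithm is:

1. Erode the coarse mask by a disc of `shrink_radius` (default 3 px) to
   form the seed. The erosion pulls the sampling region inside the true
   boundary so foreground samples are not contaminated by the wall.
2. Estimate the membership map once from the seed (foreground) and from
   the band outside the seed dilated by 2·`shrink_radius` (background).
   The band's outer width is max(8, 2·shrink_radius) px — wide enough for
   a stable density, narrow enough to stay in peri-lung tissue.
3. Iterate from the **coarse mask**: frontier pixels (8-connected to the
   region, currently outside) with p ≥ τ join; boundary pixels with p < τ
   leave. Starting from the coarse mask rather than the seed makes the
   operation a near-fixed-point when the coarse mask is already correct —
   a property the tests assert — while an eroded start would always
   regrow a full ring on the first iteration.
4. Stop when the per-iteration changed-pixel count falls to
   `stability_tolerance` (default 0) or `max_iterations` (default 100) is
   reached; this is the "movement losing speed" criterion.
5. Keep only connected components intersecting the seed (prevents leakage
   through noise speckles) and fill interior holes (vessels are lung
   tissue and belong in the mask).

The membership map is computed once, not per iteration: the refinement is
a relabelling of a fixed probability field, which makes it monotone-safe,
cheap, and deterministic.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| bandwidth h | 0.05 | normalized intensity | kernel smoothing; small h is noise-sensitive, large h blurs the wall |
| τ (decision threshold) | 0.5 | probability | membership cut; ties (p = τ) count as inside |
| shrink_radius | 3 | px | seed erosion and background-band offset |
| max_iterations | 100 | — | hard stop for the boundary motion |
| stability_tolerance | 0 | px/iteration | flux at which motion counts as converged |
| sample_cap | 5000 | samples/class | seeded subsample cap for density estimation |
| feature_mode | intensity | — | `intensity_xy` appends scaled coordinates (scale 1/image_size) |

In intensity mode the class densities are functions of a scalar in [0,1];
they are evaluated on a 2048-point grid and interpolated per pixel. The
grid spacing (≈5·10⁻⁴) is two orders of magnitude below the default
bandwidth, so the interpolation error is negligible; the spatial feature
mode uses exact blocked evaluation instead.

## The slice gate

The gate's selection protocol is fixed: z-score normalization fitted on
the training set only (population sd; zero-variance features dropped and
recorded), random hyperparameter search per classifier family scored by
mean stratified 5-fold CV accuracy (ties to the earliest draw), final
refit and evaluation on the held-out test set, and selection of the
combination with the highest test F1 — the harmonic mean of precision and
sensitivity — with ties broken by accuracy, then extractor name. Search
ranges: MLP hidden neurons uniform in [2, 1001] (Adam, ≤ 4000 iterations,
tolerance 10⁻³), k-NN neighbours in {1,3,5,7,9}, random-forest trees in
[1, 1500], C log-uniform over [2⁻⁵, 2¹⁵], polynomial degree in {3,5,7,9},
γ log-uniform over [2⁻¹⁵, 2³]. Log-uniform sampling is used where the
printed range spans decades. The default search budget is 60 draws per
family; the test suite and the acceptance script use 6 draws per family
at 128-px slices, which already saturates the phantom task.

Deep CNN extractors are a plugin interface (`register_extractor`); the
built-in extractor is a deterministic 38-dimensional descriptor: 32-bin
normalized intensity histogram, mean, sd, skewness, kurtosis, histogram
entropy, and the dark-interior fraction — the share of body pixels darker
than half the bright-body reference (95th percentile), which is
essentially the lung-field area fraction and carries most of the signal.

## The phantom

The generator emulates what the method actually relies on: a bright
elliptical body (mean 1100) on dark background (0), two dark elliptical
lung fields (mean 250) with bright vessel-like inclusions (1000), and
additive Gaussian noise (sd 40, clipped at zero), in 16-bit-like units
with no Hounsfield claim. Ground truth is the exact discrete union of the
lung ellipses, vessels included. The default canvas is 256 px (geometry
scales proportionally via `PhantomSpec.scaled` for other sizes). The
corruptor degrades truth the way a box-oriented detector does: disc
erosion or dilation, diagonal shift, or a blocky eroded bounding box.

What the phantom does *not* emulate: juxtapleural pathology, partial
volume effects at the wall, intensity inhomogeneity, anatomic variation
of lung shape, and slice-to-slice correlation. Its lung/body contrast
(850 intensity units ≈ 21 noise sd) makes the intensity posterior
unambiguous, which is why refined Dice reaches 1.0 on phantoms; passing
these tests validates the machinery (sampling, densities, boundary motion,
convergence, bookkeeping), not clinical accuracy on real CT, where
contrast at the wall is weaker and the recovered gap is smaller.

## Numerical choices and conventions

- Coordinates are row-major, 0-based, (row, col), origin top-left.
- Minmax normalization maps a constant image to all zeros (keeps the KDE
  defined); z-scoring a constant image is an error.
- MONOCHROME1 DICOMs are inverted on load (max − value) so larger always
  means brighter.
- Hausdorff distance is computed between boundary pixel centres (8-
  connectivity boundary) in Euclidean pixel units; no mm conversion is
  applied unless the caller converts with the stored pixel spacing.
- MCC is defined as 0 when a denominator factor vanishes; a both-empty
  mask pair scores Dice = Jaccard = 1 with a warning (vacuous agreement);
  sensitivity over an empty truth is reported missing, not 0.
- The Friedman statistic uses within-case mid-ranks with the standard tie
  correction (0 when every case is fully tied); pairwise flags use the
  Nemenyi critical difference at α = 0.05.
- All stochastic steps (noise, jitter, subsampling, CV shuffling, search
  draws) derive from explicit integer seeds; fixed seeds give bit-identical
  phantoms, reports, and selections.

## Known limitations

- The membership map is purely intensity-based by default; structures
  with lung-like intensity adjacent to the lung (e.g. bowel gas in a real
  scan) would be joined if 8-connected to the region. The seed-component
  filter mitigates, not eliminates, this.
- One membership estimation per slice assumes the coarse mask is close
  enough that its seed samples the true lung distribution; a grossly
  wrong detector mask violates this and the refinement will stabilize on
  the wrong boundary rather than fail loudly.
- Bandwidth is fixed, not data-driven; h = 0.05 suits 8–16-bit CT-like
  contrast after minmax normalization but should be revisited for
  low-contrast inputs.
- The refinement is strictly 2-D per slice; no through-plane consistency.
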