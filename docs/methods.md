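# Methods

## Feature model

All 33 features are per-image aggregates over the L nucleus instances of a
label map. Conventions that the printed formulas leave open are fixed as
follows and used consistently:

* **Coordinates.** (row, col), 0-based; North is decreasing row, East
  increasing column. Any consistent axis convention yields the same
  feature set up to a relabeling of the eight directions.
* **Perimeter.** P_k is the number of border pixels — nucleus pixels with
  at least one 4-neighbour outside the nucleus (image-edge pixels count as
  border). This is a literal pixel-count perimeter, so digital roundness
  R = 4πA/P² is not capped at 1 (a digital disk sits near 1.2–1.3). Tests
  therefore assert orderings and oracle equality, never R = 1.
* **Directional distance.** A discrete ray walk: starting from the rounded
  centroid pixel, step by one pixel per move — diagonal moves are (±1, ±1)
  — while the visited pixel stays inside the region; the distance is the
  Euclidean norm from the rounded centroid to the last in-region pixel, so
  diagonal distances are √2 × step count, not step counts. Both the ray
  origin and the distance endpoint use the rounded centroid; the ≤0.5 px
  difference from the real-valued centroid is negligible at nucleus scale
  and makes a single-pixel nucleus give exactly 0. If the rounded centroid
  of a concave region falls outside it, all eight distances are 0 and a
  warning is logged — this happens by design for crescents left behind by
  overlapping nuclei.
* **Fitting rectangle.** AR_k is the area of the axis-aligned bounding box
  (not the minimum-area rotated rectangle) — the simplest reading, and
  easily swapped since it is isolated in one place.
* **Divisors.** σ_D (f14–f21) uses the population divisor L; σ_Ik uses the
  population divisor x_k. A constant-intensity region reports exactly 0
  spread (guarded against the ~1e-15 residue of floating-point means).
* **Intensity channel.** Luminance 0.299R + 0.587G + 0.114B on the 0–255
  scale by default; `red`, `green`, `blue` and `hematoxylin` are config
  options.
* **Empty images.** L = 0 produces an all-zero vector plus a logged
  warning rather than an error, so batch runs keep every image in the
  table.
* **No resizing.** Features are computed in native pixels; scale enters
  f2, f3 and the directional statistics directly.

## Synthetic nucleus fields

The generator is the test substrate: it produces the morphological
contrasts the features are supposed to detect, with exact ground truth.

* **Shape.** Star-convex radial harmonic perturbation of a disk:
  r(θ) = r0·(1 + a·Σ_h c_h cos(hθ + φ_h)) with L1-normalised harmonic
  weights, then an area-preserving eccentric stretch (axis scale
  1/√(1−e)) and a seeded rotation. With a = e = 0 the rasterised mask is
  exactly the digital disk (dr² + dc²) ≤ r0², which anchors the analytic
  tests. Shapes collapsing below 5 pixels are resampled (error after 100
  attempts).
* **Rendering.** A grayscale stain canvas (light background, darker
  nuclei) is mapped to RGB through a single-stain Beer–Lambert model with
  the Ruifrok–Johnston hematoxylin absorbance vector, so colour
  deconvolution in the segmenter sees a realistic purple-ish signal.
  Additive Gaussian pixel noise (σ = 2 by default) is applied in RGB and
  clipped to [0, 255].
* **Placement.** Rejection sampling of centres inside a margin. With
  probability `overlap_fraction` a centre is drawn within 1.5 radii of an
  existing nucleus; otherwise a placement is accepted only if its mask is
  pixel-disjoint from all earlier ones, so `overlap_fraction = 0`
  guarantees the label map has exactly the requested number of instances.
  In crowded fields where disjoint placement keeps failing and overlap is
  allowed anyway, the sampler falls back to near-placement; where masks
  overlap the later label wins the contested pixels.
* **Seeding.** The master seed spawns one `SeedSequence(seed,
  spawn_key=(i,))` per image, so datasets are byte-identical across runs
  and images are independent.
* **Default class conditions.** Benign: r0 = 14 px, jitter 0.15,
  irregularity 0.05 (3 harmonics), eccentricity 0.1, 12–18 nuclei, no
  overlap, stain 90 ± 10, heterogeneity 5. Malignant: jitter 0.35,
  irregularity 0.45 (6 harmonics), eccentricity 0.45, 15–25 nuclei,
  overlap 0.3, stain 100 ± 25, heterogeneity 20. Background 220, canvas
  256 × 256. These effect sizes are deliberately strong — comparable to
  the textbook benign/malignant contrast — so the full chain separates
  the classes nearly perfectly; they are the documented study conditions,
  not tuning knobs.
* **What it does not emulate.** Chromatin texture, stromal and glandular
  context, staining batch effects, magnification changes, touching
  *tissue* structures. Passing tests show the features measure the
  geometry and intensity they claim to measure, not that real
  histopathology reaches the same accuracy.

## Segmentation front-end

Colour deconvolution (hematoxylin OD channel) → Otsu threshold →
morphological opening (radius 1) → 8-connected components → area filter
[30, 50000] px → optional distance-transform watershed split (Gaussian-
smoothed distance, peak separation 8 px). Otsu always bisects a
histogram, so on stain-free images the threshold must additionally clear
the image median by 0.05 OD units before any foreground is accepted.
The stage is deliberately swappable: every downstream function accepts
externally supplied instance maps, and the pipeline can run on ground
truth (`masks: ground_truth`) to isolate feature behaviour from
segmentation error.

## mRMR ranking

MID (difference) variant with plug-in mutual information in bits on
10-bin quantile-discretised features. Constant features occupy a single
bin (MI = 0). Scores are the selection-time criterion values — raw
relevance for the first pick, relevance minus mean redundancy afterwards —
and can go negative. Near-ties in the criterion (within 1e-12) keep the
lower feature index, making the order deterministic and robust to
floating-point summation order.

## Classifier bench

Seven fixed configurations (see README). Unstated hyperparameters were
fixed once for stable convergence at this problem size: the 64-unit
network trains for 200 epochs with batch 32 and learning rate 1e-3, no
early stopping; the decision tree's "100 splits" cap is implemented as
max_leaf_nodes = 101 (a binary tree with ≤ 100 internal splits has ≤ 101
leaves) with Gini impurity and no surrogate splits. Standardisation is
applied to the SVM and 1-NN inputs, min-max scaling to the three neural
models, nothing to the tree ensembles; all scaling statistics are fitted
on the training partition only. Evaluation uses a single stratified 80/20
split shared by all classifiers; ROC curves sweep the unique scores
descending with tie blocks processed at once, which makes the trapezoidal
AUC exactly equal to the Mann–Whitney pair-counting statistic.

## Problem sizes

The reference computation (and `scripts/acceptance.py`) uses 50 images
per class at 256 × 256 px with ~12–25 nuclei each; feature extraction and
the full bench complete in a few seconds on one CPU. Segmentation quality
(mean best-match instance IoU) is measured on the benign images, whose
ground truth is unambiguous; overlapping malignant nuclei share pixels in
the rendered image, so their IoU against the occluded ground truth is not
a meaningful segmentation score.

## Known limitations

* The directional walk returns 0 for concave regions whose rounded
  centroid falls outside the region; at high overlap this inflates the
  directional spread features (which, on this generator, happens to add
  class signal — real data may behave differently).
* Border-pixel perimeter is resolution-dependent and exceeds the
  continuum perimeter; roundness values are comparable within a dataset,
  not against the continuum 4πA/P² = 1.
* The synthetic generator's strong effect sizes mean near-ceiling
  classifier scores; the bench differentiates classifiers only on harder
  (real or deliberately weakened) inputs.
* 90° rotation equivariance of the directional features is exact up to
  centroid rounding; a centroid landing exactly on a half-pixel boundary
  can shift one ray by one pixel.
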