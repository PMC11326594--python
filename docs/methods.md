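# Methods

`folliscan` implements a classical computer-aided pipeline for polycystic
ovary syndrome (PCOS) screening on B-mode ultrasound: contrast
enhancement, hybrid fuzzy-c-means / active-contour follicle segmentation,
GLCM texture features, and classification by instance-based, linear and
ensemble learners plus a compact CNN. Because no public image cohort
exists for this task, the package ships a parametric phantom generator
that reproduces the geometric and statistical properties the pipeline
relies on, and every quantitative claim in the test suite is made on those
phantoms or on embedded published worked examples.

## Phantom model

A phantom is a smooth tissue background multiplied by fully developed
speckle, with dark elliptical follicles composited in:

- **Speckle.** Multiplicative Gamma noise with unit mean and shape
  parameter `k = 4` (per-pixel coefficient of variation `1/sqrt(k) = 0.5`),
  the standard fully-developed-speckle approximation for envelope-detected
  ultrasound. Shape is configurable.
- **Background.** Mean echo level 150 (of 255) modulated by ±8% smoothed
  Gaussian shading, emulating slow gain/attenuation variation.
- **Follicles.** Non-overlapping ellipses, major-axis diameter sampled in
  2–9 mm (class recipes use 2.5–9 mm so the clinical 2 mm minimum-size rule
  cannot discard a true follicle), axis ratio in [0.7, 1], interior echo
  level 40 (hypoechoic), rims feathered by a 1-px Gaussian so boundaries
  are soft. Placement enforces 1 mm clearance between follicles and from
  the frame so each follicle is individually resolvable; placement is by
  rejection sampling and raises an explicit error when the requested count
  cannot fit.
- **Class recipes.** PCOS: 8–15 follicles; normal: 0–2. Default canvas
  224×224 px at 0.2 mm/px, so 2–9 mm spans 10–45 px.
- **Determinism.** Everything is a pure function of (spec, seed); dataset
  generation derives per-image seeds from a master seed via
  `numpy.random.SeedSequence` spawning.

What the phantoms do *not* emulate: depth-dependent resolution and
attenuation, acoustic shadowing/enhancement, ovarian stroma and
neighbouring anatomy, probe-specific point-spread functions, or operator
variability. Passing tests therefore demonstrate the pipeline's internal
correctness and its behaviour on speckle-limited imagery with known
geometry — not clinical performance.

## Preprocessing

Grayscale conversion uses ITU-R BT.601 luma weights. CLAHE divides the
image into an 8×8 tile grid (reflect-padded to a tile multiple), equalizes
each tile's 256-bin histogram with the excess above `clip_limit` × (mean
bin count) redistributed uniformly, and remaps every pixel by bilinear
interpolation between the four nearest tile mappings. The mapping is
`round(255·cdf)`; with one tile and an infinite clip limit this reduces to
global histogram equalization, which the tests exploit as an oracle.
Defaults (8×8 tiles, clip limit 2.0) are the common CLAHE defaults.
Gaussian denoising uses sigma 1.0 px with reflective boundaries. Order is
grayscale → CLAHE → Gaussian; CLAHE before smoothing keeps the contrast
gain from being diluted, and the smoothed result is what both FCM and the
snake's edge field consume.

## Segmentation

**Fuzzy c-means.** Pixel intensities are clustered into `c = 4` groups by
minimizing `J(U,V) = Σ_i Σ_j u_ij^m |x_i − v_j|²` with fuzzifier `m = 2`,
alternating the closed-form membership and centroid updates from a
uniform-random membership initialization (seeded). Iteration stops when
the largest centroid shift falls below 1e-5 (default) or at 100
iterations. Memberships row-normalize to 1 exactly; zero-distance pixels
receive crisp membership. Centroids are reported sorted ascending so
cluster indices are well defined.

**Cluster selection.** Follicles are fluid-filled and hypoechoic, so the
darkest cluster is selected by default; an explicit index and a
ground-truth-overlap calibration strategy are available. The published
account labels "cluster 3" as the follicle cluster, but FCM clusters are
unordered, so a semantic rule (darkest) is the only transferable choice.

**Candidate pruning.** Components of the selected cluster are pruned
before refinement: size (equivalent diameter within 80%–120% of the
configured 2–12 mm band) and a hypoechogenicity gate — a component is kept
only if its mean interior intensity is at most 0.6× the mean intensity of
a 4-px surrounding annulus. On follicle-free speckle images the darkest
cluster otherwise returns dark speckle clumps; measured interior/surround
ratios are 0.35–0.44 for true follicles versus 0.80–0.89 for speckle
clumps, so 0.6 sits between the populations. This gate is what produces
the clinically expected "no follicles found" outcome on normal frames.

**Active contour.** Each surviving component's 2-px-dilated boundary,
resampled to ~1 vertex/px, initializes a closed Kass-style snake with
elasticity α = 0.1, rigidity β = 1.0. The external energy is the negative
squared gradient magnitude of the sigma-2-smoothed image, normalized to
[0, 1]; normalization makes the defaults image-independent. The update is
semi-implicit, `x ← (I + γA)⁻¹(x + γF(x))` with the circulant
pentadiagonal stiffness matrix `A`; a step that would raise the discrete
snake energy is retried with a halved step and the contour stops when no
decreasing step exists, so energy is non-increasing by construction. The
step size is γ = 1.0: with a unit-normalized field a vertex advances about
γ·|∇field| px per step, and a much smaller γ cannot cross the ~2σ capture
range within the 250-iteration budget. On a sharp synthetic disk the
refined contour sits within 0.15 px of the true boundary.

Refined contours are rasterized, relabelled, size-filtered (2 mm minimum —
smaller follicles are clinically disregarded as indistinguishable from
speckle — and a 12 mm ceiling, the 9 mm anatomical bound plus overshoot
tolerance) and gated again. The follicle count is the component count.

## Texture features

Ten features per image: five first-order statistics of the raw masked
intensities (mean, population variance and SD, skewness
`(1/N)Σ((x−x̄)/σ)³`, non-excess kurtosis `(1/N)Σ((x−x̄)/σ)⁴`; a
zero-variance region reports skewness = kurtosis = 0 by convention) and
five GLCM statistics (contrast, correlation, energy = Σp², homogeneity,
entropy = −Σ p ln p) of the quantized region. The GLCM uses 8 gray
levels, distance 1, the four standard directions accumulated, symmetric
counting, and — unlike library implementations — a mask: a pixel pair
contributes only when both pixels are inside the segmented region.
Features are computed on the union mask of all detected follicles; when
nothing is detected (typical normal frame) the whole frame is used, so the
feature row still characterizes the image. Natural log is used for
entropy. Correlation is defined as 0 when a marginal is degenerate.

## Classifiers

- **k-star** (from scratch): per-attribute exponential transformation
  kernel `P(d) ∝ exp(−d/x0)`, with `x0` solved by bisection per query so
  the effective neighbour count `(Σp)²/Σp²` equals
  `n0 + b·(N − n0)` (blend `b = 0.2` default, `n0` = instances at minimal
  distance). Joint instance probability is the product over attributes;
  class probability is the normalized same-class sum. Class probabilities
  are invariant to duplicating the training set. Missing values are not
  supported — the pipeline never produces them.
- **Linear SGD**: hinge loss, no penalty, constant learning rate 0.001 for
  100 epochs of seeded per-sample updates on internally standardized
  features; the reported coefficients are the Polyak average of the
  iterates, which leaves the update rule untouched but removes the
  last-iterate sensitivity of plain SGD to whichever margin violations
  come last.
- **Random forest**: 100 bootstrap trees with random feature subsetting;
  vote ties resolve to the lower class index in sorted label order.

Evaluation uses a stratified seeded 80/20 split. PCOS is the positive
class everywhere.

## F-Net

A deliberately tiny CNN (11,778 parameters at default widths
16,16,16,32,32,32,64; FC 64→32→2): seven 1×1 stride-1 convolutions in two
ReLU blocks of three, each block closed by batch normalization and a
stride-1 2×2 max pool (same-size output; a conventional stride-2 option
exists), a final widening conv, one global average pooling, and three
fully-connected layers ending in a 2-way softmax. Since 1×1 kernels carry
no spatial extent, the model is a per-pixel channel-mixing network pooled
over the frame: it discriminates classes through pooled intensity
statistics (the fraction of dark follicle fluid), with the stride-1 max
pools supplying the only local spatial coupling. Batch normalization is
placed once per block; the alternative (after every conv) is structurally
ambiguous in the published description and adds parameters without
changing the census invariants.

The network is implemented directly on numpy with hand-written
backpropagation — 1×1 convolutions are per-pixel matrix multiplications,
so no convolution framework is needed. Training is SGD on softmax
cross-entropy, learning rate 0.001, heavy-ball momentum 0.9, 10 epochs,
batch 4, 70/30 stratified split, all seeded; given a fixed BLAS a run is
bit-reproducible. At a few dozen training images the optimizer settings
matter: batch 4 gives proportionally more updates at the fixed learning
rate, and momentum consolidates them — without it the decision oscillates
near the boundary within the ten-epoch budget instead of settling
(momentum 0.9 is the conventional default for an SGD optimizer and is a
free choice here; the learning rate and epoch count are fixed by the
recipe). The history records end-of-epoch evaluations of the current
weights. The
global average pooling sits immediately before the FC head. Smoke-scale
runs use 112×112 inputs (the architecture is size-agnostic; 224 is the
default) and phantom recipes with disjoint background intensities, which
is the regime a pooled-statistics classifier can learn in ten epochs.

## Evaluation statistics

Confusion-matrix diagnostics treat PCOS as positive and report accuracy,
precision, recall, specificity, F1, NPV, and the false discovery
(`FP/(FP+TP)`) and false omission (`FN/(FN+TN)`) rates; any
zero-denominator ratio is reported as absent rather than 0. AUC is the
midrank (Mann–Whitney) statistic, identical to trapezoidal integration of
the ROC with tie handling; tests check it against a brute-force
pair-counting oracle. Cohort comparisons report mean ± SD per group,
percent difference `|mean_PCOS − mean_normal|/mean_normal × 100` (the
convention identifier is recorded; this convention reproduces 8 of the 10
published dataset-1 rows — the variance row is a typo in the source and
the skewness row uses the opposite denominator, and both are carried as
informational, not graded), and a Welch two-sample t-test p-value (the
source reports p-values without naming a test; Welch makes no
equal-variance assumption). Segmentation agreement is the symmetric mean
boundary distance in mm (every boundary pixel's distance to the nearest
opposite boundary, both directions) plus the Pearson r between paired
per-image foreground areas — the paired quantity is not specified in the
source, and per-image area is the natural scalar a sonographer would
compare.

## Problem sizes and numerical choices

Test-suite and acceptance runs use: 40+40 phantoms for the end-to-end
classical run, 20 phantoms for count-recovery, 64-pixel images for the
FCM-vs-brute-force oracle (tolerance 1e-6 against a 1e-12 fixed point),
≤250 snake iterations on a 100×100 disk, and 40 phantoms / 10 epochs for
the F-Net smoke run — sizes chosen as the smallest at which each
behaviour is stable and meaningful. FCM ties at zero distance give crisp
memberships split across coincident centroids; empty masks raise explicit
errors with a whole-frame fallback available for feature extraction;
degenerate (constant) regions use the zero-moment convention above.

## Known limitations

- Phantoms are statistically, not anatomically, realistic; results do not
  transfer to clinical imagery without revalidation.
- Normal phantoms may carry up to two follicles whose interiors are, by
  construction, statistically identical to PCOS follicles; the union-mask
  texture features of such an image are therefore close to a PCOS row, and
  only count- or area-like quantities (not part of the ten-feature vector)
  fully separate those cases. Held-out accuracy of the classical path
  consequently varies from draw to draw (linear SGD typically mid-80s to
  mid-90s percent; the forest somewhat higher); the reported end-to-end
  figures are per-seed instances of that distribution, not a guarantee.
- The darkest-cluster rule assumes hypoechoic targets; other lesion types
  would need a different selection strategy.
- The snake has no balloon force, so it must be initialized outside (or
  near) the target boundary — the dilated-component initialization
  guarantees this within the pipeline.
- Stride-1 max pooling keeps F-Net's feature maps full-size, which is
  faithful to the published design but costs memory; the stride-2 option
  is the pragmatic alternative.
- k-star prediction is O(N·d) per query with a bisection per attribute;
  it is meant for the small feature tables this pipeline produces.
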