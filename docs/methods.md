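# Methods

`fundusma` detects microaneurysms (MAs) — the earliest diabetic-retinopathy
lesion, visible as small isolated dark-red dots — in color fundus
photographs. The pipeline is classical: per-image preprocessing, vessel
removal, candidate extraction by connected-component shape analysis, a
44-dimensional patch descriptor centred on a directional local contrast
(DLC) measure, and a classical classifier producing a per-candidate MA
score that is evaluated at lesion level.

## Pipeline model and assumptions

**Green channel and FOV.** All analysis runs on the green channel
`I_g ∈ [0,1]`, which carries the highest lesion/background contrast in
fundus photography, restricted to the field of view (FOV). The FOV is
estimated as the largest connected component of pixels whose mean-channel
intensity exceeds 6 % of full scale, hole-filled and eroded by 3 px to
suppress rim artifacts. The method assumes a single connected illuminated
disk on a dark surround; it does no vendor-metadata parsing.

**Shade correction.** The slowly varying background is estimated with a
large median filter (nominal 50 px, odd-adjusted to 51 so the window is
centred) and removed:

    I_bg = median_{51×51}(I_g),   I_eq = I_g − I_bg,
    I_sc = clip(I_eq + mean_FOV(I_g), 0, 1)

The window must exceed the widest vessel so vessels are foreground, not
background. The median runs as a sliding-histogram rank filter on the
8-bit grid with explicit reflect padding; since `I_g` originates from
8-bit files this loses no information, and it keeps the operation
O(N·k) instead of O(N·k²). Adding the FOV-mean restores the original
gray range; the identity `mean_FOV(I_sc) = mean_FOV(I_g)` holds exactly
when no clipping occurs.

**Contrast enhancement and denoising.** `I_sc` is enhanced with CLAHE
(8×8 tiles, clip limit 0.05 as a fraction of tile pixels, output
rescaled to [0,1]) and smoothed with a unit-sum 7×7 Gaussian kernel,
σ = 1.0 (the 7 ≈ 2·3σ+1 truncation convention), giving `I_CLAHE` and
`I_gauss`. The clip limit matters: with scikit-image's CLAHE semantics a
0.01 clip is nearly linear and leaves lesions mid-gray, which defeats
the global binarization of the candidate stage; 0.05 reproduces the
intended behavior (lesions near-black after enhancement) and remains
configurable.

**Vessel enhancement and segmentation.** At each scale
σ ∈ {3, 4, 5, 6} px the Hessian of the Gaussian-smoothed `I_sc` is
computed with σ²-normalized derivative kernels (γ = 2 normalization,
without which the smallest scale dominates the multi-scale maximum).
Its eigenvalues are ordered |λ2| ≥ |λ1|; on a dark tube λ2 is large and
positive across the tube. With λρ the largest positive λ2 inside the
FOV at that scale, the enhancement response is

    E = 0                            λ2 ≤ 0 or λρ ≤ 0
    E = 1                            λ2 ≥ λρ/2 > 0
    E = λ2²(λρ−λ2)(3/(λ2+λρ))³       otherwise

bounded on [0,1] and maximal at λ2 = λρ/2. λρ is a per-scale scalar
(`lambda_rho_scope: per_scale`); a joint-over-scales variant is
available in config. The final vessel mask is the Otsu binarization of
the pixelwise max response over scales, with connected components
smaller than `min_vessel_region_area` (default 400 px²) removed so that
dot-like lesions — which the tube filter also enhances — drop out of
the mask and survive as candidates. The cutoff is an absolute pixel
area chosen to exceed the largest annotated MA (361 px in public
databases) while keeping thin vessel fragments; an optional FOV-area
rescaling supports mixed-resolution datasets but is off by default
because lesion areas are absolute pixel quantities.

**Candidate extraction.** Vessel pixels are set to zero in `I_gauss`
(`I_gsBV0`), the FOV-mean green level is subtracted, and the result is
min–max stretched to [0,1] inside the FOV (`I_CS`; a 1st–99th
percentile stretch is available in config). Candidates are the dark
class of the Otsu binarization of `I_CS` restricted to strictly
positive values — the strict inequality excludes the exactly-zero
removed-vessel pixels, so no candidate can overlap the vessel mask.
8-connected components are measured (area, moment-ellipse axes), and
two filters apply in a single pass:

* slender rejection: components with axis ratio
  R = major/minor > 1.2 × mean(R) are discarded (residual vessel
  fragments are elongated; dots are not). Degenerate 1-px-wide
  components get R = ∞ and always fail. The mean is not recomputed
  after removals.
* area cap: components above 500 px are discarded (hemorrhages and
  artifacts; MAs are far smaller).

Each surviving region yields a 25×25 patch from `I_CLAHE`, `I_g` and
the original RGB, centred on the half-up-rounded centroid with reflect
padding at image borders.

**The 44-feature descriptor.** Ordered blocks: pooled mean/std per
color space (RGB, HSV, CIELab — 2 values per space, pooling all three
channels); mean/std on `I_g` and `I_CLAHE`; 12 DLC components; six
shape measures (Area; Perimeter as Freeman-weighted boundary length;
Circularity = P²/4πA; Eccentricity = c/a of the moment ellipse; Aspect
ratio with the minor axis floored at 0.5 px; Solidity = Area / pixel-
centre convex-hull area); four texture measures (Entropy of the 8-level
quantized histogram; Energy and Homogeneity of the symmetric, distance-1
GLCM averaged over 0°/45°/90°/135°; Skewness of raw intensities, defined
0 for constant windows); mean/std of the Gaussian-filtered `I_CLAHE` at
σ ∈ {1, 2, 4, 8}, filtered on the full plane before windowing to avoid
patch-border bias; and mean signed dx/dy over the patch and over the
region boundary (central differences, boundary gradients sampled on the
full plane).

The DLC of the patch centre p along angle θ is

    DLC_p(θ) = (I_p − Ī_p(θ)) / Ī_p(θ),
    Ī_p(θ) = mean of I at (x_p + k cosθ, y_p + k sinθ), k = 1..r

with r = 12 (half the patch size), 12 angles at 30° steps,
nearest-pixel sampling (bilinear available in config) and Ī floored at
1/255 because an equalized plane can contain exact zeros. An MA —
locally darkest in every direction — has strongly negative DLC at all
angles; a vessel is negative only across the tube; a hemorrhage has
neighborhood nearly as dark as its centre (DLC ≈ 0); background is ≈ 0.
This ordering is what the classifier chiefly exploits, and it is
asserted statistically on synthetic patches (one-way ANOVA on mean DLC
across the four classes, with the MA group most negative).

**Classification.** Gaussian naive Bayes, K-nearest neighbours
(K = 5, Euclidean) and SVM-RBF (C = 1, γ = 1/44) all operate on
z-score-standardized features (the scaler is fitted on training data
only and persisted with the model). Scores are posterior probabilities
for NB/KNN and the logistic squash of the SVM decision function —
deterministic, unlike Platt scaling with its internal cross-validation.
No resampling is applied to the (heavily imbalanced) candidate set by
default. NB variances are floored at 1e-9 via the standard smoothing
term so constant features cannot degenerate.

**Evaluation.** Candidate-level ROC/AUC uses candidates matched to a
ground-truth lesion as positives and all other candidates as negatives.
Lesion-level FROC matches detections to truth one-to-one, greedily by
distance; a detection is a true positive if its region contains a truth
centroid or its centroid lies within `match_radius` = 12 px (half the
patch side) of one. The FROC score is the mean sensitivity linearly
interpolated at FPI ∈ {1/8, 1/4, 1/2, 1, 2, 4, 8}, right-constant above
the largest achieved FPI and zero below the smallest. Equal scores
collapse to a single threshold step, so curves are deterministic.

## Synthetic scenes

The generator renders the phenomenology each stage depends on, not
photorealistic retinas: a circular FOV (default 960×960, radius 440) on
a dark surround; smooth multiplicative shading (±15 %); 8 dark vessels
as curvature-bounded random walks with Gaussian cross profile, widths
6–14 px; MAs as dark circular dots with sharp support, diameters
3–12 px, contrast 20–40 % of local background (the size regime of
lesions annotated in public MA databases, well under the 500-px cap); 2 irregular blurred hemorrhages of
700–2000 px²; additive Gaussian noise σ = 0.01; and a red-dominant RGB
synthesis so the green channel is the informative plane. MA placement
rejects positions on or near vessels (a config flag permits
vessel-adjacent MAs to reproduce the known failure mode where an MA is
removed together with an attached vessel). Every draw is governed by
one seed; identical spec + seed is bit-identical.

What the generator does **not** emulate: optic disc and bright lesions,
vessel branching trees and calibre tapering, texture of the neural
retina, JPEG artifacts, inter-image color variation beyond shading.
Passing the synthetic benchmark therefore demonstrates that the
implementation is internally consistent and that each stage does its
documented job on data matching its assumptions — not clinical-grade
performance on real databases, which depends on lesion subtlety and
annotation conventions the scenes do not model.

The "easy contrast" benchmark condition used by the end-to-end checks
draws MA contrasts in [0.3, 0.45] — at or above the stated floor
(`MA_CONTRAST_FLOOR = 0.3`) above which every planted MA is expected to
surface as a candidate. Aggregate candidate recall ≥ 0.9 is the target
there; the residual misses are MAs overlapped by the (deliberately fat)
vessel enhancement mask, the same failure mode observed on real images.

## Numerical choices and degenerate inputs

* Otsu thresholds use a 256-bin histogram of masked values; the
  between-class variance is scanned over all cuts. Constant inputs are
  flagged degenerate: for vessel segmentation this yields an *empty*
  vessel mask (no evidence removes nothing), for candidate extraction
  an empty candidate list, and for the contrast stretch an all-zero
  plane with a warning.
* Reflect padding everywhere a window crosses a border (median filter,
  Gaussian kernels, patch cutting), avoiding dark-rim artifacts.
* Eigenvalues come from the closed-form 2×2 solution; the swap rule
  enforcing |λ2| ≥ |λ1| is exact, and trace/determinant identities hold
  to 1e-8 in tests.
* Patch centres round half-up per axis (deterministic ties).
* Single-pixel regions get perimeter 1 and a 0.5-px minor-axis floor.
* The benchmark problem size — 20 images at 960×960, half for training —
  was chosen so the complete end-to-end evaluation, including three
  classifiers and patch-class sampling, completes in a few minutes on
  one CPU while providing ~300 planted lesions and several thousand
  negative candidates.

## Known limitations

* The candidate stage depends on a global Otsu cut of `I_CS`; images
  whose lesion intensities straddle the threshold lose faint MAs.
  The CLAHE clip limit is the main lever.
* The vessel mask is wider than the vessel (coarse-scale response), so
  lesions within ~2σ of a vessel can be absorbed and removed — the
  dominant source of candidate-stage misses.
* The lesion-matching rule (containment or 12-px centroid distance) is
  one of several conventions in the FROC literature; comparisons across
  tools are only meaningful under a common rule and radius.
* Classifier hyperparameters are reproducible defaults, not tuned
  values; no feature selection is performed (the full 44-vector is
  always used).
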