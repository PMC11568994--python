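# Methods

This note documents the models, parameters and design decisions behind the
package, and what the synthetic study can and cannot say about real
retinal data.

## Keypoint detection by heatmap regression

Vessel crossovers and bifurcations are rare against a vast background, so
the detector regresses smooth confidence surfaces instead of a binary
mask. Targets place a unit-height isotropic Gaussian at each keypoint;
overlapping Gaussians are combined with `max`, not `+`, so a target plane
is a per-pixel detection confidence in [0, 1] and isolated peaks always
reach exactly 1. Three planes are produced — crossovers, bifurcations and
all keypoints combined — the third giving the network credit for finding a
keypoint even when its type is ambiguous.

* Target σ: **3 px** at the 256×256 generator resolution (configurable).
  Narrower targets degrade recall sharply (the positive signal becomes too
  sparse for stable regression), wider ones blur localisation; 3 px was
  fixed once against held-out detection recall and kept.
* Extraction: strict local maxima of the combined plane in a 7×7 window,
  intensity threshold 0.35, class = argmax of the two class planes at the
  peak (ties → bifurcation). The 7 px window matches the generator's 6 px
  minimum keypoint separation, so ground truth is recoverable in
  principle. Predictions are clipped to [0, 1] only at extraction; the
  network's final layer is linear and trained with plain MSE.
* Network: U-Net-style encoder–decoder on a hand-written numpy conv stack;
  desk-scale runs use 3 resolution levels at base width 16 (the
  constructor defaults to 4 levels / width 32 for larger budgets). Output
  resolution always equals input resolution; odd sizes are reflect-padded
  and cropped.
* Training: Adam, single-image batches, random affine augmentation
  (rotation ±90°, scale 0.9–1.1, shear ±20°) plus HSV jitter; targets are
  regenerated from the warped keypoints, not warped as rasters, so they
  stay exact. Random 128² crops keep CPU steps fast. Learning rate starts
  at 1e-4 and is cut ×0.1 whenever validation MSE has not improved for a
  patience measured in steps (default 2500); training stops when the next
  cut would cross 1e-7, or at an explicit step cap for desk-scale runs.
  The returned parameters are the best-validation snapshot. 25 % of the
  scenes form the validation split.

## Dense contrastive descriptors

The descriptor network is a fully convolutional, dilation-based feature
extractor (in the spirit of the modified L2-Net used for dense
description): 3×3 convolutions with dilations (1, 1, 2, 2, 3), channel
plan w, w, 2w, 2w, 2w, batch normalisation after every convolution, a 1×1
projection to D channels and L2 normalisation per pixel. There is no
spatial downsampling, so the descriptor block matches the input size. All
convolutions are *valid*: dense inference zero-pads the input once by the
receptive-field radius (9 px), which makes evaluating the network on a
receptive-field-sized patch centred at a keypoint *exactly* equal to dense
inference at that pixel. Training exploits this: only patches at keypoint
locations are pushed through the network, which is orders of magnitude
cheaper than dense passes on CPU and numerically identical.

* Desk-scale defaults: width 16, D = 128 (the conventional descriptor
  dimension for this task; the 1×1 projection makes D nearly free on CPU).
* Multiviewed batch: one base image + N = 9 augmented views (configurable
  to 1 or 19). Affine ranges: rotation ±60°, translation ±0.25 of each
  axis, scale 0.75–1.25, shear ±30°; photometric: HSV jitter always,
  Gaussian noise σ = 0.05 with probability 0.25. Keypoints are detected
  once, on the base image only; each view receives the warped coordinates.
  A keypoint that leaves any view (or comes within 3 px of a border) is
  dropped from *all* views so K stays constant and the loss index
  structure holds.
* Losses: SupCon and MP-InfoNCE exactly as defined (τ = 0.1), both with
  max-subtraction inside each log-sum-exp (stable down to τ = 0.01), plus
  a triplet baseline (cosine similarity, margin 0.05, random positive view
  and random in-batch negative per anchor — the simplest consistent
  selection rule, since none is prescribed). The two losses' individual
  log-ratio terms coincide for N = 1; the scalar aggregates keep their own
  normalisations (SupCon: 1/N prefactor only; MP-InfoNCE:
  1/(C(N+1,2)·K)). SupCon is invariant to any view relabeling;
  MP-InfoNCE is not (the anchor role follows the lower view index), which
  is a property of the formula as defined, kept deliberately.
* Sub-pixel keypoint coordinates are sampled at the nearest pixel
  (round-half-up per axis); bilinear interpolation of descriptors would
  break the unit-norm contract.
* An "epoch" is one optimizer step on one multiviewed batch (one base
  image). Desk-scale default: 1,500 steps, Adam at a constant 1e-3 (batch
  normalisation makes this rate stable; longer budgets can use the
  conventional 1e-4/15,000 regime, and the triplet baseline its customary
  1e-5 with several times more steps).

## Matching and transform estimation

Matching is bidirectional (mutual nearest neighbour in cosine similarity)
and class-restricted; ties break to the lowest index so results are
deterministic. Matches can be rescaled between detection and evaluation
resolutions (x by W_to/W_from, y by H_to/H_from). The homography is
estimated by RANSAC over 4-point minimal samples solved with a
Hartley-normalised DLT (batched SVD); consensus uses a one-way
reprojection error with a 5 px inlier threshold; the best consensus is
refit by least squares on its inliers (kept only if it does not lose
inliers). The randomized mode runs up to 10,000 iterations with early
stopping at 99.9 % confidence; the exhaustive mode enumerates every
C(M, 4) sample and is used wherever a budget-complete search is required
(VTKRS). Minimal samples containing three near-collinear points are
skipped.

## Evaluation metrics

Per pair, the control-point error is the mean Euclidean distance between
the ten mapped fixed control points and their true moving positions; a
failed registration scores +∞ so it penalises every threshold. The
registration score sweeps integer thresholds t = 1…25 px; success is
error ≤ t; the AUC is the mean of the 25 ratios (the threshold grid and
boundary closure are conventions fixed here and used consistently).
Categories aggregate as an unweighted mean and a pair-count-weighted mean.
VTKRS keeps the top-n matches per class by descriptor similarity
(capped at what a class has), n = 3…25, re-estimates the transform with
exhaustive RANSAC at each n, and averages the 23 per-n AUCs; with n at
the total match count it equals the unlimited score exactly.

## The synthetic study

`conked.synthetic` generates the study data: a bright textured fundus disc
with a low-frequency illumination falloff (fundus photographs are never
evenly lit), dark vessel trees built from cubic Bézier strokes of
decreasing width (4.5–6 px roots, ×0.78 per branching), bifurcations at
the recorded branch events, crossovers at analytic intersections between
different trees, and a 6 px minimum keypoint separation. Registration
pairs warp the scene by a sampled projective transform (affine about the
centre plus perspective terms ≤ 1.5e-4), then corrupt the moving image
with an illumination halo, an HSV shift and a mild blur; category P uses
large translations (low overlap), category A additionally erases the
middle of a few vessel segments (pathology progression), with the
repainted patches locally feathered. Control points are sampled on vessel
centrelines inside the overlap by farthest-point selection, and their
moving positions are the exact images under the true transform.

The desk-scale benchmark (`conked.benchmark`) fixes the study conditions:
ten training scenes and four held-out scenes at 256², three trees with
five branch events each (≈ 20 keypoints per scene), a 1,500–2,000-step
detector training and a 1,500-step descriptor training. Matching
precision is evaluated on held-out pairs whose relative rotation lies in
20–60° — large enough that raw patch correlation fails and matching
demands the learned viewpoint invariance; the fraction of mutual matches
within 3 px of the true warp is reported. A randomly initialised
descriptor scores ≈ 0 under this protocol, because an untrained CNN's
features correlate only for nearly aligned patches.

What passing these checks does **not** show: real fundus images carry
pathology, media opacity, camera vignetting and anatomical texture the
generator does not model; synthetic vessel junctions are more self-similar
than real ones (all trees share one rendering recipe), which makes
descriptor discrimination *harder* in some respects and easier in others
(no lesions or acquisition artefacts). Absolute precision numbers
therefore do not transfer to benchmark datasets; the study validates the
machinery — losses, batch construction, matching, estimation, metrics —
and the relative behaviours (trained ≫ untrained, multi-positive ≥
single-positive at matched budgets).

## Numerical details and edge cases

* Convolution runs one GEMM per kernel tap; gradients reuse the forward
  primitive with a flipped kernel, and every layer passed a central-
  difference gradient check.
* Dead-ReLU pixels (uniform dark regions) would yield zero descriptors;
  the final conv bias is initialised at 0.01 so normalisation is always
  well-defined.
* Heatmap Gaussians are truncated at 5σ (residual < 4e-6).
* Empty keypoint sets: targets become all-zero planes; extraction may
  return an empty set; registration returns a structured failure record in
  lenient mode instead of raising.
* Homography h₃₃ is normalised to 1 whenever non-zero; control points
  mapped to infinity mark the pair as failed rather than propagating NaNs.
* Determinism: every stochastic component takes a seed or Generator;
  trainings are bit-reproducible on one machine (pure numpy, fixed call
  order).

## Known limitations

* Desk-scale matching precision is modest. Under the 20–60° evaluation
  protocol the 1,500-step descriptor reaches a mean precision of roughly
  0.4–0.6 (scene-dependent), far above the ≈ 0 untrained baseline but well
  short of what full-length training achieves: learning rotation
  invariance of this magnitude is precisely what the long (15,000-epoch)
  schedules in the literature buy. Two structural effects also cap the
  metric: (a) ~25 % of detections have no counterpart in the other image
  (overlap loss and photometric dropout), and such orphans can form
  reciprocal wrong matches that no descriptor could score as correct;
  (b) under *mild* transforms even an untrained network matches most
  keypoints (random convolutional features preserve patch correlation on
  these small keypoint sets), so there is no regime at this scale where
  trained precision is near 1 while untrained is near 0.
* End-to-end registration is bimodal at this training scale: roughly 60 %
  of held-out pairs register to ~2 px median control-point error (RANSAC
  needs only a few correct matches), while pairs whose moving image drew a
  strong defocus corruption fail grossly — the descriptor's blur
  brittleness noted above. The mean error over a pair sample is therefore
  dominated by failures; the registration-score AUC, which counts failures
  as unsuccessful at every threshold, is the appropriate summary.
* Triplet training at its customary learning rate needs far more steps
  than the desk budget; the baseline is validated for loss decrease and
  discrimination, not for end-to-end parity.
* The CPU conv stack handles stride-1 convolutions with explicit 2×
  pooling/upsampling only — sufficient for these architectures, not a
  general framework.
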