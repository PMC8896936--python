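# Methods

This note records the modelling choices, defaults and numerical
conventions behind `ribseg`, and what the synthetic test-bed does and does
not demonstrate.

## The recognition model

The pipeline treats rib-fracture recognition as binary segmentation
followed by candidate re-scoring. Stage 1 deliberately favours recall: the
sliding-window fusion takes the per-voxel **maximum** over overlapping
window predictions, so a voxel flagged by any window stays flagged, and
candidate extraction applies no size filter by default
(`min_component_size = 1`). Stage 2 restores precision: it can only remove
candidates, so the post-classification prediction set is always a subset
of stage 1's and the false-positive count can only decrease, while every
removal risks a true detection. The interesting empirical question — which
the acceptance experiment measures — is whether the classifier removes
decoys faster than it removes lesions.

Assumptions inherited from this design:

- segmentation is binary; fracture typing (labels 1–4) is out of scope and
  all nonzero labels, including the uncertain class −1, count as
  foreground;
- candidates are connected components (26-connectivity by default) of the
  thresholded fused probability; a candidate "hits" a truth instance when
  they share at least one voxel. A candidate overlapping several instances
  marks each detected but counts once as a prediction;
- detection rates are per lesion, not per patient: recognition rate =
  detected instances / truth instances, false-positive rate = spurious
  predictions / all predictions.

## Losses

`L = L_dice + L_ce + w·L_contour`. The Dice term uses additive smoothing
`s` in numerator and denominator (default `s = 1`), computed per patch and
averaged over the batch; cross-entropy clamps probabilities to
`[1e−7, 1 − 1e−7]`. The contour term identifies the network's sigmoid
output with the smoothed region indicator of a level-set formulation, so
it reduces to the mean Euclidean norm of the finite-difference gradient of
`p` (central differences in the interior, one-sided at borders, unit voxel
spacing): a contour-length penalty that is exactly zero for constant
fields and positively homogeneous. The three terms enter unweighted by
default (`w = 1`), matching the printed form of the objective; the weight
is exposed because a pure length penalty can dominate on very small
lesions. No separate Heaviside smoothing width exists — it is absorbed
into the sigmoid. All three losses have hand-derived analytic gradients
(the contour gradient uses the exact adjoint of the difference operators,
with a `1e−12` guard where the gradient norm vanishes); a
finite-difference check in the test suite holds them to 0.1% relative.

## Preprocessing

The fingerprint's target spacing is the per-axis arithmetic **mean** of
training spacings (the median grid size is recorded alongside). Clip
bounds are the 0.5th/99.5th percentiles, with linear interpolation between
order statistics, of HU values pooled over foreground voxels of the merged
labels; a degenerate (constant-foreground) pool widens to a 2-HU band
rather than failing. The chain order is fixed: resample → clip →
normalize; clipping before or after resampling is not distinguishable from
the method description this follows, and resample-first was chosen so that
the clip and the per-sample z-score statistics see the grid the network
sees. Resampling preserves physical extent,
`new_size = round(old_size · old_spacing / target)` floored at 1, with
trilinear interpolation for images and nearest-neighbour for labels and
masks (label interpolation must not invent values). z-scoring uses
per-sample mean/SD computed after clipping and refuses volumes with
SD < 1e−8.

## Networks and training

Both networks live in `ribseg.nn`, a small numpy layer library with
explicit backward passes (same-padding im2col convolutions, instance norm,
leaky ReLU, max/avg pooling, nearest upsampling, dense blocks, Adam). The
segmenter is a U-Net: two (conv–instance-norm–leaky-ReLU) units per level,
per-axis pooling counts so anisotropic patches pool only where resolution
permits, channel doubling capped at 320, sigmoid head. Full-size
configurations (patch 96×160×160, pools [4,5,5]; 2-D 512² with [7,7]) are
shipped as presets `published_3d_fullres` / `published_3d_lowres` / `published_2d`;
the test-bed uses `tiny_3d` (32³ patch, pools [2,2,2], 8 base channels).
The cascade variant trains the coarse model on volumes resampled to the
coarse spacing and the fine model with the upsampled coarse probability as
a second input channel.

Optimizer, schedule and augmentation are not prescribed by the method
description; the package uses plain Adam at a fixed learning rate with no
augmentation as the simplest reproducible baseline. Two stabilisers matter
at this scale: gradients are clipped to a global L2 norm of 5 before each
step (batch-2 training occasionally produces spikes violent enough to
destroy a converged model), and `train_segmenter` returns the weights of
the epoch with the lowest mean training loss rather than the last epoch,
because the final epochs of a small noisy run are not reliably its best.
The loss history always records the raw trajectory. Defaults (lr 1e−2;
desk-scale profile: 40 epochs × 12 steps × batch 2, foreground-centred
patch fraction 0.7) were set where the tiny segmenter's loss reliably
converges on phantom cohorts across seeds. If the trained segmenter
surfaces no candidates at all on its own training volumes, the pipeline
extends training by up to two further seeded 12-epoch rounds before
giving up. Patch sampling centres a patch on a uniformly chosen
foreground voxel with probability `fg_patch_fraction` (window clamped
inside the volume; the chosen voxel always remains covered), otherwise
draws a uniform origin.

The classifier is a 3-D DenseNet-style network: stem conv + 2× max-pool,
two dense blocks (growth 8, two layers each) with a 1×1-conv/avg-pool
compression transition between them, global average pooling and a
single-logit sigmoid head. Its fusion weights λ are validation accuracies
on a stratified, seeded 25% split of the labelled candidates. The printed
form of the candidate fusion is an unnormalized weighted sum that can
exceed 1; since it is used as a probability, the implementation normalizes
by Σλ (the raw sum is available behind `normalized=False`).

Stage-2 supervision is not fully specified by the method description; two
mining modes are provided. `mined` (default) runs the trained segmenter on
the training volumes and labels each candidate by ≥1-voxel truth overlap —
this gives the classifier exactly the false positives stage 1 actually
makes — and always blends in one random background crop per training
volume, so the negative class spans both hard (mined) and easy (random)
examples even when an accurate segmenter leaves few false positives to
mine. `gt_plus_random` crops truth components as positives and random
off-truth centres as negatives, useful when the segmenter is too weak to
mine from. Because the candidate pool is usually skewed toward true
positives, classifier epochs are class-balanced: each epoch oversamples
the minority class to parity before shuffling into batches.

## The phantom generator

Each phantom is a soft-tissue background (−50 HU) with curved bone tubes
(+700 HU; arcs in the axial plane with a small through-plane drift),
sphere-like lesions (+200 HU) attached to the tubes by rejection sampling
(≤100 attempts, loud failure), instance labels drawn as −1 with the
configured uncertain fraction and uniformly from {1,…,4} otherwise, and
additive Gaussian noise (SD 20 HU) on the image only. Pairwise lesion
centres are kept at least one maximum lesion diameter apart so instances
stay disjoint and the connected-component count equals the lesion count.
Decoy blobs carry the same intensity as lesions but are placed away from
any rib and left unlabelled: indistinguishable from lesions by intensity
alone, they are the designed source of stage-1 false positives, so the
two-stage comparison is non-trivial. Everything is a pure function of
(config, sample index).

What the phantom does **not** emulate: anatomy (no rib cage geometry,
lungs or spine), CT physics (no beam hardening, partial volume, or
reconstruction kernel effects), reader disagreement, or the morphology of
real fracture types — the four type labels are interchangeable. Passing
tests therefore demonstrate that the pipeline's machinery is correct and
that the two-stage design behaves as intended under controlled conditions;
they say nothing about accuracy on clinical CT.

## Numerical conventions

- Axis order (z, y, x) everywhere; NIfTI I/O transposes at the boundary
  and rejects non-axis-aligned affines. Labels are stored as int8 so −1
  survives round trips.
- Surfaces: foreground voxels with a background 6-neighbour, the volume
  border counting as background; coordinates scaled to mm by the spacing.
  Nearest-surface distances use a KD-tree; the tests pin them to an
  all-pairs oracle at 1e−9 mm.
- Both-empty mask pairs define Dice = IoU = 1 and all distances 0 (with a
  warning); exactly one empty mask raises for surface distances.
- HD-95 is reported in two variants side by side: `hd95_scaled_mm` =
  0.95·HD (an outlier-damping convention) and `hd95_percentile_mm`, the
  95th percentile of pooled directed distances. The two differ and are
  never conflated.
- Window planning uses stride `patch·(1 − overlap)` with the final window
  clamped to the volume edge; candidates sort by descending voxel count,
  ties by component id; multi-scale crops pad with the image minimum.
- Per-stage seeds derive from the global seed by hashing the stage name
  (CRC-32, masked below 2³¹), so adding a stage never perturbs earlier
  stages' draws.

## Problem sizes

The default experiment profile — also what `scripts/acceptance.py` runs —
uses 20 phantoms of 64³ voxels at (1.25, 0.75, 0.75) mm spacing, 3 lesions
(radius 1.5–3 mm) and 3 decoys each, 14 for training and 6 held out; the
`tiny_3d` segmenter; and classifier crops of 16/24/32 voxels. These sizes
keep a full run in single-digit minutes on one CPU while leaving every
stage non-trivial (the stage-1 candidate set reliably contains both all
lesions and several decoys).

## Known limitations

- The cascade's end-to-end quality is exercised only as a smoke test; the
  default profile uses the single-stage 3-D segmenter.
- nnU-Net-style self-configuration (fingerprint → architecture solver),
  five-fold ensembling and test-time augmentation are intentionally out of
  scope; full-size presets record the published configurations but are not
  trained at desk scale.
- The numpy networks are single-threaded and sized for small inputs;
  training the full-size presets is out of reach by design.
- With very few held-out candidates the per-size validation accuracies λ
  are coarse (quarter-steps), which can make the fused probability
  insensitive to one classifier.
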