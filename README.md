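# ribseg

Two-stage volumetric rib-fracture recognition for CT-like images: a U-Net
segmenter proposes candidate fracture regions, and a three-size ensemble of
densely connected 3-D classifiers re-scores each candidate to exclude false
positives. The package is aimed at method developers who want the full
pipeline — preprocessing, training, sliding-window inference, candidate
classification and evaluation — runnable and testable on a single CPU,
without any external imaging data: a seeded phantom generator produces
CT-like volumes (Hounsfield-unit tubes for ribs, instance-labelled lesion
blobs, off-rib decoys) that stand in for annotated rib-fracture CT.

## Method

**Stage 1 — candidate segmentation.** Instance labels (fracture types 1–4
and the uncertain class −1) are merged into one binary foreground class.
Volumes are resampled to the mean training spacing with
`new_size = round(size · spacing / target)`, intensities are clipped to the
[0.5, 99.5] percentile window of foreground HU pooled over the training
set, and each sample is z-scored, `y = (x − mean) / std`. A U-Net-style
encoder–decoder (leaky-ReLU activations, instance normalization, per-axis
pooling counts; 2-D, 3-D and coarse-to-fine cascade variants) is trained
on sampled patches with the composite objective

```
L = L_dice + L_ce + L_contour
L_dice    = 1 − (2 Σ p·t + s) / (Σ p + Σ t + s)
L_ce      = −mean[ t log p + (1 − t) log(1 − p) ]
L_contour = mean‖∇p‖            (discrete contour-length penalty)
```

where the predicted probability field `p` plays the role of the smoothed
region indicator H_ε(φ) of an active-contour formulation. Whole volumes
are predicted as overlapping windows fused per voxel by the **maximum**,
`P_s(voxel) = max(P_s1, …, P_si)`; connected components of the thresholded
result are the candidates.

**Stage 2 — false-positive exclusion.** Around each candidate centroid,
cubic crops at three nested sizes (48/64/80 voxels at full scale, 16/24/32
in the desk-scale profile) feed three densely connected 3-D classifiers.
Their probabilities are fused by a weighted average whose weights λ_ci are
the per-size validation accuracies,

```
P_c = (λ_c1 P_c1 + λ_c2 P_c2 + λ_c3 P_c3) / (λ_c1 + λ_c2 + λ_c3),
```

and candidates below the decision threshold are dropped. Stage 2 can only
remove candidates, never add them.

**Evaluation.** Voxel overlap by Dice = 2TP/(FP + 2TP + FN) and
IoU = TP/(FP + TP + FN); surface distances (ASSD and Hausdorff, in mm)
between boundary-voxel point sets, with HD-95 reported both as 0.95·HD and
as the 95th percentile of directed distances; and per-lesion detection
rates (a truth instance counts as detected when an accepted candidate
overlaps it; an accepted candidate with no truth overlap is one false
positive).

## Worked example

`examples/` contains one short script per capability. Training and scoring
a miniature two-stage pipeline end to end
(`python examples/05_full_pipeline.py`) prints:

```
held-out lesions:          4
stage-1 recognition rate:  0.75
stage-1 false positives:   0 (rate 0.00)
stage-2 recognition rate:  0.75
stage-2 false positives:   0 (rate 0.00)
fusion weights (per-size validation accuracy): (0.75, 0.75, 0.75)
mean held-out Dice:        0.710
```

i.e. on two held-out miniature phantoms the segmenter finds 3 of 4
lesions, the classifier ensemble keeps all of them, and the fused mask
overlaps the truth at Dice 0.71. Loss and metric arithmetic on a toy
sphere (`python examples/03_losses_and_metrics.py`) prints:

```
dice loss     0.6666
cross-entropy 0.2508
contour loss  0.0593
total         0.9766
Dice 0.691  IoU 0.528  ASSD 1.36 mm  HD 2.24 mm  HD95 (0.95*HD) 2.12 mm / (95th pct) 2.00 mm
```

A thin CLI mirrors the library (`ribseg simulate|preprocess|train-seg|
predict|extract-candidates|train-cls|classify|evaluate|run-all`); `ribseg
run-all --out runs/demo --seed 1` executes the full default profile and
writes a manifest with per-stage seeds, timings and the final detection
report.

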