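"""Segmentation overlap/surface metrics and instance-level detection rates.

Overlap: Dice = 2TP/(FP + 2TP + FN) and IoU = TP/(FP + TP + FN), related by
Dice = 2*IoU/(1 + IoU).  Surfaces are foreground voxels with at least one
background 6-neighbour (the volume border counts as background), taken to
physical mm coordinates via the voxel spacing; ASSD is the symmetric mean
of nearest-surface distances and HD the symmetric maximum.  Two HD-95
variants are reported side by side: ``hd95_scaled_mm`` is 0.95 times HD (an
outlier-damping convention some groups use), ``hd95_percentile_mm`` the
more common 95th percentile of the pooled directed nearest distances.

Detection is per-lesion: a truth instance (connected component of the
merged truth labels) counts as detected iff at least one accepted
candidate shares a voxel with it; an accepted candidate overlapping no
truth instance counts as one false-positive prediction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .geometry import BinaryMask, LabelVolume, require_same_geometry
from .inference import CandidateRegion
from .volume_io import merge_labels


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int


@dataclass(frozen=True)
class SurfacePointSet:
    """Physical-mm coordinates of a mask's boundary voxels."""

    points: np.ndarray  # (n, 3) float64, mm

    @property
    def is_empty(self) -> bool:
        return len(self.points) == 0


@dataclass(frozen=True)
class SegmentationReport:
    dice: float
    iou: float
    assd_mm: float
    hd_mm: float
    hd95_scaled_mm: float
    hd95_percentile_mm: float


@dataclass(frozen=True)
class DetectionReport:
    n_truth_instances: int
    n_detected: int
    n_false_positive_predictions: int
    n_predictions: int
    recognition_rate: float
    fp_rate: float


class EmptyMaskError(ValueError):
    """Surface distances are undefined for an empty mask."""


def confusion(pred: BinaryMask, truth: BinaryMask) -> ConfusionCounts:
    """Voxelwise true/false positive and false negative counts."""
    require_same_geometry(pred, truth)
    p = pred.values.astype(bool)
    t = truth.values.astype(bool)
    return ConfusionCounts(
        tp=int(np.count_nonzero(p & t)),
        fp=int(np.count_nonzero(p & ~t)),
        fn=int(np.count_nonzero(~p & t)),
    )


def dice_metric(pred: BinaryMask, truth: BinaryMask) -> float:
    """Dice similarity 2TP/(FP + 2TP + FN); two empty masks give 1."""
    c = confusion(pred, truth)
    denom = c.fp + 2 * c.tp + c.fn
    if denom == 0:
        warnings.warn("both masks empty: Dice defined as 1", stacklevel=2)
        return 1.0
    return 2.0 * c.tp / denom


def iou_metric(pred: BinaryMask, truth: BinaryMask) -> float:
    """Jaccard overlap TP/(FP + TP + FN); two empty masks give 1."""
    c = confusion(pred, truth)
    denom = c.fp + c.tp + c.fn
    if denom == 0:
        warnings.warn("both masks empty: IoU defined as 1", stacklevel=2)
        return 1.0
    return c.tp / denom


def surface(mask: BinaryMask) -> SurfacePointSet:
    """Boundary voxels: foreground with a background 6-neighbour, the
    volume border counting as background; coordinates in mm."""
    fg = mask.values.astype(bool)
    if not fg.any():
        warnings.warn("surface of an empty mask is empty", stacklevel=2)
        return SurfacePointSet(points=np.empty((0, 3)))
    eroded = ndimage.binary_erosion(
        fg, structure=ndimage.generate_binary_structure(3, 1), border_value=0
    )
    boundary = fg & ~eroded
    idx = np.argwhere(boundary).astype(np.float64)
    spacing = np.asarray(mask.geometry.spacing_mm)
    return SurfacePointSet(points=idx * spacing)


def _directed_min_distances(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """min_b ||a_i - b|| for every a_i, via a KD-tree on b."""
    return cKDTree(b).query(a, k=1)[0]


def assd(pred: BinaryMask, truth: BinaryMask) -> float:
    """Average symmetric surface distance in mm."""
    require_same_geometry(pred, truth)
    sa, sb = surface(pred), surface(truth)
    if sa.is_empty and sb.is_empty:
        warnings.warn("both masks empty: ASSD defined as 0", stacklevel=2)
        return 0.0
    if sa.is_empty or sb.is_empty:
        raise EmptyMaskError("ASSD undefined when exactly one mask is empty")
    d_ab = _directed_min_distances(sa.points, sb.points)
    d_ba = _directed_min_distances(sb.points, sa.points)
    return float((d_ab.sum() + d_ba.sum()) / (len(d_ab) + len(d_ba)))


def hausdorff(pred: BinaryMask, truth: BinaryMask) -> tuple[float, float, float]:
    """(HD, 0.95*HD, 95th-percentile of pooled directed distances), in mm."""
    require_same_geometry(pred, truth)
    sa, sb = surface(pred), surface(truth)
    if sa.is_empty and sb.is_empty:
        warnings.warn("both masks empty: HD defined as 0", stacklevel=2)
        return 0.0, 0.0, 0.0
    if sa.is_empty or sb.is_empty:
        raise EmptyMaskError("HD undefined when exactly one mask is empty")
    d_ab = _directed_min_distances(sa.points, sb.points)
    d_ba = _directed_min_distances(sb.points, sa.points)
    hd = float(max(d_ab.max(), d_ba.max()))
    pooled = np.concatenate([d_ab, d_ba])
    return hd, 0.95 * hd, float(np.percentile(pooled, 95))


def segmentation_report(pred: BinaryMask, truth: BinaryMask) -> SegmentationReport:
    """All overlap and surface metrics for one volume pair."""
    hd, hd95p, hd95q = hausdorff(pred, truth)
    return SegmentationReport(
        dice=dice_metric(pred, truth),
        iou=iou_metric(pred, truth),
        assd_mm=assd(pred, truth),
        hd_mm=hd,
        hd95_scaled_mm=hd95p,
        hd95_percentile_mm=hd95q,
    )


def detection_report(accepted_candidates: list[CandidateRegion],
                     truth_labels: LabelVolume | BinaryMask) -> DetectionReport:
    """Per-lesion recognition rate and per-prediction false-positive rate.

    ``truth_labels`` may be an instance label volume (merged internally) or
    an already-merged binary mask.  A candidate overlapping several truth
    instances marks each of them detected but itself counts as a single
    true-positive prediction.  With no truth instances the recognition
    rate is vacuously 1; with no predictions the false-positive rate is 0.
    """
    truth_mask = (truth_labels if isinstance(truth_labels, BinaryMask)
                  else merge_labels(truth_labels))
    shape = np.asarray(truth_mask.geometry.size)
    comp, n_truth = ndimage.label(
        truth_mask.values, structure=ndimage.generate_binary_structure(3, 3)
    )
    detected = np.zeros(n_truth + 1, dtype=bool)
    n_fp = 0
    for cand in accepted_candidates:
        idx = cand.voxel_indices
        if idx.size and (idx.max(axis=0) >= shape).any():
            raise ValueError("candidate voxels fall outside the truth geometry")
        hit_ids = np.unique(comp[tuple(idx.T)]) if idx.size else np.array([], int)
        hit_ids = hit_ids[hit_ids > 0]
        if len(hit_ids):
            detected[hit_ids] = True
        else:
            n_fp += 1
    n_pred = len(accepted_candidates)
    n_detected = int(detected[1:].sum())
    return DetectionReport(
        n_truth_instances=int(n_truth),
        n_detected=n_detected,
        n_false_positive_predictions=int(n_fp),
        n_predictions=n_pred,
        recognition_rate=(n_detected / n_truth) if n_truth else 1.0,
        fp_rate=(n_fp / n_pred) if n_pred else 0.0,
    )
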