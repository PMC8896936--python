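"""Overlap and surface metrics against independent brute-force oracles."""

import numpy as np
import pytest

from ribseg.geometry import BinaryMask, GeometryError, LabelVolume, VolumeGeometry
from ribseg.inference import CandidateRegion
from ribseg.metrics import (
    EmptyMaskError,
    assd,
    confusion,
    detection_report,
    dice_metric,
    hausdorff,
    iou_metric,
    segmentation_report,
    surface,
)

from conftest import random_mask


def geom(shape, spacing=(1.0, 1.0, 1.0)):
    return VolumeGeometry(size=shape, spacing_mm=spacing)


def mask_from(arr, spacing=(1.0, 1.0, 1.0)):
    arr = np.asarray(arr, dtype=np.uint8)
    return BinaryMask(values=arr, geometry=geom(arr.shape, spacing))


# ---------------------------------------------------------------- oracles

def brute_confusion(pred, truth):
    tp = fp = fn = 0
    for idx in np.ndindex(pred.values.shape):
        p, t = pred.values[idx], truth.values[idx]
        tp += int(p and t)
        fp += int(p and not t)
        fn += int(t and not p)
    return tp, fp, fn


def brute_surface_points(mask):
    """Foreground voxels with a 6-neighbour background (border = background)."""
    arr = mask.values.astype(bool)
    pts = []
    for idx in np.argwhere(arr):
        z, y, x = idx
        on_border = False
        for dz, dy, dx in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                           (0, 0, 1), (0, 0, -1)):
            nz, ny, nx = z + dz, y + dy, x + dx
            if not (0 <= nz < arr.shape[0] and 0 <= ny < arr.shape[1]
                    and 0 <= nx < arr.shape[2]) or not arr[nz, ny, nx]:
                on_border = True
                break
        if on_border:
            pts.append(idx)
    return np.asarray(pts, dtype=float) * np.asarray(mask.geometry.spacing_mm)


def brute_assd_hd(pred, truth):
    """All-pairs symmetric surface distances."""
    a = brute_surface_points(pred)
    b = brute_surface_points(truth)
    d = np.sqrt(((a[:, None, :] - b[None, :, :]) ** 2).sum(-1))
    d_ab = d.min(axis=1)
    d_ba = d.min(axis=0)
    assd_val = (d_ab.sum() + d_ba.sum()) / (len(d_ab) + len(d_ba))
    hd_val = max(d_ab.max(), d_ba.max())
    return assd_val, hd_val


# ---------------------------------------------------------------- tests

def test_confusion_agrees_with_voxel_loop(mask_pair_factory):
    pred, truth = mask_pair_factory(shape=(8, 8, 8))
    c = confusion(pred, truth)
    assert (c.tp, c.fp, c.fn) == brute_confusion(pred, truth)


def test_confusion_edge_cases():
    truth = mask_from(np.ones((4, 4, 4)))
    empty = mask_from(np.zeros((4, 4, 4)))
    c = confusion(truth, truth)
    assert c.fp == 0 and c.fn == 0
    c = confusion(empty, truth)
    assert (c.tp, c.fp, c.fn) == (0, 0, 64)


def test_geometry_mismatch_rejected():
    a = mask_from(np.ones((4, 4, 4)))
    b = mask_from(np.ones((4, 4, 4)), spacing=(2.0, 1.0, 1.0))
    with pytest.raises(GeometryError):
        confusion(a, b)


def test_dice_and_iou_hand_values():
    # tp=2, fp=1, fn=1 -> dice 4/6, iou 1/2
    pred = np.zeros((4, 4, 4))
    truth = np.zeros((4, 4, 4))
    pred[0, 0, :3] = 1
    truth[0, 0, 1:4] = 1  # overlap voxels 1,2 -> tp=2, fp=1, fn=1
    p, t = mask_from(pred), mask_from(truth)
    assert dice_metric(p, t) == pytest.approx(4 / 6)
    assert iou_metric(p, t) == pytest.approx(0.5)


def test_identical_and_disjoint_masks():
    a = mask_from(np.pad(np.ones((2, 2, 2)), ((0, 4),) * 3))
    b = mask_from(np.pad(np.ones((2, 2, 2)), ((4, 0),) * 3))
    assert dice_metric(a, a) == 1.0
    assert iou_metric(a, a) == 1.0
    assert dice_metric(a, b) == 0.0
    assert assd(a, a) == 0.0
    assert hausdorff(a, a) == (0.0, 0.0, 0.0)


def test_dice_iou_identity_random_pairs(rng):
    for _ in range(100):
        pred = random_mask(rng, shape=(6, 6, 6))
        truth = random_mask(rng, shape=(6, 6, 6))
        d, i = dice_metric(pred, truth), iou_metric(pred, truth)
        assert d == pytest.approx(2 * i / (1 + i), abs=1e-12)


def test_surface_single_voxel_and_cube():
    single = np.zeros((5, 5, 5))
    single[2, 2, 2] = 1
    s = surface(mask_from(single))
    assert len(s.points) == 1
    np.testing.assert_allclose(s.points[0], [2, 2, 2])

    cube = np.zeros((5, 5, 5))
    cube[1:4, 1:4, 1:4] = 1
    assert len(surface(mask_from(cube)).points) == 26  # all but the centre


def test_surface_of_thin_sheet_is_everything():
    sheet = np.zeros((5, 5, 5))
    sheet[2] = 1
    assert len(surface(mask_from(sheet)).points) == 25


def test_two_point_distances_in_mm():
    a = np.zeros((5, 5, 5))
    b = np.zeros((5, 5, 5))
    a[1, 1, 1] = 1
    b[1, 1, 4] = 1  # 3 voxels apart along x at 1 mm
    assert assd(mask_from(a), mask_from(b)) == pytest.approx(3.0)
    hd, hd95p, _ = hausdorff(mask_from(a), mask_from(b))
    assert hd == pytest.approx(3.0)
    # 4 mm apart: spacing 1 mm, 4 voxels
    b4 = np.zeros((6, 6, 6))
    a6 = np.zeros((6, 6, 6))
    a6[1, 1, 1] = 1
    b4[1, 1, 5] = 1
    hd, hd95p, _ = hausdorff(mask_from(a6), mask_from(b4))
    assert (hd, hd95p) == (pytest.approx(4.0), pytest.approx(3.8))


def test_spacing_scales_distances_exactly(rng):
    a = random_mask(rng, shape=(8, 8, 8))
    b = random_mask(rng, shape=(8, 8, 8))
    a2 = mask_from(a.values, spacing=(2.0, 2.0, 2.0))
    b2 = mask_from(b.values, spacing=(2.0, 2.0, 2.0))
    assert assd(a2, b2) == pytest.approx(2 * assd(a, b))
    assert hausdorff(a2, b2)[0] == pytest.approx(2 * hausdorff(a, b)[0])


def test_surface_distances_match_all_pairs_oracle(rng):
    for trial in range(100):
        shape = tuple(rng.integers(4, 17, 3))
        spacing = tuple(rng.uniform(0.5, 3.0, 3))
        a = random_mask(rng, shape=shape, spacing=spacing, p=0.15)
        b = random_mask(rng, shape=shape, spacing=spacing, p=0.15)
        oracle_assd, oracle_hd = brute_assd_hd(a, b)
        assert assd(a, b) == pytest.approx(oracle_assd, abs=1e-9)
        assert hausdorff(a, b)[0] == pytest.approx(oracle_hd, abs=1e-9)


def test_hd_bounds_assd(rng):
    for _ in range(100):
        a = random_mask(rng, shape=(7, 7, 7))
        b = random_mask(rng, shape=(7, 7, 7))
        assert hausdorff(a, b)[0] >= assd(a, b) - 1e-12


def test_symmetry(mask_pair_factory):
    a, b = mask_pair_factory(shape=(8, 8, 8))
    assert dice_metric(a, b) == dice_metric(b, a)
    assert iou_metric(a, b) == iou_metric(b, a)
    assert assd(a, b) == pytest.approx(assd(b, a))
    assert hausdorff(a, b)[0] == pytest.approx(hausdorff(b, a)[0])


def test_empty_mask_distance_errors():
    empty = mask_from(np.zeros((4, 4, 4)))
    full = mask_from(np.ones((4, 4, 4)))
    with pytest.raises(EmptyMaskError):
        assd(empty, full)
    with pytest.raises(EmptyMaskError):
        hausdorff(full, empty)


def test_both_empty_degenerate_convention():
    empty = mask_from(np.zeros((4, 4, 4)))
    with pytest.warns(UserWarning):
        assert dice_metric(empty, empty) == 1.0
    with pytest.warns(UserWarning):
        assert assd(empty, empty) == 0.0


def test_report_internal_consistency(mask_pair_factory):
    a, b = mask_pair_factory(shape=(10, 10, 10))
    rep = segmentation_report(a, b)
    assert rep.dice == pytest.approx(2 * rep.iou / (1 + rep.iou), abs=1e-10)
    assert rep.assd_mm <= rep.hd_mm + 1e-12
    assert rep.hd95_scaled_mm == pytest.approx(0.95 * rep.hd_mm)


def _candidate_at(voxels, cid=1):
    idx = np.asarray(voxels, dtype=int)
    lo, hi = idx.min(axis=0), idx.max(axis=0)
    return CandidateRegion(
        component_id=cid, voxel_count=len(idx),
        bbox=tuple((int(a), int(b)) for a, b in zip(lo, hi)),
        centroid_voxel=tuple(idx.mean(axis=0)),
        mean_probability=1.0, voxel_indices=idx,
    )


def test_detection_report_counting():
    """10 truth lesions, 9 hit, 1 of 10 predictions spurious."""
    shape = (4, 4, 40)
    labels = np.zeros(shape, dtype=np.int8)
    for i in range(10):
        labels[2, 2, 4 * i] = (i % 4) + 1  # 10 isolated single-voxel lesions
    truth = LabelVolume(values=labels, geometry=geom(shape))
    cands = [_candidate_at([[2, 2, 4 * i]], cid=i + 1) for i in range(9)]
    cands.append(_candidate_at([[0, 0, 1]], cid=10))  # spurious
    rep = detection_report(cands, truth)
    assert rep.n_truth_instances == 10
    assert rep.n_detected == 9
    assert rep.n_false_positive_predictions == 1
    assert rep.recognition_rate == pytest.approx(0.9)
    assert rep.fp_rate == pytest.approx(0.1)


def test_detection_report_extremes():
    shape = (6, 6, 6)
    labels = np.zeros(shape, dtype=np.int8)
    labels[1:3, 1:3, 1:3] = -1
    truth = LabelVolume(values=labels, geometry=geom(shape))
    exact = [_candidate_at(np.argwhere(labels != 0))]
    rep = detection_report(exact, truth)
    assert rep.recognition_rate == 1.0 and rep.fp_rate == 0.0
    rep = detection_report([], truth)
    assert rep.recognition_rate == 0.0 and rep.fp_rate == 0.0
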