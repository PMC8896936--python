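"""Sliding-window planning, max fusion, candidate extraction, crops."""

import numpy as np
import pytest

from ribseg.geometry import ImageVolume, VolumeGeometry
from ribseg.inference import (
    crop_multiscale,
    extract_candidates,
    plan_windows,
    predict_volume,
    predict_volume_mean,
)


class StubOperator:
    """Deterministic pseudo-random 'prediction' per window content."""

    def __init__(self, patch_size, seed=0):
        self.patch_size = tuple(patch_size)
        self.seed = seed

    def predict(self, patch):
        h = int(np.abs(np.asarray(patch, dtype=np.float64)).sum() * 1e3) % (2**31)
        r = np.random.default_rng((h + self.seed) & 0x7FFFFFFF)
        return r.uniform(size=self.patch_size).astype(np.float32)


class ConstantOperator:
    def __init__(self, patch_size, value):
        self.patch_size = tuple(patch_size)
        self.value = value

    def predict(self, patch):
        return np.full(self.patch_size, self.value, dtype=np.float32)


def geom(shape, spacing=(1, 1, 1)):
    return VolumeGeometry(size=shape, spacing_mm=spacing)


class TestPlanWindows:
    def test_single_window_when_volume_equals_patch(self):
        plan = plan_windows(geom((8, 8, 8)), (8, 8, 8), 0.5)
        assert plan.origins == ((0, 0, 0),)

    def test_stride_and_clamping_enumeration(self):
        # axis length 10, patch 4, overlap 0.5 -> stride 2 -> {0,2,4,6}
        plan = plan_windows(geom((10, 10, 10)), (4, 4, 4), 0.5)
        per_axis = sorted({o[0] for o in plan.origins})
        assert per_axis == [0, 2, 4, 6]
        assert len(plan.origins) == 4**3

    def test_full_coverage_random_sizes(self, rng):
        for _ in range(20):
            shape = tuple(rng.integers(6, 30, 3))
            patch = tuple(int(rng.integers(3, s + 1)) for s in shape)
            overlap = float(rng.uniform(0, 0.9))
            plan = plan_windows(geom(shape), patch, overlap)
            covered = np.zeros(shape, dtype=bool)
            for origin in plan.origins:
                sl = tuple(slice(o, o + p) for o, p in zip(origin, patch))
                covered[sl] = True
                assert all(o >= 0 and o + p <= s
                           for o, p, s in zip(origin, patch, shape))
            assert covered.all()

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            plan_windows(geom((8, 8, 8)), (4, 4, 4), 1.0)
        with pytest.raises(ValueError):
            plan_windows(geom((4, 4, 4)), (8, 8, 8), 0.5)


class TestMaxFusion:
    def test_constant_operator_gives_constant_volume(self, rng):
        arr = rng.normal(size=(10, 10, 10)).astype(np.float32)
        plan = plan_windows(geom((10, 10, 10)), (4, 4, 4), 0.5)
        fused = predict_volume(ConstantOperator((4, 4, 4), 0.3), arr, plan)
        np.testing.assert_allclose(fused.values, 0.3)
        assert fused.counts.min() >= 1

    def test_overlap_takes_the_maximum(self):
        class TwoValueOp:
            patch_size = (2, 2, 2)

            def predict(self, patch):
                # window at origin 0 (mean>0) says 0.2, the other 0.7
                return np.full((2, 2, 2), 0.2 if patch.mean() > 0 else 0.7,
                               dtype=np.float32)

        arr = np.zeros((2, 2, 3), dtype=np.float32)
        arr[:, :, 0] = 10.0  # only the first window sees the bright slab
        plan = plan_windows(geom((2, 2, 3)), (2, 2, 2), 0.5)
        fused = predict_volume(TwoValueOp(), arr, plan)
        # shared voxels (x=1) are claimed by both windows: max(0.2, 0.7)
        assert np.all(fused.values[:, :, 1] == pytest.approx(0.7))

    def test_matches_brute_force_accumulation(self, rng):
        """Fused output equals an explicit per-voxel max over windows."""
        for trial in range(50):
            shape = tuple(rng.integers(5, 14, 3))
            patch = tuple(int(rng.integers(3, s + 1)) for s in shape)
            op = StubOperator(patch, seed=trial)
            arr = rng.normal(size=shape).astype(np.float32)
            plan = plan_windows(geom(shape), patch, float(rng.uniform(0, 0.8)))
            fused = predict_volume(op, arr, plan)
            acc = np.full(shape, -np.inf)
            for origin in plan.origins:
                sl = tuple(slice(o, o + p) for o, p in zip(origin, patch))
                acc[sl] = np.maximum(acc[sl], op.predict(arr[sl]))
            np.testing.assert_allclose(fused.values, acc, atol=1e-7)

    def test_fused_dominates_every_window(self, rng):
        shape = (9, 9, 9)
        patch = (4, 4, 4)
        op = StubOperator(patch, seed=5)
        arr = rng.normal(size=shape).astype(np.float32)
        plan = plan_windows(geom(shape), patch, 0.5)
        fused = predict_volume(op, arr, plan)
        for origin in plan.origins:
            sl = tuple(slice(o, o + p) for o, p in zip(origin, patch))
            assert np.all(fused.values[sl] >= op.predict(arr[sl]) - 1e-7)

    def test_mean_fusion_bounded_by_max_fusion(self, rng):
        shape = (8, 8, 8)
        op = StubOperator((4, 4, 4), seed=2)
        arr = rng.normal(size=shape).astype(np.float32)
        plan = plan_windows(geom(shape), (4, 4, 4), 0.5)
        mx = predict_volume(op, arr, plan)
        mn = predict_volume_mean(op, arr, plan)
        assert np.all(mn.values <= mx.values + 1e-6)


def brute_components_26(binary):
    """Flood-fill component labelling, independent of scipy."""
    seen = np.zeros_like(binary, dtype=bool)
    comps = []
    offs = [(a, b, c) for a in (-1, 0, 1) for b in (-1, 0, 1)
            for c in (-1, 0, 1) if (a, b, c) != (0, 0, 0)]
    for start in np.argwhere(binary):
        start = tuple(start)
        if seen[start]:
            continue
        stack, comp = [start], []
        seen[start] = True
        while stack:
            v = stack.pop()
            comp.append(v)
            for o in offs:
                n = tuple(v[i] + o[i] for i in range(3))
                if all(0 <= n[i] < binary.shape[i] for i in range(3)) \
                        and binary[n] and not seen[n]:
                    seen[n] = True
                    stack.append(n)
        comps.append(comp)
    return comps


class TestExtractCandidates:
    def test_nothing_above_threshold(self):
        assert extract_candidates(np.zeros((6, 6, 6)), 0.5) == []

    def test_two_disjoint_cubes(self):
        prob = np.zeros((12, 12, 12))
        prob[1:4, 1:4, 1:4] = 0.9    # 27 voxels
        prob[8:10, 8:10, 8:10] = 0.8  # 8 voxels
        cands = extract_candidates(prob, 0.5)
        assert [c.voxel_count for c in cands] == [27, 8]
        assert cands[0].mean_probability == pytest.approx(0.9)
        for c in cands:
            for (lo, hi), ctr in zip(c.bbox, c.centroid_voxel):
                assert lo <= ctr <= hi

    def test_min_component_size_filters(self):
        prob = np.zeros((10, 10, 10))
        prob[1:3, 1:3, 1:3] = 0.9
        prob[7, 7, 7] = 0.9
        assert len(extract_candidates(prob, 0.5, min_component_size=2)) == 1
        assert extract_candidates(prob, 0.5, min_component_size=100) == []

    def test_matches_flood_fill_oracle(self, rng):
        for _ in range(100):
            shape = tuple(rng.integers(4, 12, 3))
            prob = (rng.uniform(size=shape) ** 2).astype(np.float32)
            cands = extract_candidates(prob, 0.5)
            oracle = brute_components_26(prob >= 0.5)
            assert sorted(c.voxel_count for c in cands) == \
                sorted(len(comp) for comp in oracle)
            assert sum(c.voxel_count for c in cands) == int((prob >= 0.5).sum())

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            extract_candidates(np.zeros((4, 4, 4)), 0.0)


class TestCropMultiscale:
    def _candidate(self, centroid):
        cands = extract_candidates(self._prob, 0.5)
        return min(cands, key=lambda c: sum(
            (a - b) ** 2 for a, b in zip(c.centroid_voxel, centroid)))

    def test_interior_candidate_has_no_padding(self, rng):
        arr = rng.uniform(10, 20, size=(40, 40, 40)).astype(np.float32)
        prob = np.zeros_like(arr)
        prob[19:22, 19:22, 19:22] = 1.0
        cand = extract_candidates(prob, 0.5)[0]
        ms = crop_multiscale(arr, cand, sizes=(8, 12, 16))
        for crop, size in zip(ms.crops, (8, 12, 16)):
            assert crop.shape == (size,) * 3
            assert crop.min() >= 10  # no fill value present

    def test_corner_candidate_padded_with_min(self, rng):
        arr = rng.uniform(10, 20, size=(20, 20, 20)).astype(np.float32)
        prob = np.zeros_like(arr)
        prob[0, 0, 0] = 1.0
        cand = extract_candidates(prob, 0.5)[0]
        ms = crop_multiscale(arr, cand, sizes=(8, 12, 16))
        fill = arr.min()
        crop = ms.crops[0]
        assert crop.shape == (8, 8, 8)
        assert crop[0, 0, 0] == pytest.approx(fill)  # out of bounds region

    def test_nested_crops_agree_on_common_centre(self, rng):
        arr = rng.uniform(size=(40, 40, 40)).astype(np.float32)
        prob = np.zeros_like(arr)
        prob[20, 20, 20] = 1.0
        cand = extract_candidates(prob, 0.5)[0]
        ms = crop_multiscale(arr, cand, sizes=(8, 12, 16))
        small, mid, big = ms.crops
        np.testing.assert_array_equal(small, mid[2:10, 2:10, 2:10])
        np.testing.assert_array_equal(mid, big[2:14, 2:14, 2:14])

    def test_sizes_must_increase(self, rng):
        arr = rng.uniform(size=(20, 20, 20)).astype(np.float32)
        prob = np.zeros_like(arr)
        prob[10, 10, 10] = 1.0
        cand = extract_candidates(prob, 0.5)[0]
        with pytest.raises(ValueError):
            crop_multiscale(arr, cand, sizes=(16, 12, 8))
        with pytest.raises(ValueError):
            crop_multiscale(arr, cand, sizes=(4, 8, 12))
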