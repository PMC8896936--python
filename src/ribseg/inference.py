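"""Whole-volume prediction and candidate harvesting.

A large volume is predicted as overlapping fixed-size windows; where
windows overlap, the per-voxel *maximum* over window predictions is kept
(max fusion — deliberately recall-oriented: a voxel flagged by any window
stays flagged, and the second-stage classifier is responsible for
precision).  Candidates are connected components of the thresholded fused
probability; for each candidate, cubic crops at three nested sizes give
the classifier local detail plus surrounding context.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .geometry import ImageVolume, ProbabilityVolume, VolumeGeometry


@dataclass(frozen=True)
class SlidingWindowPlan:
    patch_size: tuple[int, ...]
    overlap_fraction: float
    origins: tuple[tuple[int, ...], ...]
    volume_size: tuple[int, ...]


@dataclass
class FusedProbability:
    """Max-fused per-voxel probability plus per-voxel window counts."""

    values: np.ndarray
    counts: np.ndarray
    geometry: VolumeGeometry


@dataclass(frozen=True)
class CandidateRegion:
    """One connected component of the thresholded fused probability."""

    component_id: int
    voxel_count: int
    bbox: tuple[tuple[int, int], ...]  # per-axis (min, max) inclusive
    centroid_voxel: tuple[float, ...]
    mean_probability: float
    voxel_indices: np.ndarray  # (voxel_count, ndim) int array

    def __post_init__(self) -> None:
        for (lo, hi), c in zip(self.bbox, self.centroid_voxel):
            if not lo <= c <= hi:
                raise ValueError("bbox must contain the centroid")


@dataclass(frozen=True)
class MultiScaleCrops:
    """Cubic crops at increasing edge length, all centred on one candidate."""

    crops: tuple[np.ndarray, ...]
    sizes: tuple[int, ...]
    candidate_ref: int


def _axis_origins(length: int, patch: int, stride: int) -> list[int]:
    origins = list(range(0, length - patch + 1, stride))
    if origins[-1] != length - patch:
        origins.append(length - patch)
    return origins


def plan_windows(volume_geometry, patch_size, overlap_fraction: float = 0.5
                 ) -> SlidingWindowPlan:
    """Regular window grid with stride patch*(1-overlap), final window
    clamped to abut the volume edge; every voxel is covered."""
    if not 0.0 <= overlap_fraction < 1.0:
        raise ValueError(f"overlap_fraction must lie in [0, 1), got {overlap_fraction}")
    size = (volume_geometry.size if isinstance(volume_geometry, VolumeGeometry)
            else tuple(volume_geometry))
    patch = tuple(int(p) for p in patch_size)
    if len(patch) != len(size):
        raise ValueError("patch rank must match volume rank")
    if any(p > s for p, s in zip(patch, size)):
        raise ValueError(
            f"patch {patch} exceeds volume {size}; pad the volume first"
        )
    per_axis = []
    for s, p in zip(size, patch):
        stride = max(1, int(round(p * (1.0 - overlap_fraction))))
        per_axis.append(_axis_origins(s, p, stride))
    mesh = np.meshgrid(*per_axis, indexing="ij")
    origins = tuple(
        tuple(int(m.flat[i]) for m in mesh) for i in range(mesh[0].size)
    )
    return SlidingWindowPlan(
        patch_size=patch, overlap_fraction=float(overlap_fraction),
        origins=origins, volume_size=tuple(size),
    )


def predict_volume(operator, image, plan: SlidingWindowPlan) -> FusedProbability:
    """Sliding-window prediction with per-voxel max fusion.

    ``operator`` needs ``predict(patch) -> probability patch``; ``image``
    is an :class:`ImageVolume` or a plain array, optionally with a leading
    channel axis.
    """
    if isinstance(image, ImageVolume):
        arr = image.values
        geometry = image.geometry
    else:
        arr = np.asarray(image, dtype=np.float32)
        sp_shape = arr.shape[1:] if arr.ndim == len(plan.patch_size) + 1 else arr.shape
        geometry = VolumeGeometry(size=sp_shape, spacing_mm=(1.0,) * len(sp_shape)) \
            if len(sp_shape) == 3 else None
    has_channels = arr.ndim == len(plan.patch_size) + 1
    spatial = arr.shape[1:] if has_channels else arr.shape
    if tuple(spatial) != plan.volume_size:
        raise ValueError(f"plan was made for {plan.volume_size}, volume is {spatial}")
    fused = np.zeros(spatial, dtype=np.float32)
    counts = np.zeros(spatial, dtype=np.int32)
    seen = np.zeros(spatial, dtype=bool)
    for origin in plan.origins:
        window = tuple(slice(o, o + p) for o, p in zip(origin, plan.patch_size))
        patch = arr[(slice(None),) + window] if has_channels else arr[window]
        pred = np.asarray(operator.predict(patch), dtype=np.float32)
        if pred.shape != plan.patch_size:
            raise ValueError(
                f"operator returned shape {pred.shape}, expected {plan.patch_size}"
            )
        fused[window] = np.where(seen[window], np.maximum(fused[window], pred), pred)
        seen[window] = True
        counts[window] += 1
    return FusedProbability(values=np.clip(fused, 0.0, 1.0), counts=counts,
                            geometry=geometry)


def predict_volume_mean(operator, image, plan: SlidingWindowPlan) -> FusedProbability:
    """Mean-fusion variant (for comparison with the default max fusion)."""
    if isinstance(image, ImageVolume):
        arr, geometry = image.values, image.geometry
    else:
        arr, geometry = np.asarray(image, dtype=np.float32), None
    has_channels = arr.ndim == len(plan.patch_size) + 1
    spatial = arr.shape[1:] if has_channels else arr.shape
    acc = np.zeros(spatial, dtype=np.float64)
    counts = np.zeros(spatial, dtype=np.int32)
    for origin in plan.origins:
        window = tuple(slice(o, o + p) for o, p in zip(origin, plan.patch_size))
        patch = arr[(slice(None),) + window] if has_channels else arr[window]
        acc[window] += operator.predict(patch)
        counts[window] += 1
    return FusedProbability(values=(acc / np.maximum(counts, 1)).astype(np.float32),
                            counts=counts, geometry=geometry)


def predict_volume_padded(operator, image: ImageVolume, overlap: float = 0.5
                          ) -> ProbabilityVolume:
    """Convenience wrapper: pad the volume up to the operator's patch size
    if needed, predict with max fusion, crop back, return a typed
    probability volume on the image grid."""
    patch = operator.patch_size
    arr = image.values
    pad = [(0, max(0, p - s)) for p, s in zip(patch, arr.shape)]
    padded = np.pad(arr, pad, constant_values=float(arr.min())) if any(
        p[1] for p in pad) else arr
    plan = plan_windows(padded.shape, patch, overlap)
    fused = predict_volume(operator, padded, plan)
    values = fused.values[tuple(slice(0, s) for s in arr.shape)]
    return ProbabilityVolume(values=values, geometry=image.geometry)


_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def extract_candidates(fused, threshold: float = 0.5, connectivity: int = 26,
                       min_component_size: int = 1) -> list[CandidateRegion]:
    """Threshold, label connected components, filter tiny ones.

    Returns candidates sorted by descending voxel count (ties by component
    id).  ``fused`` may be a FusedProbability, ProbabilityVolume or array.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be one of {sorted(_STRUCTURES)}")
    values = fused.values if hasattr(fused, "values") else np.asarray(fused)
    binary = values >= threshold
    labelled, n = ndimage.label(binary, structure=_STRUCTURES[connectivity])
    out: list[CandidateRegion] = []
    for comp_id in range(1, n + 1):
        idx = np.argwhere(labelled == comp_id)
        if len(idx) < min_component_size:
            continue
        lo = idx.min(axis=0)
        hi = idx.max(axis=0)
        centroid = idx.mean(axis=0)
        mean_p = float(values[tuple(idx.T)].mean())
        out.append(CandidateRegion(
            component_id=comp_id,
            voxel_count=int(len(idx)),
            bbox=tuple((int(a), int(b)) for a, b in zip(lo, hi)),
            centroid_voxel=tuple(float(c) for c in centroid),
            mean_probability=mean_p,
            voxel_indices=idx,
        ))
    out.sort(key=lambda c: (-c.voxel_count, c.component_id))
    return out


def crop_multiscale(image, candidate: CandidateRegion,
                    sizes: tuple[int, ...] = (48, 64, 80)) -> MultiScaleCrops:
    """Cut cubic crops of strictly increasing edge length centred on the
    candidate centroid (floored); out-of-bounds voxels are padded with the
    image minimum so border candidates still yield full-size crops."""
    sizes = tuple(int(s) for s in sizes)
    if any(s < 8 for s in sizes) or any(a >= b for a, b in zip(sizes, sizes[1:])):
        raise ValueError(f"sizes must be strictly increasing and >= 8, got {sizes}")
    arr = image.values if isinstance(image, ImageVolume) else np.asarray(image)
    fill = float(arr.min())
    centre = tuple(int(np.floor(c)) for c in candidate.centroid_voxel)
    crops = []
    for size in sizes:
        lo = [c - size // 2 for c in centre]
        out = np.full((size,) * arr.ndim, fill, dtype=np.float32)
        src = []
        dst = []
        for ax, l in enumerate(lo):
            s0 = max(0, l)
            s1 = min(arr.shape[ax], l + size)
            src.append(slice(s0, s1))
            dst.append(slice(s0 - l, s1 - l))
        if all(s.stop > s.start for s in src):
            out[tuple(dst)] = arr[tuple(src)]
        crops.append(out)
    return MultiScaleCrops(crops=tuple(crops), sizes=sizes,
                           candidate_ref=candidate.component_id)
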