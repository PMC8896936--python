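"""Synthetic CT-like phantoms with rib-like tubes and instance-labelled lesions.

Real rib-fracture CT is large, external and annotation-heavy; this module
generates seeded desk-scale stand-ins with the same structure so that every
downstream stage — preprocessing, segmentation training, sliding-window
inference, candidate classification, evaluation — can be exercised
hermetically.  A phantom is a soft-tissue background, a handful of curved
bone-density tubes ("ribs"), bright lesion blobs attached to the tubes
(instance-labelled with fracture types 1-4 or the uncertain class -1), and
optionally off-rib decoy blobs of lesion-like intensity that are *not*
labelled: these produce exactly the kind of stage-1 false positives the
second-stage classifier exists to remove.

Everything is a pure function of (config, sample index).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .geometry import ImageVolume, LabelVolume, VolumeGeometry
from .volume_io import write_volume


class PlacementError(RuntimeError):
    """Lesion or decoy placement failed after the retry cap — the grid is too
    small or too crowded for the requested configuration."""


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, content and intensity model of one phantom family.

    HU levels default to plausible CT values: soft tissue around -50,
    cortical-bone tubes at +700 and fresh-callus-like lesions at +200, with
    additive Gaussian noise of 20 HU, so that percentile-based HU clipping
    downstream operates on a realistic dynamic range.
    """

    grid_size: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_ribs: int = 3
    n_lesions: int = 3
    lesion_radius_mm: tuple[float, float] = (1.5, 3.0)
    hu_background: float = -50.0
    hu_bone: float = 700.0
    hu_lesion: float = 200.0
    noise_sd: float = 20.0
    uncertain_fraction: float = 0.1
    seed: int = 0
    # decoy blobs: lesion-intensity spheres placed off-rib and left unlabelled
    n_decoys: int = 0
    decoy_hu: Optional[float] = None  # defaults to hu_lesion
    rib_radius_mm: float = 2.5

    def __post_init__(self) -> None:
        object.__setattr__(self, "grid_size", tuple(int(g) for g in self.grid_size))
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))
        if any(g < 16 for g in self.grid_size):
            raise ValueError(f"grid_size must be >= 16 per axis, got {self.grid_size}")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing_mm must be positive")
        if not 0.0 <= self.uncertain_fraction <= 1.0:
            raise ValueError("uncertain_fraction must lie in [0, 1]")
        if self.lesion_radius_mm[0] > self.lesion_radius_mm[1]:
            raise ValueError("lesion_radius_mm must be (min, max) with min <= max")
        if self.n_ribs < 0 or self.n_lesions < 0 or self.n_decoys < 0:
            raise ValueError("counts must be non-negative")

    @property
    def geometry(self) -> VolumeGeometry:
        return VolumeGeometry(size=self.grid_size, spacing_mm=self.spacing_mm)


@dataclass
class LesionRecord:
    instance_id: int
    centroid_voxel: tuple[float, float, float]
    radius_mm: float
    label: int


@dataclass
class PhantomSample:
    """One generated phantom: HU image + instance labels + placement catalogue."""

    image: ImageVolume
    labels: LabelVolume
    lesion_catalogue: list[LesionRecord]
    decoy_catalogue: list[LesionRecord] = field(default_factory=list)
    index: int = 0


def _voxel_coords_mm(geometry: VolumeGeometry) -> list[np.ndarray]:
    """Per-axis physical coordinates of voxel centres (broadcastable)."""
    out = []
    for ax, (n, sp) in enumerate(zip(geometry.size, geometry.spacing_mm)):
        shape = [1, 1, 1]
        shape[ax] = n
        out.append((np.arange(n, dtype=np.float32) * sp).reshape(shape))
    return out


def _stamp_ball(mask: np.ndarray, center_mm: np.ndarray, radius_mm: float,
                spacing: np.ndarray) -> None:
    """Set mask voxels whose centre lies within radius_mm of center_mm."""
    lo = np.maximum(np.floor((center_mm - radius_mm) / spacing).astype(int), 0)
    hi = np.minimum(np.ceil((center_mm + radius_mm) / spacing).astype(int) + 1,
                    np.asarray(mask.shape))
    if np.any(lo >= hi):
        return
    grids = np.ix_(*[np.arange(lo[a], hi[a]) for a in range(3)])
    d2 = sum(((grids[a] * spacing[a] - center_mm[a]) ** 2) for a in range(3))
    sub = mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    sub |= d2 <= radius_mm ** 2


def _render_ribs(config: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    """Boolean rib mask: curved tubes (axial-plane arcs with sagittal drift)."""
    spacing = np.asarray(config.spacing_mm, dtype=np.float64)
    ext = np.asarray(config.grid_size, dtype=np.float64) * spacing
    mask = np.zeros(config.grid_size, dtype=bool)
    for _ in range(config.n_ribs):
        cz = rng.uniform(0.2, 0.8) * ext[0]
        cy = rng.uniform(0.35, 0.65) * ext[1]
        cx = rng.uniform(0.35, 0.65) * ext[2]
        arc_r = rng.uniform(0.22, 0.38) * min(ext[1], ext[2])
        theta0 = rng.uniform(0, 2 * np.pi)
        sweep = rng.uniform(0.6 * np.pi, 1.1 * np.pi)
        drift = rng.uniform(-0.15, 0.15) * ext[0]
        n_steps = max(32, int(arc_r * sweep / min(spacing)) * 2)
        t = np.linspace(0.0, 1.0, n_steps)
        theta = theta0 + sweep * t
        pz = cz + drift * (t - 0.5)
        py = cy + arc_r * np.sin(theta)
        px = cx + arc_r * np.cos(theta)
        for p in np.stack([pz, py, px], axis=1):
            _stamp_ball(mask, p, config.rib_radius_mm, spacing)
    return mask


def _draw_label(rng: np.random.Generator, uncertain_fraction: float) -> int:
    if rng.uniform() < uncertain_fraction:
        return -1
    return int(rng.integers(1, 5))


_RETRY_CAP = 100


def generate_phantom(config: PhantomConfig, index: int = 0) -> PhantomSample:
    """Generate one phantom, deterministically for fixed (config, index).

    Ribs are rendered first at ``hu_bone``; each lesion is a sphere whose
    voxel set must intersect a rib voxel (attachment), placed by rejection
    sampling with a cap of 100 attempts; pairwise lesion-centroid distances
    are kept above one maximum lesion diameter so instances stay disjoint
    and the connected-component count equals ``n_lesions``.  Decoys are the
    mirror image: spheres kept *away* from ribs and lesions, written into
    the image but not the label volume.  Gaussian noise is added to the
    image only.

    Raises :class:`PlacementError` when placement is impossible.
    """
    geometry = config.geometry
    rng = np.random.default_rng(np.random.SeedSequence([config.seed & 0x7FFFFFFF, index]))
    spacing = np.asarray(config.spacing_mm, dtype=np.float64)
    ext = np.asarray(config.grid_size, dtype=np.float64) * spacing

    rib_mask = _render_ribs(config, rng)
    image = np.full(config.grid_size, config.hu_background, dtype=np.float32)
    image[rib_mask] = config.hu_bone
    labels = np.zeros(config.grid_size, dtype=np.int8)

    rib_voxels = np.argwhere(rib_mask)
    if config.n_lesions > 0 and len(rib_voxels) == 0:
        raise PlacementError("no rib voxels to attach lesions to (n_ribs=0?)")

    max_diameter = 2.0 * config.lesion_radius_mm[1]
    centres: list[np.ndarray] = []
    catalogue: list[LesionRecord] = []
    for lesion_id in range(1, config.n_lesions + 1):
        placed = False
        for _ in range(_RETRY_CAP):
            radius = rng.uniform(*config.lesion_radius_mm)
            anchor = rib_voxels[rng.integers(len(rib_voxels))] * spacing
            centre = anchor + rng.uniform(-0.5, 0.5, size=3) * radius
            centre = np.clip(centre, radius, ext - radius)
            if any(np.linalg.norm(centre - c) < max_diameter + 1.0 for c in centres):
                continue
            blob = np.zeros(config.grid_size, dtype=bool)
            _stamp_ball(blob, centre, radius, spacing)
            if not blob.any() or not (blob & rib_mask).any():
                continue
            if (labels[blob] != 0).any():
                continue
            label = _draw_label(rng, config.uncertain_fraction)
            image[blob] = config.hu_lesion
            labels[blob] = label
            centroid = tuple(float(v) for v in np.argwhere(blob).mean(axis=0))
            catalogue.append(LesionRecord(lesion_id, centroid, float(radius), label))
            centres.append(centre)
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place lesion {lesion_id} after {_RETRY_CAP} attempts "
                f"(grid {config.grid_size} too small or too crowded)"
            )

    decoy_hu = config.hu_lesion if config.decoy_hu is None else config.decoy_hu
    decoys: list[LesionRecord] = []
    for decoy_id in range(1, config.n_decoys + 1):
        placed = False
        for _ in range(_RETRY_CAP):
            radius = rng.uniform(*config.lesion_radius_mm)
            centre = rng.uniform(radius, ext - radius)
            if any(np.linalg.norm(centre - c) < max_diameter + 1.0 for c in centres):
                continue
            blob = np.zeros(config.grid_size, dtype=bool)
            _stamp_ball(blob, centre, radius, spacing)
            if not blob.any() or (blob & rib_mask).any() or (labels[blob] != 0).any():
                continue
            # keep decoys genuinely off-rib: no rib voxel within one radius margin
            pad = np.zeros(config.grid_size, dtype=bool)
            _stamp_ball(pad, centre, radius + 2.0 * config.rib_radius_mm, spacing)
            if (pad & rib_mask).any():
                continue
            image[blob] = decoy_hu
            centroid = tuple(float(v) for v in np.argwhere(blob).mean(axis=0))
            decoys.append(LesionRecord(decoy_id, centroid, float(radius), 0))
            centres.append(centre)
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place decoy {decoy_id} after {_RETRY_CAP} attempts"
            )

    if config.noise_sd > 0:
        image = image + rng.normal(0.0, config.noise_sd, size=config.grid_size).astype(np.float32)

    return PhantomSample(
        image=ImageVolume(values=image, geometry=geometry),
        labels=LabelVolume(values=labels, geometry=geometry),
        lesion_catalogue=catalogue,
        decoy_catalogue=decoys,
        index=index,
    )


def generate_dataset(config: PhantomConfig, n: int) -> list[PhantomSample]:
    """Generate ``n`` phantoms indexed 0..n-1, each independently reproducible
    as ``generate_phantom(config, i)``."""
    if n < 1:
        raise ValueError(f"dataset size must be >= 1, got {n}")
    samples = []
    for i in range(n):
        try:
            samples.append(generate_phantom(config, i))
        except PlacementError as exc:
            raise PlacementError(f"sample {i}: {exc}") from exc
    return samples


def write_sample(sample: PhantomSample, image_path, label_path,
                 catalogue_path=None) -> None:
    """Write a phantom as a NIfTI image/label pair plus an optional JSON
    sidecar holding the lesion and decoy catalogues."""
    write_volume(sample.image, image_path)
    write_volume(sample.labels, label_path)
    if catalogue_path is not None:
        payload = {
            "index": sample.index,
            "lesions": [asdict(r) for r in sample.lesion_catalogue],
            "decoys": [asdict(r) for r in sample.decoy_catalogue],
        }
        with open(os.fspath(catalogue_path), "w") as fh:
            json.dump(payload, fh, indent=2)
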