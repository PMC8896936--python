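"""Dataset fingerprinting and the resample → clip → z-score chain.

The fingerprint captures dataset-level choices: the common target spacing
(per-axis mean of training spacings) and foreground-HU clip bounds (0.5th
and 99.5th percentiles of HU pooled over voxels where the merged label is
foreground).  Each volume is then resampled onto the target spacing with a
physical-extent-preserving grid, clipped, and z-scored with per-sample
statistics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Union

import numpy as np
from scipy import ndimage

from .geometry import (
    BinaryMask,
    ImageVolume,
    LabelVolume,
    VolumeGeometry,
)
from .volume_io import merge_labels


class EmptyForegroundError(ValueError):
    """No foreground voxel anywhere in the pooled dataset."""


class ConstantVolumeError(ValueError):
    """z-normalization of a (near-)constant volume is undefined."""


@dataclass(frozen=True)
class DatasetFingerprint:
    """Dataset-level preprocessing parameters."""

    target_spacing_mm: tuple[float, float, float]
    hu_lo: float
    hu_hi: float
    median_size: tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.hu_lo >= self.hu_hi:
            raise ValueError("hu_lo must be < hu_hi")
        if any(s <= 0 for s in self.target_spacing_mm):
            raise ValueError("target spacing must be positive")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "DatasetFingerprint":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            target_spacing_mm=tuple(d["target_spacing_mm"]),
            hu_lo=float(d["hu_lo"]),
            hu_hi=float(d["hu_hi"]),
            median_size=tuple(d["median_size"]),
        )


@dataclass(frozen=True)
class NormalizationStats:
    """Per-sample mean/SD used by the z-score step."""

    mean: float
    std: float

    def __post_init__(self) -> None:
        if self.std < 0:
            raise ValueError("std must be >= 0")


def compute_fingerprint(
    samples: list[tuple[ImageVolume, LabelVolume]],
) -> DatasetFingerprint:
    """Pool the training set into a fingerprint.

    target spacing: arithmetic mean of per-sample spacings, per axis.
    clip bounds: 0.5th / 99.5th percentiles (linear interpolation between
    order statistics) of the HU values at foreground voxels of the merged
    labels, pooled over all samples.
    median size: per-axis median of the sizes each sample would have after
    resampling to the target spacing.
    """
    if not samples:
        raise ValueError("need at least one sample")
    spacings = np.array([img.geometry.spacing_mm for img, _ in samples], dtype=np.float64)
    target = spacings.mean(axis=0)

    fg_values = []
    for img, lab in samples:
        mask = merge_labels(lab).values.astype(bool)
        if mask.any():
            fg_values.append(img.values[mask])
    if not fg_values:
        raise EmptyForegroundError("no foreground voxels in any sample")
    pooled = np.concatenate(fg_values)
    hu_lo, hu_hi = np.percentile(pooled, [0.5, 99.5])
    if hu_hi <= hu_lo:
        # degenerate foreground (constant HU): widen to a 2-HU band
        hu_lo, hu_hi = hu_lo - 1.0, hu_hi + 1.0

    sizes = []
    for img, _ in samples:
        old = np.asarray(img.geometry.size, dtype=np.float64)
        sp = np.asarray(img.geometry.spacing_mm, dtype=np.float64)
        sizes.append(np.maximum(np.rint(old * sp / target), 1).astype(int))
    median_size = tuple(int(m) for m in np.median(np.array(sizes), axis=0))

    return DatasetFingerprint(
        target_spacing_mm=tuple(float(t) for t in target),
        hu_lo=float(hu_lo),
        hu_hi=float(hu_hi),
        median_size=median_size,
    )


AnyVolume = Union[ImageVolume, LabelVolume, BinaryMask]


def resample(volume: AnyVolume, target_spacing_mm, mode: str | None = None) -> AnyVolume:
    """Resample onto ``target_spacing_mm`` preserving the physical extent.

    The new grid has per-axis size round(old_size * old_spacing / target),
    floored at 1.  ``mode`` is "continuous" (trilinear) or "nearest";
    labels and masks default to nearest so no new values are invented,
    images default to continuous.
    """
    target = np.asarray(target_spacing_mm, dtype=np.float64)
    if np.any(target <= 0):
        raise ValueError(f"target spacing must be positive, got {target}")
    if mode is None:
        mode = "continuous" if isinstance(volume, ImageVolume) else "nearest"
    if mode not in ("continuous", "nearest"):
        raise ValueError(f"mode must be 'continuous' or 'nearest', got {mode!r}")

    old_size = np.asarray(volume.geometry.size, dtype=np.float64)
    old_sp = np.asarray(volume.geometry.spacing_mm, dtype=np.float64)
    new_size = np.maximum(np.rint(old_size * old_sp / target), 1).astype(int)
    new_geometry = VolumeGeometry(
        size=tuple(int(s) for s in new_size),
        spacing_mm=tuple(float(t) for t in target),
        origin_mm=volume.geometry.origin_mm,
    )
    if tuple(new_size) == volume.geometry.size and np.allclose(old_sp, target):
        return type(volume)(values=volume.values.copy(), geometry=new_geometry)

    order = 1 if mode == "continuous" else 0
    zoom = new_size / old_size
    out = ndimage.zoom(
        volume.values.astype(np.float32),
        zoom,
        order=order,
        mode="nearest",
        grid_mode=True,
        prefilter=False,
    )
    # zoom with grid_mode can be off by one voxel in rare rounding cases
    if tuple(out.shape) != tuple(new_size):  # pragma: no cover - defensive
        out = out[tuple(slice(0, s) for s in new_size)]
    if isinstance(volume, ImageVolume):
        return ImageVolume(values=out, geometry=new_geometry)
    out_int = np.rint(out).astype(np.int8)
    if isinstance(volume, LabelVolume):
        return LabelVolume(values=out_int, geometry=new_geometry)
    return BinaryMask(values=out_int.astype(np.uint8), geometry=new_geometry)


def clip_hu(image: ImageVolume, hu_lo: float, hu_hi: float) -> ImageVolume:
    """Saturate intensities into [hu_lo, hu_hi]; in-range voxels unchanged."""
    if hu_lo >= hu_hi:
        raise ValueError(f"hu_lo ({hu_lo}) must be < hu_hi ({hu_hi})")
    return ImageVolume(
        values=np.clip(image.values, hu_lo, hu_hi), geometry=image.geometry
    )


def znormalize(image: ImageVolume) -> tuple[ImageVolume, NormalizationStats]:
    """Per-sample z-score: y = (x - mean) / std over the whole volume."""
    mean = float(image.values.mean(dtype=np.float64))
    std = float(image.values.std(dtype=np.float64))
    if std < 1e-8:
        raise ConstantVolumeError(
            f"volume is constant (std={std:.2e}); z-score undefined"
        )
    out = ((image.values.astype(np.float64) - mean) / std).astype(np.float32)
    return (
        ImageVolume(values=out, geometry=image.geometry),
        NormalizationStats(mean=mean, std=std),
    )


def preprocess_sample(
    image: ImageVolume,
    labels: LabelVolume | None,
    fingerprint: DatasetFingerprint,
) -> tuple[ImageVolume, BinaryMask | None, NormalizationStats]:
    """Apply the full chain to one sample: resample, clip, z-score; labels
    are merged to a binary mask and resampled nearest-neighbour."""
    img = resample(image, fingerprint.target_spacing_mm, mode="continuous")
    img = clip_hu(img, fingerprint.hu_lo, fingerprint.hu_hi)
    img, stats = znormalize(img)
    mask = None
    if labels is not None:
        mask = resample(merge_labels(labels), fingerprint.target_spacing_mm, mode="nearest")
    return img, mask, stats
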