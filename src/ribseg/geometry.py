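"""Voxel-grid containers shared by every stage of the pipeline.

All arrays use (z, y, x) axis order — the CT slice-stack convention — and all
physical quantities are millimetres.  ``VolumeGeometry`` carries the grid
shape, per-axis voxel spacing and the physical position of voxel (0, 0, 0);
the typed volumes below pair a value array with a geometry and validate the
pairing on construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

VALID_LABELS = frozenset({-1, 0, 1, 2, 3, 4})


class GeometryError(ValueError):
    """Raised when a volume's array and geometry disagree, or two volumes
    with incompatible geometry are combined."""


class InvalidLabelError(ValueError):
    """Raised when a label volume contains values outside {-1, 0, 1, 2, 3, 4}."""


@dataclass(frozen=True)
class VolumeGeometry:
    """Grid shape, spacing and origin of a voxel volume, in (z, y, x) order."""

    size: tuple[int, int, int]
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "size", tuple(int(s) for s in self.size))
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))
        object.__setattr__(self, "origin_mm", tuple(float(s) for s in self.origin_mm))
        if len(self.size) != 3 or len(self.spacing_mm) != 3:
            raise GeometryError("geometry is three-dimensional (z, y, x)")
        if any(s < 1 for s in self.size):
            raise GeometryError(f"all sizes must be >= 1, got {self.size}")
        if any(s <= 0 for s in self.spacing_mm):
            raise GeometryError(f"all spacings must be > 0, got {self.spacing_mm}")

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        """Physical edge length of the grid per axis."""
        return tuple(n * s for n, s in zip(self.size, self.spacing_mm))

    def almost_equal(self, other: "VolumeGeometry", tol: float = 1e-6) -> bool:
        return self.size == other.size and all(
            abs(a - b) <= tol for a, b in zip(
                self.spacing_mm + self.origin_mm, other.spacing_mm + other.origin_mm
            )
        )


def _check_shape(values: np.ndarray, geometry: VolumeGeometry) -> None:
    if tuple(values.shape) != geometry.size:
        raise GeometryError(
            f"array shape {values.shape} does not match geometry size {geometry.size}"
        )


@dataclass
class ImageVolume:
    """Scalar (Hounsfield-unit or normalized) intensity field over a grid."""

    values: np.ndarray
    geometry: VolumeGeometry

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        _check_shape(self.values, self.geometry)


@dataclass
class LabelVolume:
    """Instance-style integer labels: 0 background, 1-4 fracture types,
    -1 fracture of uncertain type.  Stored as signed 8-bit."""

    values: np.ndarray
    geometry: VolumeGeometry

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        present = set(np.unique(arr).tolist())
        if not present <= VALID_LABELS:
            raise InvalidLabelError(
                f"label volume contains invalid values {sorted(present - VALID_LABELS)}"
            )
        self.values = arr.astype(np.int8)
        _check_shape(self.values, self.geometry)


@dataclass
class BinaryMask:
    """Per-voxel {0, 1} foreground mask."""

    values: np.ndarray
    geometry: VolumeGeometry

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if not set(np.unique(arr).tolist()) <= {0, 1}:
            raise ValueError("binary mask may only contain 0 and 1")
        self.values = arr.astype(np.uint8)
        _check_shape(self.values, self.geometry)

    @property
    def foreground_count(self) -> int:
        return int(self.values.sum())


@dataclass
class ProbabilityVolume:
    """Per-voxel foreground probability in [0, 1].

    Doubles as the smoothed region indicator whose gradient magnitude the
    contour loss integrates.
    """

    values: np.ndarray
    geometry: VolumeGeometry

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        _check_shape(self.values, self.geometry)
        lo, hi = float(self.values.min(initial=0.0)), float(self.values.max(initial=0.0))
        if lo < -1e-6 or hi > 1 + 1e-6:
            raise ValueError(f"probabilities must lie in [0, 1], got range [{lo}, {hi}]")
        np.clip(self.values, 0.0, 1.0, out=self.values)


def require_same_geometry(a, b) -> None:
    """Raise GeometryError unless two volumes share size/spacing/origin."""
    if not a.geometry.almost_equal(b.geometry):
        raise GeometryError(
            f"geometry mismatch: {a.geometry} vs {b.geometry}"
        )
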