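"""NIfTI reading/writing and the label-merging rule.

Arrays are kept in (z, y, x) order internally while NIfTI stores (x, y, z),
so voxel data are transposed at the boundary.  Only axis-aligned affines
(pure per-axis scaling plus translation) are accepted: oblique acquisitions
are out of scope and rejected loudly rather than silently resampled.
"""

from __future__ import annotations

import os
from typing import Union

import nibabel as nib
import numpy as np

from .geometry import (
    BinaryMask,
    GeometryError,
    ImageVolume,
    InvalidLabelError,
    LabelVolume,
    VolumeGeometry,
)

Volume = Union[ImageVolume, LabelVolume, BinaryMask]


def _affine_from_geometry(geometry: VolumeGeometry) -> np.ndarray:
    # spacing/origin are (z, y, x); NIfTI affine columns are (x, y, z)
    affine = np.eye(4)
    affine[0, 0] = geometry.spacing_mm[2]
    affine[1, 1] = geometry.spacing_mm[1]
    affine[2, 2] = geometry.spacing_mm[0]
    affine[:3, 3] = (geometry.origin_mm[2], geometry.origin_mm[1], geometry.origin_mm[0])
    return affine


def _geometry_from_nifti(img: nib.Nifti1Image, shape_zyx: tuple[int, ...]) -> VolumeGeometry:
    affine = img.affine
    rot = affine[:3, :3]
    off_diag = rot - np.diag(np.diag(rot))
    if np.abs(off_diag).max() > 1e-6:
        raise GeometryError(
            "non-axis-aligned affine: only scaling+translation affines are supported"
        )
    scale_xyz = np.diag(rot)
    if np.any(np.abs(scale_xyz) <= 0):
        raise GeometryError("affine has zero scaling on some axis")
    spacing = (abs(scale_xyz[2]), abs(scale_xyz[1]), abs(scale_xyz[0]))
    origin = (affine[2, 3], affine[1, 3], affine[0, 3])
    return VolumeGeometry(size=shape_zyx, spacing_mm=spacing, origin_mm=origin)


def write_volume(volume: Volume, path: Union[str, os.PathLike]) -> None:
    """Write an image/label/mask volume as NIfTI-1.

    Images are stored as float32, labels as int8 (so the -1 class survives
    the round trip exactly) and masks as uint8.
    """
    if isinstance(volume, ImageVolume):
        data = volume.values.astype(np.float32)
    elif isinstance(volume, LabelVolume):
        data = volume.values.astype(np.int8)
    else:
        data = volume.values.astype(np.uint8)
    # transpose (z, y, x) -> (x, y, z) for on-disk layout
    img = nib.Nifti1Image(np.ascontiguousarray(data.T), _affine_from_geometry(volume.geometry))
    nib.save(img, os.fspath(path))


def read_volume(path: Union[str, os.PathLike], kind: str = "image") -> Volume:
    """Read a NIfTI volume as ``kind`` in {"image", "label", "mask"}.

    Label reads validate the value set and raise :class:`InvalidLabelError`
    for anything outside {-1, 0, 1, 2, 3, 4}.
    """
    if kind not in ("image", "label", "mask"):
        raise ValueError(f"kind must be 'image', 'label' or 'mask', got {kind!r}")
    img = nib.load(os.fspath(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise GeometryError(f"expected a 3D volume, got shape {data.shape}")
    data = data.T  # (x, y, z) -> (z, y, x)
    geometry = _geometry_from_nifti(img, tuple(data.shape))
    if kind == "image":
        return ImageVolume(values=data.astype(np.float32), geometry=geometry)
    if kind == "label":
        as_int = np.rint(data).astype(np.int64)
        if not np.array_equal(as_int, data):
            raise InvalidLabelError("label volume contains non-integer values")
        return LabelVolume(values=as_int, geometry=geometry)
    return BinaryMask(values=np.rint(data).astype(np.uint8), geometry=geometry)


def merge_labels(labels: LabelVolume) -> BinaryMask:
    """Collapse instance labels to a single foreground class.

    Every nonzero label — the typed classes 1-4 and the uncertain class -1
    alike — maps to 1; background stays 0.  Geometry is preserved.
    """
    return BinaryMask(values=(labels.values != 0).astype(np.uint8), geometry=labels.geometry)
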