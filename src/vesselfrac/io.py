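"""Reading and writing the pipeline's file formats.

Volumes travel as NIfTI (voxel spacing in the header), 2D projections
and masks as single-page TIFF (32-bit float for grayscale, 8-bit 0/255
for binary), cohorts as CSV.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import tifffile

from .projection import MIPImage, Volume3D
from .segmentation import BinaryMask, SkeletonMask

__all__ = [
    "read_volume", "write_volume",
    "read_image", "write_image",
    "read_mask", "write_mask",
]


def read_volume(path) -> Volume3D:
    """Load a 3D NIfTI volume; voxel spacing comes from the header zooms."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume not found: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume, got {data.ndim}D: {path}")
    zooms = img.header.get_zooms()[:3]
    return Volume3D(data, voxel_mm=tuple(float(z) for z in zooms))


def write_volume(vol: Volume3D, path) -> Path:
    path = Path(path)
    affine = np.diag(list(vol.voxel_mm) + [1.0])
    img = nib.Nifti1Image(vol.intensities.astype(np.float32), affine)
    img.header.set_zooms(vol.voxel_mm)
    nib.save(img, str(path))
    return path


def write_image(img: MIPImage | np.ndarray, path, dtype: str = "float32") -> Path:
    """Write a grayscale image as TIFF (float32, or uint8 rescaled to 0-255)."""
    path = Path(path)
    arr = img.intensities if isinstance(img, MIPImage) else np.asarray(img)
    if dtype == "uint8":
        lo, hi = float(arr.min()), float(arr.max())
        scale = 255.0 / (hi - lo) if hi > lo else 0.0
        arr = ((arr - lo) * scale).astype(np.uint8)
    else:
        arr = arr.astype(np.float32)
    tifffile.imwrite(str(path), arr)
    return path


def read_image(path) -> MIPImage:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image not found: {path}")
    arr = tifffile.imread(str(path))
    return MIPImage(np.asarray(arr, dtype=float))


def write_mask(mask: BinaryMask | SkeletonMask, path) -> Path:
    """Write a binary mask as 8-bit TIFF with foreground 255."""
    path = Path(path)
    tifffile.imwrite(str(path), (mask.pixels * 255).astype(np.uint8))
    return path


def read_mask(path) -> BinaryMask:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"mask not found: {path}")
    arr = tifffile.imread(str(path))
    return BinaryMask((np.asarray(arr) > 0).astype(np.uint8),
                      provenance="manual_import")
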