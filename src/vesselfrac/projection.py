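"""Maximum-intensity projection (MIP) of 3D angiographic volumes.

Time-of-flight MR angiography renders flowing blood bright on a dark
background, so collapsing the volume with a per-ray maximum preserves the
vascular tree in a single 2D view. The projection here is orthographic
along one of the three voxel axes; the axial (superior-inferior) axis is
the default, giving the transverse view in which the circle of Willis and
its tributaries are conventionally assessed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Volume3D", "MIPImage", "max_intensity_project"]

#: accepted axis spellings -> axis index (x = first array axis)
_AXIS_ALIASES = {
    "x": 0, "y": 1, "z": 2,
    "sagittal": 0, "coronal": 1, "axial": 2,
    0: 0, 1: 1, 2: 2,
}


@dataclass
class Volume3D:
    """A 3D grayscale volume with physical voxel spacing.

    Parameters
    ----------
    intensities : ndarray, shape (nx, ny, nz)
        Non-negative grayscale intensities.
    voxel_mm : tuple of float
        Voxel edge lengths in millimetres along each array axis.
    axis_labels : tuple of str
        Anatomical label of each array axis. The default maps the third
        axis to the superior-inferior (axial projection) direction.
    """

    intensities: np.ndarray
    voxel_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    axis_labels: tuple[str, str, str] = ("sagittal", "coronal", "axial")

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 3:
            raise ValueError(
                f"volume must be 3D, got {self.intensities.ndim}D"
            )
        if min(self.intensities.shape) < 1 or self.intensities.size == 0:
            raise ValueError("volume has an empty axis")
        self.voxel_mm = tuple(float(v) for v in self.voxel_mm)
        if len(self.voxel_mm) != 3 or any(v <= 0 for v in self.voxel_mm):
            raise ValueError(f"voxel_mm must be 3 positive reals, got {self.voxel_mm}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape


@dataclass
class MIPImage:
    """A 2D maximum-intensity projection and its pixel spacing."""

    intensities: np.ndarray
    pixel_mm: tuple[float, float] = (1.0, 1.0)
    source_axis: int = 2

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2:
            raise ValueError("MIP image must be 2D")
        self.pixel_mm = tuple(float(v) for v in self.pixel_mm)

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensities.shape


def resolve_axis(axis) -> int:
    """Map an axis name ('x'/'y'/'z', anatomical label, or index) to 0/1/2."""
    try:
        return _AXIS_ALIASES[axis if not isinstance(axis, str) else axis.lower()]
    except (KeyError, TypeError):
        raise ValueError(f"unknown projection axis {axis!r}") from None


def max_intensity_project(vol: Volume3D | np.ndarray, axis="axial") -> MIPImage:
    """Collapse a volume to 2D by taking the per-column maximum.

    Parameters
    ----------
    vol : Volume3D or 3D ndarray
        Input volume; a bare array is wrapped with unit voxel spacing.
    axis : str or int
        The axis to collapse ('x'/'y'/'z', 'sagittal'/'coronal'/'axial',
        or 0/1/2). Default: the axial axis (transverse view).

    Returns
    -------
    MIPImage
        ``out[i, j] = max_k vol[..k..]`` with ``k`` running along the
        collapsed axis; pixel spacing is the voxel spacing of the two
        remaining axes.
    """
    if not isinstance(vol, Volume3D):
        vol = Volume3D(np.asarray(vol))
    ax = resolve_axis(axis)
    data = vol.intensities
    if data.size == 0:
        raise ValueError("cannot project an empty volume")
    if not np.all(np.isfinite(data)):
        raise ValueError("volume contains non-finite intensities")
    mip = data.max(axis=ax)
    kept = [i for i in range(3) if i != ax]
    return MIPImage(
        intensities=mip,
        pixel_mm=(vol.voxel_mm[kept[0]], vol.voxel_mm[kept[1]]),
        source_axis=ax,
    )
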