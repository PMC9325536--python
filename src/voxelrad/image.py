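"""Minimal 3D image container with physical geometry and NIfTI-1 round trip.

All volumes in this package live on axis-aligned grids: the affine is a
diagonal scaling by the voxel spacing plus a translation (RAS convention).
That is sufficient for phantom studies and for co-registered clinical
volumes that have been resampled to a common frame.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np


class Modality(str, enum.Enum):
    PET = "PET"
    CT = "CT"
    T1 = "T1"
    T2FS = "T2FS"


class Units(str, enum.Enum):
    SUV = "SUV"
    HU = "HU"
    NORMALIZED = "NORMALIZED"
    ARBITRARY = "ARBITRARY"


@dataclass
class ImageVolume:
    """A 3D scalar grid with spacing/origin, modality tag and physical units.

    Parameters
    ----------
    values : ndarray of shape (nx, ny, nz)
        Voxel values. Masks use dtype bool or {0, 1}.
    spacing_mm : tuple of 3 floats
        Voxel size along each axis, millimetres. Must be positive.
    origin_mm : tuple of 3 floats
        Physical coordinate of voxel (0, 0, 0).
    modality, units
        Tags carried through the pipeline; they never alter numerics.
    """

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    modality: Modality | None = None
    units: Units = Units.ARBITRARY
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.values.ndim}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be positive, got {self.spacing_mm}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing_mm) + [1.0])
        aff[:3, 3] = self.origin_mm
        return aff

    def with_values(self, values: np.ndarray, **changes) -> "ImageVolume":
        """Copy of this volume with new voxel data on the same grid."""
        return replace(self, values=np.asarray(values), **changes)

    def same_grid(self, other: "ImageVolume", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing_mm, other.spacing_mm, atol=atol)
            and np.allclose(self.origin_mm, other.origin_mm, atol=atol)
        )

    # ---- NIfTI-1 I/O -------------------------------------------------

    def to_nifti(self, path) -> None:
        img = nib.Nifti1Image(np.asarray(self.values, dtype=np.float32), self.affine)
        img.header.set_zooms(self.spacing_mm)
        if self.modality is not None:
            img.header["descrip"] = f"{self.modality.value};{self.units.value}".encode()
        nib.save(img, str(path))

    @classmethod
    def from_nifti(cls, path, modality: Modality | None = None,
                   units: Units = Units.ARBITRARY) -> "ImageVolume":
        img = nib.load(str(path))
        aff = img.affine
        spacing = tuple(float(s) for s in np.abs(np.diag(aff)[:3]))
        origin = tuple(float(o) for o in aff[:3, 3])
        return cls(np.asanyarray(img.dataobj).astype(np.float64), spacing, origin,
                   modality=modality, units=units)


def as_bool_mask(mask: ImageVolume | np.ndarray) -> np.ndarray:
    """Return the boolean voxel array of a mask given as volume or array."""
    arr = mask.values if isinstance(mask, ImageVolume) else mask
    arr = np.asarray(arr)
    if arr.dtype != bool:
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("mask values must be in {0, 1}")
        arr = arr.astype(bool)
    return arr
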