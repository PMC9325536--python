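"""Intensity normalization, resampling, ROI conditioning and discretization.

Conventions
-----------
* All standard deviations in this module are population SDs (divide by N).
  The convention is recorded in the returned metadata so downstream scaling
  is unambiguous.
* CT ROI clipping keeps the closed interval [lo, hi]: values strictly less
  than ``lo_hu`` or strictly greater than ``hi_hu`` are excluded.
* Fixed-bin-size discretization anchors bins on multiples of the bin width
  (IBSI-style): gray level = floor(v / w) - floor(min_roi / w) + 1.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image import ImageVolume, Modality, Units, as_bool_mask

logger = logging.getLogger(__name__)

#: Default isotropic target spacings (mm) per modality.
DEFAULT_TARGET_SPACING = {
    Modality.PET: 3.0,
    Modality.CT: 1.0,
    Modality.T1: 1.0,
    Modality.T2FS: 1.0,
}


@dataclass
class ReferenceStats:
    """Pooled fat-tissue statistics behind a fat-reference normalization."""

    mu_fat: float
    sigma_fat: float
    n_reference_voxels: int
    sd_convention: str = "population"


class DiscretizationMode(str, enum.Enum):
    FIXED_BIN_SIZE = "FIXED_BIN_SIZE"
    FIXED_BIN_COUNT = "FIXED_BIN_COUNT"


@dataclass
class DiscretizationScheme:
    """Gray-level discretization: constant bin width, or a fixed number of
    equal-width bins spanning a cohort-wide intensity range."""

    mode: DiscretizationMode
    bin_width: float | None = None
    n_bins: int | None = None
    cohort_min: float | None = None
    cohort_max: float | None = None

    def __post_init__(self) -> None:
        self.mode = DiscretizationMode(self.mode)
        if self.mode is DiscretizationMode.FIXED_BIN_SIZE:
            if self.bin_width is None or self.bin_width <= 0:
                raise ValueError("FIXED_BIN_SIZE requires bin_width > 0")
        else:
            if self.n_bins is None or self.n_bins < 2:
                raise ValueError("FIXED_BIN_COUNT requires n_bins >= 2")
            if self.cohort_min is None or self.cohort_max is None \
                    or not self.cohort_max > self.cohort_min:
                raise ValueError("FIXED_BIN_COUNT requires cohort_max > cohort_min")


def resample_isotropic(img: ImageVolume, target_spacing_mm: float,
                       is_mask: bool = False) -> ImageVolume:
    """Resample to isotropic voxels: order-3 B-spline for images,
    nearest-neighbor for masks."""
    t = float(target_spacing_mm)
    if t <= 0:
        raise ValueError("target spacing must be positive")
    if np.allclose(img.spacing_mm, t):
        return img.with_values(img.values.copy())

    in_shape = img.shape
    coords = []
    out_shape = []
    for n, sp in zip(in_shape, img.spacing_mm):
        n_out = int(np.floor((n - 1) * sp / t + 1e-9)) + 1
        coords.append(np.arange(n_out) * (t / sp))
        out_shape.append(n_out)
    grid = np.meshgrid(*coords, indexing="ij")
    pts = np.stack([g.ravel() for g in grid])

    if is_mask:
        mask = as_bool_mask(img).astype(np.float64)
        out = ndimage.map_coordinates(mask, pts, order=0, mode="nearest")
        out_arr = out.reshape(out_shape).astype(np.uint8)
    else:
        out = ndimage.map_coordinates(np.asarray(img.values, dtype=np.float64),
                                      pts, order=3, mode="nearest")
        out_arr = out.reshape(out_shape)
    return ImageVolume(out_arr, (t, t, t), img.origin_mm,
                       modality=img.modality, units=img.units, meta=dict(img.meta))


def normalize_fat_reference(img: ImageVolume, fat_masks: list
                            ) -> tuple[ImageVolume, ReferenceStats]:
    """Linearly scale a T1 volume so pooled fat-sphere voxels have mean 0, SD 1.

    This is a White-Stripe-style normalization with fat as the reference
    tissue: an affine map, so inter-patient intensity ordering is preserved.
    """
    if not fat_masks:
        raise ValueError("at least one fat mask is required")
    union = np.zeros(img.shape, dtype=bool)
    for m in fat_masks:
        arr = as_bool_mask(m)
        if arr.shape != img.shape:
            raise ValueError("fat mask grid does not match the image grid")
        union |= arr
    vox = np.asarray(img.values, dtype=np.float64)[union]
    if vox.size < 2:
        raise ValueError("need at least 2 pooled fat voxels")
    mu = float(vox.mean())
    sigma = float(vox.std())  # population SD
    if sigma == 0:
        raise ValueError("fat reference voxels have zero variance")
    out = (np.asarray(img.values, dtype=np.float64) - mu) / sigma
    stats = ReferenceStats(mu, sigma, int(vox.size))
    meta = dict(img.meta)
    meta["normalization"] = {"method": "fat_reference", "mu": mu, "sigma": sigma,
                             "sd_convention": "population"}
    return img.with_values(out, units=Units.NORMALIZED, meta=meta), stats


def normalize_zscore_roi(img: ImageVolume, roi) -> ImageVolume:
    """Z-score a volume by its tumor-ROI statistics (ROI mean 0, SD 1 after)."""
    mask = as_bool_mask(roi)
    if mask.shape != img.shape:
        raise ValueError("ROI grid does not match the image grid")
    vox = np.asarray(img.values, dtype=np.float64)[mask]
    if vox.size < 2:
        raise ValueError("ROI must contain at least 2 voxels")
    mu = float(vox.mean())
    sigma = float(vox.std())
    if sigma == 0:
        raise ValueError("ROI intensities are constant; z-score undefined")
    out = (np.asarray(img.values, dtype=np.float64) - mu) / sigma
    meta = dict(img.meta)
    meta["normalization"] = {"method": "zscore_roi", "mu": mu, "sigma": sigma,
                             "sd_convention": "population"}
    return img.with_values(out, units=Units.NORMALIZED, meta=meta)


def clip_ct_roi(roi, ct: ImageVolume, lo_hu: float = -230.0,
                hi_hu: float = 600.0) -> np.ndarray:
    """Restrict a CT ROI to voxels with HU in the closed band [lo_hu, hi_hu],
    removing air and dense bone while keeping hypodensities/calcifications."""
    mask = as_bool_mask(roi)
    hu = np.asarray(ct.values)
    if mask.shape != hu.shape:
        raise ValueError("CT and ROI must share a grid")
    out = mask & (hu >= lo_hu) & (hu <= hi_hu)
    if not out.any():
        raise ValueError("CT ROI is empty after HU clipping")
    return out


def discretize(img: ImageVolume, roi, scheme: DiscretizationScheme) -> np.ndarray:
    """Map ROI intensities to 1-based integer gray levels.

    FIXED_BIN_SIZE bins are anchored at multiples of the width; the minimum
    in-ROI value always lands in level 1. FIXED_BIN_COUNT spans
    [cohort_min, cohort_max] with the top edge inclusive; out-of-range
    values are clamped with a logged warning. Voxels outside the ROI are 0.
    """
    mask = as_bool_mask(roi)
    vals = np.asarray(img.values, dtype=np.float64)
    if mask.shape != vals.shape:
        raise ValueError("image and ROI must share a grid")
    if not mask.any():
        raise ValueError("empty ROI")
    out = np.zeros(vals.shape, dtype=np.int64)
    v = vals[mask]
    if scheme.mode is DiscretizationMode.FIXED_BIN_SIZE:
        w = float(scheme.bin_width)
        levels = np.floor(v / w).astype(np.int64) - int(np.floor(v.min() / w)) + 1
    else:
        lo, hi, n = scheme.cohort_min, scheme.cohort_max, scheme.n_bins
        if v.min() < lo or v.max() > hi:
            logger.warning(
                "values outside the cohort range [%g, %g] clamped during "
                "fixed-bin-count discretization", lo, hi)
        width = (hi - lo) / n
        levels = np.floor((v - lo) / width).astype(np.int64) + 1
        levels = np.clip(levels, 1, n)  # top edge inclusive: v == hi -> n
    out[mask] = levels
    return out
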