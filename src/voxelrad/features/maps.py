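"""Sliding-window feature maps, ROI mean aggregation and grid resampling.

For each ROI voxel v, the features are computed over the cubic window
centred on v intersected with the ROI (masked extraction, the default),
and assigned to v in the resulting maps. Averaging any map over the ROI
reproduces the scalar ROI feature that the risk models consume — this
linear aggregation is what later makes the decision-map backprojection
probability-preserving.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .catalog import FeatureCatalog, DEFAULT_CATALOG
from .region import region_features
from ..image import ImageVolume, as_bool_mask


@dataclass
class FeatureMapSet:
    """Voxel-indexed feature values for one patient/modality.

    ``maps`` holds one 3D array per catalog feature, finite on ROI voxels
    and NaN elsewhere (feature values are undefined outside the ROI).
    """

    patient_id: str
    modality: str
    maps: dict
    roi: np.ndarray
    window: int
    spacing_mm: tuple
    origin_mm: tuple = (0.0, 0.0, 0.0)
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.maps)

    def stack(self, names=None) -> np.ndarray:
        names = list(self.maps) if names is None else names
        return np.stack([self.maps[n] for n in names])


def extract_feature_maps(discrete: np.ndarray, raw_img: ImageVolume, roi,
                         window: int = 9,
                         catalog: FeatureCatalog = DEFAULT_CATALOG,
                         masked: bool = True,
                         patient_id: str = "", modality: str = "",
                         ) -> FeatureMapSet:
    """Compute the voxel-wise feature maps of one modality.

    Parameters
    ----------
    discrete
        Integer gray-level volume (1-based inside the ROI), same grid as
        ``raw_img`` — texture families and histogram first-order features
        use these.
    raw_img
        The intensity volume; first-order intensity statistics use raw
        values.
    window
        Odd cubic window edge length in voxels (default 9).
    masked
        If True (default), only in-ROI voxels inside the window contribute;
        if False the full window is used, which requires gray levels and
        intensities to be defined outside the ROI as well.

    Windows holding fewer than 2 contributing voxels cannot support texture
    matrices; such voxels receive the values of the nearest computable ROI
    voxel so that every ROI voxel carries a finite value in every map.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    mask = as_bool_mask(roi)
    vals = np.asarray(raw_img.values, dtype=np.float64)
    disc = np.asarray(discrete, dtype=np.int64)
    if not (mask.shape == vals.shape == disc.shape):
        raise ValueError("discrete, raw and ROI grids must match")
    if not mask.any():
        raise ValueError("empty ROI")

    half = window // 2
    vox_vol = raw_img.voxel_volume_mm3
    nf = len(catalog)
    shape = mask.shape
    out = np.full((nf,) + shape, np.nan, dtype=np.float64)

    roi_idx = np.argwhere(mask)
    computed = []
    pending = []
    for (i, j, k) in roi_idx:
        sl = (slice(max(i - half, 0), min(i + half + 1, shape[0])),
              slice(max(j - half, 0), min(j + half + 1, shape[1])),
              slice(max(k - half, 0), min(k + half + 1, shape[2])))
        wmask = mask[sl] if masked else np.ones_like(mask[sl])
        if wmask.sum() < 2:
            pending.append((i, j, k))
            continue
        out[:, i, j, k] = region_features(disc[sl], wmask, vals[sl],
                                          vox_vol, catalog)
        computed.append((i, j, k))

    if pending:
        if not computed:
            raise ValueError("no window holds >= 2 in-ROI voxels")
        tree = cKDTree(np.asarray(computed, dtype=float))
        _, nearest = tree.query(np.asarray(pending, dtype=float))
        comp = np.asarray(computed)
        for (i, j, k), src in zip(pending, comp[nearest]):
            out[:, i, j, k] = out[:, src[0], src[1], src[2]]

    maps = {name: out[p] for p, name in enumerate(catalog.names)}
    return FeatureMapSet(patient_id, modality, maps, mask, window,
                         tuple(raw_img.spacing_mm), tuple(raw_img.origin_mm),
                         meta={"masked": masked})


def aggregate_mean(mapset: FeatureMapSet, roi=None) -> dict:
    """ROI mean of every map: g_p = (1/N_v) * sum_v x_p(v)."""
    mask = mapset.roi if roi is None else as_bool_mask(roi)
    if not mask.any():
        raise ValueError("empty ROI")
    out = {}
    for name, arr in mapset.maps.items():
        vals = arr[mask]
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"map {name!r} has non-finite values inside the ROI")
        out[name] = float(vals.mean())
    return out


@dataclass
class ROIFeatureVector:
    """Per-patient aggregated features: modality-prefixed mappable means
    plus the non-mappable shape features."""

    patient_id: str
    mappable: dict
    nonmappable: dict
    n_roi_voxels: int

    def as_series(self):
        import pandas as pd
        return pd.Series({**self.mappable, **self.nonmappable},
                         name=self.patient_id)

    def __len__(self) -> int:
        return len(self.mappable) + len(self.nonmappable)


def roi_feature_vector(mapsets: list, shape_feats: dict,
                       patient_id: str = "") -> ROIFeatureVector:
    """Concatenate the aggregated maps of several modalities with the
    mask-derived features into one patient vector."""
    mappable = {}
    n_vox = 0
    for ms in mapsets:
        means = aggregate_mean(ms)
        mappable.update({f"{ms.modality}_{k}": v for k, v in means.items()})
        n_vox = max(n_vox, int(ms.roi.sum()))
    return ROIFeatureVector(patient_id or (mapsets[0].patient_id if mapsets
                                           else ""),
                            mappable, dict(shape_feats), n_vox)


def resample_maps_common_grid(mapsets: list, spacing: float = 1.0) -> list:
    """Resample feature maps onto a common isotropic grid.

    Maps are extended outside the ROI with nearest in-ROI values before the
    order-3 B-spline interpolation (splines cannot traverse NaNs), then
    re-masked by the nearest-neighbour-resampled ROI; values outside the
    resampled ROI remain NaN.
    """
    from ..preprocess import resample_isotropic

    out = []
    for ms in mapsets:
        roi_img = ImageVolume(ms.roi.astype(np.uint8), ms.spacing_mm,
                              ms.origin_mm)
        roi_rs = resample_isotropic(roi_img, spacing, is_mask=True)
        new_roi = roi_rs.values.astype(bool)
        filled_idx = ndimage.distance_transform_edt(
            ~ms.roi, sampling=ms.spacing_mm, return_distances=False,
            return_indices=True)
        new_maps = {}
        for name, arr in ms.maps.items():
            filled = arr[tuple(filled_idx)]
            img = ImageVolume(filled, ms.spacing_mm, ms.origin_mm)
            rs = resample_isotropic(img, spacing).values
            rs[~new_roi] = np.nan
            new_maps[name] = rs
        out.append(FeatureMapSet(ms.patient_id, ms.modality, new_maps,
                                 new_roi, ms.window,
                                 (spacing,) * 3, ms.origin_mm,
                                 meta=dict(ms.meta)))
    return out
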