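"""Radiomic Decision Maps: backprojection of logistic coefficients.

For a linear decision function D(G) = beta^T z(G) + beta'^T z(G') + beta0
over ROI-averaged features, replacing each standardized aggregated feature
z_p by its standardized voxel map z_p(v) = (x_p(v) - mu_Gp) / sigma_Gp
yields a per-voxel decision value

    DV(v) = sum_p beta_p z_p(v) + beta0 .

Because the aggregation is a mean and D is linear, the ROI mean of DV plus
the non-mappable offset beta'^T z(G') passes through the logistic to the
exact model probability — the map is probability-preserving, not a post hoc
saliency estimate. The identity is exact on the native extraction grid;
resampling maps to a common display grid introduces a bounded residual that
is recorded on the exported map.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .features.maps import FeatureMapSet
from .image import ImageVolume, as_bool_mask
from .modeling import LogisticModelSpec


@dataclass
class FeatureNormalizer:
    """Cohort mean/SD (population) per selected feature — the statistics
    used both to standardize the model inputs and the feature maps."""

    stats: dict  # feature -> (mu_G, sigma_G)

    def __post_init__(self):
        for name, (_, sd) in self.stats.items():
            if not sd > 0:
                raise ValueError(f"zero cohort SD for feature {name!r}")

    @classmethod
    def from_model_spec(cls, spec: LogisticModelSpec) -> "FeatureNormalizer":
        return cls({n: spec.scaling[n] for n in spec.feature_names})


def fit_normalizer(cohort: pd.DataFrame, selected) -> FeatureNormalizer:
    """Cohort-level mean/SD of each selected aggregated feature."""
    stats = {}
    for name in selected:
        col = cohort[name].to_numpy(dtype=np.float64)
        stats[name] = (float(col.mean()), float(col.std()))
    return FeatureNormalizer(stats)


def split_feature_name(name: str) -> tuple[str, str]:
    """'PET_glcm_Contrast' -> ('PET', 'glcm_Contrast')."""
    mod, _, feat = name.partition("_")
    return mod, feat


def normalize_maps(mapset: FeatureMapSet, normalizer: FeatureNormalizer
                   ) -> FeatureMapSet:
    """Standardize the maps of one modality with cohort statistics.

    Output maps are keyed by the full modality-prefixed feature name; only
    features belonging to this mapset's modality are produced. The ROI mean
    of each output map equals the patient's z-scored aggregated feature
    (linearity of the mean). Applying the normalizer twice is not
    idempotent — it must run exactly once on raw maps.
    """
    out = {}
    for name, (mu, sd) in normalizer.stats.items():
        mod, feat = split_feature_name(name)
        if mod != mapset.modality:
            continue
        if feat not in mapset.maps:
            raise KeyError(f"feature {feat!r} missing from mapset "
                           f"{mapset.modality}")
        out[name] = (mapset.maps[feat] - mu) / sd
    return FeatureMapSet(mapset.patient_id, mapset.modality, out, mapset.roi,
                         mapset.window, mapset.spacing_mm, mapset.origin_mm,
                         meta={**mapset.meta, "normalized": True})


@dataclass
class DecisionMap:
    """Per-voxel decision values DV(v) on the ROI (NaN outside)."""

    patient_id: str
    values: np.ndarray
    roi: np.ndarray
    spacing_mm: tuple
    mean_dv: float
    nonmappable_offset: float
    model_id: str = ""
    resampling_residual: float = 0.0
    meta: dict = field(default_factory=dict)

    @property
    def probability(self) -> float:
        return probability_from_map(self)

    def to_nifti(self, path, sidecar: bool = True) -> None:
        img = ImageVolume(np.where(self.roi, self.values, np.nan),
                          self.spacing_mm)
        img.to_nifti(path)
        if sidecar:
            side = Path(str(path)).with_suffix("").with_suffix("")
            meta = {
                "patient_id": self.patient_id, "model_id": self.model_id,
                "mean_dv": self.mean_dv,
                "nonmappable_offset": self.nonmappable_offset,
                "probability": self.probability,
                "resampling_residual": self.resampling_residual,
            }
            Path(f"{side}.json").write_text(json.dumps(meta, indent=2))


def backproject(model: LogisticModelSpec, zmaps: dict, roi,
                g_prime: dict | None = None, patient_id: str = "",
                spacing_mm=(1.0, 1.0, 1.0), model_id: str = "") -> DecisionMap:
    """Build the decision map DV(v) = beta^T z(v) + beta0 on the ROI.

    Parameters
    ----------
    zmaps
        Cohort-standardized maps keyed by the model's mappable feature
        names (all on one grid).
    g_prime
        Raw (unstandardized) values of the non-mappable features; they are
        z-scored with the model's own scaling to form the constant offset
        beta'^T z(G').
    """
    mask = as_bool_mask(roi)
    missing = set(model.beta) - set(zmaps)
    extra = set(zmaps) - set(model.beta)
    if missing or extra:
        raise KeyError(f"feature maps do not match the model: missing="
                       f"{sorted(missing)}, unexpected={sorted(extra)}")
    dv = np.full(mask.shape, float(model.beta0))
    for name, b in model.beta.items():
        arr = zmaps[name]
        if arr.shape != mask.shape:
            raise ValueError(f"map {name!r} grid does not match the ROI")
        dv = dv + b * arr
    offset = 0.0
    g_prime = g_prime or {}
    for name, b in model.beta_prime.items():
        if name not in g_prime:
            raise KeyError(f"non-mappable feature {name!r} value missing")
        mu, sd = model.scaling[name]
        offset += b * (float(g_prime[name]) - mu) / sd
    vals = np.where(mask, dv, np.nan)
    mean_dv = float(dv[mask].mean()) if mask.any() else float("nan")
    return DecisionMap(patient_id, vals, mask, tuple(spacing_mm), mean_dv,
                       float(offset), model_id)


def probability_from_map(dmap: DecisionMap) -> float:
    """P = logistic(mean ROI decision value + non-mappable offset); equals
    the tabular model's predicted probability on the native grid."""
    s = dmap.mean_dv + dmap.nonmappable_offset
    if not np.isfinite(s):
        raise ValueError("non-finite decision value")
    return float(1.0 / (1.0 + np.exp(-s)))


def decision_map_for_patient(model: LogisticModelSpec, mapsets: list,
                             g_prime: dict | None = None,
                             patient_id: str = "",
                             model_id: str = "",
                             tabular_decision: float | None = None
                             ) -> DecisionMap:
    """Normalize raw per-modality mapsets with the model's cohort scaling
    and backproject; all mapsets must share one grid and ROI.

    If ``tabular_decision`` (the model's decision value from aggregated
    features) is given, the map records the aggregation residual
    |mean DV + offset - D| — zero on the native extraction grid, bounded
    but nonzero after common-grid resampling.
    """
    normalizer = FeatureNormalizer.from_model_spec(model)
    zmaps = {}
    roi = None
    spacing = None
    for ms in mapsets:
        norm = normalize_maps(ms, normalizer)
        zmaps.update(norm.maps)
        if roi is None:
            roi, spacing = ms.roi, ms.spacing_mm
        elif ms.roi.shape != roi.shape or not np.array_equal(ms.roi, roi):
            raise ValueError("mapsets must share a grid and ROI; resample "
                             "to a common grid first")
    zmaps = {k: v for k, v in zmaps.items() if k in model.beta}
    dmap = backproject(model, zmaps, roi, g_prime, patient_id, spacing,
                       model_id)
    if tabular_decision is not None:
        dmap.resampling_residual = abs(
            dmap.mean_dv + dmap.nonmappable_offset - float(tabular_decision))
    return dmap
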