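"""Simple threshold-based surrogate features and model distillation.

The surrogate feature set describes necrosis development inside the tumor
with directly interpretable sub-volumes: the absolute volume V (ml) and the
relative volume rV = V / ATV of the ROI parts that are metabolically
inactive (PET < 40% SUVmax), hypodense (CT < 20 or < 30 HU), or a union /
intersection of the two patterns; plus the conventional biomarkers and
log10 transforms of everything (volumes floored at 0.01 ml, ratios at 1e-3,
to keep the logs finite).

``distill`` trains a student logistic model on these features with a
teacher model's predictions as the target, running the same selection /
grid-search / bagging pipeline, and reports the probability agreement.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .image import ImageVolume, as_bool_mask
from .modeling import CVConfig, bag, conventional_biomarkers, grid_search

VOLUME_FLOOR_ML = 0.01
RATIO_FLOOR = 1e-3

#: names of the sub-volume defining conditions
CONDITIONS = (
    "INACTIVE_FDG", "HYPODENSE_20HU", "HYPODENSE_30HU",
    "HYPODENSE_20HU_U_INACTIVE_FDG", "HYPODENSE_30HU_U_INACTIVE_FDG",
    "HYPODENSE_20HU_I_INACTIVE_FDG", "HYPODENSE_30HU_I_INACTIVE_FDG",
)


def surrogate_features(pet: ImageVolume, ct: ImageVolume, roi,
                       inactive_fraction: float = 0.4,
                       shape_feats: dict | None = None) -> dict:
    """Sub-volume features of one patient; PET, CT and ROI share a grid."""
    mask = as_bool_mask(roi)
    if not mask.any():
        raise ValueError("empty ROI")
    suv = np.asarray(pet.values, dtype=np.float64)
    hu = np.asarray(ct.values, dtype=np.float64)
    if not (suv.shape == hu.shape == mask.shape):
        raise ValueError("PET, CT and ROI must share a grid")
    vox_ml = pet.voxel_volume_mm3 / 1000.0
    atv_ml = float(mask.sum()) * vox_ml

    suvmax = float(suv[mask].max())
    inactive = mask & (suv < inactive_fraction * suvmax)
    hypo20 = mask & (hu < 20.0)
    hypo30 = mask & (hu < 30.0)
    subsets = {
        "INACTIVE_FDG": inactive,
        "HYPODENSE_20HU": hypo20,
        "HYPODENSE_30HU": hypo30,
        "HYPODENSE_20HU_U_INACTIVE_FDG": hypo20 | inactive,
        "HYPODENSE_30HU_U_INACTIVE_FDG": hypo30 | inactive,
        "HYPODENSE_20HU_I_INACTIVE_FDG": hypo20 & inactive,
        "HYPODENSE_30HU_I_INACTIVE_FDG": hypo30 & inactive,
    }
    out = dict(conventional_biomarkers(pet, roi, inactive_fraction))
    for name, sub in subsets.items():
        v = float(sub.sum()) * vox_ml
        out[f"V_{name}"] = v
        out[f"rV_{name}"] = v / atv_ml
    if shape_feats:
        out.update(shape_feats)
    # log10 of everything, with floors keeping the transform finite
    logs = {}
    for k, v in out.items():
        floor = VOLUME_FLOOR_ML if (k.startswith("V_") or k in
                                    ("ATV", "MTV", "TLG")) else RATIO_FLOOR
        logs[f"log10_{k}"] = float(np.log10(max(v, floor)))
    out.update(logs)
    return out


def surrogate_table(cases: list, shape_by_case: dict | None = None
                    ) -> pd.DataFrame:
    """Surrogate features for a phantom cohort (one row per case)."""
    from .image import Modality
    rows = {}
    for case in cases:
        sf = (shape_by_case or {}).get(case.case_id)
        rows[case.case_id] = surrogate_features(
            case.images[Modality.PET], case.images[Modality.CT], case.roi,
            shape_feats=sf)
    return pd.DataFrame.from_dict(rows, orient="index")


def distill(teacher_probs, surrogate_df: pd.DataFrame, cv: CVConfig,
            grid_C=None, n_boot: int = 1000, seed: int = 0,
            binarize: bool = True, reduce: bool = True,
            max_k: int | None = 4):
    """Distil a teacher model into a surrogate-feature student.

    The teacher's probabilities are binarized at 0.5 to form the training
    target (set ``binarize=False`` to round-trip continuous targets through
    the same thresholding explicitly); the identical selection pipeline then
    runs on the surrogate set. Returns (BaggedModel, agreement dict) where
    agreement holds the Pearson correlation and the per-patient
    probabilities of student and teacher.
    """
    p_teacher = np.asarray(teacher_probs, dtype=np.float64)
    y_star = (p_teacher >= 0.5).astype(int)
    if np.unique(y_star).size < 2:
        raise ValueError("teacher predictions all fall on one side of 0.5; "
                         "no distillation target")
    df = surrogate_df
    if reduce:
        from .collinearity import CollinearityReducer
        red = CollinearityReducer().fit(df)
        df = red.transform(df)
    gs = grid_search(df, y_star, df.columns, cv, grid_C, max_k)
    student = bag(df, y_star, list(gs.selected_subset), gs.selected_C,
                  n_boot=n_boot, seed=seed)
    p_student = student.predict_proba(df)
    agreement = {
        "pearson_r": float(np.corrcoef(p_student, p_teacher)[0, 1]),
        "teacher_probs": p_teacher,
        "student_probs": p_student,
        "selected": list(gs.selected_subset),
    }
    return student, agreement
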