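import numpy as np
import pandas as pd
import pytest

from voxelrad import Modality, PhantomParams, generate_case, generate_cohort
from voxelrad.features import (extract_feature_maps, roi_feature_vector,
                               shape_features)
from voxelrad.preprocess import (DiscretizationMode, DiscretizationScheme,
                                 discretize)

PET_SCHEME = DiscretizationScheme(DiscretizationMode.FIXED_BIN_SIZE,
                                  bin_width=0.3125)


@pytest.fixture(scope="session")
def small_params() -> PhantomParams:
    """Compact phantom conditions used throughout the suite: 24^3 grid at
    2.5 mm (~270 tumor voxels) keeps sliding-window extraction fast."""
    return PhantomParams(grid_shape=(24, 24, 24), spacing_mm=(2.5,) * 3,
                         tumor_radius_mm=12.0)


@pytest.fixture(scope="session")
def noise_free_params(small_params) -> PhantomParams:
    import dataclasses
    return dataclasses.replace(
        small_params,
        noise_sd_by_modality={m: 0.0 for m in Modality},
    )


@pytest.fixture(scope="session")
def pet_case(small_params):
    return generate_case(small_params, label=1, seed=7)


def extract_pet(case, window=9):
    pet = case.images[Modality.PET]
    disc = discretize(pet, case.roi, PET_SCHEME)
    return extract_feature_maps(disc, pet, case.roi, window=window,
                                patient_id=case.case_id, modality="PET")


@pytest.fixture(scope="session")
def separable_cohort():
    """50 phantoms with strong class separation in both generator effects
    (necrotic fraction and peak uptake) and modest noise."""
    params = PhantomParams(
        grid_shape=(24, 24, 24), spacing_mm=(2.5,) * 3, tumor_radius_mm=12.0,
        necrotic_fraction_mean_by_class=(0.05, 0.45),
        necrotic_fraction_sd=0.04,
        suvmax_mean_by_class=(4.0, 12.0), suvmax_sd=1.0,
        noise_sd_by_modality={Modality.PET: 0.15, Modality.CT: 6.0,
                              Modality.T1: 8.0, Modality.T2FS: 8.0},
    )
    return generate_cohort(50, 19 / 51, params, seed=11)


@pytest.fixture(scope="session")
def cohort_features(separable_cohort):
    """PET feature maps aggregated to a cohort table (plus shape features);
    raw mapsets kept for the first 20 cases for decision-map checks."""
    rows = []
    mapsets = {}
    shapes = {}
    for i, case in enumerate(separable_cohort):
        ms = extract_pet(case)
        sf = shape_features(case.roi, case.roi.spacing_mm)
        vec = roi_feature_vector([ms], sf, case.case_id)
        rows.append(vec.as_series())
        shapes[case.case_id] = sf
        if i < 20:
            mapsets[case.case_id] = ms
    df = pd.DataFrame(rows)
    labels = pd.Series({c.case_id: c.label for c in separable_cohort})
    return {"df": df, "labels": labels, "mapsets": mapsets, "shapes": shapes,
            "cases": separable_cohort}
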