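"""Synthetic multimodal tumor phantoms.

Each phantom emulates, on a co-registered grid, the multimodal appearance of
a soft-tissue tumor with two sub-regional patterns known to carry prognostic
signal: a central necrotic core (cold on FDG-PET, hypodense on CT, dark on
T1, bright on fat-suppressed T2) and a metabolically hot viable rim. Binary
outcome classes differ in the distributions of two truths: the necrotic
volume fraction and the peak uptake (SUVmax), with class 1 (event) drawn
from larger means of both. The generator also plants small fat spheres in
the T1 background so fat-reference intensity normalization can be exercised
end to end.

Geometry is an axis-aligned ellipsoid with configurable anisotropy so that
shape descriptors (elongation, sphericity) vary across the defaults rather
than sitting at their spherical fixed points. All randomness flows through a
single integer seed; identical (params, label, seed) yields bit-identical
volumes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .image import ImageVolume, Modality, Units

# Nominal tissue intensities per modality: (background, rim, necrotic core).
# CT values put the core inside the hypodense [0, 20] HU band and the rim in
# [40, 80] HU, so threshold-based surrogate sub-volumes can be validated
# against the generator's truth. PET rim uptake is replaced per-case by the
# drawn SUVmax; the core stays at a fixed low uptake.
TISSUE_INTENSITY = {
    Modality.PET: {"background": 0.5, "rim": None, "core": 1.0},
    Modality.CT: {"background": 45.0, "rim": 60.0, "core": 10.0},
    Modality.T1: {"background": 100.0, "rim": 150.0, "core": 60.0},
    Modality.T2FS: {"background": 40.0, "rim": 120.0, "core": 250.0},
}

FAT_MEAN_T1 = 300.0
FAT_SD_T1 = 30.0  # fixed intensity texture inside fat spheres
FAT_SPHERE_VOLUME_MM3 = 240.0
N_FAT_SPHERES = 20

_UNITS = {
    Modality.PET: Units.SUV,
    Modality.CT: Units.HU,
    Modality.T1: Units.ARBITRARY,
    Modality.T2FS: Units.ARBITRARY,
}


@dataclass
class PhantomParams:
    """Study conditions for the phantom generator.

    ``necrotic_fraction_mean_by_class`` and ``suvmax_mean_by_class`` are
    (class 0, class 1) pairs; class 1 must have the larger necrotic mean
    (the generator's stated effect direction).
    """

    grid_shape: tuple[int, int, int] = (40, 40, 40)
    spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    tumor_radius_mm: float = 18.0
    tumor_radius_sd_mm: float = 1.5
    axis_ratios: tuple[float, float, float] = (1.0, 0.85, 0.7)
    necrotic_fraction_mean_by_class: tuple[float, float] = (0.10, 0.35)
    necrotic_fraction_sd: float = 0.06
    suvmax_mean_by_class: tuple[float, float] = (5.0, 9.0)
    suvmax_sd: float = 1.2
    noise_sd_by_modality: dict = field(default_factory=lambda: {
        Modality.PET: 0.2, Modality.CT: 8.0, Modality.T1: 10.0, Modality.T2FS: 10.0,
    })
    seed: int = 0

    def __post_init__(self) -> None:
        f0, f1 = self.necrotic_fraction_mean_by_class
        if not (0.0 <= f0 <= 1.0 and 0.0 <= f1 <= 1.0):
            raise ValueError("necrotic fraction means must lie in [0, 1]")
        if f1 < f0:
            raise ValueError("class-1 necrotic fraction mean must be >= class-0 mean")
        if self.tumor_radius_mm <= 0:
            raise ValueError("tumor radius must be positive")
        if any(s <= 0 for s in self.suvmax_mean_by_class):
            raise ValueError("SUVmax means must be positive")
        if any(r <= 0 for r in self.axis_ratios):
            raise ValueError("axis ratios must be positive")


@dataclass
class MultimodalCase:
    """One phantom patient: four modality volumes, ROI, fat masks, label, truth."""

    case_id: str
    images: dict
    roi: ImageVolume
    fat_masks: list
    label: int
    truth: dict

    @property
    def fat_mask_union(self) -> np.ndarray:
        out = np.zeros(self.roi.shape, dtype=bool)
        for m in self.fat_masks:
            out |= m.values.astype(bool)
        return out


def _grid_coords(params: PhantomParams) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    axes = []
    for n, sp in zip(params.grid_shape, params.spacing_mm):
        c = (np.arange(n) - (n - 1) / 2.0) * sp
        axes.append(c)
    return np.meshgrid(*axes, indexing="ij")


def generate_case(params: PhantomParams, label: int, seed: int,
                  case_id: str | None = None) -> MultimodalCase:
    """Generate one multimodal phantom case.

    Raises
    ------
    ValueError
        If the tumor ellipsoid does not fit inside the field of view.
    """
    if label not in (0, 1):
        raise ValueError("label must be 0 or 1")
    semi = np.asarray(params.axis_ratios) * params.tumor_radius_mm
    extent = np.asarray(params.grid_shape) * np.asarray(params.spacing_mm)
    if np.any(2 * semi + 2 * np.asarray(params.spacing_mm) > extent):
        raise ValueError(
            f"tumor semi-axes {tuple(semi)} mm do not fit inside the "
            f"field of view {tuple(extent)} mm; enlarge grid_shape or "
            "shrink tumor_radius_mm"
        )

    rng = np.random.default_rng(seed)
    xx, yy, zz = _grid_coords(params)

    # per-case size variability, clipped so the tumor always fits
    if params.tumor_radius_sd_mm > 0:
        r_max = float(np.min((extent / 2 - np.asarray(params.spacing_mm))
                             / np.asarray(params.axis_ratios)))
        radius = float(np.clip(
            rng.normal(params.tumor_radius_mm, params.tumor_radius_sd_mm),
            0.35 * params.tumor_radius_mm, r_max))
        semi = np.asarray(params.axis_ratios) * radius

    frac_mean = params.necrotic_fraction_mean_by_class[label]
    frac = float(np.clip(rng.normal(frac_mean, params.necrotic_fraction_sd), 0.0, 0.85))
    suv_mean = params.suvmax_mean_by_class[label]
    suvmax = float(max(rng.normal(suv_mean, params.suvmax_sd), 1.5))

    r2 = (xx / semi[0]) ** 2 + (yy / semi[1]) ** 2 + (zz / semi[2]) ** 2
    tumor = r2 <= 1.0
    if frac > 0:
        s = frac ** (1.0 / 3.0)
        core = (xx / (s * semi[0])) ** 2 + (yy / (s * semi[1])) ** 2 \
            + (zz / (s * semi[2])) ** 2 <= 1.0
        core &= tumor
    else:
        core = np.zeros_like(tumor)
    rim = tumor & ~core

    n_tumor = int(tumor.sum())
    measured_frac = float(core.sum()) / n_tumor

    fat_union, fat_masks_arr = _place_fat_spheres(params, tumor, rng, semi)

    images = {}
    for mod in (Modality.PET, Modality.CT, Modality.T1, Modality.T2FS):
        levels = TISSUE_INTENSITY[mod]
        rim_value = suvmax if mod is Modality.PET else levels["rim"]
        vol = np.full(params.grid_shape, levels["background"], dtype=np.float64)
        vol[rim] = rim_value
        vol[core] = levels["core"]
        if mod is Modality.T1:
            vol[fat_union] = rng.normal(FAT_MEAN_T1, FAT_SD_T1, int(fat_union.sum()))
        sd = float(params.noise_sd_by_modality.get(mod, 0.0))
        if sd > 0:
            vol = vol + rng.normal(0.0, sd, vol.shape)
        images[mod] = ImageVolume(vol, params.spacing_mm, modality=mod,
                                  units=_UNITS[mod])

    roi = ImageVolume(tumor.astype(np.uint8), params.spacing_mm)
    fat_masks = [ImageVolume(m.astype(np.uint8), params.spacing_mm)
                 for m in fat_masks_arr]
    truth = {
        "necrotic_fraction": measured_frac,
        "necrotic_fraction_drawn": frac,
        "suvmax": suvmax,
        "tumor_radius_mm": float(semi[0] / params.axis_ratios[0]),
        "n_tumor_voxels": n_tumor,
    }
    return MultimodalCase(case_id or f"case_{seed}", images, roi, fat_masks,
                          int(label), truth)


def _place_fat_spheres(params: PhantomParams, tumor: np.ndarray,
                       rng: np.random.Generator, semi: np.ndarray):
    """Rejection-sample ~20 non-tumor fat spheres of ~240 mm^3 in the T1 frame."""
    xx, yy, zz = _grid_coords(params)
    extent = np.asarray(params.grid_shape) * np.asarray(params.spacing_mm)
    r_fat = (3.0 * FAT_SPHERE_VOLUME_MM3 / (4.0 * np.pi)) ** (1.0 / 3.0)
    fat_union = np.zeros(params.grid_shape, dtype=bool)
    masks = []
    tries = 0
    while len(masks) < N_FAT_SPHERES and tries < 500:
        tries += 1
        c = rng.uniform(-extent / 2 + r_fat, extent / 2 - r_fat)
        # keep the sphere clear of the tumor ellipsoid
        if np.sum((c / (semi + r_fat)) ** 2) <= 1.0:
            continue
        sphere = (xx - c[0]) ** 2 + (yy - c[1]) ** 2 + (zz - c[2]) ** 2 <= r_fat ** 2
        sphere &= ~tumor
        if sphere.sum() < 2 or (sphere & fat_union).any():
            continue
        fat_union |= sphere
        masks.append(sphere)
    return fat_union, masks


def generate_cohort(n: int, prevalence: float, params: PhantomParams,
                    seed: int) -> list[MultimodalCase]:
    """Generate a labelled cohort; floor(n * prevalence) cases are class 1.

    Per-case seeds are derived deterministically from the cohort seed, so the
    cohort is reproducible and individual cases can be regenerated alone.
    """
    if not (0.0 < prevalence < 1.0):
        raise ValueError("prevalence must lie strictly between 0 and 1")
    if n < 4:
        raise ValueError("need n >= 4")
    n1 = int(np.floor(n * prevalence))
    n0 = n - n1
    if min(n0, n1) < 2:
        raise ValueError(
            f"class sizes ({n0}, {n1}) leave a class with <2 members; "
            "stratified cross-validation would be impossible"
        )
    rng = np.random.default_rng(seed)
    labels = rng.permutation(np.r_[np.ones(n1, dtype=int), np.zeros(n0, dtype=int)])
    case_seeds = rng.integers(0, 2**31 - 1, size=n)
    return [
        generate_case(params, int(lab), int(cs), case_id=f"case_{i:03d}")
        for i, (lab, cs) in enumerate(zip(labels, case_seeds))
    ]


def write_cohort(cases: list, outdir) -> Path:
    """Write NIfTI volumes and a manifest CSV; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for case in cases:
        row = {"case_id": case.case_id, "label": case.label, **case.truth}
        for mod, img in case.images.items():
            p = outdir / f"{case.case_id}_{mod.value}.nii.gz"
            img.to_nifti(p)
            row[f"path_{mod.value}"] = p.name
        p = outdir / f"{case.case_id}_roi.nii.gz"
        case.roi.to_nifti(p)
        row["path_roi"] = p.name
        for k, fm in enumerate(case.fat_masks):
            fm.to_nifti(outdir / f"{case.case_id}_fat{k:02d}.nii.gz")
        row["n_fat_masks"] = len(case.fat_masks)
        rows.append(row)
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
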