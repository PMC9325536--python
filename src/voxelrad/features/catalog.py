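"""Catalog of the engineered features computed per sliding window.

Five families over the discretized gray levels and the raw intensities:
18 first-order, 24 GLCM, 14 GLDM, 16 GLRLM and 5 NGTDM features — 77
voxel-mappable features per modality — plus 14 mask-derived shape/volume
descriptors that have no voxel-level counterpart.
"""

from __future__ import annotations

from dataclasses import dataclass, field

FIRSTORDER_NAMES = [
    "Energy", "TotalEnergy", "Entropy", "Minimum", "10Percentile",
    "90Percentile", "Maximum", "Mean", "Median", "InterquartileRange",
    "Range", "MeanAbsoluteDeviation", "RobustMeanAbsoluteDeviation",
    "RootMeanSquared", "Skewness", "Kurtosis", "Variance", "Uniformity",
]

GLCM_NAMES = [
    "Autocorrelation", "JointAverage", "ClusterProminence", "ClusterShade",
    "ClusterTendency", "Contrast", "Correlation", "DifferenceAverage",
    "DifferenceEntropy", "DifferenceVariance", "JointEnergy", "JointEntropy",
    "Imc1", "Imc2", "Idm", "Idmn", "Id", "Idn", "InverseVariance",
    "MaximumProbability", "SumAverage", "SumEntropy", "SumSquares", "MCC",
]

GLDM_NAMES = [
    "SmallDependenceEmphasis", "LargeDependenceEmphasis",
    "GrayLevelNonUniformity", "DependenceNonUniformity",
    "DependenceNonUniformityNormalized", "GrayLevelVariance",
    "DependenceVariance", "DependenceEntropy", "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis", "SmallDependenceLowGrayLevelEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
]

GLRLM_NAMES = [
    "ShortRunEmphasis", "LongRunEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "GrayLevelVariance",
    "RunVariance", "RunEntropy", "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis", "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
]

NGTDM_NAMES = ["Coarseness", "Contrast", "Busyness", "Complexity", "Strength"]

SHAPE_NAMES = [
    "MeshVolume", "VoxelVolume", "SurfaceArea", "SurfaceVolumeRatio",
    "Sphericity", "Maximum3DDiameter", "Maximum2DDiameterSlice",
    "Maximum2DDiameterColumn", "Maximum2DDiameterRow", "MajorAxisLength",
    "MinorAxisLength", "LeastAxisLength", "Elongation", "Flatness",
]

_FAMILY_NAMES = {
    "firstorder": FIRSTORDER_NAMES,
    "glcm": GLCM_NAMES,
    "gldm": GLDM_NAMES,
    "glrlm": GLRLM_NAMES,
    "ngtdm": NGTDM_NAMES,
}


@dataclass(frozen=True)
class FeatureCatalog:
    """The ordered set of voxel-mappable features (family-prefixed names)."""

    families: tuple = ("firstorder", "glcm", "gldm", "glrlm", "ngtdm")
    names: tuple = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        unknown = set(self.families) - set(_FAMILY_NAMES)
        if unknown:
            raise ValueError(f"unknown feature families: {sorted(unknown)}")
        names = tuple(f"{fam}_{n}" for fam in self.families
                      for n in _FAMILY_NAMES[fam])
        if len(set(names)) != len(names):
            raise ValueError("feature names must be unique")
        object.__setattr__(self, "names", names)

    def __len__(self) -> int:
        return len(self.names)


DEFAULT_CATALOG = FeatureCatalog()
assert len(DEFAULT_CATALOG) == 77
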