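"""Single-region feature engine: texture matrices and the 77-feature vector.

This module computes all voxel-mappable features for one voxel set (a whole
ROI or one sliding-window neighbourhood). Texture matrices follow the
standard engineered-radiomics definitions:

* GLCM — symmetric, distance 1, pair counts accumulated over the 13 unique
  3D directions into a single matrix, normalized after accumulation (no
  distance weighting).
* GLRLM — maximal same-level runs accumulated over the same 13 directions;
  out-of-mask voxels break runs.
* GLDM — dependence threshold alpha = 0 at Chebyshev distance 1; a voxel's
  dependence is 1 (itself) plus the number of in-mask neighbours with equal
  gray level.
* NGTDM — distance 1; a voxel contributes only if it has at least one
  in-mask neighbour.

Gray levels are the global discretized levels restricted to those present
in the voxel set (no per-window re-binning): levels absent from the set
contribute zero probability, so feature values are identical to computing
with the full global level axis.
"""

from __future__ import annotations

import numpy as np

from .catalog import (FIRSTORDER_NAMES, GLCM_NAMES, GLDM_NAMES, GLRLM_NAMES,
                      NGTDM_NAMES, FeatureCatalog, DEFAULT_CATALOG)

_EPS = np.spacing(1.0)

#: The 13 unique 3D direction offsets (half of the 26-neighbourhood).
OFFSETS_13 = np.array([
    (0, 0, 1), (0, 1, 0), (1, 0, 0),
    (0, 1, 1), (0, 1, -1), (1, 0, 1), (1, 0, -1), (1, 1, 0), (1, -1, 0),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
], dtype=int)

OFFSETS_26 = np.vstack([OFFSETS_13, -OFFSETS_13])


def _shift(arr: np.ndarray, off, fill=0) -> np.ndarray:
    """Return out with out[v] = arr[v + off], filling out-of-grid with `fill`."""
    out = np.full_like(arr, fill)
    src = []
    dst = []
    for n, o in zip(arr.shape, off):
        if o >= 0:
            src.append(slice(o, n))
            dst.append(slice(0, n - o))
        else:
            src.append(slice(0, n + o))
            dst.append(slice(-o, n))
    out[tuple(dst)] = arr[tuple(src)]
    return out


def texture_matrices(levels: np.ndarray, mask: np.ndarray) -> dict:
    """Build GLCM/GLDM/GLRLM/NGTDM raw matrices for one masked voxel set.

    Returns a dict with the matrices, the gray-level values indexing their
    rows, and the masked voxel count.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 2:
        raise ValueError("texture matrices need at least 2 masked voxels")
    levels = np.asarray(levels)
    vals = levels[mask]
    u = np.unique(vals)
    nu = u.size
    # compact index volume: -1 outside mask
    idx = np.full(levels.shape, -1, dtype=np.int64)
    idx[mask] = np.searchsorted(u, vals)

    # ---- GLCM ---------------------------------------------------------
    glcm = np.zeros((nu, nu), dtype=np.float64)
    for off in OFFSETS_13:
        nb_idx = _shift(idx, off, fill=-1)
        ok = (idx >= 0) & (nb_idx >= 0)
        if ok.any():
            a = idx[ok]
            b = nb_idx[ok]
            glcm += np.bincount(a * nu + b, minlength=nu * nu).reshape(nu, nu)
    glcm = glcm + glcm.T  # symmetric pairs

    # ---- GLDM (alpha=0, distance 1) ----------------------------------
    dep = np.zeros(levels.shape, dtype=np.int64)
    nbr_sum = np.zeros(levels.shape, dtype=np.float64)
    nbr_cnt = np.zeros(levels.shape, dtype=np.int64)
    lev_in = np.where(mask, levels, 0).astype(np.float64)
    for off in OFFSETS_26:
        nb_mask = _shift(mask, off, fill=False)
        dep += (nb_mask & (_shift(idx, off, fill=-1) == idx)).astype(np.int64)
        nbr_sum += _shift(lev_in, off, fill=0.0)
        nbr_cnt += nb_mask.astype(np.int64)
    dep = dep + 1  # the centre voxel counts itself
    dep_vals = dep[mask]
    kmax = int(dep_vals.max())
    gldm = np.zeros((nu, kmax), dtype=np.float64)
    np.add.at(gldm, (idx[mask], dep_vals - 1), 1.0)

    # ---- NGTDM --------------------------------------------------------
    valid = mask & (nbr_cnt > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        a_bar = np.where(nbr_cnt > 0, nbr_sum / np.maximum(nbr_cnt, 1), 0.0)
    diffs = np.abs(levels.astype(np.float64) - a_bar)
    s_i = np.bincount(idx[valid], weights=diffs[valid], minlength=nu)
    n_i = np.bincount(idx[valid], minlength=nu).astype(np.float64)

    # ---- GLRLM --------------------------------------------------------
    max_len = int(max(levels.shape)) * 2
    glrlm = np.zeros((nu, max_len), dtype=np.float64)
    for off in OFFSETS_13:
        cont = (idx >= 0) & (_shift(idx, off, fill=-1) == idx) & \
            (_shift(mask, off, fill=False))
        # run starts: in-mask voxels not continued from the previous voxel
        prev = _shift(cont, -off, fill=False)
        start = mask & ~prev
        # chain length at every voxel: 1 + longest continuation streak
        total = mask.astype(np.int64)
        c = cont.copy()
        m = 1
        while c.any():
            total += c
            c = c & _shift(cont, off * m)
            m += 1
        lens = total[start]
        lvls = idx[start]
        np.add.at(glrlm, (lvls, lens - 1), 1.0)
    glrlm = glrlm[:, :max(int(glrlm.sum(axis=0).nonzero()[0].max()) + 1, 1)]

    return {
        "levels": u.astype(np.float64),
        "n_voxels": int(mask.sum()),
        "glcm": glcm,
        "gldm": gldm,
        "glrlm": glrlm,
        "ngtdm_s": s_i,
        "ngtdm_n": n_i,
        "ngtdm_nvp": int(valid.sum()),
    }


# ----------------------------------------------------------------------
# feature formulas
# ----------------------------------------------------------------------

def firstorder_features(raw: np.ndarray, levels: np.ndarray,
                        voxel_volume_mm3: float) -> dict:
    """18 first-order features; intensity statistics use raw values,
    Entropy/Uniformity use the discretized histogram."""
    x = np.asarray(raw, dtype=np.float64).ravel()
    n = x.size
    counts = np.bincount(np.asarray(levels, dtype=np.int64).ravel())
    p = counts[counts > 0] / n
    mean = x.mean()
    m2 = ((x - mean) ** 2).mean()
    m3 = ((x - mean) ** 3).mean()
    m4 = ((x - mean) ** 4).mean()
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    sub = x[(x >= p10) & (x <= p90)]
    rmad = np.abs(sub - sub.mean()).mean() if sub.size else 0.0
    return {
        "Energy": float(np.sum(x ** 2)),
        "TotalEnergy": float(voxel_volume_mm3 * np.sum(x ** 2)),
        "Entropy": float(-np.sum(p * np.log2(p))),
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": float(mean),
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "RobustMeanAbsoluteDeviation": float(rmad),
        "RootMeanSquared": float(np.sqrt(np.mean(x ** 2))),
        "Skewness": float(m3 / m2 ** 1.5) if m2 > 0 else 0.0,
        "Kurtosis": float(m4 / m2 ** 2) if m2 > 0 else 0.0,
        "Variance": float(m2),
        "Uniformity": float(np.sum(p ** 2)),
    }


def glcm_features(glcm: np.ndarray, levels: np.ndarray) -> dict:
    P = glcm / glcm.sum() if glcm.sum() > 0 else glcm
    g = levels
    ng = g.size
    i = g[:, None]
    j = g[None, :]
    px = P.sum(axis=1)
    mu = float(np.sum(g * px))
    sig2 = float(np.sum((g - mu) ** 2 * px))
    sig = np.sqrt(sig2)

    # difference and sum distributions over |i-j| and i+j
    absdiff = np.abs(i - j)
    dvals = np.unique(absdiff)
    pdiff = np.array([P[absdiff == d].sum() for d in dvals])
    sums = i + j
    svals = np.unique(sums)
    psum = np.array([P[sums == s].sum() for s in svals])

    da = float(np.sum(dvals * pdiff))
    nz = P > 0
    hxy = float(-np.sum(P[nz] * np.log2(P[nz])))
    pxpy = px[:, None] * px[None, :]
    hxy1 = float(-np.sum(P * np.log2(pxpy + _EPS)))
    nzx = pxpy > 0
    hxy2 = float(-np.sum(pxpy[nzx] * np.log2(pxpy[nzx])))
    hx = float(-np.sum(px[px > 0] * np.log2(px[px > 0])))

    if ng > 1 and sig2 > 0:
        corr = float((np.sum(i * j * P) - mu * mu) / sig2)
    else:
        corr = 1.0
    imc1 = (hxy - hxy1) / hx if hx > 0 else 0.0
    imc2 = float(np.sqrt(max(1.0 - np.exp(-2.0 * (hxy2 - hxy)), 0.0)))

    if ng > 1:
        # Q(a,b) = sum_k P(a,k) P(b,k) / (px(a) py(k)); py = px by symmetry
        safe_px = np.where(px > 0, px, 1.0)
        q = (P / safe_px[:, None]) @ (P / safe_px[:, None])
        eig = np.sort(np.real(np.linalg.eigvals(q)))
        mcc = float(np.sqrt(max(eig[-2], 0.0)))
    else:
        mcc = 1.0

    offdiag = absdiff > 0
    return {
        "Autocorrelation": float(np.sum(i * j * P)),
        "JointAverage": mu,
        "ClusterProminence": float(np.sum((i + j - 2 * mu) ** 4 * P)),
        "ClusterShade": float(np.sum((i + j - 2 * mu) ** 3 * P)),
        "ClusterTendency": float(np.sum((i + j - 2 * mu) ** 2 * P)),
        "Contrast": float(np.sum((i - j) ** 2 * P)),
        "Correlation": corr,
        "DifferenceAverage": da,
        "DifferenceEntropy": float(-np.sum(pdiff[pdiff > 0]
                                           * np.log2(pdiff[pdiff > 0]))),
        "DifferenceVariance": float(np.sum((dvals - da) ** 2 * pdiff)),
        "JointEnergy": float(np.sum(P ** 2)),
        "JointEntropy": hxy,
        "Imc1": float(imc1),
        "Imc2": imc2,
        "Idm": float(np.sum(P / (1.0 + (i - j) ** 2))),
        "Idmn": float(np.sum(P / (1.0 + ((i - j) / ng) ** 2))),
        "Id": float(np.sum(P / (1.0 + absdiff))),
        "Idn": float(np.sum(P / (1.0 + absdiff / ng))),
        "InverseVariance": float(np.sum(P[offdiag] / absdiff[offdiag] ** 2)),
        "MaximumProbability": float(P.max()),
        "SumAverage": float(np.sum(svals * psum)),
        "SumEntropy": float(-np.sum(psum[psum > 0] * np.log2(psum[psum > 0]))),
        "SumSquares": sig2,
        "MCC": mcc,
    }


def gldm_features(gldm: np.ndarray, levels: np.ndarray) -> dict:
    nz_total = gldm.sum()
    i = levels[:, None]
    k = np.arange(1, gldm.shape[1] + 1, dtype=np.float64)[None, :]
    p = gldm / nz_total
    pg = p.sum(axis=1)
    pk = p.sum(axis=0)
    mu_g = np.sum(levels * pg)
    mu_k = np.sum(k.ravel() * pk)
    pnz = p[p > 0]
    return {
        "SmallDependenceEmphasis": float(np.sum(gldm / k ** 2) / nz_total),
        "LargeDependenceEmphasis": float(np.sum(gldm * k ** 2) / nz_total),
        "GrayLevelNonUniformity": float(np.sum(gldm.sum(axis=1) ** 2) / nz_total),
        "DependenceNonUniformity": float(np.sum(gldm.sum(axis=0) ** 2) / nz_total),
        "DependenceNonUniformityNormalized":
            float(np.sum(gldm.sum(axis=0) ** 2) / nz_total ** 2),
        "GrayLevelVariance": float(np.sum((levels - mu_g) ** 2 * pg)),
        "DependenceVariance": float(np.sum((k.ravel() - mu_k) ** 2 * pk)),
        "DependenceEntropy": float(-np.sum(pnz * np.log2(pnz))),
        "LowGrayLevelEmphasis": float(np.sum(gldm / i ** 2) / nz_total),
        "HighGrayLevelEmphasis": float(np.sum(gldm * i ** 2) / nz_total),
        "SmallDependenceLowGrayLevelEmphasis":
            float(np.sum(gldm / (i ** 2 * k ** 2)) / nz_total),
        "SmallDependenceHighGrayLevelEmphasis":
            float(np.sum(gldm * i ** 2 / k ** 2) / nz_total),
        "LargeDependenceLowGrayLevelEmphasis":
            float(np.sum(gldm * k ** 2 / i ** 2) / nz_total),
        "LargeDependenceHighGrayLevelEmphasis":
            float(np.sum(gldm * i ** 2 * k ** 2) / nz_total),
    }


def glrlm_features(glrlm: np.ndarray, levels: np.ndarray, n_voxels: int) -> dict:
    nr = glrlm.sum()
    i = levels[:, None]
    l = np.arange(1, glrlm.shape[1] + 1, dtype=np.float64)[None, :]
    p = glrlm / nr
    pg = p.sum(axis=1)
    pl = p.sum(axis=0)
    mu_g = np.sum(levels * pg)
    mu_l = np.sum(l.ravel() * pl)
    pnz = p[p > 0]
    return {
        "ShortRunEmphasis": float(np.sum(glrlm / l ** 2) / nr),
        "LongRunEmphasis": float(np.sum(glrlm * l ** 2) / nr),
        "GrayLevelNonUniformity": float(np.sum(glrlm.sum(axis=1) ** 2) / nr),
        "GrayLevelNonUniformityNormalized":
            float(np.sum(glrlm.sum(axis=1) ** 2) / nr ** 2),
        "RunLengthNonUniformity": float(np.sum(glrlm.sum(axis=0) ** 2) / nr),
        "RunLengthNonUniformityNormalized":
            float(np.sum(glrlm.sum(axis=0) ** 2) / nr ** 2),
        "RunPercentage": float(nr / (13.0 * n_voxels)),
        "GrayLevelVariance": float(np.sum((levels - mu_g) ** 2 * pg)),
        "RunVariance": float(np.sum((l.ravel() - mu_l) ** 2 * pl)),
        "RunEntropy": float(-np.sum(pnz * np.log2(pnz))),
        "LowGrayLevelRunEmphasis": float(np.sum(glrlm / i ** 2) / nr),
        "HighGrayLevelRunEmphasis": float(np.sum(glrlm * i ** 2) / nr),
        "ShortRunLowGrayLevelEmphasis":
            float(np.sum(glrlm / (i ** 2 * l ** 2)) / nr),
        "ShortRunHighGrayLevelEmphasis":
            float(np.sum(glrlm * i ** 2 / l ** 2) / nr),
        "LongRunLowGrayLevelEmphasis":
            float(np.sum(glrlm * l ** 2 / i ** 2) / nr),
        "LongRunHighGrayLevelEmphasis":
            float(np.sum(glrlm * i ** 2 * l ** 2) / nr),
    }


def ngtdm_features(s_i: np.ndarray, n_i: np.ndarray, levels: np.ndarray,
                   nvp: int) -> dict:
    present = n_i > 0
    s = s_i[present]
    n = n_i[present]
    g = levels[present]
    p = n / nvp if nvp > 0 else n
    ngp = int(present.sum())

    denom_coarse = float(np.sum(p * s))
    coarseness = 1.0 / denom_coarse if denom_coarse > 0 else 1e6

    if ngp > 1 and nvp > 0:
        gi = g[:, None]
        gj = g[None, :]
        pi = p[:, None]
        pj = p[None, :]
        contrast = float(np.sum(pi * pj * (gi - gj) ** 2)
                         / (ngp * (ngp - 1)) * np.sum(s) / nvp)
        denom_busy = float(np.sum(np.abs(gi * pi - gj * pj)))
        busyness = denom_coarse / denom_busy if denom_busy > 0 else 0.0
        num = np.abs(gi - gj) * (pi * s[:, None] + pj * s[None, :]) / (pi + pj)
        complexity = float(np.sum(num) / nvp)
        ssum = float(np.sum(s))
        strength = float(np.sum((pi + pj) * (gi - gj) ** 2)) / ssum \
            if ssum > 0 else 0.0
    else:
        contrast = busyness = complexity = strength = 0.0
    return {
        "Coarseness": coarseness,
        "Contrast": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }


def region_features(levels: np.ndarray, mask: np.ndarray, raw: np.ndarray,
                    voxel_volume_mm3: float = 1.0,
                    catalog: FeatureCatalog = DEFAULT_CATALOG) -> np.ndarray:
    """All catalog features for one masked voxel set, in catalog order."""
    mask = np.asarray(mask, dtype=bool)
    mats = texture_matrices(levels, mask)
    fam_values = {}
    if "firstorder" in catalog.families:
        fam_values["firstorder"] = firstorder_features(
            np.asarray(raw)[mask], np.asarray(levels)[mask], voxel_volume_mm3)
    if "glcm" in catalog.families:
        fam_values["glcm"] = glcm_features(mats["glcm"], mats["levels"])
    if "gldm" in catalog.families:
        fam_values["gldm"] = gldm_features(mats["gldm"], mats["levels"])
    if "glrlm" in catalog.families:
        fam_values["glrlm"] = glrlm_features(mats["glrlm"], mats["levels"],
                                             mats["n_voxels"])
    if "ngtdm" in catalog.families:
        fam_values["ngtdm"] = ngtdm_features(mats["ngtdm_s"], mats["ngtdm_n"],
                                             mats["levels"], mats["ngtdm_nvp"])
    out = np.empty(len(catalog), dtype=np.float64)
    for pos, name in enumerate(catalog.names):
        fam, feat = name.split("_", 1)
        out[pos] = fam_values[fam][feat]
    return out
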