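"""Brute-force single-region reference implementation used as an
independent oracle in tests.

Everything here is computed with explicit Python loops and dictionaries,
sharing no code path with the package's vectorized engine: texture
matrices are built by enumerating voxels and neighbour offsets one by one,
and features are evaluated by looping over matrix entries.
"""

from __future__ import annotations

import math
from collections import defaultdict

import numpy as np

DIRECTIONS = [
    (0, 0, 1), (0, 1, 0), (1, 0, 0),
    (0, 1, 1), (0, 1, -1), (1, 0, 1), (1, 0, -1), (1, 1, 0), (1, -1, 0),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
]
NEIGHBOURS_26 = [(dx, dy, dz)
                 for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
                 if (dx, dy, dz) != (0, 0, 0)]


def _inside(shape, v):
    return all(0 <= c < n for c, n in zip(v, shape))


def oracle_glcm(levels, mask):
    """Symmetric co-occurrence counts accumulated over the 13 directions."""
    shape = mask.shape
    counts = defaultdict(float)
    for v in zip(*np.nonzero(mask)):
        for d in DIRECTIONS:
            w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
            if _inside(shape, w) and mask[w]:
                a, b = int(levels[v]), int(levels[w])
                counts[(a, b)] += 1
                counts[(b, a)] += 1
    return dict(counts)


def oracle_glrlm(levels, mask):
    """Run counts {(level, length): n} accumulated over the 13 directions."""
    shape = mask.shape
    runs = defaultdict(float)
    for d in DIRECTIONS:
        for v in zip(*np.nonzero(mask)):
            prev = (v[0] - d[0], v[1] - d[1], v[2] - d[2])
            if _inside(shape, prev) and mask[prev] \
                    and levels[prev] == levels[v]:
                continue  # not a run start
            length = 1
            w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
            while _inside(shape, w) and mask[w] and levels[w] == levels[v]:
                length += 1
                w = (w[0] + d[0], w[1] + d[1], w[2] + d[2])
            runs[(int(levels[v]), length)] += 1
    return dict(runs)


def oracle_gldm(levels, mask, alpha=0):
    """Dependence counts {(level, k): n}; k includes the centre voxel."""
    shape = mask.shape
    out = defaultdict(float)
    for v in zip(*np.nonzero(mask)):
        k = 1
        for d in NEIGHBOURS_26:
            w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
            if _inside(shape, w) and mask[w] \
                    and abs(int(levels[w]) - int(levels[v])) <= alpha:
                k += 1
        out[(int(levels[v]), k)] += 1
    return dict(out)


def oracle_ngtdm(levels, mask):
    """Returns (s, n, nvp): per-level sums of |i - neighbour mean| and
    counts over voxels with at least one in-mask neighbour."""
    shape = mask.shape
    s = defaultdict(float)
    n = defaultdict(int)
    nvp = 0
    for v in zip(*np.nonzero(mask)):
        nb = []
        for d in NEIGHBOURS_26:
            w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
            if _inside(shape, w) and mask[w]:
                nb.append(int(levels[w]))
        if not nb:
            continue
        nvp += 1
        lev = int(levels[v])
        s[lev] += abs(lev - sum(nb) / len(nb))
        n[lev] += 1
    return dict(s), dict(n), nvp


# ----------------------------------------------------------------------
# feature formulas, evaluated entry by entry
# ----------------------------------------------------------------------

def _log2(x):
    return math.log2(x)


def oracle_firstorder(raw_vals, level_vals, voxel_volume):
    x = [float(v) for v in raw_vals]
    n = len(x)
    mean = sum(x) / n
    m2 = sum((v - mean) ** 2 for v in x) / n
    m3 = sum((v - mean) ** 3 for v in x) / n
    m4 = sum((v - mean) ** 4 for v in x) / n
    hist = defaultdict(int)
    for lv in level_vals:
        hist[int(lv)] += 1
    probs = [c / n for c in hist.values()]
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    sub = [v for v in x if p10 <= v <= p90]
    sub_mean = sum(sub) / len(sub) if sub else 0.0
    energy = sum(v * v for v in x)
    return {
        "Energy": energy,
        "TotalEnergy": voxel_volume * energy,
        "Entropy": -sum(p * _log2(p) for p in probs),
        "Minimum": min(x),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": max(x),
        "Mean": mean,
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": max(x) - min(x),
        "MeanAbsoluteDeviation": sum(abs(v - mean) for v in x) / n,
        "RobustMeanAbsoluteDeviation":
            sum(abs(v - sub_mean) for v in sub) / len(sub) if sub else 0.0,
        "RootMeanSquared": math.sqrt(sum(v * v for v in x) / n),
        "Skewness": m3 / m2 ** 1.5 if m2 > 0 else 0.0,
        "Kurtosis": m4 / m2 ** 2 if m2 > 0 else 0.0,
        "Variance": m2,
        "Uniformity": sum(p * p for p in probs),
    }


def oracle_glcm_features(counts):
    total = sum(counts.values())
    p = {k: v / total for k, v in counts.items()}
    levels = sorted({i for i, _ in p} | {j for _, j in p})
    ng = len(levels)
    px = defaultdict(float)
    for (i, j), v in p.items():
        px[i] += v
    mu = sum(i * v for i, v in px.items())
    sig2 = sum((i - mu) ** 2 * v for i, v in px.items())
    pdiff = defaultdict(float)
    psum = defaultdict(float)
    for (i, j), v in p.items():
        pdiff[abs(i - j)] += v
        psum[i + j] += v
    da = sum(k * v for k, v in pdiff.items())
    hxy = -sum(v * _log2(v) for v in p.values() if v > 0)
    eps = np.spacing(1.0)
    hxy1 = -sum(v * _log2(px[i] * px[j] + eps) for (i, j), v in p.items())
    hxy2 = -sum(px[i] * px[j] * _log2(px[i] * px[j])
                for i in levels for j in levels
                if px[i] * px[j] > 0)
    hx = -sum(v * _log2(v) for v in px.values() if v > 0)
    if ng > 1 and sig2 > 0:
        corr = (sum(i * j * v for (i, j), v in p.items()) - mu * mu) / sig2
    else:
        corr = 1.0
    if ng > 1:
        q = np.zeros((ng, ng))
        pos = {g: a for a, g in enumerate(levels)}
        for a, gi in enumerate(levels):
            for b, gj in enumerate(levels):
                acc = 0.0
                for gk in levels:
                    num = p.get((gi, gk), 0.0) * p.get((gj, gk), 0.0)
                    den = px[gi] * px[gk]
                    if den > 0:
                        acc += num / den
                q[a, b] = acc
        eig = sorted(np.real(np.linalg.eigvals(q)))
        mcc = math.sqrt(max(eig[-2], 0.0))
    else:
        mcc = 1.0
    return {
        "Autocorrelation": sum(i * j * v for (i, j), v in p.items()),
        "JointAverage": mu,
        "ClusterProminence": sum((i + j - 2 * mu) ** 4 * v
                                 for (i, j), v in p.items()),
        "ClusterShade": sum((i + j - 2 * mu) ** 3 * v
                            for (i, j), v in p.items()),
        "ClusterTendency": sum((i + j - 2 * mu) ** 2 * v
                               for (i, j), v in p.items()),
        "Contrast": sum((i - j) ** 2 * v for (i, j), v in p.items()),
        "Correlation": corr,
        "DifferenceAverage": da,
        "DifferenceEntropy": -sum(v * _log2(v) for v in pdiff.values()
                                  if v > 0),
        "DifferenceVariance": sum((k - da) ** 2 * v
                                  for k, v in pdiff.items()),
        "JointEnergy": sum(v * v for v in p.values()),
        "JointEntropy": hxy,
        "Imc1": (hxy - hxy1) / hx if hx > 0 else 0.0,
        "Imc2": math.sqrt(max(1.0 - math.exp(-2.0 * (hxy2 - hxy)), 0.0)),
        "Idm": sum(v / (1.0 + (i - j) ** 2) for (i, j), v in p.items()),
        "Idmn": sum(v / (1.0 + ((i - j) / ng) ** 2)
                    for (i, j), v in p.items()),
        "Id": sum(v / (1.0 + abs(i - j)) for (i, j), v in p.items()),
        "Idn": sum(v / (1.0 + abs(i - j) / ng) for (i, j), v in p.items()),
        "InverseVariance": sum(v / (i - j) ** 2 for (i, j), v in p.items()
                               if i != j),
        "MaximumProbability": max(p.values()),
        "SumAverage": sum(k * v for k, v in psum.items()),
        "SumEntropy": -sum(v * _log2(v) for v in psum.values() if v > 0),
        "SumSquares": sig2,
        "MCC": mcc,
    }


def oracle_gldm_features(matrix):
    nz = sum(matrix.values())
    levels = sorted({i for i, _ in matrix})
    ks = sorted({k for _, k in matrix})
    row = {i: sum(v for (a, _), v in matrix.items() if a == i)
           for i in levels}
    col = {k: sum(v for (_, b), v in matrix.items() if b == k) for k in ks}
    mu_g = sum(i * v for i, v in row.items()) / nz
    mu_k = sum(k * v for k, v in col.items()) / nz
    return {
        "SmallDependenceEmphasis":
            sum(v / k ** 2 for (_, k), v in matrix.items()) / nz,
        "LargeDependenceEmphasis":
            sum(v * k ** 2 for (_, k), v in matrix.items()) / nz,
        "GrayLevelNonUniformity": sum(v ** 2 for v in row.values()) / nz,
        "DependenceNonUniformity": sum(v ** 2 for v in col.values()) / nz,
        "DependenceNonUniformityNormalized":
            sum(v ** 2 for v in col.values()) / nz ** 2,
        "GrayLevelVariance":
            sum((i - mu_g) ** 2 * v for i, v in row.items()) / nz,
        "DependenceVariance":
            sum((k - mu_k) ** 2 * v for k, v in col.items()) / nz,
        "DependenceEntropy":
            -sum((v / nz) * _log2(v / nz) for v in matrix.values() if v > 0),
        "LowGrayLevelEmphasis":
            sum(v / i ** 2 for (i, _), v in matrix.items()) / nz,
        "HighGrayLevelEmphasis":
            sum(v * i ** 2 for (i, _), v in matrix.items()) / nz,
        "SmallDependenceLowGrayLevelEmphasis":
            sum(v / (i ** 2 * k ** 2) for (i, k), v in matrix.items()) / nz,
        "SmallDependenceHighGrayLevelEmphasis":
            sum(v * i ** 2 / k ** 2 for (i, k), v in matrix.items()) / nz,
        "LargeDependenceLowGrayLevelEmphasis":
            sum(v * k ** 2 / i ** 2 for (i, k), v in matrix.items()) / nz,
        "LargeDependenceHighGrayLevelEmphasis":
            sum(v * i ** 2 * k ** 2 for (i, k), v in matrix.items()) / nz,
    }


def oracle_glrlm_features(runs, n_voxels):
    nr = sum(runs.values())
    levels = sorted({i for i, _ in runs})
    lens = sorted({l for _, l in runs})
    row = {i: sum(v for (a, _), v in runs.items() if a == i) for i in levels}
    col = {l: sum(v for (_, b), v in runs.items() if b == l) for l in lens}
    mu_g = sum(i * v for i, v in row.items()) / nr
    mu_l = sum(l * v for l, v in col.items()) / nr
    return {
        "ShortRunEmphasis": sum(v / l ** 2 for (_, l), v in runs.items()) / nr,
        "LongRunEmphasis": sum(v * l ** 2 for (_, l), v in runs.items()) / nr,
        "GrayLevelNonUniformity": sum(v ** 2 for v in row.values()) / nr,
        "GrayLevelNonUniformityNormalized":
            sum(v ** 2 for v in row.values()) / nr ** 2,
        "RunLengthNonUniformity": sum(v ** 2 for v in col.values()) / nr,
        "RunLengthNonUniformityNormalized":
            sum(v ** 2 for v in col.values()) / nr ** 2,
        "RunPercentage": nr / (13.0 * n_voxels),
        "GrayLevelVariance":
            sum((i - mu_g) ** 2 * v for i, v in row.items()) / nr,
        "RunVariance": sum((l - mu_l) ** 2 * v for l, v in col.items()) / nr,
        "RunEntropy": -sum((v / nr) * _log2(v / nr)
                           for v in runs.values() if v > 0),
        "LowGrayLevelRunEmphasis":
            sum(v / i ** 2 for (i, _), v in runs.items()) / nr,
        "HighGrayLevelRunEmphasis":
            sum(v * i ** 2 for (i, _), v in runs.items()) / nr,
        "ShortRunLowGrayLevelEmphasis":
            sum(v / (i ** 2 * l ** 2) for (i, l), v in runs.items()) / nr,
        "ShortRunHighGrayLevelEmphasis":
            sum(v * i ** 2 / l ** 2 for (i, l), v in runs.items()) / nr,
        "LongRunLowGrayLevelEmphasis":
            sum(v * l ** 2 / i ** 2 for (i, l), v in runs.items()) / nr,
        "LongRunHighGrayLevelEmphasis":
            sum(v * i ** 2 * l ** 2 for (i, l), v in runs.items()) / nr,
    }


def oracle_ngtdm_features(s, n, nvp):
    levels = sorted(n)
    p = {i: n[i] / nvp for i in levels}
    ngp = len(levels)
    denom = sum(p[i] * s.get(i, 0.0) for i in levels)
    coarseness = 1.0 / denom if denom > 0 else 1e6
    if ngp > 1 and nvp > 0:
        contrast = (sum(p[i] * p[j] * (i - j) ** 2
                        for i in levels for j in levels)
                    / (ngp * (ngp - 1))) * sum(s.values()) / nvp
        busy_den = sum(abs(i * p[i] - j * p[j])
                       for i in levels for j in levels)
        busyness = denom / busy_den if busy_den > 0 else 0.0
        complexity = sum(abs(i - j) * (p[i] * s.get(i, 0.0)
                                       + p[j] * s.get(j, 0.0))
                         / (p[i] + p[j])
                         for i in levels for j in levels) / nvp
        stot = sum(s.values())
        strength = (sum((p[i] + p[j]) * (i - j) ** 2
                        for i in levels for j in levels) / stot
                    if stot > 0 else 0.0)
    else:
        contrast = busyness = complexity = strength = 0.0
    return {"Coarseness": coarseness, "Contrast": contrast,
            "Busyness": busyness, "Complexity": complexity,
            "Strength": strength}


def oracle_region_features(levels, mask, raw, voxel_volume=1.0):
    """All 77 features for one voxel set, family-prefixed names."""
    mask = np.asarray(mask, dtype=bool)
    raw_vals = np.asarray(raw)[mask]
    lev_vals = np.asarray(levels)[mask]
    out = {}
    for name, val in oracle_firstorder(raw_vals, lev_vals,
                                       voxel_volume).items():
        out[f"firstorder_{name}"] = val
    for name, val in oracle_glcm_features(oracle_glcm(levels, mask)).items():
        out[f"glcm_{name}"] = val
    for name, val in oracle_gldm_features(oracle_gldm(levels, mask)).items():
        out[f"gldm_{name}"] = val
    for name, val in oracle_glrlm_features(oracle_glrlm(levels, mask),
                                           int(mask.sum())).items():
        out[f"glrlm_{name}"] = val
    s, n, nvp = oracle_ngtdm(levels, mask)
    for name, val in oracle_ngtdm_features(s, n, nvp).items():
        out[f"ngtdm_{name}"] = val
    return out
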