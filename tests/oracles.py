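"""Independent brute-force oracles for the radiomic feature definitions.

Everything here is written as plain, slow, loop-based code straight from
the defining formulas, deliberately sharing no helpers with the package
implementation, so agreement between the two is meaningful.
"""

from __future__ import annotations

import math
from collections import defaultdict

import numpy as np

ANGLES = [
    (0, 0, 1), (0, 1, 0), (1, 0, 0),
    (0, 1, 1), (0, 1, -1), (1, 0, 1), (1, 0, -1), (1, 1, 0), (1, -1, 0),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
]

NEIGHBORS_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]


def _inside(shape, p):
    return all(0 <= p[k] < shape[k] for k in range(3))


# ---------------------------------------------------------------------------
# first order
# ---------------------------------------------------------------------------

def first_order_oracle(values, levels, voxel_volume):
    """18 first-order features from their single-pass definitions."""
    x = sorted(float(v) for v in values)
    n = len(x)

    def pct(q):
        # linear interpolation of order statistics
        h = (n - 1) * q / 100.0
        lo = math.floor(h)
        hi = min(lo + 1, n - 1)
        return x[lo] + (h - lo) * (x[hi] - x[lo])

    mean = sum(x) / n
    var = sum((v - mean) ** 2 for v in x) / n
    p10, p25, p50, p75, p90 = (pct(q) for q in (10, 25, 50, 75, 90))
    robust = [v for v in x if p10 <= v <= p90]
    rmean = sum(robust) / len(robust)
    counts = defaultdict(int)
    for lv in levels:
        counts[int(lv)] += 1
    probs = [c / n for c in counts.values()]
    sd = math.sqrt(var)
    energy = sum(v * v for v in x)
    return {
        "10Percentile": p10,
        "90Percentile": p90,
        "Energy": energy,
        "Entropy": -sum(p * math.log2(p) for p in probs if p > 0),
        "InterquartileRange": p75 - p25,
        "Kurtosis": (sum((v - mean) ** 4 for v in x) / n) / var**2 if var > 0 else 0.0,
        "Maximum": x[-1],
        "Mean": mean,
        "MeanAbsoluteDeviation": sum(abs(v - mean) for v in x) / n,
        "Median": p50,
        "Minimum": x[0],
        "Range": x[-1] - x[0],
        "RobustMeanAbsoluteDeviation": sum(abs(v - rmean) for v in robust) / len(robust),
        "RootMeanSquared": math.sqrt(energy / n),
        "Skewness": (sum((v - mean) ** 3 for v in x) / n) / sd**3 if var > 0 else 0.0,
        "TotalEnergy": voxel_volume * energy,
        "Uniformity": sum(p * p for p in probs),
        "Variance": var,
    }


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def glcm_matrix_oracle(levels, angle, ng):
    """Symmetrized, normalized co-occurrence matrix by explicit voxel-pair
    enumeration (both directions of the angle)."""
    shape = levels.shape
    mat = np.zeros((ng, ng))
    for xx in range(shape[0]):
        for yy in range(shape[1]):
            for zz in range(shape[2]):
                i = levels[xx, yy, zz]
                if i <= 0:
                    continue
                for sgn in (1, -1):
                    q = (xx + sgn * angle[0], yy + sgn * angle[1], zz + sgn * angle[2])
                    if not _inside(shape, q):
                        continue
                    j = levels[q]
                    if j > 0:
                        mat[i - 1, j - 1] += 1
    total = mat.sum()
    return mat / total if total else mat


def glcm_features_oracle(levels, ng):
    """24 co-occurrence features, direction-averaged, from the formulas."""
    per_angle = []
    for angle in ANGLES:
        p = glcm_matrix_oracle(levels, angle, ng)
        if p.sum() == 0:
            continue
        per_angle.append(_glcm_single_oracle(p))
    return {k: float(np.mean([f[k] for f in per_angle])) for k in per_angle[0]}


def _glcm_single_oracle(p):
    ng = p.shape[0]
    idx = list(range(1, ng + 1))
    px = [sum(p[i - 1][j - 1] for j in idx) for i in idx]
    py = [sum(p[i - 1][j - 1] for i in idx) for j in idx]
    ux = sum(i * px[i - 1] for i in idx)
    uy = sum(j * py[j - 1] for j in idx)
    sx = math.sqrt(sum((i - ux) ** 2 * px[i - 1] for i in idx))
    sy = math.sqrt(sum((j - uy) ** 2 * py[j - 1] for j in idx))
    pxy_sum = defaultdict(float)
    pxy_diff = defaultdict(float)
    for i in idx:
        for j in idx:
            pxy_sum[i + j] += p[i - 1][j - 1]
            pxy_diff[abs(i - j)] += p[i - 1][j - 1]

    def ent(vals):
        return -sum(v * math.log2(v) for v in vals if v > 0)

    hxy = ent(p.ravel())
    hx, hy = ent(px), ent(py)
    hxy1 = -sum(
        p[i - 1][j - 1] * math.log2(px[i - 1] * py[j - 1])
        for i in idx for j in idx
        if p[i - 1][j - 1] > 0 and px[i - 1] * py[j - 1] > 0
    )
    hxy2 = -sum(
        px[i - 1] * py[j - 1] * math.log2(px[i - 1] * py[j - 1])
        for i in idx for j in idx
        if px[i - 1] * py[j - 1] > 0
    )
    da = sum(k * v for k, v in pxy_diff.items())
    out = {
        "Autocorrelation": sum(i * j * p[i - 1][j - 1] for i in idx for j in idx),
        "ClusterProminence": sum((i + j - ux - uy) ** 4 * p[i - 1][j - 1] for i in idx for j in idx),
        "ClusterShade": sum((i + j - ux - uy) ** 3 * p[i - 1][j - 1] for i in idx for j in idx),
        "ClusterTendency": sum((i + j - ux - uy) ** 2 * p[i - 1][j - 1] for i in idx for j in idx),
        "Contrast": sum((i - j) ** 2 * p[i - 1][j - 1] for i in idx for j in idx),
        "DifferenceAverage": da,
        "DifferenceEntropy": ent(pxy_diff.values()),
        "DifferenceVariance": sum((k - da) ** 2 * v for k, v in pxy_diff.items()),
        "Id": sum(p[i - 1][j - 1] / (1 + abs(i - j)) for i in idx for j in idx),
        "Idm": sum(p[i - 1][j - 1] / (1 + (i - j) ** 2) for i in idx for j in idx),
        "Idmn": sum(p[i - 1][j - 1] / (1 + (i - j) ** 2 / ng**2) for i in idx for j in idx),
        "Idn": sum(p[i - 1][j - 1] / (1 + abs(i - j) / ng) for i in idx for j in idx),
        "InverseVariance": sum(
            p[i - 1][j - 1] / (i - j) ** 2 for i in idx for j in idx if i != j
        ),
        "JointAverage": ux,
        "JointEnergy": sum(v * v for v in p.ravel()),
        "JointEntropy": hxy,
        "MaximumProbability": max(p.ravel()),
        "SumAverage": sum(k * v for k, v in pxy_sum.items()),
        "SumEntropy": ent(pxy_sum.values()),
        "SumSquares": sum((i - ux) ** 2 * px[i - 1] for i in idx),
    }
    out["Correlation"] = (
        (out["Autocorrelation"] - ux * uy) / (sx * sy) if sx > 0 and sy > 0 else 1.0
    )
    denom = max(hx, hy)
    out["Imc1"] = (hxy - hxy1) / denom if denom > 0 else 0.0
    out["Imc2"] = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy)))) if hxy2 >= hxy else 0.0
    present = [i for i in idx if px[i - 1] > 0]
    if len(present) > 1:
        q = np.zeros((len(present), len(present)))
        for a, i in enumerate(present):
            for b, j in enumerate(present):
                q[a, b] = sum(
                    p[i - 1][k - 1] * p[j - 1][k - 1] / (px[i - 1] * py[k - 1])
                    for k in idx if py[k - 1] > 0
                )
        ev = sorted(np.real(np.linalg.eigvals(q)))
        out["MCC"] = math.sqrt(max(0.0, min(1.0, ev[-2])))
    else:
        out["MCC"] = 1.0
    return out


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------

def glrlm_matrices_oracle(levels, ng):
    """Run-length matrix per direction by explicitly walking every line."""
    shape = levels.shape
    mats = []
    for angle in ANGLES:
        runs = defaultdict(int)
        starts = [
            (x, y, z)
            for x in range(shape[0]) for y in range(shape[1]) for z in range(shape[2])
            if not _inside(shape, (x - angle[0], y - angle[1], z - angle[2]))
        ]
        for start in starts:
            pos = start
            cur, length = 0, 0
            while _inside(shape, pos):
                v = levels[pos]
                if v == cur and v > 0:
                    length += 1
                else:
                    if cur > 0:
                        runs[(cur, length)] += 1
                    cur, length = (v, 1) if v > 0 else (0, 0)
                pos = (pos[0] + angle[0], pos[1] + angle[1], pos[2] + angle[2])
            if cur > 0:
                runs[(cur, length)] += 1
        max_len = max((l for _, l in runs), default=1)
        mat = np.zeros((ng, max_len))
        for (lvl, length), c in runs.items():
            mat[lvl - 1, length - 1] += c
        mats.append(mat)
    return mats


def size_family_oracle(mat, n_voxels):
    """The 16 level-by-size formulas shared by GLRLM/GLSZM/GLDM oracles."""
    ns = mat.sum()
    ng, nl = mat.shape
    out = defaultdict(float)
    for i in range(1, ng + 1):
        for l in range(1, nl + 1):
            c = mat[i - 1, l - 1]
            if c == 0:
                continue
            out["SmallEmphasis"] += c / l**2
            out["LargeEmphasis"] += c * l**2
            out["LowGrayLevelEmphasis"] += c / i**2
            out["HighGrayLevelEmphasis"] += c * i**2
            out["SmallLowEmphasis"] += c / (i**2 * l**2)
            out["SmallHighEmphasis"] += c * i**2 / l**2
            out["LargeLowEmphasis"] += c * l**2 / i**2
            out["LargeHighEmphasis"] += c * i**2 * l**2
    for k in list(out):
        out[k] /= ns
    out["GrayLevelNonUniformity"] = sum(mat.sum(axis=1) ** 2) / ns
    out["GrayLevelNonUniformityNormalized"] = sum(mat.sum(axis=1) ** 2) / ns**2
    out["SizeNonUniformity"] = sum(mat.sum(axis=0) ** 2) / ns
    out["SizeNonUniformityNormalized"] = sum(mat.sum(axis=0) ** 2) / ns**2
    out["Percentage"] = ns / n_voxels
    p = mat / ns
    mu_i = sum(i * p[i - 1, l - 1] for i in range(1, ng + 1) for l in range(1, nl + 1))
    mu_l = sum(l * p[i - 1, l - 1] for i in range(1, ng + 1) for l in range(1, nl + 1))
    out["GrayLevelVariance"] = sum(
        (i - mu_i) ** 2 * p[i - 1, l - 1] for i in range(1, ng + 1) for l in range(1, nl + 1)
    )
    out["SizeVariance"] = sum(
        (l - mu_l) ** 2 * p[i - 1, l - 1] for i in range(1, ng + 1) for l in range(1, nl + 1)
    )
    out["Entropy"] = -sum(v * math.log2(v) for v in p.ravel() if v > 0)
    return dict(out)


# ---------------------------------------------------------------------------
# GLSZM (breadth-first flood fill)
# ---------------------------------------------------------------------------

def glszm_matrix_oracle(levels, ng):
    shape = levels.shape
    seen = set()
    zones = defaultdict(int)
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                if levels[x, y, z] <= 0 or (x, y, z) in seen:
                    continue
                lvl = levels[x, y, z]
                stack, size = [(x, y, z)], 0
                seen.add((x, y, z))
                while stack:
                    p = stack.pop()
                    size += 1
                    for d in NEIGHBORS_26:
                        q = (p[0] + d[0], p[1] + d[1], p[2] + d[2])
                        if q in seen or not _inside(shape, q) or levels[q] != lvl:
                            continue
                        seen.add(q)
                        stack.append(q)
                zones[(lvl, size)] += 1
    max_size = max(s for _, s in zones)
    mat = np.zeros((ng, max_size))
    for (lvl, size), c in zones.items():
        mat[lvl - 1, size - 1] += c
    return mat


# ---------------------------------------------------------------------------
# GLDM
# ---------------------------------------------------------------------------

def gldm_matrix_oracle(levels, ng, alpha=0):
    shape = levels.shape
    counts = defaultdict(int)
    max_dep = 1
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                i = levels[x, y, z]
                if i <= 0:
                    continue
                dep = 1  # the voxel itself
                for d in NEIGHBORS_26:
                    q = (x + d[0], y + d[1], z + d[2])
                    if _inside(shape, q) and levels[q] > 0 and abs(int(levels[q]) - int(i)) <= alpha:
                        dep += 1
                counts[(int(i), dep)] += 1
                max_dep = max(max_dep, dep)
    mat = np.zeros((ng, max_dep))
    for (lvl, dep), c in counts.items():
        mat[lvl - 1, dep - 1] += c
    return mat


# ---------------------------------------------------------------------------
# NGTDM
# ---------------------------------------------------------------------------

def ngtdm_features_oracle(levels, ng):
    shape = levels.shape
    s = defaultdict(float)
    n = defaultdict(int)
    nvp = 0
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                i = int(levels[x, y, z])
                if i <= 0:
                    continue
                nb = [
                    int(levels[x + d[0], y + d[1], z + d[2]])
                    for d in NEIGHBORS_26
                    if _inside(shape, (x + d[0], y + d[1], z + d[2]))
                    and levels[x + d[0], y + d[1], z + d[2]] > 0
                ]
                if not nb:
                    continue
                nvp += 1
                n[i] += 1
                s[i] += abs(i - sum(nb) / len(nb))
    p = {i: n[i] / nvp for i in n}
    present = sorted(p)
    ngp = len(present)
    sum_ps = sum(p[i] * s[i] for i in present)
    coarseness = min(1.0 / sum_ps if sum_ps > 0 else 1e6, 1e6)
    if ngp > 1:
        contrast = (
            sum(p[i] * p[j] * (i - j) ** 2 for i in present for j in present)
            / (ngp * (ngp - 1))
        ) * sum(s.values()) / nvp
        busy_den = sum(abs(i * p[i] - j * p[j]) for i in present for j in present)
        busyness = sum_ps / busy_den if busy_den > 0 else 0.0
        complexity = sum(
            abs(i - j) * (p[i] * s[i] + p[j] * s[j]) / (p[i] + p[j])
            for i in present for j in present
        ) / nvp
        ssum = sum(s.values())
        strength = (
            sum((p[i] + p[j]) * (i - j) ** 2 for i in present for j in present) / ssum
            if ssum > 0 else 0.0
        )
    else:
        contrast = busyness = complexity = strength = 0.0
    return {
        "Busyness": busyness,
        "Coarseness": coarseness,
        "Complexity": complexity,
        "Contrast": contrast,
        "Strength": strength,
    }
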