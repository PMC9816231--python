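"""Gray-level texture matrices and their named features.

Five matrix families over the discretized ROI:

* GLCM  — co-occurrence at distance 1 over the 13 unique 3D directions;
  matrices are symmetrized and probability-normalized per direction, and
  feature values averaged over directions that contain at least one pair.
* GLRLM — run lengths per direction (runs break at mask boundaries and
  level changes), features averaged over the 13 directions.
* GLSZM — size zones: 26-connected components of constant gray level.
* GLDM  — dependence counts: a 26-neighbour is dependent if its level
  differs by at most ``alpha``; the dependence size includes the center
  voxel, so sizes run from 1 to 27.
* NGTDM — per-level sums of absolute differences from the mean of the
  in-mask 26-neighbourhood (voxels with no in-mask neighbour are skipped).

Degenerate single-gray-level conventions: GLCM Correlation and MCC are 1,
Imc1/Imc2 are 0, NGTDM Contrast is 0, Coarseness is capped at 1e6.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

import numpy as np
from scipy import ndimage

from .preprocess import DiscretizedROI

__all__ = [
    "ANGLES_13",
    "glcm_matrices",
    "glcm_features",
    "glrlm_matrices",
    "glrlm_features",
    "glszm_matrix",
    "glszm_features",
    "gldm_matrix",
    "gldm_features",
    "ngtdm_table",
    "ngtdm_features",
    "GLCM_NAMES",
    "GLRLM_NAMES",
    "GLSZM_NAMES",
    "GLDM_NAMES",
    "NGTDM_NAMES",
]

#: The 13 unique direction vectors of the 26-neighbourhood (one per +/- pair).
ANGLES_13: Tuple[Tuple[int, int, int], ...] = (
    (0, 0, 1), (0, 1, 0), (1, 0, 0),
    (0, 1, 1), (0, 1, -1), (1, 0, 1), (1, 0, -1), (1, 1, 0), (1, -1, 0),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
)

_OFFSETS_26 = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
)

GLCM_NAMES = (
    "Autocorrelation", "ClusterProminence", "ClusterShade", "ClusterTendency",
    "Contrast", "Correlation", "DifferenceAverage", "DifferenceEntropy",
    "DifferenceVariance", "Id", "Idm", "Idmn", "Idn", "Imc1", "Imc2",
    "InverseVariance", "JointAverage", "JointEnergy", "JointEntropy", "MCC",
    "MaximumProbability", "SumAverage", "SumEntropy", "SumSquares",
)
GLRLM_NAMES = (
    "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance", "HighGrayLevelRunEmphasis", "LongRunEmphasis",
    "LongRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LowGrayLevelRunEmphasis", "RunEntropy", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "RunVariance",
    "ShortRunEmphasis", "ShortRunHighGrayLevelEmphasis",
    "ShortRunLowGrayLevelEmphasis",
)
GLSZM_NAMES = (
    "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance", "HighGrayLevelZoneEmphasis", "LargeAreaEmphasis",
    "LargeAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
    "LowGrayLevelZoneEmphasis", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "SmallAreaEmphasis",
    "SmallAreaHighGrayLevelEmphasis", "SmallAreaLowGrayLevelEmphasis",
    "ZoneEntropy", "ZonePercentage", "ZoneVariance",
)
GLDM_NAMES = (
    "DependenceEntropy", "DependenceNonUniformity",
    "DependenceNonUniformityNormalized", "DependenceVariance",
    "GrayLevelNonUniformity", "GrayLevelVariance", "HighGrayLevelEmphasis",
    "LargeDependenceEmphasis", "LargeDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis", "LowGrayLevelEmphasis",
    "SmallDependenceEmphasis", "SmallDependenceHighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
)
NGTDM_NAMES = ("Busyness", "Coarseness", "Complexity", "Contrast", "Strength")


def _shifted_views(arr: np.ndarray, offset):
    """Overlapping views of arr and arr shifted by ``offset``."""
    sl_a, sl_b = [], []
    for d, n in zip(offset, arr.shape):
        if d >= 0:
            sl_a.append(slice(0, n - d))
            sl_b.append(slice(d, n))
        else:
            sl_a.append(slice(-d, n))
            sl_b.append(slice(0, n + d))
    return arr[tuple(sl_a)], arr[tuple(sl_b)]


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def glcm_matrices(disc: DiscretizedROI, distance: int = 1) -> List[np.ndarray]:
    """Symmetric, normalized co-occurrence matrix per direction.

    Directions with no valid voxel pair are omitted.
    """
    ng = disc.level_count
    lv = disc.levels
    mats = []
    for angle in ANGLES_13:
        off = tuple(distance * a for a in angle)
        a, b = _shifted_views(lv, off)
        valid = (a > 0) & (b > 0)
        if not valid.any():
            continue
        i, j = a[valid] - 1, b[valid] - 1
        counts = np.bincount(i * ng + j, minlength=ng * ng).reshape(ng, ng).astype(float)
        counts = counts + counts.T
        mats.append(counts / counts.sum())
    return mats


def _glcm_features_single(p: np.ndarray) -> Dict[str, float]:
    ng = p.shape[0]
    i = np.arange(1, ng + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    ux = float((i * px).sum())
    uy = float((i * py).sum())
    sx = float(np.sqrt(((i - ux) ** 2 * px).sum()))
    sy = float(np.sqrt(((i - uy) ** 2 * py).sum()))

    # diagonal (difference) and cross-diagonal (sum) distributions
    k_diff = np.arange(0, ng, dtype=float)
    p_diff = np.array([p[np.abs(ii - jj) == k].sum() for k in k_diff])
    k_sum = np.arange(2, 2 * ng + 1, dtype=float)
    p_sum = np.array([p[(ii + jj) == k].sum() for k in k_sum])

    def ent(q):
        q = q[q > 0]
        return float(-(q * np.log2(q)).sum()) if q.size else 0.0

    hxy = ent(p.ravel())
    hx = ent(px)
    with np.errstate(divide="ignore", invalid="ignore"):
        pxy = np.outer(px, py)
        lg = np.where(pxy > 0, np.log2(np.where(pxy > 0, pxy, 1.0)), 0.0)
    hxy1 = float(-(p * lg).sum())
    hxy2 = float(-(pxy * lg).sum())

    da = float((k_diff * p_diff).sum())
    contrast = float(((ii - jj) ** 2 * p).sum())
    autoc = float((ii * jj * p).sum())

    if sx > 0 and sy > 0:
        correlation = (autoc - ux * uy) / (sx * sy)
    else:
        correlation = 1.0

    denom = max(hx, ent(py))
    imc1 = (hxy - hxy1) / denom if denom > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy))))) if hxy2 >= hxy else 0.0

    # MCC: second largest eigenvalue of Q
    nz = px > 0
    if nz.sum() > 1:
        psub = p[np.ix_(nz, nz)]
        q = (psub[:, None, :] * psub[None, :, :] /
             (px[nz][:, None, None] * py[nz][None, None, :])).sum(axis=2)
        ev = np.sort(np.real(np.linalg.eigvals(q)))
        mcc = float(np.sqrt(max(0.0, min(1.0, ev[-2]))))
    else:
        mcc = 1.0

    off = np.abs(ii - jj)
    inv_var = float((p[off > 0] / off[off > 0] ** 2).sum())

    return {
        "Autocorrelation": autoc,
        "ClusterProminence": float(((ii + jj - ux - uy) ** 4 * p).sum()),
        "ClusterShade": float(((ii + jj - ux - uy) ** 3 * p).sum()),
        "ClusterTendency": float(((ii + jj - ux - uy) ** 2 * p).sum()),
        "Contrast": contrast,
        "Correlation": float(correlation),
        "DifferenceAverage": da,
        "DifferenceEntropy": ent(p_diff),
        "DifferenceVariance": float(((k_diff - da) ** 2 * p_diff).sum()),
        "Id": float((p / (1.0 + off)).sum()),
        "Idm": float((p / (1.0 + off**2)).sum()),
        "Idmn": float((p / (1.0 + off**2 / ng**2)).sum()),
        "Idn": float((p / (1.0 + off / ng)).sum()),
        "Imc1": float(imc1),
        "Imc2": imc2,
        "InverseVariance": inv_var,
        "JointAverage": ux,
        "JointEnergy": float((p**2).sum()),
        "JointEntropy": hxy,
        "MCC": mcc,
        "MaximumProbability": float(p.max()),
        "SumAverage": float((k_sum * p_sum).sum()),
        "SumEntropy": ent(p_sum),
        "SumSquares": float(((i - ux) ** 2 * px).sum()),
    }


def glcm_features(disc: DiscretizedROI, distance: int = 1) -> Dict[str, float]:
    """24 co-occurrence features, averaged over the 13 directions."""
    mats = glcm_matrices(disc, distance)
    if not mats:
        raise ValueError("no co-occurring voxel pairs in ROI")
    per_angle = [_glcm_features_single(p) for p in mats]
    return {name: float(np.mean([f[name] for f in per_angle])) for name in GLCM_NAMES}


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------

def _rle_matrix(lines: np.ndarray, ng: int) -> np.ndarray:
    """Run-length matrix from stacked lines (one row per traversal line;
    entries <= 0 break runs).  Fully vectorized."""
    n_rows, n_cols = lines.shape
    # separator column guarantees runs never span adjacent rows
    flat = np.concatenate([lines, np.full((n_rows, 1), -1, dtype=lines.dtype)], axis=1).ravel()
    breaks = np.flatnonzero(flat[1:] != flat[:-1]) + 1
    starts = np.concatenate([[0], breaks])
    ends = np.concatenate([breaks, [flat.size]])
    values = flat[starts]
    lengths = ends - starts
    keep = values > 0
    values, lengths = values[keep], lengths[keep]
    mat = np.zeros((ng, int(lengths.max()) if lengths.size else 1), dtype=float)
    if lengths.size:
        np.add.at(mat, (values - 1, lengths - 1), 1.0)
    return mat


def glrlm_matrices(disc: DiscretizedROI) -> List[np.ndarray]:
    """One run-length matrix P[level-1, length-1] per direction."""
    lv = disc.levels
    ng = disc.level_count
    shape = np.array(lv.shape)
    coords = np.indices(lv.shape).reshape(3, -1).T
    mats = []
    for angle in ANGLES_13:
        d = np.array(angle)
        prev = coords - d
        out = (prev < 0).any(axis=1) | (prev >= shape).any(axis=1)
        starts = coords[out]
        # walk each line from its start, gathering levels (0 once off-grid)
        steps = np.arange(int(max(shape)))
        pos = starts[:, None, :] + steps[None, :, None] * d[None, None, :]
        inside = ((pos >= 0) & (pos < shape)).all(axis=2)
        pos_clipped = np.clip(pos, 0, shape - 1)
        lines = np.where(
            inside,
            lv[pos_clipped[..., 0], pos_clipped[..., 1], pos_clipped[..., 2]],
            0,
        ).astype(np.int64)
        mats.append(_rle_matrix(lines, ng))
    return mats


def _rl_features(mat: np.ndarray, n_voxels: int) -> Dict[str, float]:
    """Shared level-by-size feature formulas (runs, zones and dependences
    differ only in what the size axis counts; callers rename via maps)."""
    ns = mat.sum()
    if ns == 0:
        raise ValueError("empty texture matrix")
    ng, nl = mat.shape
    i = np.arange(1, ng + 1, dtype=float)[:, None]
    l = np.arange(1, nl + 1, dtype=float)[None, :]
    p = mat / ns
    mu_i = (i * p).sum()
    mu_l = (l * p).sum()
    pz = p[p > 0]
    return {
        "SmallEmphasis": float((mat / l**2).sum() / ns),
        "LargeEmphasis": float((mat * l**2).sum() / ns),
        "GrayLevelNonUniformity": float((mat.sum(axis=1) ** 2).sum() / ns),
        "GrayLevelNonUniformityNormalized": float((mat.sum(axis=1) ** 2).sum() / ns**2),
        "SizeNonUniformity": float((mat.sum(axis=0) ** 2).sum() / ns),
        "SizeNonUniformityNormalized": float((mat.sum(axis=0) ** 2).sum() / ns**2),
        "Percentage": float(ns / n_voxels),
        "GrayLevelVariance": float(((i - mu_i) ** 2 * p).sum()),
        "SizeVariance": float(((l - mu_l) ** 2 * p).sum()),
        "Entropy": float(-(pz * np.log2(pz)).sum()),
        "LowGrayLevelEmphasis": float((mat / i**2).sum() / ns),
        "HighGrayLevelEmphasis": float((mat * i**2).sum() / ns),
        "SmallLowEmphasis": float((mat / (i**2 * l**2)).sum() / ns),
        "SmallHighEmphasis": float((mat * i**2 / l**2).sum() / ns),
        "LargeLowEmphasis": float((mat * l**2 / i**2).sum() / ns),
        "LargeHighEmphasis": float((mat * i**2 * l**2).sum() / ns),
    }


_GLRLM_MAP = {
    "ShortRunEmphasis": "SmallEmphasis",
    "LongRunEmphasis": "LargeEmphasis",
    "GrayLevelNonUniformity": "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized": "GrayLevelNonUniformityNormalized",
    "RunLengthNonUniformity": "SizeNonUniformity",
    "RunLengthNonUniformityNormalized": "SizeNonUniformityNormalized",
    "RunPercentage": "Percentage",
    "GrayLevelVariance": "GrayLevelVariance",
    "RunVariance": "SizeVariance",
    "RunEntropy": "Entropy",
    "LowGrayLevelRunEmphasis": "LowGrayLevelEmphasis",
    "HighGrayLevelRunEmphasis": "HighGrayLevelEmphasis",
    "ShortRunLowGrayLevelEmphasis": "SmallLowEmphasis",
    "ShortRunHighGrayLevelEmphasis": "SmallHighEmphasis",
    "LongRunLowGrayLevelEmphasis": "LargeLowEmphasis",
    "LongRunHighGrayLevelEmphasis": "LargeHighEmphasis",
}


def glrlm_features(disc: DiscretizedROI) -> Dict[str, float]:
    """16 run-length features, averaged over the 13 directions."""
    nvox = int(disc.mask.sum())
    per_angle = [_rl_features(m, nvox) for m in glrlm_matrices(disc)]
    return {
        name: float(np.mean([f[_GLRLM_MAP[name]] for f in per_angle]))
        for name in GLRLM_NAMES
    }


# ---------------------------------------------------------------------------
# GLSZM
# ---------------------------------------------------------------------------

def glszm_matrix(disc: DiscretizedROI) -> np.ndarray:
    """Size-zone matrix P[level-1, size-1]; zones are 26-connected."""
    lv = disc.levels
    ng = disc.level_count
    structure = np.ones((3, 3, 3), dtype=int)
    zones = []  # (level, size)
    for level in range(1, ng + 1):
        lab, n = ndimage.label(lv == level, structure=structure)
        if n:
            sizes = np.bincount(lab.ravel())[1:]
            zones.extend((level, int(s)) for s in sizes)
    if not zones:
        raise ValueError("no zones in ROI")
    max_size = max(s for _, s in zones)
    mat = np.zeros((ng, max_size), dtype=float)
    for level, size in zones:
        mat[level - 1, size - 1] += 1
    return mat


_GLSZM_MAP = {
    "SmallAreaEmphasis": "SmallEmphasis",
    "LargeAreaEmphasis": "LargeEmphasis",
    "GrayLevelNonUniformity": "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized": "GrayLevelNonUniformityNormalized",
    "SizeZoneNonUniformity": "SizeNonUniformity",
    "SizeZoneNonUniformityNormalized": "SizeNonUniformityNormalized",
    "ZonePercentage": "Percentage",
    "GrayLevelVariance": "GrayLevelVariance",
    "ZoneVariance": "SizeVariance",
    "ZoneEntropy": "Entropy",
    "LowGrayLevelZoneEmphasis": "LowGrayLevelEmphasis",
    "HighGrayLevelZoneEmphasis": "HighGrayLevelEmphasis",
    "SmallAreaLowGrayLevelEmphasis": "SmallLowEmphasis",
    "SmallAreaHighGrayLevelEmphasis": "SmallHighEmphasis",
    "LargeAreaLowGrayLevelEmphasis": "LargeLowEmphasis",
    "LargeAreaHighGrayLevelEmphasis": "LargeHighEmphasis",
}


def glszm_features(disc: DiscretizedROI) -> Dict[str, float]:
    f = _rl_features(glszm_matrix(disc), int(disc.mask.sum()))
    return {name: f[_GLSZM_MAP[name]] for name in GLSZM_NAMES}


# ---------------------------------------------------------------------------
# GLDM
# ---------------------------------------------------------------------------

def gldm_matrix(disc: DiscretizedROI, alpha: int = 0) -> np.ndarray:
    """Dependence matrix P[level-1, size-1]; size = 1 + dependent neighbours."""
    lv = disc.levels
    ng = disc.level_count
    dep = np.zeros(lv.shape, dtype=np.int64)
    for off in _OFFSETS_26:
        a, b = _shifted_views(lv, off)
        contrib = (b > 0) & (a > 0) & (np.abs(a - b) <= alpha)
        sl = tuple(
            slice(0, n - d) if d >= 0 else slice(-d, n)
            for d, n in zip(off, lv.shape)
        )
        dep[sl] += contrib
    sizes = dep[disc.mask] + 1  # center voxel counts itself
    levels = lv[disc.mask]
    mat = np.zeros((ng, 27), dtype=float)
    np.add.at(mat, (levels - 1, sizes - 1), 1.0)
    used = np.where(mat.any(axis=0))[0]
    return mat[:, : used[-1] + 1]


_GLDM_MAP = {
    "SmallDependenceEmphasis": "SmallEmphasis",
    "LargeDependenceEmphasis": "LargeEmphasis",
    "GrayLevelNonUniformity": "GrayLevelNonUniformity",
    "DependenceNonUniformity": "SizeNonUniformity",
    "DependenceNonUniformityNormalized": "SizeNonUniformityNormalized",
    "GrayLevelVariance": "GrayLevelVariance",
    "DependenceVariance": "SizeVariance",
    "DependenceEntropy": "Entropy",
    "LowGrayLevelEmphasis": "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis": "HighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis": "SmallLowEmphasis",
    "SmallDependenceHighGrayLevelEmphasis": "SmallHighEmphasis",
    "LargeDependenceLowGrayLevelEmphasis": "LargeLowEmphasis",
    "LargeDependenceHighGrayLevelEmphasis": "LargeHighEmphasis",
}


def gldm_features(disc: DiscretizedROI, alpha: int = 0) -> Dict[str, float]:
    f = _rl_features(gldm_matrix(disc, alpha), int(disc.mask.sum()))
    return {name: f[_GLDM_MAP[name]] for name in GLDM_NAMES}


# ---------------------------------------------------------------------------
# NGTDM
# ---------------------------------------------------------------------------

def ngtdm_table(disc: DiscretizedROI):
    """Per-level (n_i, p_i, s_i) over voxels with at least one in-mask
    26-neighbour."""
    lv = disc.levels.astype(float)
    mask = disc.mask
    ng = disc.level_count
    nb_sum = np.zeros(lv.shape)
    nb_cnt = np.zeros(lv.shape)
    inm = mask.astype(float)
    for off in _OFFSETS_26:
        sl_a = tuple(
            slice(0, n - d) if d >= 0 else slice(-d, n)
            for d, n in zip(off, lv.shape)
        )
        sl_b = tuple(
            slice(d, n) if d >= 0 else slice(0, n + d)
            for d, n in zip(off, lv.shape)
        )
        nb_sum[sl_a] += lv[sl_b] * inm[sl_b]
        nb_cnt[sl_a] += inm[sl_b]
    valid = mask & (nb_cnt > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        avg = np.where(valid, nb_sum / np.where(nb_cnt > 0, nb_cnt, 1.0), 0.0)
    diffs = np.abs(lv - avg)[valid]
    levels = disc.levels[valid]
    n_i = np.bincount(levels, minlength=ng + 1)[1:].astype(float)
    s_i = np.zeros(ng)
    np.add.at(s_i, levels - 1, diffs)
    nvp = n_i.sum()
    if nvp == 0:
        raise ValueError("no voxels with valid neighbourhood")
    return n_i, n_i / nvp, s_i


def ngtdm_features(disc: DiscretizedROI) -> Dict[str, float]:
    n_i, p_i, s_i = ngtdm_table(disc)
    ng = p_i.size
    nvp = n_i.sum()
    i = np.arange(1, ng + 1, dtype=float)
    present = p_i > 0
    ngp = int(present.sum())

    sum_ps = float((p_i * s_i).sum())
    coarseness = 1.0 / sum_ps if sum_ps > 0 else 1e6
    coarseness = min(coarseness, 1e6)

    if ngp > 1:
        pi_, pj_ = np.meshgrid(p_i, p_i, indexing="ij")
        ii, jj = np.meshgrid(i, i, indexing="ij")
        both = (pi_ > 0) & (pj_ > 0)
        contrast = (
            float((pi_ * pj_ * (ii - jj) ** 2)[both].sum()) / (ngp * (ngp - 1))
        ) * float(s_i.sum()) / nvp
        busy_den = float(np.abs(ii * pi_ - jj * pj_)[both].sum())
        busyness = sum_ps / busy_den if busy_den > 0 else 0.0
        si_, sj_ = np.meshgrid(s_i, s_i, indexing="ij")
        complexity = float(
            (np.abs(ii - jj)[both] * (pi_[both] * si_[both] + pj_[both] * sj_[both])
             / (pi_[both] + pj_[both])).sum()
        ) / nvp
        ssum = float(s_i.sum())
        strength = (
            float(((pi_ + pj_) * (ii - jj) ** 2)[both].sum()) / ssum if ssum > 0 else 0.0
        )
    else:
        contrast, busyness, complexity, strength = 0.0, 0.0, 0.0, 0.0

    return {
        "Busyness": busyness,
        "Coarseness": coarseness,
        "Complexity": complexity,
        "Contrast": contrast,
        "Strength": strength,
    }
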