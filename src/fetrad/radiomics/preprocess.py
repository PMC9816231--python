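"""ROI preprocessing for feature extraction: isotropic resampling and
fixed-bin-width gray-level discretization.

Images are resampled to an isotropic grid (default 2.03 mm) with trilinear
interpolation; masks with nearest-neighbour so they stay binary.  Gray
levels are min-of-ROI referenced:

    level = floor((x - min_ROI) / bin_width) + 1

so texture features are invariant under adding a constant to all
intensities.  The cohort-level bin width for continuous images is the mean
per-patient interquartile range divided by 4.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Tuple

import numpy as np
import SimpleITK as sitk

__all__ = [
    "ResampledROI",
    "DiscretizedROI",
    "resample_isotropic",
    "compute_bin_width_iqr4",
    "discretize",
    "crop_to_mask",
]

DEFAULT_SPACING = 2.03  # mm, isotropic


@dataclass
class ResampledROI:
    """Image values and binary mask on a shared isotropic grid."""

    values: np.ndarray
    mask: np.ndarray
    spacing: Tuple[float, float, float]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask).astype(bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask grids differ")
        if not self.mask.any():
            raise ValueError("ROI mask is empty")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def roi_values(self) -> np.ndarray:
        return self.values[self.mask]

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class DiscretizedROI:
    """Integer gray levels 1..N_g on the ROI grid; 0 marks outside-mask."""

    levels: np.ndarray
    mask: np.ndarray
    bin_width: float
    level_count: int

    @property
    def roi_levels(self) -> np.ndarray:
        return self.levels[self.mask]


def crop_to_mask(image: np.ndarray, mask: np.ndarray, margin: int = 3):
    """Crop image and mask to the mask bounding box plus ``margin`` voxels.

    Keeps enough context for boundary interpolation while making texture
    passes cheap on large grids.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("mask is empty")
    lo, hi = [], []
    for ax in range(3):
        proj = np.any(mask, axis=tuple(a for a in range(3) if a != ax))
        nz = np.where(proj)[0]
        lo.append(max(0, nz[0] - margin))
        hi.append(min(mask.shape[ax], nz[-1] + 1 + margin))
    sl = tuple(slice(l, h) for l, h in zip(lo, hi))
    return np.asarray(image)[sl], mask[sl]


def _to_sitk(arr: np.ndarray, voxel_size, is_mask: bool) -> sitk.Image:
    # numpy array is (x, y, z); SimpleITK expects (z, y, x) in memory
    a = np.ascontiguousarray(np.transpose(arr, (2, 1, 0)))
    img = sitk.GetImageFromArray(a.astype(np.uint8 if is_mask else np.float64))
    img.SetSpacing(tuple(float(v) for v in voxel_size))
    return img


def resample_isotropic(
    image: np.ndarray,
    mask: np.ndarray,
    voxel_size: Sequence[float],
    spacing: float = DEFAULT_SPACING,
) -> ResampledROI:
    """Resample image (trilinear) and mask (nearest-neighbour) to an
    isotropic grid covering the input volume."""
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask).astype(bool)
    if image.shape != mask.shape:
        raise ValueError("image and mask grids differ")

    in_img = _to_sitk(image, voxel_size, is_mask=False)
    in_msk = _to_sitk(mask, voxel_size, is_mask=True)
    out_size = [
        max(1, int(np.ceil(sz * sp / spacing)))
        for sz, sp in zip(in_img.GetSize(), in_img.GetSpacing())
    ]
    rf = sitk.ResampleImageFilter()
    rf.SetOutputSpacing((spacing,) * 3)
    rf.SetSize(out_size)
    rf.SetOutputOrigin(in_img.GetOrigin())
    rf.SetOutputDirection(in_img.GetDirection())
    rf.SetInterpolator(sitk.sitkLinear)
    out_img = rf.Execute(in_img)
    rf.SetInterpolator(sitk.sitkNearestNeighbor)
    out_msk = rf.Execute(in_msk)

    values = np.transpose(sitk.GetArrayFromImage(out_img), (2, 1, 0))
    rmask = np.transpose(sitk.GetArrayFromImage(out_msk), (2, 1, 0)).astype(bool)
    if not rmask.any():
        raise ValueError("mask is empty after resampling")
    return ResampledROI(
        values=values,
        mask=rmask,
        spacing=(spacing,) * 3,
        provenance={
            "input_voxel_size_mm": [float(v) for v in voxel_size],
            "interpolation": {"image": "trilinear", "mask": "nearest"},
        },
    )


def compute_bin_width_iqr4(cohort_roi_values: Sequence[np.ndarray]) -> float:
    """Cohort bin width: mean over patients of (Q3 - Q1), divided by 4.

    Quartiles use linear interpolation of order statistics.
    """
    if len(cohort_roi_values) == 0:
        raise ValueError("need at least one patient ROI")
    iqrs = []
    for vals in cohort_roi_values:
        vals = np.asarray(vals, dtype=float).ravel()
        if vals.size == 0:
            raise ValueError("empty ROI in cohort")
        q1, q3 = np.percentile(vals, [25, 75])
        iqrs.append(q3 - q1)
    width = float(np.mean(iqrs)) / 4.0
    if width <= 0:
        raise ValueError("all ROIs are constant; bin width would be zero")
    return width


def discretize(roi: ResampledROI, bin_width: float) -> DiscretizedROI:
    """Fixed-bin-width discretization, min-of-ROI referenced."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    vals = roi.roi_values
    lo = vals.min()
    lv = np.floor((roi.values - lo) / bin_width).astype(np.int64) + 1
    levels = np.where(roi.mask, lv, 0)
    return DiscretizedROI(
        levels=levels,
        mask=roi.mask,
        bin_width=float(bin_width),
        level_count=int(levels[roi.mask].max()),
    )
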