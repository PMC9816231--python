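"""Full 107-feature extraction from a parametric image within a tumor VOI.

The canonical feature order is: 18 first-order, 14 shape, 24 GLCM, 16 GLRLM,
16 GLSZM, 14 GLDM, 5 NGTDM — alphabetical within each class — with names
``<class>_<FeatureName>`` (e.g. ``glcm_ClusterProminence``).  This order also
defines the iteration order of the pairwise correlation filter used during
feature selection, so it is part of the package contract.

Default bin widths follow the pipeline configuration: 0.13 for TBR images
(cohort-average interquartile range divided by 4) and 5 for time-to-peak
maps (the smallest frame duration, in minutes, of the group definitions).
Under the min-referenced floor formula a width of 5 collapses the six
ordinal groups to two gray levels; ``ttp_group_levels=True`` instead treats
each group as its own level (bin width 1), provided because published
practice is ambiguous on this point.
"""

from __future__ import annotations

from collections import OrderedDict
from typing import Dict, Optional, Sequence, Union

import numpy as np

from ..parametric import ParametricImage
from .firstorder import FIRSTORDER_NAMES, first_order_features
from .preprocess import (
    DEFAULT_SPACING,
    crop_to_mask,
    discretize,
    resample_isotropic,
)
from .shape import SHAPE_NAMES, shape_features
from .texture import (
    GLCM_NAMES,
    GLDM_NAMES,
    GLRLM_NAMES,
    GLSZM_NAMES,
    NGTDM_NAMES,
    glcm_features,
    gldm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
)

__all__ = [
    "FEATURE_NAMES",
    "DEFAULT_BIN_WIDTH_TBR",
    "DEFAULT_BIN_WIDTH_TTP",
    "extract_all",
]

DEFAULT_BIN_WIDTH_TBR = 0.13
DEFAULT_BIN_WIDTH_TTP = 5.0

_CLASSES = (
    ("firstorder", FIRSTORDER_NAMES),
    ("shape", SHAPE_NAMES),
    ("glcm", GLCM_NAMES),
    ("glrlm", GLRLM_NAMES),
    ("glszm", GLSZM_NAMES),
    ("gldm", GLDM_NAMES),
    ("ngtdm", NGTDM_NAMES),
)

#: The 107 feature names in canonical order.
FEATURE_NAMES = tuple(
    f"{cls}_{name}" for cls, names in _CLASSES for name in names
)


def extract_all(
    image: Union[ParametricImage, np.ndarray],
    mask: np.ndarray,
    bin_width: Optional[float] = None,
    spacing: float = DEFAULT_SPACING,
    voxel_size: Optional[Sequence[float]] = None,
    glcm_distance: int = 1,
    gldm_alpha: int = 0,
    crop_margin: int = 3,
    ttp_group_levels: bool = False,
) -> "OrderedDict[str, float]":
    """Resample, discretize and extract all 107 features.

    ``bin_width`` defaults by image kind: 0.13 for TBR, 5 for TTP.  The
    image is cropped to the mask bounding box (plus a margin supplying
    interpolation context) before resampling.  ``ttp_group_levels=True``
    switches TTP maps to bin width 1 so each ordinal group keeps its own
    gray level instead of the literal width-5 rule.
    """
    if isinstance(image, ParametricImage):
        data = np.asarray(image.data, dtype=float)
        vs = image.voxel_size
        if bin_width is None:
            if image.kind == "TBR":
                bin_width = DEFAULT_BIN_WIDTH_TBR
            else:
                bin_width = 1.0 if ttp_group_levels else DEFAULT_BIN_WIDTH_TTP
    else:
        data = np.asarray(image, dtype=float)
        if voxel_size is None:
            raise ValueError("voxel_size required for bare-array input")
        vs = tuple(voxel_size)
        if bin_width is None:
            raise ValueError("bin_width required for bare-array input")

    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("mask is empty")
    data_c, mask_c = crop_to_mask(data, mask, margin=crop_margin)
    roi = resample_isotropic(data_c, mask_c, vs, spacing=spacing)
    disc = discretize(roi, bin_width)

    out: "OrderedDict[str, float]" = OrderedDict()
    blocks = {
        "firstorder": first_order_features(roi, disc),
        "shape": shape_features(roi.mask, roi.spacing),
        "glcm": glcm_features(disc, distance=glcm_distance),
        "glrlm": glrlm_features(disc),
        "glszm": glszm_features(disc),
        "gldm": gldm_features(disc, alpha=gldm_alpha),
        "ngtdm": ngtdm_features(disc),
    }
    for cls, names in _CLASSES:
        for name in names:
            out[f"{cls}_{name}"] = float(blocks[cls][name])
    assert len(out) == 107
    return out
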