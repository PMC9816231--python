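"""First-order (intensity histogram) features.

Computed on the raw resampled intensities within the ROI, except Entropy
and Uniformity which use the discretized gray-level distribution.  Skewness
and kurtosis use population moments; kurtosis is not excess-corrected.
"""

from __future__ import annotations

from typing import Dict

import numpy as np

from .preprocess import DiscretizedROI, ResampledROI

__all__ = ["first_order_features", "FIRSTORDER_NAMES"]

FIRSTORDER_NAMES = (
    "10Percentile", "90Percentile", "Energy", "Entropy", "InterquartileRange",
    "Kurtosis", "Maximum", "Mean", "MeanAbsoluteDeviation", "Median", "Minimum",
    "Range", "RobustMeanAbsoluteDeviation", "RootMeanSquared", "Skewness",
    "TotalEnergy", "Uniformity", "Variance",
)


def first_order_features(roi: ResampledROI, disc: DiscretizedROI) -> Dict[str, float]:
    x = roi.roi_values
    n = x.size
    mean = x.mean()
    var = x.var()  # population
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])

    robust = x[(x >= p10) & (x <= p90)]
    rmad = float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0

    if var > 0:
        sd = np.sqrt(var)
        skew = float(np.mean((x - mean) ** 3) / sd**3)
        kurt = float(np.mean((x - mean) ** 4) / var**2)
    else:
        skew, kurt = 0.0, 0.0

    counts = np.bincount(disc.roi_levels)[1:]
    p = counts[counts > 0] / n
    entropy = float(-(p * np.log2(p)).sum())
    uniformity = float((p**2).sum())

    energy = float((x**2).sum())
    return {
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Energy": energy,
        "Entropy": entropy,
        "InterquartileRange": float(p75 - p25),
        "Kurtosis": kurt,
        "Maximum": float(x.max()),
        "Mean": float(mean),
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "Median": float(p50),
        "Minimum": float(x.min()),
        "Range": float(x.max() - x.min()),
        "RobustMeanAbsoluteDeviation": rmad,
        "RootMeanSquared": float(np.sqrt(np.mean(x**2))),
        "Skewness": skew,
        "TotalEnergy": float(roi.voxel_volume * energy),
        "Uniformity": uniformity,
        "Variance": float(var),
    }
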