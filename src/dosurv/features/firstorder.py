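"""The 18 first-order dose-distribution statistics.

Intensity statistics are computed on the raw in-mask doses; entropy and
uniformity use the 0.5 Gy fixed-bin-width discretization so that they match
the gray levels the texture matrices see.
"""

from __future__ import annotations

import numpy as np

from ..volume import DoseVolume
from .discretize import DiscretizedVolume

FIRSTORDER_NAMES = (
    "energy",
    "total_energy",
    "entropy",
    "minimum",
    "p10",
    "p90",
    "maximum",
    "mean",
    "median",
    "interquartile_range",
    "range",
    "mean_absolute_deviation",
    "robust_mean_absolute_deviation",
    "root_mean_squared",
    "skewness",
    "kurtosis",
    "variance",
    "uniformity",
)


def first_order_features(
    disc: DiscretizedVolume, volume: DoseVolume, region: str
) -> dict[str, float]:
    """Compute the 18 first-order features of ``region``.

    Skewness is the standardized third central moment and kurtosis the
    (non-excess) standardized fourth moment; both are defined as 0 for a
    constant region.  Total energy scales energy by the voxel volume in mm3.
    """
    x = volume.region_doses(region)
    n = x.size
    mean = float(x.mean())
    var = float(np.mean((x - mean) ** 2))
    p10, p25, p75, p90 = (float(np.percentile(x, q)) for q in (10, 25, 75, 90))
    robust = x[(x >= p10) & (x <= p90)]

    levels = disc.in_mask_levels()
    p = np.bincount(levels)[1:] / n
    p = p[p > 0]

    if var > 0:
        skew = float(np.mean((x - mean) ** 3) / var**1.5)
        kurt = float(np.mean((x - mean) ** 4) / var**2)
    else:
        skew = 0.0
        kurt = 0.0

    energy = float(np.sum(x**2))
    return {
        "energy": energy,
        "total_energy": volume.voxel_volume_mm3 * energy,
        "entropy": float(-np.sum(p * np.log2(p))),
        "minimum": float(x.min()),
        "p10": p10,
        "p90": p90,
        "maximum": float(x.max()),
        "mean": mean,
        "median": float(np.median(x)),
        "interquartile_range": p75 - p25,
        "range": float(x.max() - x.min()),
        "mean_absolute_deviation": float(np.mean(np.abs(x - mean))),
        "robust_mean_absolute_deviation": float(np.mean(np.abs(robust - robust.mean()))),
        "root_mean_squared": float(np.sqrt(np.mean(x**2))),
        "skewness": skew,
        "kurtosis": kurt,
        "variance": var,
        "uniformity": float(np.sum(p**2)),
    }
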