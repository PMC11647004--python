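"""Mean dose and dose-volume-histogram indicators.

The 24 dose-volume indicators are 12 dose quantiles D_x and 12 volume
fractions V_d:

* ``D_x`` — minimum dose (Gy) received by the hottest x% of the region, i.e.
  the (100 - x)% quantile of the voxel dose distribution; D_70 is the 30%
  quantile, D_2 the clipping threshold.
* ``V_d`` — percentage of the region volume receiving at least d Gy.
"""

from __future__ import annotations

import numpy as np

from ..volume import DoseVolume

#: Hottest-percentage grid for D_x.
D_PERCENTAGES = (2, 5, 10, 20, 30, 40, 50, 60, 70, 80, 90, 98)
#: Dose thresholds (Gy) for V_d.
V_THRESHOLDS_GY = (1, 2, 5, 10, 15, 20, 25, 30, 35, 40, 45, 50)


def mean_dose(volume: DoseVolume, region: str) -> float:
    """Arithmetic mean of the in-mask voxel doses, in Gy."""
    return float(volume.region_doses(region).mean())


def dose_volume_indicators(volume: DoseVolume, region: str) -> dict[str, float]:
    """The 24 D_x / V_d indicators for ``region``.

    Quantiles use linear interpolation on the empirical distribution.
    """
    doses = volume.region_doses(region)
    out: dict[str, float] = {}
    for x in D_PERCENTAGES:
        out[f"D_{x}"] = float(np.percentile(doses, 100 - x))
    for d in V_THRESHOLDS_GY:
        out[f"V_{d}"] = float(100.0 * np.mean(doses >= d))
    return out
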