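"""Fixed-bin-width gray-level discretization of a dose region.

Texture matrices operate on positive integer gray levels.  Doses are binned
with a fixed width (0.5 Gy by default) anchored at the in-mask minimum dose:

    level(v) = floor((dose(v) - origin) / bin_width) + 1,  origin = min dose.

The in-mask maximum maps to the top level, so a uniform region has a single
level.  Anchoring the origin at the minimum makes every level-based texture
feature invariant to adding a constant dose offset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..volume import ConfigurationError, DoseVolume


@dataclass
class DiscretizedVolume:
    """Integer gray levels on the voxel grid; 0 marks out-of-mask voxels."""

    levels: np.ndarray  # int array, 0 outside mask, 1..n_levels inside
    mask: np.ndarray
    n_levels: int
    bin_width: float
    bin_origin: float

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def in_mask_levels(self) -> np.ndarray:
        return self.levels[self.mask]


def discretize(volume: DoseVolume, region: str, bin_width: float = 0.5) -> DiscretizedVolume:
    """Discretize the in-mask doses of ``region`` into gray levels."""
    if bin_width <= 0:
        raise ConfigurationError("bin_width must be positive")
    mask = volume.region_mask(region)
    doses = volume.values[mask]
    origin = float(doses.min())
    levels = np.zeros(volume.values.shape, dtype=np.int32)
    lev = np.floor((doses - origin) / bin_width).astype(np.int64) + 1
    n_levels = int(lev.max())
    levels[mask] = lev
    return DiscretizedVolume(
        levels=levels,
        mask=mask,
        n_levels=n_levels,
        bin_width=float(bin_width),
        bin_origin=origin,
    )
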