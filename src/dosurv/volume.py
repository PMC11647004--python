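"""Voxelized dose distributions and radiotherapy courses.

A :class:`DoseVolume` holds a 3D grid of absorbed dose (Gy) on an isotropic
voxel lattice together with binary region-of-interest masks for the heart and
its anatomical subparts.  A :class:`RTCourse` is the ordered sequence of dose
volumes delivered over the sessions of one radiotherapy course.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

#: Canonical region names.  ``whole_heart`` encloses the five subparts.
WHOLE_HEART = "whole_heart"
SUBPARTS = (
    "left_atrium",
    "right_atrium",
    "left_ventricle",
    "right_ventricle",
    "myocardium",
)
REGIONS = (WHOLE_HEART,) + SUBPARTS


class ConfigurationError(ValueError):
    """Raised for invalid shapes, spacings or region specifications."""


@dataclass
class DoseVolume:
    """Absorbed dose on a voxel grid with named binary region masks.

    Parameters
    ----------
    values
        3D array of dose in Gy; finite and non-negative.
    spacing
        Voxel edge length per axis in mm (default 2 mm isotropic).
    masks
        Mapping region name -> boolean array of the same shape as ``values``.
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ConfigurationError("dose grid must be 3D")
        if not np.all(np.isfinite(self.values)):
            raise ConfigurationError("dose values must be finite")
        if np.any(self.values < 0):
            raise ConfigurationError("dose values must be non-negative")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ConfigurationError("spacing must be three positive lengths")
        self.spacing = spacing
        for name, mask in self.masks.items():
            if name not in REGIONS:
                raise ConfigurationError(f"unknown region name: {name!r}")
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != self.values.shape:
                raise ConfigurationError(
                    f"mask {name!r} shape {mask.shape} != dose shape {self.values.shape}"
                )
            self.masks[name] = mask

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def region_mask(self, region: str) -> np.ndarray:
        try:
            mask = self.masks[region]
        except KeyError:
            raise ConfigurationError(f"volume has no mask for region {region!r}") from None
        if not mask.any():
            raise ConfigurationError(f"mask for region {region!r} is empty")
        return mask

    def region_doses(self, region: str) -> np.ndarray:
        """1D array of in-mask voxel doses for ``region``."""
        return self.values[self.region_mask(region)]

    def copy(self) -> "DoseVolume":
        return DoseVolume(
            values=self.values.copy(),
            spacing=self.spacing,
            masks={k: v.copy() for k, v in self.masks.items()},
        )


@dataclass
class RTCourse:
    """Ordered radiotherapy sessions for one patient on a common grid.

    ``sessions`` is a list of ``(start_offset_days, DoseVolume)`` pairs with
    non-decreasing offsets, the first at day 0.
    """

    sessions: list[tuple[float, DoseVolume]]

    def __post_init__(self) -> None:
        if not self.sessions:
            raise ConfigurationError("a course needs at least one session")
        offsets = [float(o) for o, _ in self.sessions]
        if offsets[0] != 0:
            raise ConfigurationError("first session offset must be 0 days")
        if any(b < a for a, b in zip(offsets, offsets[1:])):
            raise ConfigurationError("session offsets must be non-decreasing")

    @property
    def n_sessions(self) -> int:
        return len(self.sessions)


def _affine(spacing: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def save_volume(volume: DoseVolume, dose_path: str | Path, mask_dir: str | Path | None = None) -> None:
    """Write the dose grid (and optionally each region mask) as NIfTI."""
    dose_path = Path(dose_path)
    nib.save(nib.Nifti1Image(volume.values.astype(np.float32), _affine(volume.spacing)), dose_path)
    if mask_dir is not None:
        mask_dir = Path(mask_dir)
        mask_dir.mkdir(parents=True, exist_ok=True)
        for name, mask in volume.masks.items():
            img = nib.Nifti1Image(mask.astype(np.uint8), _affine(volume.spacing))
            nib.save(img, mask_dir / f"{name}.nii.gz")


def load_volume(dose_path: str | Path, mask_paths: dict[str, str | Path] | None = None) -> DoseVolume:
    """Read a dose grid and region masks from NIfTI files."""
    img = nib.load(str(dose_path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    values = np.asarray(img.dataobj, dtype=float)
    masks = {}
    if mask_paths:
        for name, path in mask_paths.items():
            masks[name] = np.asarray(nib.load(str(path)).dataobj) > 0
    return DoseVolume(values=values, spacing=spacing, masks=masks)
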