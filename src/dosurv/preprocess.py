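"""Per-patient dose preprocessing.

Multi-session courses are collapsed to one volume by summing, voxel by voxel,
all sessions that started within a six-month window of the first treatment;
later sessions are left out.  High-dose outlier voxels are then clipped at the
98% quantile of the in-heart dose distribution (the D_2 indicator).
"""

from __future__ import annotations

import numpy as np

from .volume import WHOLE_HEART, ConfigurationError, DoseVolume, RTCourse

#: Six months expressed in days; sessions starting at most this many days
#: after the first one are summed (boundary inclusive).
SUMMATION_WINDOW_DAYS = 183


def aggregate_sessions(course: RTCourse, window_days: float = SUMMATION_WINDOW_DAYS) -> DoseVolume:
    """Sum the session dose grids delivered within ``window_days`` of day 0.

    Sessions with a start offset strictly greater than ``window_days`` are
    ignored.  Masks (one anatomy per patient) are taken from the first
    session.  Raises if session grids disagree in shape or spacing.
    """
    first_offset, first = course.sessions[0]
    total = np.zeros_like(first.values)
    for offset, vol in course.sessions:
        if vol.values.shape != first.values.shape:
            raise ConfigurationError(
                f"session grid shape {vol.values.shape} != {first.values.shape}"
            )
        if vol.spacing != first.spacing:
            raise ConfigurationError("sessions must share voxel spacing")
        if offset <= window_days:
            total += vol.values
    return DoseVolume(
        values=total,
        spacing=first.spacing,
        masks={k: v.copy() for k, v in first.masks.items()},
    )


def clip_outliers(
    volume: DoseVolume, region: str = WHOLE_HEART, quantile: float = 0.98
) -> DoseVolume:
    """Clip in-mask doses at the empirical ``quantile`` of the region's doses.

    The threshold (D_2 when ``quantile`` is 0.98) is the order-statistic
    quantile — the largest observed dose at or below the requested rank — so
    clipping is exactly idempotent and the threshold is always an observed
    dose.  Voxels outside the mask are untouched; never dose-increasing.
    """
    if not 0 < quantile <= 1:
        raise ConfigurationError("quantile must be in (0, 1]")
    mask = volume.region_mask(region)
    q = float(np.quantile(volume.values[mask], quantile, method="lower"))
    out = volume.copy()
    out.values[mask] = np.minimum(out.values[mask], q)
    return out


def preprocess_course(
    course: RTCourse,
    window_days: float = SUMMATION_WINDOW_DAYS,
    clip_quantile: float = 0.98,
) -> DoseVolume:
    """Standard per-patient preprocessing: session summation then clipping."""
    vol = aggregate_sessions(course, window_days=window_days)
    return clip_outliers(vol, region=WHOLE_HEART, quantile=clip_quantile)
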