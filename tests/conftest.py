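"""Shared fixtures: small random masked volumes and censored datasets."""

from __future__ import annotations

import numpy as np
import pytest

from dosurv.volume import SUBPARTS, WHOLE_HEART, DoseVolume


def random_masked_volume(
    rng: np.random.Generator,
    max_shape: tuple[int, int, int] = (8, 8, 8),
    max_levels: int = 6,
    bin_width: float = 0.5,
) -> DoseVolume:
    """Small random dose volume with an irregular whole-heart mask.

    Doses are drawn on a lattice of at most ``max_levels`` distinct values
    spaced ``bin_width`` apart, so discretized gray levels are exact.
    """
    shape = tuple(int(rng.integers(3, s + 1)) for s in max_shape)
    mask = rng.random(shape) < 0.7
    if not mask.any():
        mask[tuple(s // 2 for s in shape)] = True
    levels = rng.integers(0, max_levels, size=shape)
    values = np.where(mask, levels * bin_width, 0.0)
    return DoseVolume(values=values, masks={WHOLE_HEART: mask})


def small_heart_volume(rng: np.random.Generator, shape=(12, 12, 12)) -> DoseVolume:
    """Dose volume with whole-heart plus all five subpart masks."""
    grid = np.ogrid[0 : shape[0], 0 : shape[1], 0 : shape[2]]
    c = [(s - 1) / 2 for s in shape]
    r2 = sum(((g - ci) / (0.45 * s)) ** 2 for g, ci, s in zip(grid, c, shape))
    whole = r2 <= 1.0
    shell = whole & (r2 > 0.5)
    interior = whole & ~shell
    left = np.zeros(shape, bool)
    left[: shape[0] // 2] = True
    top = np.zeros(shape, bool)
    top[:, :, shape[2] // 2 :] = True
    masks = {
        WHOLE_HEART: whole,
        "left_atrium": interior & left & top,
        "right_atrium": interior & ~left & top,
        "left_ventricle": interior & left & ~top,
        "right_ventricle": interior & ~left & ~top,
        "myocardium": shell,
    }
    assert all(m.any() for m in masks.values())
    values = np.where(whole, rng.gamma(2.0, 2.0, size=shape), 0.0)
    return DoseVolume(values=values, masks=masks)


def random_censored_dataset(rng: np.random.Generator, n: int | None = None):
    """(risk, time, event) with ties in times and moderate censoring."""
    n = n or int(rng.integers(30, 200))
    time = np.round(rng.exponential(10.0, n), 1) + 0.1
    event = rng.random(n) < rng.uniform(0.2, 0.7)
    if event.sum() == 0:
        event[rng.integers(n)] = True
    risk = rng.normal(size=n)
    return risk, time, event.astype(int)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20251001)


@pytest.fixture
def heart_volume(rng) -> DoseVolume:
    return small_heart_volume(rng)
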