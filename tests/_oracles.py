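"""Independent brute-force oracles for texture and metric computations.

Everything here is written as plain nested loops over voxels, pairs, runs,
zones and neighbourhoods, straight from the textbook definitions, so that the
package's vectorized implementations can be checked against an independent
code path.  Nothing in this module imports from :mod:`dosurv`.
"""

from __future__ import annotations

import math
from collections import defaultdict

import numpy as np

OFFSETS_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]
OFFSETS_13 = [o for o in OFFSETS_26 if o > (0, 0, 0)]


def _entropy(values) -> float:
    return -sum(p * math.log2(p) for p in values if p > 0)


def _in_bounds(idx, shape) -> bool:
    return all(0 <= i < s for i, s in zip(idx, shape))


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def glcm_counts(levels: np.ndarray, mask: np.ndarray, offset) -> dict:
    """Symmetric co-occurrence counts {(i, j): count} for one offset."""
    counts: dict = defaultdict(float)
    shape = levels.shape
    for idx in np.ndindex(shape):
        if not mask[idx]:
            continue
        nb = tuple(i + o for i, o in zip(idx, offset))
        if _in_bounds(nb, shape) and mask[nb]:
            a, b = int(levels[idx]), int(levels[nb])
            counts[(a, b)] += 1
            counts[(b, a)] += 1
    return dict(counts)


def glcm_features_single(counts: dict, n_levels_present: int | None = None) -> dict:
    """The 24 co-occurrence features from a counts dict, by scalar loops."""
    total = sum(counts.values())
    p = {k: v / total for k, v in counts.items()}
    levels = sorted({i for i, _ in p} | {j for _, j in p})
    ng = len(levels)
    px = {i: sum(p.get((i, j), 0.0) for j in levels) for i in levels}
    py = {j: sum(p.get((i, j), 0.0) for i in levels) for j in levels}
    ux = sum(i * px[i] for i in levels)
    uy = sum(j * py[j] for j in levels)
    sx = math.sqrt(sum(px[i] * (i - ux) ** 2 for i in levels))
    sy = math.sqrt(sum(py[j] * (j - uy) ** 2 for j in levels))

    p_diff = defaultdict(float)
    p_sum = defaultdict(float)
    for (i, j), v in p.items():
        p_diff[abs(i - j)] += v
        p_sum[i + j] += v
    da = sum(k * v for k, v in p_diff.items())

    autocorr = sum(v * i * j for (i, j), v in p.items())
    hx = _entropy(px.values())
    hy = _entropy(py.values())
    hxy = _entropy(p.values())
    hxy1 = -sum(v * math.log2(px[i] * py[j]) for (i, j), v in p.items() if px[i] * py[j] > 0)
    hxy2 = -sum(
        px[i] * py[j] * math.log2(px[i] * py[j])
        for i in levels
        for j in levels
        if px[i] * py[j] > 0
    )
    imc1 = (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    imc2 = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy))))

    if ng > 1:
        q = np.zeros((ng, ng))
        for a, i in enumerate(levels):
            for b, j in enumerate(levels):
                q[a, b] = sum(
                    p.get((i, k), 0.0) * p.get((j, k), 0.0) / (px[i] * py[k])
                    for k in levels
                    if px[i] > 0 and py[k] > 0
                )
        eig = sorted(np.real(np.linalg.eigvals(q)))
        mcc = math.sqrt(max(0.0, eig[-2]))
    else:
        mcc = 1.0

    corr = (autocorr - ux * uy) / (sx * sy) if sx > 0 and sy > 0 else 1.0
    return {
        "autocorrelation": autocorr,
        "joint_average": ux,
        "cluster_prominence": sum(v * (i + j - ux - uy) ** 4 for (i, j), v in p.items()),
        "cluster_shade": sum(v * (i + j - ux - uy) ** 3 for (i, j), v in p.items()),
        "cluster_tendency": sum(v * (i + j - ux - uy) ** 2 for (i, j), v in p.items()),
        "contrast": sum(v * (i - j) ** 2 for (i, j), v in p.items()),
        "correlation": corr,
        "difference_average": da,
        "difference_entropy": _entropy(p_diff.values()),
        "difference_variance": sum(v * (k - da) ** 2 for k, v in p_diff.items()),
        "inverse_difference": sum(v / (1 + k) for k, v in p_diff.items()),
        "inverse_difference_moment": sum(v / (1 + k**2) for k, v in p_diff.items()),
        "inverse_difference_moment_normalized": sum(
            v / (1 + (k / ng) ** 2) for k, v in p_diff.items()
        ),
        "inverse_difference_normalized": sum(v / (1 + k / ng) for k, v in p_diff.items()),
        "imc1": imc1,
        "imc2": imc2,
        "inverse_variance": sum(v / k**2 for k, v in p_diff.items() if k >= 1),
        "joint_energy": sum(v**2 for v in p.values()),
        "joint_entropy": hxy,
        "mcc": mcc,
        "maximum_probability": max(p.values()),
        "sum_average": sum(k * v for k, v in p_sum.items()),
        "sum_entropy": _entropy(p_sum.values()),
        "sum_squares": sum(v * (i - ux) ** 2 for (i, j), v in p.items()),
    }


def glcm_features(levels: np.ndarray, mask: np.ndarray) -> dict:
    per_dir = []
    for off in OFFSETS_13:
        counts = glcm_counts(levels, mask, off)
        if counts:
            per_dir.append(glcm_features_single(counts))
    names = per_dir[0].keys()
    return {n: float(np.mean([f[n] for f in per_dir])) for n in names}


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------

def run_length_counts(levels: np.ndarray, mask: np.ndarray, offset) -> dict:
    """{(level, run_length): count} for maximal runs along one offset."""
    counts: dict = defaultdict(float)
    shape = levels.shape
    for idx in np.ndindex(shape):
        if not mask[idx]:
            continue
        prev = tuple(i - o for i, o in zip(idx, offset))
        if _in_bounds(prev, shape) and mask[prev] and levels[prev] == levels[idx]:
            continue  # not the start of a run
        length = 1
        cur = idx
        while True:
            nxt = tuple(i + o for i, o in zip(cur, offset))
            if _in_bounds(nxt, shape) and mask[nxt] and levels[nxt] == levels[idx]:
                length += 1
                cur = nxt
            else:
                break
        counts[(int(levels[idx]), length)] += 1
    return dict(counts)


def size_distribution_features(counts: dict, n_voxels: int) -> dict:
    """Shared 16 features of a {(gray level, size): count} matrix."""
    nz = sum(counts.values())
    p = {k: v / nz for k, v in counts.items()}
    glevels = sorted({g for g, _ in counts})
    sizes = sorted({s for _, s in counts})
    pg = {g: sum(p.get((g, s), 0.0) for s in sizes) for g in glevels}
    ps = {s: sum(p.get((g, s), 0.0) for g in glevels) for s in sizes}
    mu_g = sum(g * pg[g] for g in glevels)
    mu_s = sum(s * ps[s] for s in sizes)
    return {
        "small": sum(v / s**2 for (g, s), v in counts.items()) / nz,
        "large": sum(v * s**2 for (g, s), v in counts.items()) / nz,
        "gln": sum((pg[g] * nz) ** 2 for g in glevels) / nz,
        "glnn": sum((pg[g] * nz) ** 2 for g in glevels) / nz**2,
        "sn": sum((ps[s] * nz) ** 2 for s in sizes) / nz,
        "snn": sum((ps[s] * nz) ** 2 for s in sizes) / nz**2,
        "pct": nz / n_voxels,
        "glv": sum(v * (g - mu_g) ** 2 for (g, s), v in p.items()),
        "sv": sum(v * (s - mu_s) ** 2 for (g, s), v in p.items()),
        "ent": _entropy(p.values()),
        "lgl": sum(v / g**2 for (g, s), v in counts.items()) / nz,
        "hgl": sum(v * g**2 for (g, s), v in counts.items()) / nz,
        "slgl": sum(v / (g**2 * s**2) for (g, s), v in counts.items()) / nz,
        "shgl": sum(v * g**2 / s**2 for (g, s), v in counts.items()) / nz,
        "llgl": sum(v * s**2 / g**2 for (g, s), v in counts.items()) / nz,
        "lhgl": sum(v * g**2 * s**2 for (g, s), v in counts.items()) / nz,
    }


_GLRLM_KEYS = (
    "short_run_emphasis", "long_run_emphasis", "gray_level_nonuniformity",
    "gray_level_nonuniformity_normalized", "run_length_nonuniformity",
    "run_length_nonuniformity_normalized", "run_percentage", "gray_level_variance",
    "run_variance", "run_entropy", "low_gray_level_run_emphasis",
    "high_gray_level_run_emphasis", "short_run_low_gray_level_emphasis",
    "short_run_high_gray_level_emphasis", "long_run_low_gray_level_emphasis",
    "long_run_high_gray_level_emphasis",
)
_GLSZM_KEYS = (
    "small_area_emphasis", "large_area_emphasis", "gray_level_nonuniformity",
    "gray_level_nonuniformity_normalized", "size_zone_nonuniformity",
    "size_zone_nonuniformity_normalized", "zone_percentage", "gray_level_variance",
    "zone_variance", "zone_entropy", "low_gray_level_zone_emphasis",
    "high_gray_level_zone_emphasis", "small_area_low_gray_level_emphasis",
    "small_area_high_gray_level_emphasis", "large_area_low_gray_level_emphasis",
    "large_area_high_gray_level_emphasis",
)
_ORDER = (
    "small", "large", "gln", "glnn", "sn", "snn", "pct", "glv", "sv", "ent",
    "lgl", "hgl", "slgl", "shgl", "llgl", "lhgl",
)


def glrlm_features(levels: np.ndarray, mask: np.ndarray) -> dict:
    n_vox = int(mask.sum())
    per_dir = []
    for off in OFFSETS_13:
        vals = size_distribution_features(run_length_counts(levels, mask, off), n_vox)
        per_dir.append({k: vals[o] for k, o in zip(_GLRLM_KEYS, _ORDER)})
    return {k: float(np.mean([f[k] for f in per_dir])) for k in _GLRLM_KEYS}


# ---------------------------------------------------------------------------
# GLSZM
# ---------------------------------------------------------------------------

def zone_counts(levels: np.ndarray, mask: np.ndarray) -> dict:
    """{(level, zone_size): count} by depth-first flood fill, 26-connected."""
    shape = levels.shape
    seen = np.zeros(shape, dtype=bool)
    counts: dict = defaultdict(float)
    for idx in np.ndindex(shape):
        if not mask[idx] or seen[idx]:
            continue
        level = int(levels[idx])
        stack = [idx]
        seen[idx] = True
        size = 0
        while stack:
            cur = stack.pop()
            size += 1
            for off in OFFSETS_26:
                nb = tuple(i + o for i, o in zip(cur, off))
                if (
                    _in_bounds(nb, shape)
                    and mask[nb]
                    and not seen[nb]
                    and int(levels[nb]) == level
                ):
                    seen[nb] = True
                    stack.append(nb)
        counts[(level, size)] += 1
    return dict(counts)


def glszm_features(levels: np.ndarray, mask: np.ndarray) -> dict:
    vals = size_distribution_features(zone_counts(levels, mask), int(mask.sum()))
    return {k: vals[o] for k, o in zip(_GLSZM_KEYS, _ORDER)}


# ---------------------------------------------------------------------------
# NGTDM
# ---------------------------------------------------------------------------

def ngtdm_features(levels: np.ndarray, mask: np.ndarray) -> dict:
    shape = levels.shape
    n = defaultdict(int)
    s = defaultdict(float)
    nvp = 0
    for idx in np.ndindex(shape):
        if not mask[idx]:
            continue
        nbs = []
        for off in OFFSETS_26:
            nb = tuple(i + o for i, o in zip(idx, off))
            if _in_bounds(nb, shape) and mask[nb]:
                nbs.append(int(levels[nb]))
        if not nbs:
            continue
        nvp += 1
        g = int(levels[idx])
        n[g] += 1
        s[g] += abs(g - sum(nbs) / len(nbs))
    p = {g: n[g] / nvp for g in n}
    glevels = sorted(p)
    ngp = len(glevels)
    coarse_den = sum(p[g] * s[g] for g in glevels)
    coarseness = 1.0 / coarse_den if coarse_den > 0 else 1e6
    if ngp > 1:
        contrast = (
            sum(p[i] * p[j] * (i - j) ** 2 for i in glevels for j in glevels)
            / (ngp * (ngp - 1))
            * sum(s.values())
            / nvp
        )
        busy_den = sum(abs(i * p[i] - j * p[j]) for i in glevels for j in glevels)
        busyness = coarse_den / busy_den if busy_den > 0 else 0.0
        complexity = (
            sum(
                abs(i - j) * (p[i] * s[i] + p[j] * s[j]) / (p[i] + p[j])
                for i in glevels
                for j in glevels
            )
            / nvp
        )
        s_total = sum(s.values())
        strength = (
            sum((p[i] + p[j]) * (i - j) ** 2 for i in glevels for j in glevels) / s_total
            if s_total > 0
            else 0.0
        )
    else:
        contrast = busyness = complexity = strength = 0.0
    return {
        "coarseness": coarseness,
        "contrast": contrast,
        "busyness": busyness,
        "complexity": complexity,
        "strength": strength,
    }


# ---------------------------------------------------------------------------
# GLDM
# ---------------------------------------------------------------------------

def dependence_counts(levels: np.ndarray, mask: np.ndarray, alpha: int = 0) -> dict:
    """{(level, dependence): count}; the centre voxel depends on itself."""
    shape = levels.shape
    counts: dict = defaultdict(float)
    for idx in np.ndindex(shape):
        if not mask[idx]:
            continue
        dep = 1
        for off in OFFSETS_26:
            nb = tuple(i + o for i, o in zip(idx, off))
            if _in_bounds(nb, shape) and mask[nb] and abs(int(levels[nb]) - int(levels[idx])) <= alpha:
                dep += 1
        counts[(int(levels[idx]), dep)] += 1
    return dict(counts)


def gldm_features(levels: np.ndarray, mask: np.ndarray, alpha: int = 0) -> dict:
    counts = dependence_counts(levels, mask, alpha)
    nz = sum(counts.values())
    p = {k: v / nz for k, v in counts.items()}
    glevels = sorted({g for g, _ in counts})
    deps = sorted({d for _, d in counts})
    pg = {g: sum(p.get((g, d), 0.0) for d in deps) for g in glevels}
    pd_ = {d: sum(p.get((g, d), 0.0) for g in glevels) for d in deps}
    mu_g = sum(g * pg[g] for g in glevels)
    mu_d = sum(d * pd_[d] for d in deps)
    return {
        "small_dependence_emphasis": sum(v / d**2 for (g, d), v in counts.items()) / nz,
        "large_dependence_emphasis": sum(v * d**2 for (g, d), v in counts.items()) / nz,
        "gray_level_nonuniformity": sum((pg[g] * nz) ** 2 for g in glevels) / nz,
        "dependence_nonuniformity": sum((pd_[d] * nz) ** 2 for d in deps) / nz,
        "dependence_nonuniformity_normalized": sum((pd_[d] * nz) ** 2 for d in deps) / nz**2,
        "gray_level_variance": sum(v * (g - mu_g) ** 2 for (g, d), v in p.items()),
        "dependence_variance": sum(v * (d - mu_d) ** 2 for (g, d), v in p.items()),
        "dependence_entropy": _entropy(p.values()),
        "low_gray_level_emphasis": sum(v / g**2 for (g, d), v in counts.items()) / nz,
        "high_gray_level_emphasis": sum(v * g**2 for (g, d), v in counts.items()) / nz,
        "small_dependence_low_gray_level_emphasis": sum(
            v / (g**2 * d**2) for (g, d), v in counts.items()
        )
        / nz,
        "small_dependence_high_gray_level_emphasis": sum(
            v * g**2 / d**2 for (g, d), v in counts.items()
        )
        / nz,
        "large_dependence_low_gray_level_emphasis": sum(
            v * d**2 / g**2 for (g, d), v in counts.items()
        )
        / nz,
        "large_dependence_high_gray_level_emphasis": sum(
            v * g**2 * d**2 for (g, d), v in counts.items()
        )
        / nz,
    }


# ---------------------------------------------------------------------------
# First order and DVH
# ---------------------------------------------------------------------------

def first_order_features(doses: np.ndarray, levels: np.ndarray, voxel_volume: float) -> dict:
    x = np.asarray(doses, float)
    n = x.size
    mean = x.mean()
    var = float(np.mean((x - mean) ** 2))
    hist = defaultdict(int)
    for lv in levels:
        hist[int(lv)] += 1
    p = [c / n for c in hist.values()]
    p10, p90 = np.percentile(x, 10), np.percentile(x, 90)
    robust = x[(x >= p10) & (x <= p90)]
    return {
        "energy": float(np.sum(x**2)),
        "total_energy": voxel_volume * float(np.sum(x**2)),
        "entropy": _entropy(p),
        "minimum": float(x.min()),
        "p10": float(p10),
        "p90": float(p90),
        "maximum": float(x.max()),
        "mean": float(mean),
        "median": float(np.median(x)),
        "interquartile_range": float(np.percentile(x, 75) - np.percentile(x, 25)),
        "range": float(x.max() - x.min()),
        "mean_absolute_deviation": float(np.mean(np.abs(x - mean))),
        "robust_mean_absolute_deviation": float(np.mean(np.abs(robust - robust.mean()))),
        "root_mean_squared": float(np.sqrt(np.mean(x**2))),
        "skewness": float(np.mean((x - mean) ** 3) / var**1.5) if var > 0 else 0.0,
        "kurtosis": float(np.mean((x - mean) ** 4) / var**2) if var > 0 else 0.0,
        "variance": var,
        "uniformity": float(sum(q**2 for q in p)),
    }


def dvh_indicators(doses: np.ndarray) -> dict:
    """All 24 D_x / V_d values by explicit sorting and counting."""
    x = np.sort(np.asarray(doses, float))
    out = {}
    for pct in (2, 5, 10, 20, 30, 40, 50, 60, 70, 80, 90, 98):
        out[f"D_{pct}"] = float(np.percentile(x, 100 - pct))
    for d in (1, 2, 5, 10, 15, 20, 25, 30, 35, 40, 45, 50):
        out[f"V_{d}"] = 100.0 * float(np.sum(x >= d)) / x.size
    return out


# ---------------------------------------------------------------------------
# Survival metrics
# ---------------------------------------------------------------------------

def harrell_c_pairs(risk, time, event) -> float:
    """Concordance by explicit enumeration over all ordered pairs."""
    num = den = 0.0
    n = len(time)
    for i in range(n):
        if not event[i]:
            continue
        for j in range(n):
            if j == i:
                continue
            comparable = time[j] > time[i] or (time[j] == time[i] and not event[j])
            if not comparable:
                continue
            den += 1
            if risk[i] > risk[j] + 1e-8:
                num += 1
            elif abs(risk[i] - risk[j]) <= 1e-8:
                num += 0.5
    return num / den
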