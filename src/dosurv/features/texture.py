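"""Texture features of a discretized 3D dose region.

Five gray-level matrix families are implemented — co-occurrence (GLCM,
24 features), run length (GLRLM, 16), size zone (GLSZM, 16), neighbouring
gray-tone difference (NGTDM, 5) and dependence (GLDM, 14).  All families use
distance-1 neighbourhoods with 26-connectivity (13 unique direction vectors);
GLCM and GLRLM build one matrix per direction, compute features per direction
and average them, GLSZM/NGTDM/GLDM are direction-free.

Gray-level weights in the formulas are the actual discretized level values;
rows/columns for absent levels are dropped, and ``Ng`` counts the distinct
levels present in the region.  Degenerate single-level regions keep every
feature finite: entropies are 0, energies 1, and correlation-type features 1.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .discretize import DiscretizedVolume

#: The 13 unique direction vectors of a 26-connected 3D neighbourhood
#: (one representative per +/- pair).
DIRECTIONS_13 = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)

GLCM_NAMES = (
    "autocorrelation",
    "joint_average",
    "cluster_prominence",
    "cluster_shade",
    "cluster_tendency",
    "contrast",
    "correlation",
    "difference_average",
    "difference_entropy",
    "difference_variance",
    "inverse_difference",
    "inverse_difference_moment",
    "inverse_difference_moment_normalized",
    "inverse_difference_normalized",
    "imc1",
    "imc2",
    "inverse_variance",
    "joint_energy",
    "joint_entropy",
    "mcc",
    "maximum_probability",
    "sum_average",
    "sum_entropy",
    "sum_squares",
)

GLRLM_NAMES = (
    "short_run_emphasis",
    "long_run_emphasis",
    "gray_level_nonuniformity",
    "gray_level_nonuniformity_normalized",
    "run_length_nonuniformity",
    "run_length_nonuniformity_normalized",
    "run_percentage",
    "gray_level_variance",
    "run_variance",
    "run_entropy",
    "low_gray_level_run_emphasis",
    "high_gray_level_run_emphasis",
    "short_run_low_gray_level_emphasis",
    "short_run_high_gray_level_emphasis",
    "long_run_low_gray_level_emphasis",
    "long_run_high_gray_level_emphasis",
)

GLSZM_NAMES = (
    "small_area_emphasis",
    "large_area_emphasis",
    "gray_level_nonuniformity",
    "gray_level_nonuniformity_normalized",
    "size_zone_nonuniformity",
    "size_zone_nonuniformity_normalized",
    "zone_percentage",
    "gray_level_variance",
    "zone_variance",
    "zone_entropy",
    "low_gray_level_zone_emphasis",
    "high_gray_level_zone_emphasis",
    "small_area_low_gray_level_emphasis",
    "small_area_high_gray_level_emphasis",
    "large_area_low_gray_level_emphasis",
    "large_area_high_gray_level_emphasis",
)

NGTDM_NAMES = ("coarseness", "contrast", "busyness", "complexity", "strength")

GLDM_NAMES = (
    "small_dependence_emphasis",
    "large_dependence_emphasis",
    "gray_level_nonuniformity",
    "dependence_nonuniformity",
    "dependence_nonuniformity_normalized",
    "gray_level_variance",
    "dependence_variance",
    "dependence_entropy",
    "low_gray_level_emphasis",
    "high_gray_level_emphasis",
    "small_dependence_low_gray_level_emphasis",
    "small_dependence_high_gray_level_emphasis",
    "large_dependence_low_gray_level_emphasis",
    "large_dependence_high_gray_level_emphasis",
)

TEXTURE_FAMILIES = {
    "GLCM": GLCM_NAMES,
    "GLRLM": GLRLM_NAMES,
    "GLSZM": GLSZM_NAMES,
    "NGTDM": NGTDM_NAMES,
    "GLDM": GLDM_NAMES,
}


def _shifted_views(arr: np.ndarray, offset: tuple[int, int, int]):
    """Return (base_view, shifted_view): base[v] pairs with shifted[v] = arr[v + offset]."""
    slices_a, slices_b = [], []
    for d, size in zip(offset, arr.shape):
        if d >= 0:
            slices_a.append(slice(0, size - d))
            slices_b.append(slice(d, size))
        else:
            slices_a.append(slice(-d, size))
            slices_b.append(slice(0, size + d))
    return arr[tuple(slices_a)], arr[tuple(slices_b)]


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)))


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def glcm_matrices(disc: DiscretizedVolume) -> list[np.ndarray]:
    """Symmetric co-occurrence count matrices, one per direction.

    Matrix entry (a, b) counts ordered in-mask voxel pairs at the given
    offset with levels (a+1, b+1); each unordered pair is counted twice.
    """
    lev = np.where(disc.mask, disc.levels, 0)
    ng = disc.n_levels
    out = []
    for off in DIRECTIONS_13:
        a, b = _shifted_views(lev, off)
        valid = (a > 0) & (b > 0)
        ia, ib = a[valid] - 1, b[valid] - 1
        counts = np.bincount(ia * ng + ib, minlength=ng * ng).reshape(ng, ng).astype(float)
        out.append(counts + counts.T)
    return out


def _glcm_features_single(counts: np.ndarray) -> dict[str, float]:
    total = counts.sum()
    if total == 0:
        # no valid voxel pair along this direction
        return {name: np.nan for name in GLCM_NAMES}
    present = np.flatnonzero(counts.sum(axis=0) + counts.sum(axis=1))
    g = (present + 1).astype(float)  # actual gray level values
    p = counts[np.ix_(present, present)] / total
    ng = g.size

    px = p.sum(axis=1)
    py = p.sum(axis=0)
    ux = float(np.sum(g * px))
    uy = float(np.sum(g * py))
    sx = float(np.sqrt(np.sum(px * (g - ux) ** 2)))
    sy = float(np.sqrt(np.sum(py * (g - uy) ** 2)))

    gi = g[:, None]
    gj = g[None, :]
    autocorr = float(np.sum(p * gi * gj))

    # distributions of level sums and absolute differences
    ks = np.abs(gi - gj).astype(int)
    p_diff = np.bincount(ks.ravel(), weights=p.ravel())
    kd = np.arange(p_diff.size, dtype=float)
    sums = (gi + gj).astype(int)
    p_sum = np.bincount(sums.ravel(), weights=p.ravel())
    km = np.arange(p_sum.size, dtype=float)

    diff_avg = float(np.sum(kd * p_diff))

    hx = _entropy(px)
    hy = _entropy(py)
    hxy = _entropy(p)
    outer = px[:, None] * py[None, :]
    pos = (p > 0) & (outer > 0)
    hxy1 = float(-np.sum(p[pos] * np.log2(outer[pos])))
    opos = outer > 0
    hxy2 = float(-np.sum(outer[opos] * np.log2(outer[opos])))
    denom = max(hx, hy)
    imc1 = float((hxy - hxy1) / denom) if denom > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    if ng > 1:
        q = (p / px[:, None]) @ (p / py[None, :]).T  # Q[i,j] = sum_k p(i,k) p(j,k) / (px(i) py(k))
        eig = np.linalg.eigvals(q)
        eig = np.sort(np.real(eig))
        mcc = float(np.sqrt(max(0.0, eig[-2])))
    else:
        mcc = 1.0

    corr = float((autocorr - ux * uy) / (sx * sy)) if sx > 0 and sy > 0 else 1.0

    inv_var_mask = kd >= 1
    return {
        "autocorrelation": autocorr,
        "joint_average": ux,
        "cluster_prominence": float(np.sum(p * (gi + gj - ux - uy) ** 4)),
        "cluster_shade": float(np.sum(p * (gi + gj - ux - uy) ** 3)),
        "cluster_tendency": float(np.sum(p * (gi + gj - ux - uy) ** 2)),
        "contrast": float(np.sum(p * (gi - gj) ** 2)),
        "correlation": corr,
        "difference_average": diff_avg,
        "difference_entropy": _entropy(p_diff),
        "difference_variance": float(np.sum((kd - diff_avg) ** 2 * p_diff)),
        "inverse_difference": float(np.sum(p_diff / (1.0 + kd))),
        "inverse_difference_moment": float(np.sum(p_diff / (1.0 + kd**2))),
        "inverse_difference_moment_normalized": float(np.sum(p_diff / (1.0 + (kd / ng) ** 2))),
        "inverse_difference_normalized": float(np.sum(p_diff / (1.0 + kd / ng))),
        "imc1": imc1,
        "imc2": imc2,
        "inverse_variance": float(np.sum(p_diff[inv_var_mask] / kd[inv_var_mask] ** 2)),
        "joint_energy": float(np.sum(p**2)),
        "joint_entropy": hxy,
        "mcc": mcc,
        "maximum_probability": float(p.max()),
        "sum_average": float(np.sum(km * p_sum)),
        "sum_entropy": _entropy(p_sum),
        "sum_squares": float(np.sum(p * (gi - ux) ** 2)),
    }


def glcm_features(disc: DiscretizedVolume) -> dict[str, float]:
    """The 24 co-occurrence features, averaged over the 13 directions."""
    per_dir = [_glcm_features_single(m) for m in glcm_matrices(disc)]
    return {
        name: float(np.nanmean([f[name] for f in per_dir])) for name in GLCM_NAMES
    }


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------

def run_length_matrix(disc: DiscretizedVolume, offset: tuple[int, int, int]) -> np.ndarray:
    """Run-length count matrix along one direction.

    Entry (i, j) counts maximal runs of j+1 consecutive in-mask voxels with
    gray level i+1 along the direction; out-of-mask voxels break runs.
    In-mask voxels are ordered lexicographically by (line identifier,
    position along the line) and runs are read off with one pass.
    """
    coords = np.argwhere(disc.mask)
    lv = disc.levels[disc.mask].astype(np.int64)
    d = np.asarray(offset)
    step = int(d @ d)  # position increment between consecutive line voxels
    s = coords @ d
    # cross-product components identify the line through each voxel
    k1 = coords[:, 1] * d[2] - coords[:, 2] * d[1]
    k2 = coords[:, 2] * d[0] - coords[:, 0] * d[2]
    k3 = coords[:, 0] * d[1] - coords[:, 1] * d[0]
    order = np.lexsort((s, k3, k2, k1))
    s, k1, k2, k3, lv = s[order], k1[order], k2[order], k3[order], lv[order]
    breaks = (
        (np.diff(k1) != 0)
        | (np.diff(k2) != 0)
        | (np.diff(k3) != 0)
        | (np.diff(s) != step)
        | (np.diff(lv) != 0)
    )
    starts = np.r_[0, np.flatnonzero(breaks) + 1]
    lengths = np.diff(np.r_[starts, lv.size])
    levels_of_runs = lv[starts]
    ng = disc.n_levels
    max_len = int(lengths.max())
    idx = (levels_of_runs - 1) * max_len + (lengths - 1)
    return np.bincount(idx, minlength=ng * max_len).reshape(ng, max_len).astype(float)


def _size_distribution_features(counts: np.ndarray, n_voxels: int, names: tuple[str, ...], kind: str) -> dict[str, float]:
    """Shared formula block for GLRLM/GLSZM-style (gray level x size) matrices.

    Every emphasis feature factorizes over the gray-level and size marginals
    (or a single matrix-vector product), so no full-matrix temporaries are
    needed except for the entropy.
    """
    nz = counts.sum()
    ng_axis = counts.sum(axis=1)
    ns_axis = counts.sum(axis=0)
    g = np.arange(1, counts.shape[0] + 1, dtype=float)
    j = np.arange(1, counts.shape[1] + 1, dtype=float)
    g2, jinv2, j2 = g**2, 1.0 / j**2, j**2
    mu_g = float((g * ng_axis).sum() / nz)
    mu_j = float((j * ns_axis).sum() / nz)
    a_small = counts @ jinv2  # per gray level: sum_j counts / j^2
    a_large = counts @ j2
    p = counts / nz
    vals = {
        "small": float(a_small.sum() / nz),
        "large": float(a_large.sum() / nz),
        "gln": float((ng_axis**2).sum() / nz),
        "glnn": float((ng_axis**2).sum() / nz**2),
        "sn": float((ns_axis**2).sum() / nz),
        "snn": float((ns_axis**2).sum() / nz**2),
        "pct": float(nz / n_voxels),
        "glv": float((ng_axis * (g - mu_g) ** 2).sum() / nz),
        "sv": float((ns_axis * (j - mu_j) ** 2).sum() / nz),
        "ent": _entropy(p.ravel()),
        "lgl": float((ng_axis / g2).sum() / nz),
        "hgl": float((ng_axis * g2).sum() / nz),
        "slgl": float((a_small / g2).sum() / nz),
        "shgl": float((a_small * g2).sum() / nz),
        "llgl": float((a_large / g2).sum() / nz),
        "lhgl": float((a_large * g2).sum() / nz),
    }
    order = (
        "small", "large", "gln", "glnn", "sn", "snn", "pct", "glv", "sv",
        "ent", "lgl", "hgl", "slgl", "shgl", "llgl", "lhgl",
    )
    return dict(zip(names, (vals[k] for k in order)))


def glrlm_features(disc: DiscretizedVolume) -> dict[str, float]:
    """The 16 run-length features, averaged over the 13 directions."""
    n = disc.n_voxels
    per_dir = [
        _size_distribution_features(run_length_matrix(disc, off), n, GLRLM_NAMES, "run")
        for off in DIRECTIONS_13
    ]
    return {name: float(np.mean([f[name] for f in per_dir])) for name in GLRLM_NAMES}


# ---------------------------------------------------------------------------
# GLSZM
# ---------------------------------------------------------------------------

def size_zone_matrix(disc: DiscretizedVolume) -> np.ndarray:
    """Zone count matrix: entry (i, s) counts 26-connected zones of level i+1 and size s+1."""
    lev = np.where(disc.mask, disc.levels, 0)
    zones: list[tuple[int, int]] = []
    for level in np.unique(lev[lev > 0]):
        labels, n_comp = ndimage.label(lev == level, structure=_STRUCT_26)
        sizes = np.bincount(labels.ravel())[1:]
        zones.extend((int(level), int(s)) for s in sizes)
    ng = disc.n_levels
    max_size = max(s for _, s in zones)
    counts = np.zeros((ng, max_size))
    for level, s in zones:
        counts[level - 1, s - 1] += 1
    return counts


def glszm_features(disc: DiscretizedVolume) -> dict[str, float]:
    """The 16 size-zone features."""
    return _size_distribution_features(size_zone_matrix(disc), disc.n_voxels, GLSZM_NAMES, "zone")


# ---------------------------------------------------------------------------
# NGTDM
# ---------------------------------------------------------------------------

def ngtdm_table(disc: DiscretizedVolume) -> tuple[np.ndarray, np.ndarray, int]:
    """Per-level counts n_i and summed gray-tone differences s_i.

    For each in-mask voxel with at least one in-mask 26-neighbour, the
    absolute difference between its level and the mean level of those
    neighbours is accumulated into its level's s_i.  Returns (n, s, n_valid)
    with arrays indexed by level-1.
    """
    lev = np.where(disc.mask, disc.levels, 0).astype(float)
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0
    nb_sum = ndimage.correlate(lev, kernel, mode="constant", cval=0.0)
    nb_cnt = ndimage.correlate(disc.mask.astype(float), kernel, mode="constant", cval=0.0)
    valid = disc.mask & (nb_cnt > 0.5)
    ng = disc.n_levels
    n = np.zeros(ng)
    s = np.zeros(ng)
    idx = disc.levels[valid] - 1
    diffs = np.abs(lev[valid] - nb_sum[valid] / nb_cnt[valid])
    np.add.at(n, idx, 1.0)
    np.add.at(s, idx, diffs)
    return n, s, int(valid.sum())


def ngtdm_features(disc: DiscretizedVolume) -> dict[str, float]:
    """The 5 neighbouring gray-tone difference features."""
    n, s, nvp = ngtdm_table(disc)
    p = n / nvp
    g = np.arange(1, n.size + 1, dtype=float)
    present = p > 0
    ngp = int(present.sum())
    gp, pp, sp = g[present], p[present], s[present]

    coarse_den = float(np.sum(pp * sp))
    coarseness = 1.0 / coarse_den if coarse_den > 0 else 1e6

    if ngp > 1:
        pi = pp[:, None]
        pj = pp[None, :]
        gi = gp[:, None]
        gj = gp[None, :]
        contrast = float(
            np.sum(pi * pj * (gi - gj) ** 2) / (ngp * (ngp - 1)) * np.sum(sp) / nvp
        )
        busy_den = float(np.sum(np.abs(gi * pi - gj * pj)))
        busyness = coarse_den / busy_den if busy_den > 0 else 0.0
        complexity = float(np.sum(np.abs(gi - gj) * (pi * sp[:, None] + pj * sp[None, :]) / (pi + pj)) / nvp)
        s_sum = float(np.sum(sp))
        strength = float(np.sum((pi + pj) * (gi - gj) ** 2)) / s_sum if s_sum > 0 else 0.0
    else:
        contrast = 0.0
        busyness = 0.0
        complexity = 0.0
        strength = 0.0
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

def dependence_matrix(disc: DiscretizedVolume, alpha: int = 0) -> np.ndarray:
    """Gray-level dependence count matrix.

    A 26-neighbour is dependent on its centre voxel when the absolute level
    difference is at most ``alpha``; the centre counts itself, so dependence
    sizes start at 1.  Entry (i, d) counts voxels of level i+1 with
    dependence size d+1.
    """
    lev = np.where(disc.mask, disc.levels, 0)
    dep = np.ones(lev.shape, dtype=np.int64)  # self-dependence
    for off in DIRECTIONS_13:
        a, b = _shifted_views(lev, off)
        close = (a > 0) & (b > 0) & (np.abs(a - b) <= alpha)
        sl_a, sl_b = [], []
        for d, size in zip(off, lev.shape):
            if d >= 0:
                sl_a.append(slice(0, size - d))
                sl_b.append(slice(d, size))
            else:
                sl_a.append(slice(-d, size))
                sl_b.append(slice(0, size + d))
        dep[tuple(sl_a)] += close
        dep[tuple(sl_b)] += close
    ng = disc.n_levels
    inm = lev > 0
    max_dep = int(dep[inm].max())
    idx = (lev[inm] - 1) * max_dep + (dep[inm] - 1)
    return np.bincount(idx, minlength=ng * max_dep).reshape(ng, max_dep).astype(float)


def gldm_features(disc: DiscretizedVolume, alpha: int = 0) -> dict[str, float]:
    """The 14 gray-level dependence features."""
    counts = dependence_matrix(disc, alpha=alpha)
    nz = counts.sum()  # equals the number of in-mask voxels
    p = counts / nz
    g = np.arange(1, counts.shape[0] + 1, dtype=float)[:, None]
    j = np.arange(1, counts.shape[1] + 1, dtype=float)[None, :]
    pg = p.sum(axis=1)
    pj = p.sum(axis=0)
    mu_g = float(np.sum(g.ravel() * pg))
    mu_j = float(np.sum(j.ravel() * pj))
    return {
        "small_dependence_emphasis": float(np.sum(counts / j**2) / nz),
        "large_dependence_emphasis": float(np.sum(counts * j**2) / nz),
        "gray_level_nonuniformity": float(np.sum(counts.sum(axis=1) ** 2) / nz),
        "dependence_nonuniformity": float(np.sum(counts.sum(axis=0) ** 2) / nz),
        "dependence_nonuniformity_normalized": float(np.sum(counts.sum(axis=0) ** 2) / nz**2),
        "gray_level_variance": float(np.sum(p * (g - mu_g) ** 2)),
        "dependence_variance": float(np.sum(p * (j - mu_j) ** 2)),
        "dependence_entropy": _entropy(p.ravel()),
        "low_gray_level_emphasis": float(np.sum(counts / g**2) / nz),
        "high_gray_level_emphasis": float(np.sum(counts * g**2) / nz),
        "small_dependence_low_gray_level_emphasis": float(np.sum(counts / (g**2 * j**2)) / nz),
        "small_dependence_high_gray_level_emphasis": float(np.sum(counts * g**2 / j**2) / nz),
        "large_dependence_low_gray_level_emphasis": float(np.sum(counts * j**2 / g**2) / nz),
        "large_dependence_high_gray_level_emphasis": float(np.sum(counts * g**2 * j**2) / nz),
    }


def texture_matrix_features(disc: DiscretizedVolume, family: str) -> dict[str, float]:
    """Dispatch on matrix ``family`` in {GLRLM, GLSZM, NGTDM, GLDM}."""
    fams = {
        "GLRLM": glrlm_features,
        "GLSZM": glszm_features,
        "NGTDM": ngtdm_features,
        "GLDM": gldm_features,
    }
    try:
        fn = fams[family]
    except KeyError:
        raise ValueError(f"unknown texture family {family!r}; expected one of {sorted(fams)}") from None
    return fn(disc)
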