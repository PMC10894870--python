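"""IBSI-style 3-D radiomics feature extraction inside an ROI.

Conventions
-----------
* Fixed-bin-number (FBN) discretisation into grey levels ``1..n``:
  ``level(v) = min(floor(n * (v - min) / (max - min)) + 1, n)``.
* Texture matrices use 3-D merged-direction aggregation: the 13 unique
  voxel-offset directions (Chebyshev distance 1) are accumulated into a
  single matrix before features are computed.
* Zones (GLSZM / GLDZM) are 26-connected components of equal grey level;
  the GLDZM zone distance is the city-block distance to the ROI border
  (border voxels, including those at the image edge, have distance 1).
* Histogram kurtosis is excess kurtosis; moments use population
  normalisation.
* Feature names follow the MIRP-style dialect
  ``family_feature[_3d][_fbn_nNN]`` with a ``log_`` prefix for features
  computed on the Laplacian-of-Gaussian-filtered image.

Degenerate inputs (constant ROI) yield NaN for the affected features and
the names are reported in a flag set rather than silently propagated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume import RoiMask, Volume

__all__ = [
    "FeatureConfig",
    "discretize_fbn",
    "intensity_statistics",
    "intensity_histogram_features",
    "ivh_features",
    "local_intensity_peak",
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "gldzm_features",
    "ngtdm_features",
    "extract_all",
    "SIGNATURE_FEATURES",
]

# the eight headline signature features of the modality-specific models
SIGNATURE_FEATURES = (
    "log_ih_kurt_fbn_n16",
    "dzm_ldhge_3d_fbn_n32",
    "ih_rmad_fbn_n32",
    "log_stat_min",
    "stat_max",
    "ivh_diff_i25_i75",
    "dzm_zd_var_3d_fbn_n32",
    "loc_peak_glob",
)

# 13 unique directions covering the 26-neighbourhood up to sign
DIRECTIONS_3D = [
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
]

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class FeatureConfig:
    bin_counts: tuple[int, ...] = (16, 32)
    ivh_fractions: tuple[tuple[float, float], ...] = ((0.10, 0.90), (0.25, 0.75))
    peak_volume_cm3: float = 1.0

    def __post_init__(self) -> None:
        if any(n < 2 for n in self.bin_counts):
            raise ValueError("bin counts must be >= 2")
        for lo, hi in self.ivh_fractions:
            if not (0.0 < lo < 1.0 and 0.0 < hi < 1.0):
                raise ValueError("IVH fractions must lie in (0, 1)")


# ---------------------------------------------------------------------------
# discretisation and first-order features
# ---------------------------------------------------------------------------

def discretize_fbn(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Fixed-bin-number discretisation into integer levels ``1..n_bins``."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty ROI")
    vmin, vmax = values.min(), values.max()
    if vmax <= vmin:
        return np.ones(values.shape, dtype=int)
    lev = np.floor(n_bins * (values - vmin) / (vmax - vmin)).astype(int) + 1
    return np.minimum(lev, n_bins)


def _moments(v: np.ndarray) -> tuple[float, float, float, float]:
    mu = v.mean()
    m2 = ((v - mu) ** 2).mean()
    if m2 == 0:
        return mu, 0.0, np.nan, np.nan
    m3 = ((v - mu) ** 3).mean()
    m4 = ((v - mu) ** 4).mean()
    return mu, m2, m3 / m2**1.5, m4 / m2**2 - 3.0


def intensity_statistics(values: np.ndarray, prefix: str = "stat") -> dict[str, float]:
    """First-order intensity statistics (population moments, per IBSI)."""
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("empty ROI")
    mu, var, skew, kurt = _moments(v)
    p10, p25, med, p75, p90 = np.percentile(v, [10, 25, 50, 75, 90])
    inner = v[(v >= p10) & (v <= p90)]
    out = {
        "mean": mu, "var": var, "skew": skew, "kurt": kurt,
        "median": med, "min": v.min(), "p10": p10, "p90": p90, "max": v.max(),
        "iqr": p75 - p25, "range": v.max() - v.min(),
        "mad": np.abs(v - mu).mean(),
        "rmad": np.abs(inner - inner.mean()).mean() if inner.size else np.nan,
        "medad": np.abs(v - med).mean(),
        "cov": math.sqrt(var) / mu if mu != 0 else np.nan,
        "qcod": (p75 - p25) / (p75 + p25) if (p75 + p25) != 0 else np.nan,
        "energy": float((v**2).sum()),
        "rms": math.sqrt((v**2).mean()),
    }
    return {f"{prefix}_{k}": float(x) for k, x in out.items()}


def intensity_histogram_features(values: np.ndarray, n_bins: int) -> dict[str, float]:
    """First-order statistics of the FBN-discretised histogram."""
    lev = discretize_fbn(np.asarray(values, dtype=float).ravel(), n_bins)
    g = lev.astype(float)
    mu, var, skew, kurt = _moments(g)
    p10, p25, med, p75, p90 = np.percentile(g, [10, 25, 50, 75, 90])
    inner = g[(g >= p10) & (g <= p90)]
    counts = np.bincount(lev, minlength=n_bins + 1)[1:]
    p = counts / counts.sum()
    nz = p[p > 0]
    grad = np.gradient(counts.astype(float))
    tag = f"fbn_n{n_bins}"
    out = {
        "mean": mu, "var": var, "skew": skew, "kurt": kurt,
        "median": med, "min": g.min(), "p10": p10, "p90": p90, "max": g.max(),
        "mode": float(np.argmax(counts) + 1),
        "iqr": p75 - p25, "range": g.max() - g.min(),
        "mad": np.abs(g - mu).mean(),
        "rmad": np.abs(inner - inner.mean()).mean() if inner.size else np.nan,
        "medad": np.abs(g - med).mean(),
        "cov": math.sqrt(var) / mu if mu != 0 else np.nan,
        "qcod": (p75 - p25) / (p75 + p25) if (p75 + p25) != 0 else np.nan,
        "entropy": float(-(nz * np.log2(nz)).sum()),
        "uniformity": float((p**2).sum()),
        "max_grad": float(grad.max()),
        "max_grad_g": float(np.argmax(grad) + 1),
        "min_grad": float(grad.min()),
        "min_grad_g": float(np.argmin(grad) + 1),
    }
    return {f"ih_{k}_{tag}": float(x) for k, x in out.items()}


def ivh_features(values: np.ndarray,
                 fractions=((0.10, 0.90), (0.25, 0.75))) -> dict[str, float]:
    """Intensity-volume histogram features.

    ``I_x`` is the minimum intensity contained in the x% most intense
    volume fraction; ``V_x`` is the volume fraction at or above the
    intensity ``min + x * range``.
    """
    v = np.sort(np.asarray(values, dtype=float).ravel())
    if v.size < 1:
        raise ValueError("empty ROI")
    n = v.size
    rng_ = v[-1] - v[0]

    def i_at(frac):
        k = max(int(math.ceil(frac * n)), 1)
        return float(v[n - k])        # min of the k most intense voxels

    def v_at(frac):
        if rng_ == 0:
            return 1.0
        thr = v[0] + frac * rng_
        return float((v >= thr).sum() / n)

    out: dict[str, float] = {}
    for lo, hi in fractions:
        plo, phi = int(round(lo * 100)), int(round(hi * 100))
        out[f"ivh_i{plo}"] = i_at(lo)
        out[f"ivh_i{phi}"] = i_at(hi)
        out[f"ivh_v{plo}"] = v_at(lo)
        out[f"ivh_v{phi}"] = v_at(hi)
        out[f"ivh_diff_i{plo}_i{phi}"] = i_at(lo) - i_at(hi)
        out[f"ivh_diff_v{plo}_v{phi}"] = v_at(lo) - v_at(hi)
    return out


def _sphere_offsets(radius_mm: float, spacing) -> np.ndarray:
    r_vox = [int(math.floor(radius_mm / s)) for s in spacing]
    offs = []
    for dx in range(-r_vox[0], r_vox[0] + 1):
        for dy in range(-r_vox[1], r_vox[1] + 1):
            for dz in range(-r_vox[2], r_vox[2] + 1):
                d = math.sqrt((dx * spacing[0]) ** 2 + (dy * spacing[1]) ** 2
                              + (dz * spacing[2]) ** 2)
                if d <= radius_mm + 1e-9:
                    offs.append((dx, dy, dz))
    return np.asarray(offs, dtype=int)


def local_intensity_peak(vol: Volume, roi: RoiMask,
                         peak_volume_cm3: float = 1.0) -> dict[str, float]:
    """Global and local intensity peak over a 1 cm^3 sphere (by default).

    For every ROI voxel the mean intensity within the sphere (clipped to
    the image grid) is computed; ``loc_peak_glob`` is the maximum of these
    means, ``loc_peak_loc`` is the sphere mean at the most intense ROI
    voxel (maximum over ties).
    """
    radius_mm = (3.0 * peak_volume_cm3 * 1000.0 / (4.0 * math.pi)) ** (1.0 / 3.0)
    if all(radius_mm >= (n - 1) * s
           for n, s in zip(vol.shape, vol.spacing)):
        raise ValueError("peak sphere exceeds the image grid everywhere")
    offs = _sphere_offsets(radius_mm, vol.spacing)
    kernel_shape = tuple(2 * int(math.floor(radius_mm / s)) + 1 for s in vol.spacing)
    kernel = np.zeros(kernel_shape)
    centre = tuple(k // 2 for k in kernel_shape)
    for o in offs:
        kernel[centre[0] + o[0], centre[1] + o[1], centre[2] + o[2]] = 1.0
    sums = ndimage.correlate(vol.data, kernel, mode="constant", cval=0.0)
    counts = ndimage.correlate(np.ones(vol.shape), kernel,
                               mode="constant", cval=0.0)
    means = sums / counts
    m = roi.data
    vals = vol.data[m]
    glob = float(means[m].max())
    peak_mask = m & (vol.data == vals.max())
    loc = float(means[peak_mask].max())
    return {"loc_peak_glob": glob, "loc_peak_loc": loc}


# ---------------------------------------------------------------------------
# texture matrices
# ---------------------------------------------------------------------------

def _levels_volume(vol_or_values, mask: np.ndarray, n_bins: int) -> np.ndarray:
    """Discretised grey-level volume; 0 outside the ROI."""
    lev = np.zeros(mask.shape, dtype=int)
    lev[mask] = discretize_fbn(vol_or_values[mask], n_bins)
    return lev


def _shift_pairs(levels, mask, d):
    """Index pairs of in-ROI voxels separated by offset d (one orientation)."""
    src = [slice(max(-o, 0), levels.shape[ax] - max(o, 0))
           for ax, o in enumerate(d)]
    dst = [slice(max(o, 0), levels.shape[ax] - max(-o, 0))
           for ax, o in enumerate(d)]
    a, b = levels[tuple(src)], levels[tuple(dst)]
    ma, mb = mask[tuple(src)], mask[tuple(dst)]
    ok = ma & mb
    return a[ok], b[ok]


def glcm_matrix(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    """Symmetric merged-direction grey-level co-occurrence matrix (counts)."""
    mat = np.zeros((n_levels, n_levels))
    for d in DIRECTIONS_3D:
        a, b = _shift_pairs(levels, mask, d)
        np.add.at(mat, (a - 1, b - 1), 1.0)
        np.add.at(mat, (b - 1, a - 1), 1.0)
    return mat


def glcm_features(levels: np.ndarray, mask: np.ndarray, n_levels: int,
                  tag: str = "") -> dict[str, float]:
    mat = glcm_matrix(levels, mask, n_levels)
    total = mat.sum()
    if total == 0:
        return {f"cm_{k}{tag}": np.nan for k in ("joint_max",)}
    p = mat / total
    i = np.arange(1, n_levels + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    mu = float((ii * p).sum())
    var = float(((ii - mu) ** 2 * p).sum())
    # difference and sum marginals
    k_diff = np.arange(0, n_levels, dtype=float)
    p_diff = np.zeros(n_levels)
    np.add.at(p_diff, np.abs(ii - jj).astype(int), p)
    k_sum = np.arange(2, 2 * n_levels + 1, dtype=float)
    p_sum = np.zeros(2 * n_levels - 1)
    np.add.at(p_sum, (ii + jj).astype(int) - 2, p)

    def ent(q):
        q = q[q > 0]
        return float(-(q * np.log2(q)).sum())

    diff_avg = float((k_diff * p_diff).sum())
    sum_avg = float((k_sum * p_sum).sum())
    hxy = ent(p.ravel())
    pxy = np.outer(px, px)
    with np.errstate(divide="ignore"):
        hxy1 = float(-(p[pxy > 0] * np.log2(pxy[pxy > 0])).sum())
    hxy2 = ent(pxy.ravel())
    hx = ent(px)
    off = ii != jj
    out = {
        "joint_max": float(p.max()),
        "joint_avg": mu,
        "joint_var": var,
        "joint_entr": hxy,
        "diff_avg": diff_avg,
        "diff_var": float(((k_diff - diff_avg) ** 2 * p_diff).sum()),
        "diff_entr": ent(p_diff),
        "sum_avg": sum_avg,
        "sum_var": float(((k_sum - sum_avg) ** 2 * p_sum).sum()),
        "sum_entr": ent(p_sum),
        "energy": float((p**2).sum()),
        "contrast": float(((ii - jj) ** 2 * p).sum()),
        "dissimilarity": float((np.abs(ii - jj) * p).sum()),
        "inv_diff": float((p / (1.0 + np.abs(ii - jj))).sum()),
        "inv_diff_norm": float((p / (1.0 + np.abs(ii - jj) / n_levels)).sum()),
        "inv_diff_mom": float((p / (1.0 + (ii - jj) ** 2)).sum()),
        "inv_diff_mom_norm": float((p / (1.0 + ((ii - jj) / n_levels) ** 2)).sum()),
        "inv_var": float((p[off] / (ii[off] - jj[off]) ** 2).sum()),
        "corr": float((((ii - mu) * (jj - mu) * p).sum()) / var) if var > 0 else np.nan,
        "auto_corr": float((ii * jj * p).sum()),
        "clust_tend": float(((ii + jj - 2 * mu) ** 2 * p).sum()),
        "clust_shade": float(((ii + jj - 2 * mu) ** 3 * p).sum()),
        "clust_prom": float(((ii + jj - 2 * mu) ** 4 * p).sum()),
        "info_corr1": (hxy - hxy1) / hx if hx > 0 else np.nan,
        "info_corr2": math.sqrt(max(1.0 - math.exp(-2.0 * (hxy2 - hxy)), 0.0)),
    }
    return {f"cm_{k}{tag}": v for k, v in out.items()}


def glrlm_matrix(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    """Merged-direction grey-level run-length matrix (counts)."""
    max_len = max(levels.shape)
    mat = np.zeros((n_levels, max_len))
    shape = levels.shape
    for d in DIRECTIONS_3D:
        # run starts: in-ROI voxels whose predecessor along d is absent/different
        idx = np.argwhere(mask)
        prev = idx - np.asarray(d)
        inside = np.all((prev >= 0) & (prev < np.asarray(shape)), axis=1)
        same = np.zeros(len(idx), dtype=bool)
        pi = prev[inside]
        same[inside] = (mask[pi[:, 0], pi[:, 1], pi[:, 2]]
                        & (levels[pi[:, 0], pi[:, 1], pi[:, 2]]
                           == levels[idx[inside][:, 0], idx[inside][:, 1],
                                     idx[inside][:, 2]]))
        for (x, y, z) in idx[~same]:
            g = levels[x, y, z]
            length = 1
            nx, ny, nz = x + d[0], y + d[1], z + d[2]
            while (0 <= nx < shape[0] and 0 <= ny < shape[1]
                   and 0 <= nz < shape[2] and mask[nx, ny, nz]
                   and levels[nx, ny, nz] == g):
                length += 1
                nx, ny, nz = nx + d[0], ny + d[1], nz + d[2]
            mat[g - 1, length - 1] += 1.0
    return mat


def _rl_style_features(mat: np.ndarray, n_voxels: int, family: str,
                       axis_name: str, perc_denominator: int,
                       tag: str = "") -> dict[str, float]:
    """Shared formulas of the run-length / size-zone / distance-zone families."""
    ns = mat.sum()
    if ns == 0:
        return {}
    i = np.arange(1, mat.shape[0] + 1, dtype=float)[:, None]
    j = np.arange(1, mat.shape[1] + 1, dtype=float)[None, :]
    p = mat / ns
    si = mat.sum(axis=1)
    sj = mat.sum(axis=0)
    mu_i = float((i * p).sum())
    mu_j = float((j * p).sum())
    nz = p[p > 0]
    short, long_ = ("sre", "lre") if family == "rlm" else (
        ("sze", "lze") if family == "szm" else ("sde", "lde"))
    lg, hg = ("lgre", "hgre") if family == "rlm" else (
        ("lgze", "hgze") if family == "szm" else ("lgze", "hgze"))
    combos = {
        "rlm": ("srlge", "srhge", "lrlge", "lrhge"),
        "szm": ("szlge", "szhge", "lzlge", "lzhge"),
        "dzm": ("sdlge", "sdhge", "ldlge", "ldhge"),
    }[family]
    nu_j = {"rlm": "rlnu", "szm": "zsnu", "dzm": "zdnu"}[family]
    var_j = {"rlm": "rl_var", "szm": "zs_var", "dzm": "zd_var"}[family]
    entr = {"rlm": "rl_entr", "szm": "zs_entr", "dzm": "zd_entr"}[family]
    perc = {"rlm": "r_perc", "szm": "z_perc", "dzm": "z_perc"}[family]
    out = {
        short: float((mat / j**2).sum() / ns),
        long_: float((mat * j**2).sum() / ns),
        lg: float((mat / i**2).sum() / ns),
        hg: float((mat * i**2).sum() / ns),
        combos[0]: float((mat / (i**2 * j**2)).sum() / ns),
        combos[1]: float((mat * i**2 / j**2).sum() / ns),
        combos[2]: float((mat * j**2 / i**2).sum() / ns),
        combos[3]: float((mat * i**2 * j**2).sum() / ns),
        "glnu": float((si**2).sum() / ns),
        "glnu_norm": float((si**2).sum() / ns**2),
        nu_j: float((sj**2).sum() / ns),
        f"{nu_j}_norm": float((sj**2).sum() / ns**2),
        perc: float(ns / perc_denominator),
        "gl_var": float(((i - mu_i) ** 2 * p).sum()),
        var_j: float(((j - mu_j) ** 2 * p).sum()),
        entr: float(-(nz * np.log2(nz)).sum()),
    }
    return {f"{family}_{k}_3d{tag}": v for k, v in out.items()}


def glrlm_features(levels, mask, n_levels, tag: str = "") -> dict[str, float]:
    mat = glrlm_matrix(levels, mask, n_levels)
    return _rl_style_features(mat, int(mask.sum()), "rlm", "run",
                              int(mask.sum()) * len(DIRECTIONS_3D), tag)


def _zones(levels: np.ndarray, mask: np.ndarray):
    """26-connected zones of equal grey level: list of (level, voxel-index array)."""
    zones = []
    for g in np.unique(levels[mask]):
        comp, n = ndimage.label((levels == g) & mask, structure=_STRUCT26)
        for z in range(1, n + 1):
            zones.append((int(g), np.argwhere(comp == z)))
    return zones


def glszm_matrix(levels, mask, n_levels) -> np.ndarray:
    zones = _zones(levels, mask)
    max_size = max((len(v) for _, v in zones), default=1)
    mat = np.zeros((n_levels, max_size))
    for g, vox in zones:
        mat[g - 1, len(vox) - 1] += 1.0
    return mat


def glszm_features(levels, mask, n_levels, tag: str = "") -> dict[str, float]:
    mat = glszm_matrix(levels, mask, n_levels)
    return _rl_style_features(mat, int(mask.sum()), "szm", "size",
                              int(mask.sum()), tag)


def roi_border_distance(mask: np.ndarray) -> np.ndarray:
    """City-block distance to the ROI border; border voxels (incl. voxels at
    the image edge) have distance 1."""
    padded = np.pad(mask, 1, mode="constant", constant_values=False)
    dist = ndimage.distance_transform_cdt(padded, metric="taxicab")
    return dist[1:-1, 1:-1, 1:-1]


def gldzm_matrix(levels, mask, n_levels) -> np.ndarray:
    dist = roi_border_distance(mask)
    zones = _zones(levels, mask)
    max_d = int(dist[mask].max()) if mask.any() else 1
    mat = np.zeros((n_levels, max_d))
    for g, vox in zones:
        d = int(dist[vox[:, 0], vox[:, 1], vox[:, 2]].min())
        mat[g - 1, d - 1] += 1.0
    return mat


def gldzm_features(levels, mask, n_levels, tag: str = "") -> dict[str, float]:
    mat = gldzm_matrix(levels, mask, n_levels)
    return _rl_style_features(mat, int(mask.sum()), "dzm", "dist",
                              int(mask.sum()), tag)


def ngtdm_features(levels, mask, n_levels, tag: str = "") -> dict[str, float]:
    """Neighbourhood grey-tone difference features (26-neighbourhood)."""
    nv = int(mask.sum())
    if nv == 0:
        raise ValueError("empty ROI")
    # neighbour sums/counts accumulated by shifting the padded grids
    nb_sum = np.zeros(mask.shape)
    nb_cnt = np.zeros(mask.shape)
    lev_f = levels.astype(float)
    m_f = mask.astype(float)
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if dx == dy == dz == 0:
                    continue
                shifted_l = np.roll(lev_f * m_f, (dx, dy, dz), axis=(0, 1, 2))
                shifted_m = np.roll(m_f, (dx, dy, dz), axis=(0, 1, 2))
                # zero out wrap-around
                for ax, o in enumerate((dx, dy, dz)):
                    if o == 1:
                        sl = [slice(None)] * 3
                        sl[ax] = slice(0, 1)
                        shifted_l[tuple(sl)] = 0.0
                        shifted_m[tuple(sl)] = 0.0
                    elif o == -1:
                        sl = [slice(None)] * 3
                        sl[ax] = slice(-1, None)
                        shifted_l[tuple(sl)] = 0.0
                        shifted_m[tuple(sl)] = 0.0
                nb_sum += shifted_l
                nb_cnt += shifted_m
    has_nb = mask & (nb_cnt > 0)
    avg = np.zeros(mask.shape)
    avg[has_nb] = nb_sum[has_nb] / nb_cnt[has_nb]
    n_i = np.zeros(n_levels)
    s_i = np.zeros(n_levels)
    g_in = levels[has_nb]
    diffs = np.abs(g_in - avg[has_nb])
    np.add.at(n_i, g_in - 1, 1.0)
    np.add.at(s_i, g_in - 1, diffs)
    nv_eff = n_i.sum()
    p_i = n_i / nv_eff
    present = np.where(n_i > 0)[0]
    i_vals = present + 1.0
    npres = len(present)
    ps, ss = p_i[present], s_i[present]
    dot = float((ps * ss).sum())
    coars = 1.0 / dot if dot > 0 else 1e6
    if npres > 1:
        pij_d2 = np.add.outer(-i_vals, i_vals) ** 2
        contrast = float((np.outer(ps, ps) * pij_d2).sum()
                         / (npres * (npres - 1))) * float(ss.sum() / nv_eff)
        denom_busy = float(np.abs(np.subtract.outer(i_vals * ps, i_vals * ps)).sum())
        busy = dot / denom_busy if denom_busy > 0 else 0.0
        pi_si = ps * ss
        comp = float((np.abs(np.subtract.outer(i_vals, i_vals))
                      * (np.add.outer(pi_si, pi_si))
                      / np.add.outer(ps, ps)).sum() / nv_eff)
        strength_num = float((np.add.outer(ps, ps) * pij_d2).sum())
        strength = strength_num / ss.sum() if ss.sum() > 0 else 0.0
    else:
        contrast, busy, comp, strength = 0.0, 0.0, 0.0, 0.0
    out = {"coarseness": coars, "contrast": contrast, "busyness": busy,
           "complexity": comp, "strength": strength}
    return {f"ngt_{k}_3d{tag}": v for k, v in out.items()}


# ---------------------------------------------------------------------------
# full extraction
# ---------------------------------------------------------------------------

def _first_order(vol: Volume, roi: RoiMask, cfg: FeatureConfig,
                 prefix: str = "") -> tuple[dict[str, float], set[str]]:
    vals = vol.data[roi.data]
    flags: set[str] = set()
    feats = {f"{prefix}{k}": v
             for k, v in intensity_statistics(vals).items()}
    constant = np.ptp(vals) == 0
    for nb in cfg.bin_counts:
        feats.update({f"{prefix}{k}": v
                      for k, v in intensity_histogram_features(vals, nb).items()})
    if constant:
        flags |= {k for k in feats if k.endswith(("skew", "kurt"))
                  or "_skew_" in k or "_kurt_" in k}
    return feats, flags


def extract_all(vol: Volume, roi: RoiMask, cfg: FeatureConfig | None = None,
                apply_log: bool = True, log_sigma_mm: float = 2.0,
                ) -> tuple[pd.Series, set[str]]:
    """Full feature vector for one (volume, ROI) pair.

    Returns a deterministic, name-sorted series plus the set of features
    flagged degenerate (NaN-valued) for this subject.  Texture, IVH and
    local-peak families are computed on the base image; first-order
    intensity and histogram features additionally on the LoG-filtered
    image (``log_`` prefix).
    """
    from .imgproc import log_filter

    cfg = cfg or FeatureConfig()
    if roi.is_empty():
        raise ValueError("empty ROI")
    mask = roi.data
    vals = vol.data[mask]
    feats, flags = _first_order(vol, roi, cfg)
    feats.update(ivh_features(vals, cfg.ivh_fractions))
    feats.update(local_intensity_peak(vol, roi, cfg.peak_volume_cm3))

    constant = np.ptp(vals) == 0
    for nb in cfg.bin_counts:
        tag = f"_fbn_n{nb}"
        lev = _levels_volume(vol.data, mask, nb)
        fams = {}
        fams.update(glcm_features(lev, mask, nb, tag))
        fams.update(glrlm_features(lev, mask, nb, tag))
        fams.update(glszm_features(lev, mask, nb, tag))
        fams.update(gldzm_features(lev, mask, nb, tag))
        fams.update(ngtdm_features(lev, mask, nb, tag))
        if constant:
            flags |= set(fams)
        feats.update(fams)

    if apply_log:
        log_vol = log_filter(vol, log_sigma_mm)
        lf, lflags = _first_order(log_vol, roi, cfg, prefix="log_")
        feats.update(lf)
        flags |= lflags
    for k, v in feats.items():
        if isinstance(v, float) and not np.isfinite(v):
            flags.add(k)
    series = pd.Series(feats, dtype=float).sort_index()
    return series, flags
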