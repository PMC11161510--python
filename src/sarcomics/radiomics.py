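"""Handcrafted radiomics: 59 texture features per sequence + 4 shape features.

All texture families operate on a gray-level-discretized volume
(integer levels 1..N inside the mask, 0 outside) and are therefore
invariant to positive affine transforms of the raw intensities:

* 13 first-order histogram statistics,
* 21 gray-level co-occurrence (GLCM) features (7 statistics at voxel
  distances 1, 2 and 4),
* 11 gray-level run-length (GLRLM) features,
* 3 neighborhood gray-level difference (NGLDM) features,
* 11 gray-level zone-length (GLZLM) features with 26-connected zones.

Second-order matrices aggregate the 13 unique 3-D directions. The
4 shape features (volume, voxel count, sphericity, surface-to-volume
compacity) are computed on the contrast-enhanced mask with face-counted
surface area. Reproducibility across repeated segmentations is scored
with a two-way absolute-agreement single-measurement intraclass
correlation coefficient; features with ICC below 0.90 are discarded.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .images import SegmentationMask

__all__ = [
    "DIRECTIONS_13",
    "first_order_features",
    "glcm_features",
    "glrlm_features",
    "ngldm_features",
    "glzlm_features",
    "shape_features",
    "extract_features",
    "icc",
    "filter_robust_features",
]

# one representative per +/- pair of the 26 neighborhood offsets
DIRECTIONS_13 = [
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1),
    (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
]

COARSENESS_CAP = 1e6


def _crop_to_mask(disc: np.ndarray, mask: np.ndarray, pad: int = 0):
    idx = np.where(mask)
    lo = [max(0, int(i.min()) - pad) for i in idx]
    hi = [min(s, int(i.max()) + 1 + pad) for i, s in zip(idx, mask.shape)]
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    return disc[sl], mask[sl]


def _check_inputs(disc, mask) -> tuple[np.ndarray, np.ndarray]:
    disc = np.asarray(disc)
    m = mask.values if isinstance(mask, SegmentationMask) else np.asarray(mask).astype(bool)
    if disc.shape != m.shape:
        raise ValueError("discretized volume and mask shapes differ")
    if not m.any():
        raise ValueError("mask has no foreground voxel")
    return disc, m


def _shifted_views(arr: np.ndarray, off):
    """Return aligned views (a, b) with b displaced by ``off`` from a."""
    sl_a, sl_b = [], []
    for o, n in zip(off, arr.shape):
        if o >= 0:
            sl_a.append(slice(0, n - o))
            sl_b.append(slice(o, n))
        else:
            sl_a.append(slice(-o, n))
            sl_b.append(slice(0, n + o))
    return arr[tuple(sl_a)], arr[tuple(sl_b)]


# ---------------------------------------------------------------- first order

def first_order_features(disc, mask) -> dict:
    """13 histogram statistics of the in-mask discretized levels."""
    disc, m = _check_inputs(disc, mask)
    x = disc[m].astype(float)
    levels, counts = np.unique(x, return_counts=True)
    p = counts / counts.sum()
    sd = float(x.std())
    if sd > 0:
        skew = float(stats.skew(x))
        kurt = float(stats.kurtosis(x, fisher=False))
    else:  # degenerate: symmetric point mass (documented neutral values)
        skew, kurt = 0.0, 0.0
    return {
        "fo_mean": float(x.mean()),
        "fo_sd": sd,
        "fo_variance": float(x.var()),
        "fo_skewness": skew,
        "fo_kurtosis": kurt,
        "fo_min": float(x.min()),
        "fo_max": float(x.max()),
        "fo_median": float(np.median(x)),
        "fo_p10": float(np.percentile(x, 10)),
        "fo_p90": float(np.percentile(x, 90)),
        "fo_energy": float(np.sum(p ** 2)),
        "fo_entropy": float(-np.sum(p * np.log2(p))),
        "fo_occupied_levels": float(len(levels)),
    }


# ----------------------------------------------------------------------- GLCM

def _glcm_matrix(disc, m, distance, directions):
    """Symmetric normalized co-occurrence matrix over the directions."""
    n_lev = int(disc[m].max())
    lv = np.where(m, disc, 0).astype(np.int64)
    counts = np.zeros((n_lev, n_lev), dtype=float)
    for d in directions:
        off = tuple(int(c) * distance for c in d)
        if any(abs(o) >= s for o, s in zip(off, lv.shape)):
            continue
        a, b = _shifted_views(lv, off)
        valid = (a > 0) & (b > 0)
        if not valid.any():
            continue
        code = (a[valid] - 1) * n_lev + (b[valid] - 1)
        counts += np.bincount(code, minlength=n_lev * n_lev).reshape(n_lev, n_lev)
    counts = counts + counts.T
    total = counts.sum()
    return counts, total, n_lev


def _glcm_stats(P, levels):
    i = levels[:, None]
    j = levels[None, :]
    pi = P.sum(axis=1)
    mu_i = float((levels * pi).sum())
    sd_i = float(np.sqrt((pi * (levels - mu_i) ** 2).sum()))
    nz = P > 0
    entropy = float(-np.sum(P[nz] * np.log2(P[nz])))
    if sd_i > 0:
        corr = float(np.sum(P * (i - mu_i) * (j - mu_i)) / (sd_i * sd_i))
    else:
        corr = 1.0  # single-level matrix: documented neutral value
    return {
        "homogeneity": float(np.sum(P / (1.0 + np.abs(i - j)))),
        "energy": float(np.sum(P ** 2)),
        "contrast": float(np.sum(P * (i - j) ** 2)),
        "correlation": corr,
        "entropy": entropy,
        "dissimilarity": float(np.sum(P * np.abs(i - j))),
        "idm": float(np.sum(P / (1.0 + (i - j) ** 2))),
    }


_GLCM_NEUTRAL = {"homogeneity": 1.0, "energy": 1.0, "contrast": 0.0,
                 "correlation": 1.0, "entropy": 0.0, "dissimilarity": 0.0,
                 "idm": 1.0}


def glcm_features(disc, mask, distances=(1, 2, 4), directions=DIRECTIONS_13) -> dict:
    """7 co-occurrence statistics per neighbor distance (21 features).

    Each matrix aggregates pairs over all directions (both voxels
    in-mask), is symmetrized and normalized to sum 1. A distance with no
    valid pair yields documented neutral values.
    """
    disc, m = _check_inputs(disc, mask)
    disc, m = _crop_to_mask(disc, m)
    out = {}
    for dist in distances:
        counts, total, n_lev = _glcm_matrix(disc, m, dist, directions)
        if total == 0:
            vals = dict(_GLCM_NEUTRAL)
        else:
            vals = _glcm_stats(counts / total, np.arange(1, n_lev + 1, dtype=float))
        for k, v in vals.items():
            out[f"glcm_{k}_d{dist}"] = v
    return out


# ---------------------------------------------------------------------- GLRLM

def _runs(disc, m, directions):
    """(gray level, run length) pairs over the given directions."""
    lv = np.where(m, disc, 0).astype(np.int64)
    lv, _ = _crop_to_mask(lv, lv > 0)
    max_len = max(lv.shape)
    all_g, all_l = [], []
    for d in directions:
        off = tuple(int(c) for c in d)
        # same[x]: x and x+d are both in-mask with equal level
        same = np.zeros(lv.shape, dtype=bool)
        a, b = _shifted_views(lv, off)
        sa, _ = _shifted_views(same, off)
        sa[...] = (a > 0) & (a == b)
        # f[x] = remaining run length starting at x (fixed point over chain)
        f = (lv > 0).astype(np.int64)
        for _ in range(max_len - 1):
            nxt = np.zeros(lv.shape, dtype=np.int64)
            na, nb = _shifted_views(nxt, off)
            na[...] = _shifted_views(f, off)[1]
            new = np.where(same, 1 + nxt, (lv > 0).astype(np.int64))
            if np.array_equal(new, f):
                break
            f = new
        # start[x]: in-mask and predecessor along -d is not part of same run
        prev_same = np.zeros(lv.shape, dtype=bool)
        pa, pb = _shifted_views(prev_same, off)
        pb[...] = _shifted_views(same, off)[0]
        start = (lv > 0) & ~prev_same
        all_g.append(lv[start])
        all_l.append(f[start])
    return np.concatenate(all_g), np.concatenate(all_l)


def _rl_formulas(g, l, n_vox, prefix) -> dict:
    g = g.astype(float)
    l = l.astype(float)
    n_r = len(g)
    if n_r == 0:
        return {f"{prefix}_{nm}": 0.0 for nm in
                ("sre", "lre", "gln", "rln", "rp", "lgre", "hgre",
                 "srlge", "srhge", "lrlge", "lrhge")}
    g_marg = {gi: np.sum(g == gi) for gi in np.unique(g)}
    l_marg = {li: np.sum(l == li) for li in np.unique(l)}
    return {
        f"{prefix}_sre": float(np.mean(1.0 / l ** 2)),
        f"{prefix}_lre": float(np.mean(l ** 2)),
        f"{prefix}_gln": float(sum(v ** 2 for v in g_marg.values()) / n_r),
        f"{prefix}_rln": float(sum(v ** 2 for v in l_marg.values()) / n_r),
        f"{prefix}_rp": float(n_r / n_vox),
        f"{prefix}_lgre": float(np.mean(1.0 / g ** 2)),
        f"{prefix}_hgre": float(np.mean(g ** 2)),
        f"{prefix}_srlge": float(np.mean(1.0 / (g ** 2 * l ** 2))),
        f"{prefix}_srhge": float(np.mean(g ** 2 / l ** 2)),
        f"{prefix}_lrlge": float(np.mean(l ** 2 / g ** 2)),
        f"{prefix}_lrhge": float(np.mean(g ** 2 * l ** 2)),
    }


def glrlm_features(disc, mask, directions=DIRECTIONS_13) -> dict:
    """11 run-length statistics aggregated over the 3-D directions."""
    disc, m = _check_inputs(disc, mask)
    g, l = _runs(disc, m, directions)
    # run percentage is normalized per direction so that an image of
    # all length-1 runs has RP = 1 regardless of the direction count
    return _rl_formulas(g, l, int(m.sum()) * len(directions), "glrlm")


# ---------------------------------------------------------------------- NGLDM

def ngldm_features(disc, mask) -> dict:
    """Coarseness, contrast and busyness from 26-neighborhood differences."""
    disc, m = _check_inputs(disc, mask)
    disc, m = _crop_to_mask(disc, m)
    lv = np.where(m, disc, 0).astype(float)
    nb_sum = np.zeros(lv.shape)
    nb_cnt = np.zeros(lv.shape)
    for d in DIRECTIONS_13:
        for off in (d, tuple(-c for c in d)):
            a_sum, b_val = _shifted_views(nb_sum, off)[0], _shifted_views(lv, off)[1]
            a_msk = _shifted_views(m, off)[0]
            b_msk = _shifted_views(m, off)[1]
            a_cnt = _shifted_views(nb_cnt, off)[0]
            sel = b_msk
            a_sum[sel] += b_val[sel]
            a_cnt[sel] += 1.0
    x = disc[m].astype(float)
    cnt = nb_cnt[m]
    s_vox = np.zeros_like(x)
    has_nb = cnt > 0
    s_vox[has_nb] = np.abs(x[has_nb] - nb_sum[m][has_nb] / cnt[has_nb])
    levels = np.unique(disc[m])
    n = len(x)
    p_i = np.array([np.mean(x == g) for g in levels])
    s_i = np.array([s_vox[x == g].sum() for g in levels])
    denom = float(np.sum(p_i * s_i))
    coarseness = min(1.0 / denom, COARSENESS_CAP) if denom > 0 else COARSENESS_CAP
    ng = len(levels)
    if ng > 1:
        diff2 = (levels[:, None].astype(float) - levels[None, :]) ** 2
        contrast = float(np.sum(p_i[:, None] * p_i[None, :] * diff2)
                         / (ng * (ng - 1)) * (s_i.sum() / n))
        numer = float(np.sum(p_i * s_i))
        bus_den = float(np.sum(np.abs(levels[:, None] * p_i[:, None]
                                      - levels[None, :] * p_i[None, :])))
        busyness = numer / bus_den if bus_den > 0 else 0.0
    else:
        contrast, busyness = 0.0, 0.0
    return {"ngldm_coarseness": float(coarseness),
            "ngldm_contrast": contrast,
            "ngldm_busyness": float(busyness)}


# ---------------------------------------------------------------------- GLZLM

def glzlm_features(disc, mask) -> dict:
    """11 zone-length statistics (26-connected iso-level zones)."""
    from skimage.measure import label as sk_label

    disc, m = _check_inputs(disc, mask)
    disc, m = _crop_to_mask(disc, m)
    lv = np.where(m, disc, 0)
    # one labelling pass: equal-valued 26-connected voxels share a zone
    lab = sk_label(lv, connectivity=3, background=0)
    n_lab = lab.max()
    if n_lab == 0:
        return _rl_formulas(np.array([]), np.array([]), int(m.sum()), "glzlm")
    sizes = np.bincount(lab.ravel())[1:]
    first = np.zeros(n_lab + 1, dtype=np.int64)
    flat_lab = lab.ravel()
    nz = np.flatnonzero(flat_lab)
    # gray level of each zone from any member voxel
    first[flat_lab[nz[::-1]]] = nz[::-1]
    zones_g = lv.ravel()[first[1:]]
    return _rl_formulas(zones_g, sizes, int(m.sum()), "glzlm")


# ---------------------------------------------------------------------- shape

def shape_features(mask: SegmentationMask, spacing=None) -> dict:
    """Volume (mL), voxel count, sphericity, surface-to-volume compacity.

    Surface area comes from a marching-cubes mesh of the binary mask
    (face counting on the voxel grid overestimates curved surfaces by
    up to 50%, which would bound sphericity away from 1), so the
    sphericity of a digitized ball approaches 1 as the radius grows.
    """
    from skimage.measure import marching_cubes, mesh_surface_area

    if isinstance(mask, SegmentationMask):
        m = mask.values
        spacing = mask.spacing if spacing is None else spacing
    else:
        m = np.asarray(mask).astype(bool)
        spacing = (1.0, 1.0, 1.0) if spacing is None else spacing
    if not m.any():
        raise ValueError("mask has no foreground voxel")
    sx, sy, sz = (float(s) for s in spacing)
    n = int(m.sum())
    voxel_vol = sx * sy * sz
    volume_mm3 = n * voxel_vol
    padded = np.pad(m.astype(float), 1)
    verts, faces, *_ = marching_cubes(padded, level=0.5,
                                      spacing=(sx, sy, sz))
    area = float(mesh_surface_area(verts, faces))
    sphericity = (np.pi ** (1.0 / 3.0)) * (6.0 * volume_mm3) ** (2.0 / 3.0) / area
    return {
        "shape_volume_ml": volume_mm3 / 1000.0,
        "shape_voxel_count": float(n),
        "shape_sphericity": float(sphericity),
        "shape_compacity": float(area / volume_mm3),
    }


# ------------------------------------------------------------------ assembly

def extract_features(disc_by_channel: dict, mask, spacing=None,
                     shape_channel: str = "CE") -> dict:
    """All texture features per channel plus shape features.

    Names follow ``<sequence>_<family>_<feature>[_d<distance>]``.
    """
    out = {}
    for seq, disc in disc_by_channel.items():
        for fam in (first_order_features, glcm_features, glrlm_features,
                    ngldm_features, glzlm_features):
            for name, val in fam(disc, mask).items():
                out[f"{seq}_{name}"] = val
    if shape_channel is not None:
        for name, val in shape_features(mask, spacing).items():
            out[name] = val
    return out


# ----------------------------------------------------------------------- ICC

def icc(measurements: np.ndarray) -> pd.Series:
    """Two-way absolute-agreement single-measurement ICC per feature.

    ``measurements`` is (n_subjects, 2, n_features) — two repeated
    extractions per subject. Features with zero total variance get
    ICC = NaN (treated as failing the reproducibility filter).
    """
    x = np.asarray(measurements, dtype=float)
    if x.ndim == 2:
        x = x[:, :, None]
    n, k, p = x.shape
    if n < 3 or k != 2:
        raise ValueError("need >= 3 subjects and exactly 2 repeats")
    grand = x.mean(axis=(0, 1))
    row_m = x.mean(axis=1)
    col_m = x.mean(axis=0)
    msr = k * ((row_m - grand) ** 2).sum(axis=0) / (n - 1)
    msc = n * ((col_m - grand) ** 2).sum(axis=0) / (k - 1)
    sse = ((x - row_m[:, None, :] - col_m[None, :, :] + grand) ** 2).sum(axis=(0, 1))
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = (msr - mse) / denom
    vals = np.where(denom <= 0, np.nan, vals)
    return pd.Series(vals, name="icc")


def filter_robust_features(matrix: pd.DataFrame, icc_values: pd.Series,
                           threshold: float = 0.90) -> pd.DataFrame:
    """Keep features with ICC >= threshold (boundary inclusive)."""
    missing = [c for c in matrix.columns if c not in icc_values.index]
    if missing:
        raise ValueError(f"ICC report does not cover: {missing[:5]}")
    keep = [c for c in matrix.columns
            if np.isfinite(icc_values[c]) and icc_values[c] >= threshold]
    if not keep:
        raise ValueError("no feature passes the reproducibility filter")
    return matrix[keep]
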