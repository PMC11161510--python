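"""MRI intensity harmonization.

Conventional MRI has no standardized intensity units and multi-scanner
cohorts mix voxel geometries, so every volume passes a fixed
post-processing chain before feature extraction:

1. resample to a common voxel size (default 1 x 1 x 4 mm, linear
   interpolation in physical space),
2. divide out a smooth multiplicative bias field estimated as a
   low-order polynomial in the log-intensity domain,
3. histogram-match to a cohort reference by quantile mapping,
4. rescale intensities affinely to the fixed range [-10000, +10000].

Gray-level discretization (256 levels over the in-mask range) and
center-slice extraction feed the handcrafted and deep radiomics
branches respectively.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .images import ImageVolume, SegmentationMask

__all__ = [
    "resample_to_spacing",
    "resample_mask",
    "correct_bias_field",
    "match_histogram",
    "rescale_range",
    "discretize",
    "extract_center_slice",
    "harmonize_volume",
]

DEFAULT_SPACING = (1.0, 1.0, 4.0)
RESCALE_LO = -10000.0
RESCALE_HI = 10000.0


def _resample_values(values: np.ndarray, spacing, target, order: int) -> np.ndarray:
    spacing = np.asarray(spacing, float)
    target = np.asarray(target, float)
    if np.any(target <= 0):
        raise ValueError("target spacing must be positive")
    new_shape = np.maximum(1, np.round(np.array(values.shape) * spacing / target)).astype(int)
    # output voxel centers expressed in input index coordinates
    grids = [np.arange(n) * t / s for n, t, s in zip(new_shape, target, spacing)]
    coords = np.meshgrid(*grids, indexing="ij")
    return ndimage.map_coordinates(values, coords, order=order, mode="nearest")


def resample_to_spacing(vol: ImageVolume, target=DEFAULT_SPACING) -> ImageVolume:
    """Resample onto the target voxel spacing by linear interpolation.

    Voxel centers of the output grid are mapped to physical space and
    the input is interpolated there; the physical extent is preserved
    within one voxel. An input already at the target spacing is returned
    value-identical.
    """
    out = _resample_values(vol.values, vol.spacing, target, order=1)
    return ImageVolume(out, tuple(float(t) for t in np.atleast_1d(target)), vol.origin)


def resample_mask(mask: SegmentationMask, target=DEFAULT_SPACING) -> SegmentationMask:
    """Resample a binary mask (linear on the indicator, threshold 0.5)."""
    out = _resample_values(mask.values.astype(float), mask.spacing, target, order=1)
    return SegmentationMask(out > 0.5, tuple(float(t) for t in np.atleast_1d(target)))


def _polynomial_design(shape, order: int) -> np.ndarray:
    axes = [np.linspace(-1.0, 1.0, n) if n > 1 else np.zeros(n) for n in shape]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    cols = []
    for a in range(order + 1):
        for b in range(order + 1 - a):
            for c in range(order + 1 - a - b):
                cols.append((xx ** a) * (yy ** b) * (zz ** c))
    return np.stack([c.ravel() for c in cols], axis=1)


def correct_bias_field(vol: ImageVolume, mask: SegmentationMask, order: int = 2) -> ImageVolume:
    """Remove a smooth multiplicative intensity bias.

    The field is estimated by least-squares fit of a polynomial of the
    given order to log-intensities inside the mask, then divided out of
    the whole volume. The in-mask mean of the input is restored, so only
    the spatial modulation changes. Non-positive in-mask intensities are
    shifted positive before the log fit (documented convention).
    """
    mask.require_nonempty()
    if mask.values.shape != vol.values.shape:
        raise ValueError("mask and volume shapes differ")
    values = vol.values.astype(float)
    m = mask.values
    shift = 0.0
    vmin = values[m].min()
    if vmin <= 0:
        shift = 1.0 - vmin
    work = values + shift
    design = _polynomial_design(values.shape, order)
    logv = np.log(work.reshape(-1)[m.reshape(-1)])
    coef, *_ = np.linalg.lstsq(design[m.reshape(-1)], logv, rcond=None)
    field = np.exp(design @ coef).reshape(values.shape)
    field /= field.reshape(-1)[m.reshape(-1)].mean()
    out = work / field
    out *= work[m].mean() / out[m].mean()
    return vol.copy_with(values=out - shift)


def match_histogram(vol: ImageVolume, reference: ImageVolume,
                    match_points: int = 256) -> ImageVolume:
    """Quantile-mapping histogram matching against a reference volume.

    Empirical quantiles at ``match_points`` evenly spaced probabilities
    are computed for both volumes and the piecewise-linear monotone map
    source-quantile -> reference-quantile is applied. A constant
    reference collapses the output to that constant.
    """
    if match_points < 2:
        raise ValueError("match_points must be >= 2")
    ref = reference.values
    if ref.max() == ref.min():
        return vol.copy_with(values=np.full(vol.values.shape, float(ref.flat[0])))
    src = vol.values
    if src.max() == src.min():
        # degenerate source: map everything to the reference median
        return vol.copy_with(values=np.full(src.shape, float(np.median(ref))))
    q = np.linspace(0.0, 1.0, match_points)
    src_q = np.quantile(src, q)
    ref_q = np.quantile(ref, q)
    # enforce strictly increasing knots for interpolation
    keep = np.concatenate([[True], np.diff(src_q) > 0])
    out = np.interp(src, src_q[keep], ref_q[keep])
    return vol.copy_with(values=out)


def rescale_range(vol: ImageVolume, lo: float = RESCALE_LO, hi: float = RESCALE_HI) -> ImageVolume:
    """Affine map of the volume's [min, max] onto [lo, hi].

    A constant volume maps to ``lo`` (documented convention). Applying
    the operation twice equals applying it once.
    """
    if hi <= lo:
        raise ValueError("hi must exceed lo")
    v = vol.values
    vmin, vmax = float(v.min()), float(v.max())
    if vmax == vmin:
        return vol.copy_with(values=np.full(v.shape, lo))
    out = (v - vmin) / (vmax - vmin) * (hi - lo) + lo
    return vol.copy_with(values=out)


def discretize(vol: ImageVolume, mask: SegmentationMask, n_levels: int = 256) -> np.ndarray:
    """Min-max gray-level discretization of in-mask intensities.

    In-mask intensities are binned into integer levels 1..n_levels over
    the in-mask [min, max] range, which makes every downstream texture
    feature invariant to positive affine intensity transforms. Voxels
    outside the mask are set to 0. A constant in-mask region maps to
    level 1.
    """
    mask.require_nonempty()
    if n_levels < 1:
        raise ValueError("n_levels must be >= 1")
    v = vol.values
    m = mask.values
    vmin, vmax = v[m].min(), v[m].max()
    out = np.zeros(v.shape, dtype=np.int32)
    if vmax == vmin:
        out[m] = 1
        return out
    lev = np.floor((v[m] - vmin) / (vmax - vmin) * n_levels).astype(np.int32) + 1
    out[m] = np.clip(lev, 1, n_levels)
    return out


def extract_center_slice(vol: ImageVolume, mask: SegmentationMask, axis: int = 2) -> np.ndarray:
    """Tumor-midpoint 2-D slice with out-of-mask pixels zeroed.

    The slice index is floor of the mean of the first and last
    mask-bearing indices along ``axis`` (third array axis by default).
    """
    mask.require_nonempty()
    idx = np.where(mask.values.any(axis=tuple(a for a in range(3) if a != axis)))[0]
    mid = int((idx[0] + idx[-1]) // 2)
    sl = [slice(None)] * 3
    sl[axis] = mid
    plane = vol.values[tuple(sl)].copy()
    plane[~mask.values[tuple(sl)]] = 0.0
    return plane


def harmonize_volume(vol: ImageVolume, mask: SegmentationMask,
                     reference: ImageVolume | None = None,
                     target_spacing=DEFAULT_SPACING,
                     bias_order: int = 2) -> tuple[ImageVolume, SegmentationMask]:
    """Full fixed-order chain: resample -> bias-correct -> match -> rescale.

    Returns the harmonized volume (range exactly [-10000, 10000] for
    non-constant inputs) together with the mask resampled to the same
    grid. When ``reference`` is None the histogram-matching step is the
    identity (self-reference).
    """
    v = resample_to_spacing(vol, target_spacing)
    m = resample_mask(mask, target_spacing)
    if not m.values.any():
        raise ValueError("mask vanished under resampling")
    v = correct_bias_field(v, m, order=bias_order)
    if reference is not None:
        v = match_histogram(v, reference)
    return rescale_range(v), m
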