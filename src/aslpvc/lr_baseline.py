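"""Kernel-wise linear-regression partial-volume correction.

Within a small sliding kernel (default 5x5x1) the GM and WM magnetizations
are assumed constant, so the in-kernel difference intensities regress on the
two tissue-proportion columns without intercept.  The same pass applied to
each volume of a series yields the per-measurement estimates used to
initialize the EM (the "LR-initialized" variant).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import ndimage

from .core_model import (
    DifferenceSeries,
    ParamMaps,
    TissueFractionVolume,
    _spread_init,
    init_from_uncorrected,
)
from .errors import InvalidInputError

__all__ = ["LRConfig", "lr_fit_kernel", "lr_correct_volume", "init_from_lr"]

_COL_EPS = 1e-12  # a design column with sum of squares below this is absent


@dataclass
class LRConfig:
    """Kernel geometry and degenerate-design policy for the LR correction."""

    kernel_x: int = 5
    kernel_y: int = 5
    kernel_z: int = 1
    min_valid_voxels: int = 2
    rank_deficiency_policy: Literal["pseudo_inverse", "single_tissue_fallback"] = (
        "single_tissue_fallback"
    )
    # kernels whose normal-equation determinant falls below this fraction of
    # its maximum are treated as effectively single-tissue
    collinearity_rtol: float = 0.05
    clamp_negative: bool = False

    def __post_init__(self) -> None:
        for k in (self.kernel_x, self.kernel_y, self.kernel_z):
            if k < 1 or k % 2 == 0:
                raise InvalidInputError("kernel dimensions must be odd and >= 1")
        if self.min_valid_voxels < 2:
            raise InvalidInputError("min_valid_voxels must be >= 2")
        if self.rank_deficiency_policy not in ("pseudo_inverse", "single_tissue_fallback"):
            raise InvalidInputError(
                f"unknown rank_deficiency_policy {self.rank_deficiency_policy!r}"
            )


def lr_fit_kernel(
    values: np.ndarray,
    p_gm: np.ndarray,
    p_wm: np.ndarray,
    config: LRConfig | None = None,
) -> tuple[float, float]:
    """No-intercept least squares of kernel intensities on tissue proportions.

    Returns ``(dm_gm, dm_wm)``; NaN marks a tissue that is absent from the
    kernel or unresolvable under the rank-deficiency policy.
    """
    config = config or LRConfig()
    values = np.asarray(values, dtype=np.float64)
    p_gm = np.asarray(p_gm, dtype=np.float64)
    p_wm = np.asarray(p_wm, dtype=np.float64)
    if not (values.shape == p_gm.shape == p_wm.shape) or values.ndim != 1:
        raise InvalidInputError("values, p_gm, p_wm must be equal-length vectors")
    if values.size < config.min_valid_voxels:
        return (np.nan, np.nan)

    a11 = float(np.dot(p_gm, p_gm))
    a22 = float(np.dot(p_wm, p_wm))
    a12 = float(np.dot(p_gm, p_wm))
    b1 = float(np.dot(p_gm, values))
    b2 = float(np.dot(p_wm, values))
    gm_present = a11 > _COL_EPS
    wm_present = a22 > _COL_EPS

    if gm_present and wm_present:
        det = a11 * a22 - a12 * a12
        if det > config.collinearity_rtol * a11 * a22:
            dm_gm = (a22 * b1 - a12 * b2) / det
            dm_wm = (a11 * b2 - a12 * b1) / det
            return (dm_gm, dm_wm)
        if config.rank_deficiency_policy == "pseudo_inverse":
            sol = np.linalg.lstsq(np.column_stack([p_gm, p_wm]), values, rcond=None)[0]
            return (float(sol[0]), float(sol[1]))
        # single_tissue_fallback: attribute signal to the dominant column
        if a11 >= a22:
            return (b1 / a11, np.nan)
        return (np.nan, b2 / a22)
    if gm_present:
        return (b1 / a11, np.nan)
    if wm_present:
        return (np.nan, b2 / a22)
    return (np.nan, np.nan)


def _kernel_sums(arr: np.ndarray, config: LRConfig) -> np.ndarray:
    """Sliding-window sums with zero padding (= boundary truncation)."""
    kernel = np.ones((config.kernel_x, config.kernel_y, config.kernel_z))
    return ndimage.correlate(arr, kernel, mode="constant", cval=0.0)


def lr_correct_volume(
    image: np.ndarray,
    fractions: TissueFractionVolume,
    config: LRConfig | None = None,
) -> ParamMaps:
    """Sliding-kernel LR over every masked voxel of one 3-D difference image.

    Only in-volume, in-mask voxels enter each regression (the kernel is
    truncated at boundaries).  Vectorized via windowed normal-equation sums;
    per-voxel results are identical to :func:`lr_fit_kernel`.
    """
    config = config or LRConfig()
    image = np.asarray(image, dtype=np.float64)
    if image.shape != fractions.grid_shape:
        raise InvalidInputError("image and fractions shapes differ")
    mask = fractions.mask & np.isfinite(image)
    w = mask.astype(np.float64)
    pg = np.where(mask, fractions.p_gm, 0.0)
    pw = np.where(mask, fractions.p_wm, 0.0)
    y = np.where(mask, image, 0.0)

    n = _kernel_sums(w, config)
    a11 = _kernel_sums(pg * pg, config)
    a22 = _kernel_sums(pw * pw, config)
    a12 = _kernel_sums(pg * pw, config)
    b1 = _kernel_sums(pg * y, config)
    b2 = _kernel_sums(pw * y, config)

    dm_gm = np.full(image.shape, np.nan)
    dm_wm = np.full(image.shape, np.nan)

    valid = fractions.mask & (np.rint(n) >= config.min_valid_voxels)
    gm_present = a11 > _COL_EPS
    wm_present = a22 > _COL_EPS
    det = a11 * a22 - a12 * a12
    well_cond = det > config.collinearity_rtol * a11 * a22

    both = valid & gm_present & wm_present & well_cond
    with np.errstate(invalid="ignore", divide="ignore"):
        dm_gm[both] = (a22[both] * b1[both] - a12[both] * b2[both]) / det[both]
        dm_wm[both] = (a11[both] * b2[both] - a12[both] * b1[both]) / det[both]

        gm_only = valid & gm_present & ~(wm_present & well_cond)
        wm_only = valid & wm_present & ~(gm_present & well_cond)
        collinear = valid & gm_present & wm_present & ~well_cond
        if config.rank_deficiency_policy == "single_tissue_fallback":
            use_gm = collinear & (a11 >= a22)
            use_wm = collinear & (a11 < a22)
            dm_gm[(gm_only & ~collinear) | use_gm] = (
                b1[(gm_only & ~collinear) | use_gm] / a11[(gm_only & ~collinear) | use_gm]
            )
            dm_wm[(wm_only & ~collinear) | use_wm] = (
                b2[(wm_only & ~collinear) | use_wm] / a22[(wm_only & ~collinear) | use_wm]
            )
        else:
            dm_gm[gm_only & ~collinear] = b1[gm_only & ~collinear] / a11[gm_only & ~collinear]
            dm_wm[wm_only & ~collinear] = b2[wm_only & ~collinear] / a22[wm_only & ~collinear]
            for i, j, k in zip(*np.nonzero(collinear)):
                sel = _kernel_neighbourhood(mask, i, j, k, config)
                dm_gm[i, j, k], dm_wm[i, j, k] = lr_fit_kernel(
                    image[sel], fractions.p_gm[sel], fractions.p_wm[sel], config
                )

    if config.clamp_negative:
        dm_gm = np.where(np.isnan(dm_gm), np.nan, np.maximum(dm_gm, 0.0))
        dm_wm = np.where(np.isnan(dm_wm), np.nan, np.maximum(dm_wm, 0.0))

    maps = ParamMaps.empty(image.shape)
    maps.dm_gm = dm_gm
    maps.dm_wm = dm_wm
    maps.converged = valid
    return maps


def _kernel_neighbourhood(
    mask: np.ndarray, i: int, j: int, k: int, config: LRConfig
) -> tuple[np.ndarray, ...]:
    """Indices of in-mask voxels inside the kernel centred on (i, j, k)."""
    hx, hy, hz = config.kernel_x // 2, config.kernel_y // 2, config.kernel_z // 2
    sl = (
        slice(max(i - hx, 0), i + hx + 1),
        slice(max(j - hy, 0), j + hy + 1),
        slice(max(k - hz, 0), k + hz + 1),
    )
    sub = np.zeros_like(mask)
    sub[sl] = mask[sl]
    return np.nonzero(sub)


def init_from_lr(
    series: DifferenceSeries,
    fractions: TissueFractionVolume,
    config: LRConfig | None = None,
    variance_floor: float = 1e-8,
    s0_mode: str = "std",
) -> ParamMaps:
    """Per-measurement LR pass used to initialize the EM.

    Each of the T difference volumes is LR-corrected; per voxel and tissue the
    initial magnetization is the mean over measurements and the initial
    variance parameter is the spread of the T per-measurement estimates (the
    standard deviation by default, per the stated recipe).  Voxels with fewer
    than two valid per-measurement estimates fall back to the
    uncorrected-image initialization.
    """
    config = config or LRConfig()
    if series.n_measurements < 2:
        raise InvalidInputError("need at least 2 measurements")
    if series.grid_shape != fractions.grid_shape:
        raise InvalidInputError("series and fractions shapes differ")

    T = series.n_measurements
    shape = fractions.grid_shape
    stack_gm = np.empty(shape + (T,))
    stack_wm = np.empty(shape + (T,))
    for t in range(T):
        per_t = lr_correct_volume(series.data[..., t], fractions, config)
        stack_gm[..., t] = per_t.dm_gm
        stack_wm[..., t] = per_t.dm_wm

    fallback = init_from_uncorrected(
        series, fractions, variance_floor=variance_floor, s0_mode=s0_mode
    )
    maps = ParamMaps.empty(shape)
    mask = fractions.mask
    for tissue, stack, p in (
        ("gm", stack_gm, fractions.p_gm),
        ("wm", stack_wm, fractions.p_wm),
    ):
        valid = np.isfinite(stack)
        count = valid.sum(axis=3)
        ok = mask & (count >= 2)
        with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
            masked = np.where(valid, stack, np.nan)
            dm0 = np.nanmean(masked, axis=3)
            var0 = np.nanvar(masked, axis=3)
            spread = _spread_init(var0, np.where(p > 0, p, 1.0), s0_mode)
        s0 = np.maximum(np.where(np.isfinite(spread), spread, variance_floor),
                        variance_floor)
        dm_map = getattr(maps, f"dm_{tissue}")
        s_map = getattr(maps, f"s_{tissue}")
        dm_map[ok] = dm0[ok]
        s_map[ok] = s0[ok]
        fb = mask & ~ok
        dm_map[fb] = getattr(fallback, f"dm_{tissue}")[fb]
        s_map[fb] = getattr(fallback, f"s_{tissue}")[fb]
    return maps
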