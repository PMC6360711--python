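"""Statistical perfusion model of mixed voxels and its EM estimator.

Each voxel of a label/control difference series is modelled as the sum of a
grey-matter (GM) and a white-matter (WM) Gaussian component whose means and
variances are scaled by the tissue proportions of the voxel:

    mean   = p_gm * dm_gm + p_wm * dm_wm
    var    = p_gm * s_gm  + p_wm * s_wm

The per-voxel parameters ``(dm_gm, dm_wm, s_gm, s_wm)`` are estimated from the
T repeated measurements by expectation-maximization, treating the unobserved
per-measurement tissue contributions as latent variables constrained to sum to
the observation.  Only the tissue-weighted sums of the parameters are
identifiable from a single voxel; the split between tissues is determined by
the initialization, which is where structural (tissue-probability) information
enters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Union

import numpy as np

from .errors import (
    DegenerateModelError,
    InitFailureError,
    InvalidInputError,
    OutsideMaskError,
)

__all__ = [
    "TissueFractionVolume",
    "DifferenceSeries",
    "VoxelParams",
    "LatentMoments",
    "EMConfig",
    "ParamMaps",
    "CalibrationConstants",
    "CBFMaps",
    "apply_probability_mask",
    "voxel_sufficient_stats",
    "e_step",
    "m_step",
    "fit_voxel",
    "fit_pure_voxel",
    "fit_volume",
    "init_from_uncorrected",
    "compute_gaussian_loglik",
    "quantify_cbf",
]

_PROB_EPS = 1e-6


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class TissueFractionVolume:
    """Per-voxel GM/WM proportions with the analyzable-voxel mask."""

    p_gm: np.ndarray
    p_wm: np.ndarray
    mask: np.ndarray
    voxel_size_mm: tuple = (3.0, 3.0, 3.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.p_gm = np.asarray(self.p_gm, dtype=np.float64)
        self.p_wm = np.asarray(self.p_wm, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.p_gm.ndim != 3:
            raise InvalidInputError("tissue fractions must be 3-D volumes")
        if self.p_gm.shape != self.p_wm.shape or self.p_gm.shape != self.mask.shape:
            raise InvalidInputError("p_gm, p_wm and mask shapes differ")
        for name, p in (("p_gm", self.p_gm), ("p_wm", self.p_wm)):
            if np.any(p < -_PROB_EPS) or np.any(p > 1 + _PROB_EPS):
                raise InvalidInputError(f"{name} outside [0, 1]")
        if np.any(self.p_gm + self.p_wm > 1 + _PROB_EPS):
            raise InvalidInputError("p_gm + p_wm exceeds 1")

    @property
    def grid_shape(self) -> tuple:
        return self.p_gm.shape


@dataclass
class DifferenceSeries:
    """T label/control difference volumes stacked along the 4th axis."""

    data: np.ndarray
    voxel_size_mm: tuple = (3.0, 3.0, 3.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise InvalidInputError("difference series must be 4-D (x, y, z, t)")

    @property
    def grid_shape(self) -> tuple:
        return self.data.shape[:3]

    @property
    def n_measurements(self) -> int:
        return self.data.shape[3]

    def time_average(self) -> np.ndarray:
        return self.data.mean(axis=3)


@dataclass
class VoxelParams:
    """Model parameters of a single voxel."""

    dm_gm: float
    dm_wm: float
    s_gm: float
    s_wm: float
    gm_absent: bool = False
    wm_absent: bool = False

    def as_array(self) -> np.ndarray:
        return np.array([self.dm_gm, self.dm_wm, self.s_gm, self.s_wm], dtype=float)


@dataclass
class LatentMoments:
    """Conditional first and second moments of the latent tissue contributions."""

    x_gm: np.ndarray
    x_wm: np.ndarray
    x2_gm: np.ndarray
    x2_wm: np.ndarray


@dataclass
class EMConfig:
    """Iteration control for the per-voxel EM.

    ``stop_rule='fixed_iterations'`` runs exactly ``max_iter`` passes (the
    protocol used for the method comparisons); ``'param_change'`` stops as
    soon as the largest absolute parameter change drops below ``tol``.
    ``m_step_variant='as_printed'`` uses the previous mean iterate inside the
    variance update; ``'joint_update'`` uses the freshly updated mean (the
    classical EM M-step, guaranteeing monotone likelihood ascent).
    """

    max_iter: int = 100
    tol: float = 1e-3
    stop_rule: Literal["fixed_iterations", "param_change"] = "fixed_iterations"
    variance_floor: float = 1e-8
    m_step_variant: Literal["as_printed", "joint_update"] = "as_printed"
    pure_tissue_threshold: float = 0.0

    def __post_init__(self) -> None:
        if self.max_iter < 1:
            raise InvalidInputError("max_iter must be >= 1")
        if self.tol < 0:
            raise InvalidInputError("tol must be >= 0")
        if self.variance_floor <= 0:
            raise InvalidInputError("variance_floor must be > 0")
        if not 0 <= self.pure_tissue_threshold < 1:
            raise InvalidInputError("pure_tissue_threshold must be in [0, 1)")
        if self.stop_rule not in ("fixed_iterations", "param_change"):
            raise InvalidInputError(f"unknown stop_rule {self.stop_rule!r}")
        if self.m_step_variant not in ("as_printed", "joint_update"):
            raise InvalidInputError(f"unknown m_step_variant {self.m_step_variant!r}")


@dataclass
class ParamMaps:
    """Per-voxel parameter volumes; NaN marks missing (outside mask / absent tissue)."""

    dm_gm: np.ndarray
    dm_wm: np.ndarray
    s_gm: np.ndarray
    s_wm: np.ndarray
    n_iter: np.ndarray
    converged: np.ndarray

    @classmethod
    def empty(cls, grid_shape: tuple) -> "ParamMaps":
        nan = lambda: np.full(grid_shape, np.nan)
        return cls(
            dm_gm=nan(),
            dm_wm=nan(),
            s_gm=nan(),
            s_wm=nan(),
            n_iter=np.zeros(grid_shape, dtype=np.int32),
            converged=np.zeros(grid_shape, dtype=bool),
        )


@dataclass
class CalibrationConstants:
    """Tissue conversion factors and equilibrium magnetization.

    With ``f_gm = f_wm = 1`` and ``m0 = 1`` (the phantom convention) CBF
    values equal the difference-magnetization values numerically.
    """

    f_gm: float = 1.0
    f_wm: float = 1.0
    m0: Union[float, np.ndarray] = 1.0

    def __post_init__(self) -> None:
        if self.f_gm <= 0 or self.f_wm <= 0:
            raise InvalidInputError("calibration factors must be > 0")


@dataclass
class CBFMaps:
    """Per-voxel CBF volumes in mL/100 g/min."""

    cbf_gm: np.ndarray
    cbf_wm: np.ndarray
    cbf_total: np.ndarray
    cbf_gm_pure: np.ndarray


# ---------------------------------------------------------------------------
# masking
# ---------------------------------------------------------------------------


def apply_probability_mask(
    p_gm: np.ndarray,
    p_wm: np.ndarray,
    threshold: float = 0.1,
    voxel_size_mm: tuple = (3.0, 3.0, 3.0),
    affine: np.ndarray | None = None,
) -> TissueFractionVolume:
    """Remove voxels with both tissue probabilities below ``threshold``.

    Probabilities below the threshold are zeroed, so a voxel with e.g.
    ``p_gm < threshold`` keeps only its WM component and is handled by the
    single-tissue estimation path.
    """
    if not 0 <= threshold < 1:
        raise InvalidInputError("threshold must be in [0, 1)")
    p_gm = np.asarray(p_gm, dtype=np.float64).copy()
    p_wm = np.asarray(p_wm, dtype=np.float64).copy()
    if threshold > 0:
        p_gm[p_gm < threshold] = 0.0
        p_wm[p_wm < threshold] = 0.0
        mask = (p_gm >= threshold) | (p_wm >= threshold)
    else:
        mask = (p_gm + p_wm) > 0
    return TissueFractionVolume(
        p_gm=p_gm, p_wm=p_wm, mask=mask, voxel_size_mm=voxel_size_mm, affine=affine
    )


# ---------------------------------------------------------------------------
# per-voxel operations
# ---------------------------------------------------------------------------


def voxel_sufficient_stats(y: np.ndarray) -> tuple[float, float]:
    """Sample mean and population variance of one voxel's measurement vector."""
    y = np.asarray(y, dtype=np.float64)
    if y.ndim != 1 or y.size < 2:
        raise InvalidInputError("need a 1-D vector of at least 2 measurements")
    if not np.all(np.isfinite(y)):
        raise InvalidInputError("non-finite measurement values")
    mean = float(y.mean())
    var = float(np.mean((y - mean) ** 2))
    return mean, var


def e_step(
    y_t: Union[float, np.ndarray],
    params: VoxelParams,
    p_gm: float,
    p_wm: float,
) -> LatentMoments:
    """Conditional moments of the latent tissue contributions given Y = X_gm + X_wm.

    The latent pair is bivariate Gaussian with independent components of
    means ``p * dm`` and variances ``p * s``; conditioning on their sum gives
    the usual linear update with weight proportional to each component's
    variance, and a shared conditional variance.
    """
    y = np.atleast_1d(np.asarray(y_t, dtype=np.float64))
    v_gm = p_gm * params.s_gm
    v_wm = p_wm * params.s_wm
    total = v_gm + v_wm
    if total <= 0:
        if p_gm > 0 and p_wm > 0:
            raise DegenerateModelError("zero total variance in mixed voxel")
        # single-tissue voxel: the whole observation belongs to the present tissue
        if p_gm > 0:
            x_gm = y
            x_wm = np.zeros_like(y)
        else:
            x_gm = np.zeros_like(y)
            x_wm = y
        return LatentMoments(x_gm=x_gm, x_wm=x_wm, x2_gm=x_gm**2, x2_wm=x_wm**2)
    mu = p_gm * params.dm_gm + p_wm * params.dm_wm
    w_gm = v_gm / total
    w_wm = v_wm / total
    innov = y - mu
    x_gm = p_gm * params.dm_gm + w_gm * innov
    x_wm = p_wm * params.dm_wm + w_wm * innov
    cond_var = v_gm * v_wm / total
    return LatentMoments(
        x_gm=x_gm,
        x_wm=x_wm,
        x2_gm=x_gm**2 + cond_var,
        x2_wm=x_wm**2 + cond_var,
    )


def m_step(
    moments: LatentMoments,
    params_prev: VoxelParams,
    p_gm: float,
    p_wm: float,
    T: int,
    variant: str = "as_printed",
    variance_floor: float = 1e-8,
) -> VoxelParams:
    """Update the four voxel parameters from the latent moments.

    ``variant='as_printed'`` references the previous mean iterate inside the
    variance numerator; ``'joint_update'`` references the new one (the exact
    maximizer of the expected complete-data log-likelihood).
    """
    if p_gm <= 0 or p_wm <= 0:
        raise OutsideMaskError("m_step requires both tissue proportions > 0")
    if T < 2:
        raise InvalidInputError("need T >= 2")
    dm_gm_new = float(np.sum(moments.x_gm) / (T * p_gm))
    dm_wm_new = float(np.sum(moments.x_wm) / (T * p_wm))
    if variant == "joint_update":
        ref_gm, ref_wm = dm_gm_new, dm_wm_new
    elif variant == "as_printed":
        ref_gm, ref_wm = params_prev.dm_gm, params_prev.dm_wm
    else:
        raise InvalidInputError(f"unknown m_step variant {variant!r}")
    a_gm = p_gm * ref_gm
    a_wm = p_wm * ref_wm
    s_gm_new = float(
        np.sum(moments.x2_gm - 2 * moments.x_gm * a_gm + a_gm**2) / (T * p_gm)
    )
    s_wm_new = float(
        np.sum(moments.x2_wm - 2 * moments.x_wm * a_wm + a_wm**2) / (T * p_wm)
    )
    return VoxelParams(
        dm_gm=dm_gm_new,
        dm_wm=dm_wm_new,
        s_gm=max(s_gm_new, variance_floor),
        s_wm=max(s_wm_new, variance_floor),
    )


def fit_pure_voxel(
    y: np.ndarray,
    p_tissue: float,
    tissue: str = "gm",
    variance_floor: float = 1e-8,
) -> VoxelParams:
    """Closed-form single-tissue fit: dm = mean/p, s = popvar/p.

    The absent tissue's parameters are set to 0 / the variance floor and
    flagged absent so downstream maps can mark them missing.
    """
    if p_tissue <= 0:
        raise OutsideMaskError("p_tissue must be > 0")
    mean, var = voxel_sufficient_stats(y)
    dm = mean / p_tissue
    s = max(var / p_tissue, variance_floor)
    if tissue == "gm":
        return VoxelParams(dm_gm=dm, dm_wm=0.0, s_gm=s, s_wm=variance_floor, wm_absent=True)
    if tissue == "wm":
        return VoxelParams(dm_gm=0.0, dm_wm=dm, s_gm=variance_floor, s_wm=s, gm_absent=True)
    raise InvalidInputError(f"unknown tissue {tissue!r}")


def fit_voxel(
    y: np.ndarray,
    p_gm: float,
    p_wm: float,
    init: VoxelParams,
    config: EMConfig | None = None,
) -> tuple[VoxelParams, int, bool]:
    """Run the EM on one voxel's measurement vector.

    Returns the final parameters, the number of iterations executed and
    whether the last parameter change was below ``config.tol``.
    """
    config = config or EMConfig()
    y = np.asarray(y, dtype=np.float64)
    if not np.all(np.isfinite(y)):
        raise InvalidInputError("non-finite measurement values")
    if p_gm <= 0 and p_wm <= 0:
        raise OutsideMaskError("voxel has no tissue")
    thr = config.pure_tissue_threshold
    if p_wm <= thr:
        return fit_pure_voxel(y, p_gm, "gm", config.variance_floor), 0, True
    if p_gm <= thr:
        return fit_pure_voxel(y, p_wm, "wm", config.variance_floor), 0, True

    params = VoxelParams(
        dm_gm=init.dm_gm,
        dm_wm=init.dm_wm,
        s_gm=max(init.s_gm, config.variance_floor),
        s_wm=max(init.s_wm, config.variance_floor),
    )
    T = y.size
    delta = np.inf
    n_done = 0
    for n_done in range(1, config.max_iter + 1):
        moments = e_step(y, params, p_gm, p_wm)
        new = m_step(
            moments,
            params,
            p_gm,
            p_wm,
            T,
            variant=config.m_step_variant,
            variance_floor=config.variance_floor,
        )
        delta = float(np.max(np.abs(new.as_array() - params.as_array())))
        params = new
        if config.stop_rule == "param_change" and delta < config.tol:
            break
    return params, n_done, delta < config.tol


# ---------------------------------------------------------------------------
# volume-level driver (vectorized, mathematically identical to fit_voxel)
# ---------------------------------------------------------------------------


def _check_shapes(series: DifferenceSeries, fractions: TissueFractionVolume) -> None:
    if series.grid_shape != fractions.grid_shape:
        raise InvalidInputError(
            f"series grid {series.grid_shape} != fractions grid {fractions.grid_shape}"
        )


def _masked_stats(series: DifferenceSeries, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    y = series.data[mask]  # (n_vox, T)
    if not np.all(np.isfinite(y)):
        raise InvalidInputError("non-finite series values inside the mask")
    ybar = y.mean(axis=1)
    yvar = y.var(axis=1)  # population variance
    return ybar, yvar


def _em_mixed_vectorized(
    ybar: np.ndarray,
    yvar: np.ndarray,
    pg: np.ndarray,
    pw: np.ndarray,
    dm_g: np.ndarray,
    dm_w: np.ndarray,
    s_g: np.ndarray,
    s_w: np.ndarray,
    config: EMConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """EM on all mixed voxels at once.

    Every latent first moment is linear in Y_t, so the M-step depends on the
    data only through the per-voxel sample mean and population variance; the
    iteration below is algebraically identical to running ``e_step``/``m_step``
    over the full measurement vector.
    """
    floor = config.variance_floor
    dm_g = dm_g.copy()
    dm_w = dm_w.copy()
    s_g = np.maximum(s_g, floor)
    s_w = np.maximum(s_w, floor)
    n = dm_g.size
    n_iter = np.zeros(n, dtype=np.int32)
    last_delta = np.full(n, np.inf)
    active = np.ones(n, dtype=bool)

    for it in range(1, config.max_iter + 1):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        g, w = pg[idx], pw[idx]
        a_g = g * dm_g[idx]
        a_w = w * dm_w[idx]
        v_g = g * s_g[idx]
        v_w = w * s_w[idx]
        tot = v_g + v_w
        wt_g = v_g / tot
        wt_w = v_w / tot
        innov = ybar[idx] - (a_g + a_w)
        c_g = a_g + wt_g * innov  # per-t mean of the GM latent moments
        c_w = a_w + wt_w * innov
        cond_var = v_g * v_w / tot
        dm_g_new = c_g / g
        dm_w_new = c_w / w
        if config.m_step_variant == "joint_update":
            ref_g, ref_w = g * dm_g_new, w * dm_w_new
        else:
            ref_g, ref_w = a_g, a_w
        # mean over t of X^2 is c^2 + wt^2 * popvar(y); add shared cond. variance
        m2_g = c_g**2 + wt_g**2 * yvar[idx] + cond_var
        m2_w = c_w**2 + wt_w**2 * yvar[idx] + cond_var
        s_g_new = np.maximum((m2_g - 2 * c_g * ref_g + ref_g**2) / g, floor)
        s_w_new = np.maximum((m2_w - 2 * c_w * ref_w + ref_w**2) / w, floor)

        delta = np.maximum.reduce(
            [
                np.abs(dm_g_new - dm_g[idx]),
                np.abs(dm_w_new - dm_w[idx]),
                np.abs(s_g_new - s_g[idx]),
                np.abs(s_w_new - s_w[idx]),
            ]
        )
        dm_g[idx] = dm_g_new
        dm_w[idx] = dm_w_new
        s_g[idx] = s_g_new
        s_w[idx] = s_w_new
        n_iter[idx] = it
        last_delta[idx] = delta
        if config.stop_rule == "param_change":
            active[idx[delta < config.tol]] = False

    converged = last_delta < config.tol
    return dm_g, dm_w, s_g, s_w, n_iter, converged


def fit_volume(
    series: DifferenceSeries,
    fractions: TissueFractionVolume,
    init_maps: ParamMaps,
    config: EMConfig | None = None,
) -> ParamMaps:
    """Apply the EM voxel-wise over the masked volume.

    Mixed voxels run the EM; voxels where one proportion is at or below
    ``config.pure_tissue_threshold`` use the closed-form single-tissue fit.
    Voxels outside the mask stay NaN.
    """
    config = config or EMConfig()
    _check_shapes(series, fractions)
    mask = fractions.mask
    ybar, yvar = _masked_stats(series, mask)
    pg = fractions.p_gm[mask]
    pw = fractions.p_wm[mask]
    thr = config.pure_tissue_threshold
    floor = config.variance_floor

    n = pg.size
    dm_g = np.full(n, np.nan)
    dm_w = np.full(n, np.nan)
    s_g = np.full(n, np.nan)
    s_w = np.full(n, np.nan)
    n_iter = np.zeros(n, dtype=np.int32)
    converged = np.zeros(n, dtype=bool)

    mixed = (pg > thr) & (pw > thr)
    pure_g = (pg > thr) & ~mixed
    pure_w = (pw > thr) & ~mixed

    if np.any(mixed):
        init_g = init_maps.dm_gm[mask][mixed]
        init_w = init_maps.dm_wm[mask][mixed]
        init_sg = init_maps.s_gm[mask][mixed]
        init_sw = init_maps.s_wm[mask][mixed]
        for name, arr in (
            ("dm_gm", init_g),
            ("dm_wm", init_w),
            ("s_gm", init_sg),
            ("s_wm", init_sw),
        ):
            if not np.all(np.isfinite(arr)):
                raise InvalidInputError(f"init map {name} not defined on all mixed voxels")
        out = _em_mixed_vectorized(
            ybar[mixed], yvar[mixed], pg[mixed], pw[mixed],
            init_g, init_w, init_sg, init_sw, config,
        )
        dm_g[mixed], dm_w[mixed], s_g[mixed], s_w[mixed], n_iter[mixed], converged[mixed] = out

    if np.any(pure_g):
        dm_g[pure_g] = ybar[pure_g] / pg[pure_g]
        s_g[pure_g] = np.maximum(yvar[pure_g] / pg[pure_g], floor)
        converged[pure_g] = True
    if np.any(pure_w):
        dm_w[pure_w] = ybar[pure_w] / pw[pure_w]
        s_w[pure_w] = np.maximum(yvar[pure_w] / pw[pure_w], floor)
        converged[pure_w] = True

    maps = ParamMaps.empty(fractions.grid_shape)
    maps.dm_gm[mask] = dm_g
    maps.dm_wm[mask] = dm_w
    maps.s_gm[mask] = s_g
    maps.s_wm[mask] = s_w
    maps.n_iter[mask] = n_iter
    maps.converged[mask] = converged
    return maps


# ---------------------------------------------------------------------------
# initialization and diagnostics
# ---------------------------------------------------------------------------


def _spread_init(var: np.ndarray | float, mean_p: np.ndarray | float, s0_mode: str):
    """Initial variance-parameter value from a sample variance and a proportion.

    ``'std'`` follows the stated initialization recipe literally (the spread
    is entered as a standard deviation); ``'var'`` enters it as a variance;
    the ``*_over_p`` variants divide by the tissue proportion for dimensional
    consistency with the proportion-scaled variance model.
    """
    if s0_mode == "std":
        return np.sqrt(var)
    if s0_mode == "var":
        return var
    if s0_mode == "std_over_p":
        return np.sqrt(var) / mean_p
    if s0_mode == "var_over_p":
        return var / mean_p
    raise InvalidInputError(f"unknown s0_mode {s0_mode!r}")


def init_from_uncorrected(
    series: DifferenceSeries,
    fractions: TissueFractionVolume,
    gm_pure_cut: float = 0.9,
    wm_pure_cut: float = 0.9,
    variance_floor: float = 1e-8,
    divide_mean_by_proportion: bool = False,
    s0_mode: str = "std",
) -> ParamMaps:
    """Spatially constant initialization from the time-averaged image.

    ``dm_gm`` starts at the mean of the averaged image over near-pure GM
    voxels (``p_gm >= gm_pure_cut``); ``s_gm`` at the spread of that region
    (by default its standard deviation, per the stated recipe; see
    :func:`_spread_init`); symmetrically for WM.
    """
    _check_shapes(series, fractions)
    avg = series.time_average()
    maps = ParamMaps.empty(fractions.grid_shape)
    mask = fractions.mask
    for tissue, p, cut in (
        ("gm", fractions.p_gm, gm_pure_cut),
        ("wm", fractions.p_wm, wm_pure_cut),
    ):
        region = mask & (p >= cut)
        if not np.any(region):
            raise InitFailureError(
                f"no voxels with p_{tissue} >= {cut}; cannot initialize {tissue.upper()}"
            )
        vals = avg[region]
        mean_p = float(p[region].mean())
        dm0 = float(vals.mean())
        if divide_mean_by_proportion:
            dm0 /= mean_p
        s0 = max(float(_spread_init(vals.var(), mean_p, s0_mode)), variance_floor)
        getattr(maps, f"dm_{tissue}")[mask] = dm0
        getattr(maps, f"s_{tissue}")[mask] = s0
    return maps


def compute_gaussian_loglik(
    series: DifferenceSeries,
    fractions: TissueFractionVolume,
    maps: ParamMaps,
) -> np.ndarray:
    """Per-voxel Gaussian log-likelihood of the series under the fitted model.

    Depends on the parameters only through the identifiable tissue-weighted
    mean and variance.  NaN outside the mask.
    """
    _check_shapes(series, fractions)
    mask = fractions.mask
    y = series.data[mask]
    T = series.n_measurements
    ybar = y.mean(axis=1)
    yvar = y.var(axis=1)
    pg = fractions.p_gm[mask]
    pw = fractions.p_wm[mask]
    dm_g = np.nan_to_num(maps.dm_gm[mask])
    dm_w = np.nan_to_num(maps.dm_wm[mask])
    s_g = np.nan_to_num(maps.s_gm[mask])
    s_w = np.nan_to_num(maps.s_wm[mask])
    mu = pg * dm_g + pw * dm_w
    var = pg * s_g + pw * s_w
    if np.any(var <= 0):
        raise DegenerateModelError("zero model variance inside the mask")
    ll = -0.5 * T * (np.log(2 * np.pi * var) + (yvar + (ybar - mu) ** 2) / var)
    out = np.full(fractions.grid_shape, np.nan)
    out[mask] = ll
    return out


def quantify_cbf(
    maps: ParamMaps,
    fractions: TissueFractionVolume,
    calib: CalibrationConstants | None = None,
) -> CBFMaps:
    """Convert difference-magnetization maps to CBF maps.

    ``cbf_gm``/``cbf_wm`` are the per-voxel tissue contributions
    (proportion-weighted); ``cbf_gm_pure`` is the per-unit-GM value used in
    ROI analyses.  Absent-tissue contributions count as zero in the total.
    """
    calib = calib or CalibrationConstants()
    mask = fractions.mask
    m0 = np.asarray(calib.m0, dtype=np.float64)
    if m0.ndim == 3:
        if np.any(m0[mask] <= 0):
            raise InvalidInputError("nonpositive M0 inside the mask")
    elif float(m0) <= 0:
        raise InvalidInputError("nonpositive M0")
    nanshape = fractions.grid_shape
    cbf_gm = np.full(nanshape, np.nan)
    cbf_wm = np.full(nanshape, np.nan)
    cbf_total = np.full(nanshape, np.nan)
    cbf_gm_pure = np.full(nanshape, np.nan)

    m0_m = m0[mask] if m0.ndim == 3 else float(m0)
    dm_g = maps.dm_gm[mask]
    dm_w = maps.dm_wm[mask]
    pg = fractions.p_gm[mask]
    pw = fractions.p_wm[mask]
    gm_part = np.where(np.isnan(dm_g), 0.0, pg * calib.f_gm * np.nan_to_num(dm_g)) / m0_m
    wm_part = np.where(np.isnan(dm_w), 0.0, pw * calib.f_wm * np.nan_to_num(dm_w)) / m0_m
    cbf_gm[mask] = gm_part
    cbf_wm[mask] = wm_part
    cbf_total[mask] = gm_part + wm_part
    cbf_gm_pure[mask] = calib.f_gm * dm_g / m0_m
    return CBFMaps(cbf_gm=cbf_gm, cbf_wm=cbf_wm, cbf_total=cbf_total, cbf_gm_pure=cbf_gm_pure)
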