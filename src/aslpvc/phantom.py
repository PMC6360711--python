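"""Digital head phantom: synthetic tissue fractions, truth maps, noisy series.

The anatomy is procedural (no external data): a warped radial field defines a
WM core wrapped in a GM ribbon; blurring the tissue indicators creates the
mixed boundary voxels that partial-volume correction acts on.  Ground-truth
perfusion is piecewise constant (GM 60, WM 20 mL/100 g/min) with optional
spherical/cubic lesions, and the noisy series adds i.i.d. Gaussian noise to
the clean mixture signal for each of the T measurements.

Signal convention: calibration factors and M0 are 1, so signal units equal
mL/100 g/min.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .core_model import (
    DifferenceSeries,
    TissueFractionVolume,
    apply_probability_mask,
)
from .errors import InvalidInputError

__all__ = [
    "LesionSpec",
    "PhantomConfig",
    "PhantomTruth",
    "synth_fractions",
    "place_lesions",
    "default_sim1_lesions",
    "default_sim2_lesions",
    "build_truth_sim1",
    "build_truth_sim2",
    "render_series",
]


@dataclass
class LesionSpec:
    """A spherical or cubic perfusion lesion in voxel coordinates."""

    shape: str  # 'sphere' | 'cube'
    center: tuple
    size: int  # radius in voxels (sphere) or edge length (cube)
    cbf_value: float

    def __post_init__(self) -> None:
        if self.shape not in ("sphere", "cube"):
            raise InvalidInputError(f"unknown lesion shape {self.shape!r}")
        if self.size <= 0:
            raise InvalidInputError("lesion size must be > 0")
        if self.cbf_value < 0:
            raise InvalidInputError("lesion CBF must be >= 0")

    def mask_array(self, grid_shape: tuple) -> np.ndarray:
        """Boolean membership grid; raises if the lesion leaves the grid."""
        out = np.zeros(grid_shape, dtype=bool)
        cx, cy, cz = self.center
        if self.shape == "sphere":
            r = self.size
            lo = [int(np.floor(c - r)) for c in (cx, cy, cz)]
            hi = [int(np.ceil(c + r)) for c in (cx, cy, cz)]
            if min(lo) < 0 or any(h >= s for h, s in zip(hi, grid_shape)):
                raise InvalidInputError(f"sphere lesion at {self.center} leaves the grid")
            ix, iy, iz = np.ogrid[
                lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1
            ]
            # a voxel belongs to the sphere if its centre lies strictly inside
            inside = (ix - cx) ** 2 + (iy - cy) ** 2 + (iz - cz) ** 2 < r**2
            out[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1] = inside
        else:
            e = self.size
            start = [int(c) - (e - 1) // 2 for c in (cx, cy, cz)]
            if min(start) < 0 or any(s + e > g for s, g in zip(start, grid_shape)):
                raise InvalidInputError(f"cube lesion at {self.center} leaves the grid")
            out[
                start[0] : start[0] + e,
                start[1] : start[1] + e,
                start[2] : start[2] + e,
            ] = True
        return out


@dataclass
class PhantomConfig:
    """Generating configuration of the phantom and its noisy series."""

    grid_shape: tuple = (60, 72, 60)
    voxel_size_mm: tuple = (3.0, 3.0, 3.0)
    gm_cbf: float = 60.0
    wm_cbf: float = 20.0
    lesions: Optional[Sequence[LesionSpec]] = None
    noise_std: float = 10.0
    n_pairs: int = 40
    seed: int = 0
    prob_floor: float = 0.1

    def __post_init__(self) -> None:
        if self.noise_std < 0:
            raise InvalidInputError("noise_std must be >= 0")
        if self.n_pairs < 1:
            raise InvalidInputError("n_pairs must be >= 1")


@dataclass
class PhantomTruth:
    """Ground-truth CBF volumes plus everything needed to regenerate them."""

    fractions: TissueFractionVolume
    gm_cbf_true: np.ndarray
    wm_cbf_true: np.ndarray
    clean_signal: np.ndarray
    config: PhantomConfig
    lesions: list = field(default_factory=list)
    lesion_masks: list = field(default_factory=list)


def synth_fractions(
    grid_shape: tuple = (60, 72, 60),
    seed: int = 0,
    voxel_size_mm: tuple = (3.0, 3.0, 3.0),
    prob_floor: float = 0.1,
    wm_radius: float = 0.70,
    gm_outer: float = 0.80,
    inner_width: float = 0.10,
    outer_width: float = 0.008,
    warp_std: float = 0.25,
    warp_sigma: float = 2.5,
    brain_scale: float = 0.40,
    deep_gm: bool = True,
) -> TissueFractionVolume:
    """Procedural brain-like GM/WM probability volume.

    A smoothly warped radial field defines a WM core wrapped in a thin,
    folded cortical GM ribbon.  The GM/WM interface is a wide linear ramp
    (mixed voxels with ``p_gm + p_wm = 1``, as in segmentations of deep
    boundaries), while the outer GM/CSF edge is a narrow ramp (thin
    partial-volume rim).  Two ellipsoidal deep-GM nuclei sit inside the WM
    core (the homogeneous GM territory that hosts simulated lesions).
    Voxels with both probabilities below ``prob_floor`` are masked out.
    """
    if len(grid_shape) != 3 or min(grid_shape) < 16:
        raise InvalidInputError("grid must be 3-D with at least 16 voxels per axis")
    rng = np.random.default_rng(seed)
    ax = [(np.arange(n) - (n - 1) / 2) / (brain_scale * n) for n in grid_shape]
    gx = ax[0][:, None, None]
    gy = ax[1][None, :, None]
    gz = ax[2][None, None, :]
    r = np.sqrt(gx**2 + gy**2 + gz**2)
    warp = ndimage.gaussian_filter(rng.standard_normal(grid_shape), warp_sigma)
    sd = warp.std()
    if sd > 0:
        warp *= warp_std / sd
    fld = r + warp
    # 0 inside the WM core, ramping to 1 across the GM/WM interface
    u_inner = np.clip((fld - wm_radius) / inner_width + 0.5, 0.0, 1.0)
    # 1 inside the brain, ramping to 0 across the outer (CSF) edge
    u_outer = np.clip((gm_outer - fld) / outer_width + 0.5, 0.0, 1.0)
    v_deep = np.zeros(grid_shape)
    if deep_gm:
        # paired deep-GM nuclei: GM share taken from the WM core
        for cx in (-0.33, 0.33):
            d = np.sqrt(
                ((gx - cx) / 0.30) ** 2 + (gy / 0.24) ** 2 + (gz / 0.24) ** 2
            )
            v_deep = np.maximum(v_deep, np.clip((1.0 - d) / 0.30 + 0.5, 0.0, 1.0))
    p_gm = u_outer * (u_inner + (1.0 - u_inner) * v_deep)
    p_wm = u_outer * (1.0 - u_inner) * (1.0 - v_deep)
    return apply_probability_mask(
        p_gm, p_wm, threshold=prob_floor, voxel_size_mm=voxel_size_mm
    )


def place_lesions(
    fractions: TissueFractionVolume,
    prototypes: Sequence[tuple],
) -> list[LesionSpec]:
    """Deterministically place lesion prototypes in high-GM territory.

    ``prototypes`` is a sequence of ``(shape, size, cbf_value)``.  The x-range
    of the grid is split into one slab per lesion and each lesion is centred
    on the slab's maximum of the smoothed GM probability, keeping a margin so
    lesions fit the grid and cannot overlap across slabs.
    """
    k = len(prototypes)
    nx = fractions.grid_shape[0]
    score = ndimage.gaussian_filter(
        np.where(fractions.mask, fractions.p_gm, 0.0), 3.0
    )
    edges = np.linspace(0, nx, k + 1).astype(int)
    specs: list[LesionSpec] = []
    for idx, (shape, size, value) in enumerate(prototypes):
        reff = size if shape == "sphere" else (size + 1) // 2
        margin = reff + 1
        xlo = edges[idx] + margin
        xhi = edges[idx + 1] - margin
        if xhi <= xlo:
            raise InvalidInputError("grid too small to place lesions")
        sub = score[xlo:xhi].copy()
        sub[:, :margin, :] = -np.inf
        sub[:, -margin:, :] = -np.inf
        sub[:, :, :margin] = -np.inf
        sub[:, :, -margin:] = -np.inf
        flat = int(np.argmax(sub))
        ci, cj, ck = np.unravel_index(flat, sub.shape)
        specs.append(
            LesionSpec(shape=shape, center=(int(ci + xlo), int(cj), int(ck)), size=size,
                       cbf_value=float(value))
        )
    return specs


def default_sim1_lesions(fractions: TissueFractionVolume) -> list[LesionSpec]:
    """Hypo- (30) and hyper-perfused (90) spheres of radius 5 voxels."""
    return place_lesions(fractions, [("sphere", 5, 30.0), ("sphere", 5, 90.0)])


def default_sim2_lesions(fractions: TissueFractionVolume) -> list[LesionSpec]:
    """Three small-contrast lesions: sphere r5 @75, cube 3x3x3 @45, cube 2x2x2 @75."""
    return place_lesions(
        fractions, [("sphere", 5, 75.0), ("cube", 3, 45.0), ("cube", 2, 75.0)]
    )


def _build_truth(
    fractions: TissueFractionVolume,
    config: PhantomConfig,
    lesions: Sequence[LesionSpec],
) -> PhantomTruth:
    shape = fractions.grid_shape
    gm_true = np.full(shape, config.gm_cbf)
    wm_true = np.full(shape, config.wm_cbf)
    masks = []
    occupied = np.zeros(shape, dtype=bool)
    for spec in lesions:
        lmask = spec.mask_array(shape)
        if np.any(lmask & occupied):
            raise InvalidInputError("lesions overlap")
        occupied |= lmask
        gm_true[lmask] = spec.cbf_value
        masks.append(lmask)
    clean = np.where(
        fractions.mask, fractions.p_gm * gm_true + fractions.p_wm * wm_true, 0.0
    )
    return PhantomTruth(
        fractions=fractions,
        gm_cbf_true=gm_true,
        wm_cbf_true=wm_true,
        clean_signal=clean,
        config=config,
        lesions=list(lesions),
        lesion_masks=masks,
    )


def build_truth_sim1(
    fractions: TissueFractionVolume, config: PhantomConfig | None = None
) -> PhantomTruth:
    """Simulation-1 truth: homogeneous GM 60 / WM 20 with hypo/hyper spheres."""
    config = config or PhantomConfig(grid_shape=fractions.grid_shape)
    lesions = (
        config.lesions if config.lesions is not None else default_sim1_lesions(fractions)
    )
    return _build_truth(fractions, config, lesions)


def build_truth_sim2(
    fractions: TissueFractionVolume, config: PhantomConfig | None = None
) -> PhantomTruth:
    """Simulation-2 truth: three small lesions whose contrast equals the high noise level."""
    config = config or PhantomConfig(grid_shape=fractions.grid_shape, noise_std=15.0)
    lesions = (
        config.lesions if config.lesions is not None else default_sim2_lesions(fractions)
    )
    return _build_truth(fractions, config, lesions)


def render_series(
    truth: PhantomTruth,
    noise_std: float | None = None,
    n_pairs: int | None = None,
    seed: int | None = None,
) -> DifferenceSeries:
    """Generate the T noisy difference volumes for one phantom realization.

    Noise is drawn only for in-mask voxels; outside voxels are zero.
    """
    cfg = truth.config
    noise_std = cfg.noise_std if noise_std is None else noise_std
    n_pairs = cfg.n_pairs if n_pairs is None else n_pairs
    seed = cfg.seed if seed is None else seed
    if noise_std < 0:
        raise InvalidInputError("noise_std must be >= 0")
    mask = truth.fractions.mask
    shape = truth.fractions.grid_shape
    data = np.zeros(shape + (n_pairs,))
    clean = truth.clean_signal[mask]
    if noise_std > 0:
        rng = np.random.default_rng(seed)
        noise = rng.normal(0.0, noise_std, size=(clean.size, n_pairs))
        data[mask] = clean[:, None] + noise
    else:
        data[mask] = clean[:, None]
    return DifferenceSeries(data=data, voxel_size_mm=truth.fractions.voxel_size_mm)
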