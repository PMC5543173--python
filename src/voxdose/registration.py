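"""Masked multi-resolution log-diffeomorphic demons registration.

The transform is parameterised by a stationary velocity field ``v``; the
deformation applied to the moving image is ``exp(v)`` (scaling and squaring),
so ``exp(-v)`` is always available as its inverse. Per iteration a symmetric
Thirion-type force is computed inside the reference-space mask, smoothed with
a fluid kernel, composed into the velocity at first order (``v <- v + u``)
and the velocity is smoothed with a diffusion kernel. A 3-level image pyramid
(x4, x2, x1 downsampling by default) handles large offsets.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .fields import VelocityField, exp_velocity, warp_scalar
from .grids import BinaryMask, Grid, ScalarVolume

__all__ = ["DemonsParams", "demons_register", "build_registration_mask", "normalize_intensity"]

log = logging.getLogger(__name__)


@dataclass
class DemonsParams:
    levels: int = 3
    downsample_factors: tuple[int, ...] = (4, 2, 1)
    iters_per_level: tuple[int, ...] = (50, 50, 30)
    fluid_sigma: float = 2.0  # mm, smoothing of the update field
    diffusion_sigma: float = 1.5  # mm, smoothing of the velocity field
    force_epsilon_rel: float = 1e-6  # denominator floor, fraction of intensity range^2
    max_step_voxels: float = 0.5  # cap on the per-iteration update

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if len(self.downsample_factors) != self.levels or len(self.iters_per_level) != self.levels:
            raise ValueError("downsample_factors and iters_per_level must have `levels` entries")
        if self.fluid_sigma < 0 or self.diffusion_sigma < 0:
            raise ValueError("smoothing sigmas must be non-negative")
        if self.max_step_voxels <= 0:
            raise ValueError("max_step_voxels must be positive")


def normalize_intensity(fixed: np.ndarray, moving: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rescale both images to [0, 1] over their joint 1st-99th percentile range."""
    joint = np.concatenate([fixed.ravel(), moving.ravel()])
    lo, hi = np.percentile(joint, [1.0, 99.0])
    if hi <= lo:
        hi = lo + 1.0
    scale = 1.0 / (hi - lo)
    return (
        np.clip((fixed - lo) * scale, 0.0, 1.0),
        np.clip((moving - lo) * scale, 0.0, 1.0),
    )


def build_registration_mask(
    body: BinaryMask, organs: list[BinaryMask], radius_mm: float
) -> BinaryMask:
    """Body contour intersected with a spherical dilation of the organ union.

    The dilation ball is measured in millimetres (converted per-axis by the
    voxel spacing); this reproduces the registration mask used to focus the
    demons forces on the anatomy of interest.
    """
    if radius_mm < 0:
        raise ValueError("radius_mm must be non-negative")
    grid = body.grid
    union = np.zeros(grid.shape, dtype=bool)
    for organ in organs:
        if not organ.grid.same_as(grid):
            raise ValueError("all masks must share the body mask's grid")
        union |= organ.data
    if not union.any():
        raise ValueError("organ union is empty")
    if radius_mm == 0:
        dilated = union
    else:
        dist = ndimage.distance_transform_edt(~union, sampling=grid.spacing)
        dilated = dist <= radius_mm
    return BinaryMask(dilated & body.data, grid, "registration_mask")


# ---------------------------------------------------------------------------
# pyramid helpers
# ---------------------------------------------------------------------------

def _downsample_volume(data: np.ndarray, factor: int, order: int = 1) -> np.ndarray:
    if factor == 1:
        return data
    smoothed = ndimage.gaussian_filter(data, sigma=factor / 2.0)
    return ndimage.zoom(smoothed, 1.0 / factor, order=order, grid_mode=True, mode="nearest")


def _level_grid(grid: Grid, shape: tuple[int, ...]) -> Grid:
    spacing = tuple(
        grid.spacing[a] * grid.shape[a] / shape[a] for a in range(3)
    )
    return Grid(tuple(shape), spacing, grid.origin)


def _resize_vector(data: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    if tuple(data.shape[:3]) == tuple(shape):
        return data
    out = np.empty(tuple(shape) + (3,))
    zoom = [shape[a] / data.shape[a] for a in range(3)]
    for c in range(3):
        out[..., c] = ndimage.zoom(
            data[..., c], zoom, order=1, grid_mode=True, mode="nearest"
        )
    return out


def _mm_sigma_to_vox(sigma_mm: float, spacing) -> list[float]:
    return [sigma_mm / s for s in spacing]


def _smooth_vector(data: np.ndarray, sigma_mm: float, spacing) -> np.ndarray:
    # kernels are specified in mm but never narrower than one voxel at the
    # working resolution, so coarse pyramid levels stay regularised
    if sigma_mm <= 0:
        return data
    sig = [max(s, 1.0) for s in _mm_sigma_to_vox(sigma_mm, spacing)]
    out = np.empty_like(data)
    for c in range(3):
        out[..., c] = ndimage.gaussian_filter(data[..., c], sig)
    return out


# ---------------------------------------------------------------------------
# core iteration
# ---------------------------------------------------------------------------

def demons_register(
    fixed: ScalarVolume,
    moving: ScalarVolume,
    mask: BinaryMask,
    params: DemonsParams | None = None,
    seed: int = 0,
) -> VelocityField:
    """Register ``moving`` onto ``fixed`` inside ``mask``.

    Returns the stationary velocity ``v`` such that ``moving o exp(v) ~ fixed``
    within the mask. The algorithm is fully deterministic given its inputs;
    ``seed`` is accepted for interface uniformity with the stochastic stages.

    If the masked SSD increases monotonically over an entire pyramid level a
    divergence warning is emitted and the best velocity seen so far is kept.
    """
    del seed  # deterministic algorithm
    if params is None:
        params = DemonsParams()
    if not fixed.grid.same_as(moving.grid) or not fixed.grid.same_as(mask.grid):
        raise ValueError("fixed, moving and mask must share one grid (resample first)")
    if not mask.data.any():
        raise ValueError("registration mask is empty")

    f_norm, m_norm = normalize_intensity(fixed.data, moving.data)
    eps = params.force_epsilon_rel  # intensities are in [0, 1] after normalisation

    v_data: np.ndarray | None = None
    full_grid = fixed.grid
    for level in range(params.levels):
        factor = params.downsample_factors[level]
        f_l = _downsample_volume(f_norm, factor)
        m_l = _downsample_volume(m_norm, factor)
        mask_l = _downsample_volume(mask.data.astype(np.float64), factor) >= 0.5
        grid_l = _level_grid(full_grid, f_l.shape)
        if not mask_l.any():
            mask_l = _downsample_volume(mask.data.astype(np.float64), factor) > 0

        if v_data is None:
            v_data = np.zeros(f_l.shape + (3,))
        else:
            v_data = _resize_vector(v_data, f_l.shape)

        v_data = _demons_level(
            f_l, m_l, mask_l, grid_l, v_data, params, eps,
            n_iter=params.iters_per_level[level], level=level,
        )

    assert v_data is not None
    v_data = _resize_vector(v_data, full_grid.shape)
    return VelocityField(v_data, full_grid)


def _demons_level(
    f: np.ndarray,
    m: np.ndarray,
    mask: np.ndarray,
    grid: Grid,
    v_data: np.ndarray,
    params: DemonsParams,
    eps: float,
    n_iter: int,
    level: int,
) -> np.ndarray:
    spacing = grid.spacing
    max_step_mm = params.max_step_voxels * min(spacing)
    grad_f = np.stack(np.gradient(f, *spacing), axis=-1)
    moving_vol = ScalarVolume(m, grid)
    fill = float(m.min())

    best = v_data.copy()
    best_ssd = np.inf
    prev_ssd = np.inf
    n_increases = 0

    for it in range(n_iter):
        phi = exp_velocity(VelocityField(v_data, grid))
        m_w = warp_scalar(moving_vol, phi, fill=fill).data
        diff = f - m_w
        ssd = float((diff[mask] ** 2).sum())
        if ssd < best_ssd:
            best_ssd = ssd
            best = v_data.copy()
        n_increases = n_increases + 1 if ssd > prev_ssd else 0
        prev_ssd = ssd

        grad_m = np.stack(np.gradient(m_w, *spacing), axis=-1)
        J = 0.5 * (grad_f + grad_m)
        jnorm2 = (J**2).sum(axis=-1)
        denom = jnorm2 + (diff / max_step_mm) ** 2
        denom = np.maximum(denom, eps)
        u = (diff / denom)[..., None] * J
        # hard cap so one iteration never moves more than max_step
        umag = np.sqrt((u**2).sum(axis=-1))
        over = umag > max_step_mm
        if over.any():
            u[over] *= (max_step_mm / umag[over])[..., None]
        u[~mask] = 0.0

        u = _smooth_vector(u, params.fluid_sigma, spacing)
        v_data = v_data + u  # first-order log composition
        v_data = _smooth_vector(v_data, params.diffusion_sigma, spacing)

    if n_increases >= n_iter and n_iter > 1:
        warnings.warn(
            f"demons level {level}: masked SSD increased monotonically; "
            "keeping best velocity seen",
            RuntimeWarning,
        )
        return best

    # keep whichever of (final, best) matched better
    phi = exp_velocity(VelocityField(v_data, grid))
    m_w = warp_scalar(moving_vol, phi, fill=fill).data
    final_ssd = float(((f - m_w)[mask] ** 2).sum())
    if final_ssd <= best_ssd:
        return v_data
    return best
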