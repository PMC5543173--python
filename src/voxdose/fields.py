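"""Stationary velocity fields, deformation fields and their algebra.

A :class:`DeformationField` stores per-voxel displacements ``u`` (mm, world
axes) on a reference grid; the point map it encodes is ``phi(x) = x + u(x)``.
A :class:`VelocityField` is a stationary velocity whose exponential (computed
by scaling and squaring) is a diffeomorphic deformation with ``exp(-v)`` as
its inverse — the property that makes dose warping invertible.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grids import BinaryMask, Grid, ScalarVolume

__all__ = [
    "VelocityField",
    "DeformationField",
    "zero_velocity",
    "exp_velocity",
    "compose",
    "warp_scalar",
    "warp_mask",
    "jacobian_determinant",
]


def _check_vec(data: np.ndarray, grid: Grid) -> np.ndarray:
    data = np.asarray(data, dtype=np.float64)
    if data.ndim != 4 or data.shape[3] != 3:
        raise ValueError("vector field data must have shape (nx, ny, nz, 3)")
    if tuple(data.shape[:3]) != grid.shape:
        raise ValueError("vector field shape does not match grid")
    return data


@dataclass
class VelocityField:
    """Stationary velocity (mm) on a reference grid."""

    data: np.ndarray
    grid: Grid

    def __post_init__(self) -> None:
        self.data = _check_vec(self.data, self.grid)

    def __neg__(self) -> "VelocityField":
        return VelocityField(-self.data, self.grid)

    def max_displacement_voxels(self) -> float:
        """Largest per-voxel displacement magnitude measured in voxel units."""
        vox = self.data / np.asarray(self.grid.spacing)
        return float(np.sqrt((vox**2).sum(axis=-1)).max())


@dataclass
class DeformationField:
    """Displacement field (mm): maps reference-grid points to source-space points."""

    data: np.ndarray
    grid: Grid

    def __post_init__(self) -> None:
        self.data = _check_vec(self.data, self.grid)

    def magnitude_voxels(self) -> np.ndarray:
        vox = self.data / np.asarray(self.grid.spacing)
        return np.sqrt((vox**2).sum(axis=-1))


def zero_velocity(grid: Grid) -> VelocityField:
    return VelocityField(np.zeros(grid.shape + (3,)), grid)


def identity_deformation(grid: Grid) -> DeformationField:
    return DeformationField(np.zeros(grid.shape + (3,)), grid)


def _index_grid(grid: Grid) -> np.ndarray:
    """(3, nx, ny, nz) voxel-index coordinates."""
    return np.indices(grid.shape, dtype=np.float64)


def _lookup_coords(grid: Grid, displacement_mm: np.ndarray) -> np.ndarray:
    """Voxel-unit sampling coordinates for ``x + u(x)``."""
    coords = _index_grid(grid)
    for a in range(3):
        coords[a] += displacement_mm[..., a] / grid.spacing[a]
    return coords


def _sample_vector(field: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Trilinear lookup of a vector field at voxel-unit coords, edge-clamped."""
    out = np.empty(coords.shape[1:] + (3,))
    for a in range(3):
        out[..., a] = ndimage.map_coordinates(
            field[..., a], coords, order=1, mode="nearest"
        )
    return out


def compose(f: DeformationField, g: DeformationField) -> DeformationField:
    """Displacement of the composed point map ``phi_f o phi_g``.

    ``(f o g)(x) = g(x) + f(x + g(x))`` with trilinear, edge-clamped lookups.
    """
    if not f.grid.same_as(g.grid):
        raise ValueError("compose requires both fields on the same grid")
    coords = _lookup_coords(g.grid, g.data)
    return DeformationField(g.data + _sample_vector(f.data, coords), g.grid)


def exp_velocity(v: VelocityField, n_squarings: int | str = "auto") -> DeformationField:
    """Exponentiate a stationary velocity by scaling and squaring.

    With ``n_squarings="auto"`` the number of squarings is chosen so the scaled
    field's maximum displacement is at most 0.5 voxel, which keeps the implicit
    small-deformation step valid. ``exp(-v)`` is the inverse of ``exp(v)``.
    """
    if not np.all(np.isfinite(v.data)):
        raise ValueError("velocity field contains non-finite values")
    if n_squarings == "auto":
        m = v.max_displacement_voxels()
        n = 0 if m <= 0.5 else int(np.ceil(np.log2(m / 0.5)))
    else:
        n = int(n_squarings)
        if n < 0:
            raise ValueError("n_squarings must be non-negative")
    u = DeformationField(v.data / (2.0**n), v.grid)
    for _ in range(n):
        u = compose(u, u)
    return u


def warp_scalar(
    vol: ScalarVolume,
    field: DeformationField,
    mode: str = "trilinear",
    fill: float = 0.0,
) -> ScalarVolume:
    """Pull a scalar volume back through a deformation: ``out(x) = vol(x + u(x))``.

    Lookups outside the source extent return ``fill``.
    """
    if not np.all(np.isfinite(field.data)):
        raise ValueError("deformation field contains non-finite values")
    order = {"trilinear": 1, "nearest": 0}.get(mode)
    if order is None:
        raise ValueError(f"unknown interpolation mode {mode!r}")
    coords = _lookup_coords(field.grid, field.data)
    out = ndimage.map_coordinates(
        vol.data, coords, order=order, mode="constant", cval=float(fill)
    )
    return ScalarVolume(out, field.grid)


def warp_mask(mask: BinaryMask, field: DeformationField) -> BinaryMask:
    """Warp a binary mask: trilinear warp of the 0/1 volume, thresholded at 0.5."""
    vol = ScalarVolume(mask.data.astype(np.float64), mask.grid)
    warped = warp_scalar(vol, field, mode="trilinear", fill=0.0)
    return BinaryMask(warped.data >= 0.5, field.grid, mask.name)


def jacobian_determinant(field: DeformationField) -> np.ndarray:
    """Voxelwise Jacobian determinant of the point map ``x + u(x)``."""
    J = np.empty(field.grid.shape + (3, 3))
    for comp in range(3):
        grads = np.gradient(field.data[..., comp], *field.grid.spacing)
        for axis in range(3):
            J[..., comp, axis] = grads[axis]
        J[..., comp, comp] += 1.0
    return np.linalg.det(J)

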