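"""Core voxel-grid containers.

All volumes in this package live on axis-aligned 3D grids: world position of
voxel index ``i`` along axis ``a`` is ``origin[a] + i * spacing[a]`` (mm).
Direction-cosine-general grids are intentionally unsupported.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Grid", "ScalarVolume", "BinaryMask"]


@dataclass(frozen=True)
class Grid:
    """Axis-aligned sampling grid: shape (voxels), spacing and origin (mm)."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("Grid is strictly three-dimensional")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if any(int(n) <= 0 for n in self.shape):
            raise ValueError(f"shape must be positive, got {self.shape}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    @property
    def extent(self) -> tuple[float, float, float]:
        """Physical size of the grid along each axis in mm."""
        return tuple(n * s for n, s in zip(self.shape, self.spacing))

    def same_as(self, other: "Grid", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )

    def world_coordinates(self) -> np.ndarray:
        """(nx, ny, nz, 3) array of world positions (mm) of all voxel centres."""
        axes = [
            self.origin[a] + np.arange(self.shape[a]) * self.spacing[a]
            for a in range(3)
        ]
        return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)


def _check_grid(data: np.ndarray, grid: Grid) -> None:
    if tuple(data.shape[:3]) != grid.shape:
        raise ValueError(f"array shape {data.shape[:3]} does not match grid {grid.shape}")


@dataclass
class ScalarVolume:
    """A scalar field sampled on a grid: CT-like intensity, dose (Gy), a statistic
    or a p-value, depending on context."""

    data: np.ndarray
    grid: Grid

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        _check_grid(self.data, self.grid)
        if self.data.ndim != 3:
            raise ValueError("ScalarVolume data must be 3D")

    def copy(self) -> "ScalarVolume":
        return ScalarVolume(self.data.copy(), self.grid)


@dataclass
class BinaryMask:
    """A boolean structure mask on a grid, tagged with the structure's name."""

    data: np.ndarray
    grid: Grid
    name: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        _check_grid(self.data, self.grid)
        if self.data.ndim != 3:
            raise ValueError("BinaryMask data must be 3D")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def volume_cm3(self) -> float:
        """Physical volume of the mask in cm^3."""
        return self.n_voxels * self.grid.voxel_volume / 1000.0

    def copy(self) -> "BinaryMask":
        return BinaryMask(self.data.copy(), self.grid, self.name)
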