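"""Core voxel-lattice containers.

Every map in the pipeline (field maps in Hz, susceptibility maps in ppm,
masks, magnitude images) is carried as a :class:`VoxelVolume`: a 3-D scalar
lattice with a voxel-to-world affine (world coordinates in mm) and a units
tag.  The scanner frame follows the acquisition convention: the array axes
(i, j, k) map to scanner (x, y, z) with

* x — partition encoding, right–left,
* y — first phase encoding, anterior–posterior,
* z — B0 / readout, head–foot,

and the world origin at the grid centre.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

__all__ = ["UnitsError", "Grid", "VoxelVolume", "center_affine"]

#: permitted units tags
UNITS = ("Hz", "ppm", "1")


class UnitsError(ValueError):
    """Raised when volumes with incompatible units are combined."""


def center_affine(shape: Iterable[int], voxel_size) -> np.ndarray:
    """4x4 voxel→world affine with isotropic/anisotropic spacing in mm and
    the world origin at the grid centre."""
    shape = np.asarray(tuple(shape), dtype=float)
    vs = np.broadcast_to(np.asarray(voxel_size, dtype=float), (3,)).copy()
    aff = np.eye(4)
    aff[:3, :3] = np.diag(vs)
    aff[:3, 3] = -vs * (shape - 1) / 2.0
    return aff


@dataclass(frozen=True)
class Grid:
    """Sampling lattice: shape + voxel→world affine (mm)."""

    shape: tuple[int, int, int]
    affine: np.ndarray

    @property
    def voxel_size(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def world_coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable world-coordinate arrays (x, y, z) in mm."""
        idx = np.meshgrid(*(np.arange(n) for n in self.shape), indexing="ij", sparse=True)
        A, t = self.affine[:3, :3], self.affine[:3, 3]
        # diagonal affines only (the package never shears its own grids)
        return tuple(A[d, d] * idx[d] + t[d] for d in range(3))

    def same_as(self, other: "Grid", atol: float = 1e-6) -> bool:
        return self.shape == tuple(other.shape) and np.allclose(
            self.affine, other.affine, atol=atol
        )


@dataclass
class VoxelVolume:
    """3-D scalar lattice + world affine + units tag.

    ``valid`` optionally marks voxels carrying trustworthy values (e.g. field
    map voxels with sufficient signal magnitude); ``None`` means all valid.
    """

    data: np.ndarray
    affine: np.ndarray
    units: str = "1"
    valid: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D volume, got shape {self.data.shape}")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if self.units not in UNITS:
            raise UnitsError(f"unknown units tag {self.units!r}; expected one of {UNITS}")
        if self.valid is not None and self.valid.shape != self.data.shape:
            raise ValueError("valid mask shape mismatch")

    # ------------------------------------------------------------------ grid
    @property
    def grid(self) -> Grid:
        return Grid(tuple(self.data.shape), self.affine)

    @property
    def voxel_size(self) -> np.ndarray:
        return self.grid.voxel_size

    def valid_mask(self) -> np.ndarray:
        if self.valid is None:
            return np.ones(self.data.shape, dtype=bool)
        return self.valid.astype(bool)

    def like(self, data: np.ndarray, units: str | None = None,
             valid: np.ndarray | None = None) -> "VoxelVolume":
        """New volume on this grid."""
        return VoxelVolume(np.asarray(data), self.affine.copy(),
                           self.units if units is None else units, valid)

    def copy(self) -> "VoxelVolume":
        return VoxelVolume(self.data.copy(), self.affine.copy(), self.units,
                           None if self.valid is None else self.valid.copy())

    # ------------------------------------------------------------ arithmetic
    def _check_compatible(self, other: "VoxelVolume"):
        if not isinstance(other, VoxelVolume):
            raise TypeError("operand must be a VoxelVolume")
        if self.units != other.units:
            raise UnitsError(
                f"cannot combine volumes with units {self.units!r} and {other.units!r}"
            )
        if not self.grid.same_as(other.grid):
            raise ValueError("grid mismatch between operands")

    def _merged_valid(self, other: "VoxelVolume") -> np.ndarray | None:
        if self.valid is None and other.valid is None:
            return None
        return self.valid_mask() & other.valid_mask()

    def __add__(self, other):
        if np.isscalar(other):
            return self.like(self.data + other, valid=self.valid)
        self._check_compatible(other)
        return self.like(self.data + other.data, valid=self._merged_valid(other))

    def __sub__(self, other):
        if np.isscalar(other):
            return self.like(self.data - other, valid=self.valid)
        self._check_compatible(other)
        return self.like(self.data - other.data, valid=self._merged_valid(other))

    def __mul__(self, scalar):
        if not np.isscalar(scalar):
            raise TypeError("volumes can only be scaled by scalars")
        return self.like(self.data * scalar, valid=self.valid)

    __rmul__ = __mul__
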