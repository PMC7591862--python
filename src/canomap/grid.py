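"""Voxel grid geometry and masks.

All volumes of one study live on a single shared :class:`GridSpace`.  Masked
arrays use a stable voxel ordering — lexicographic by (i, j, k) index, i.e.
C-order flat index — so that row ``k`` of a connectome always refers to the
same voxel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GridSpace", "VoxelMask", "GridMismatchError"]


class GridMismatchError(ValueError):
    """Two volumes that must share a grid do not."""


@dataclass(frozen=True)
class GridSpace:
    """A regular 3-D voxel grid.

    Parameters
    ----------
    shape
        Number of voxels along each axis; every entry >= 1.
    spacing
        Voxel size in mm along each axis; every entry > 0.
    affine
        Optional 4x4 voxel-index -> mm affine.  Defaults to a diagonal
        affine ``diag(spacing)`` with origin at voxel (0, 0, 0), so the
        mm coordinate of a voxel centre is simply ``index * spacing``.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    affine: tuple = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        spacing = tuple(float(s) for s in self.spacing)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ValueError(f"shape must be three entries >= 1, got {shape}")
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be three entries > 0, got {spacing}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", spacing)
        if self.affine is None:
            aff = np.eye(4)
            aff[0, 0], aff[1, 1], aff[2, 2] = spacing
        else:
            aff = np.asarray(self.affine, dtype=float)
            if aff.shape != (4, 4):
                raise ValueError("affine must be 4x4")
        object.__setattr__(self, "affine", tuple(map(tuple, aff)))

    # -- geometry ---------------------------------------------------------
    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def affine_array(self) -> np.ndarray:
        return np.asarray(self.affine, dtype=float)

    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def flat_to_ijk(self, flat: np.ndarray) -> np.ndarray:
        """(N,) C-order flat indices -> (N, 3) integer voxel indices."""
        return np.stack(np.unravel_index(np.asarray(flat), self.shape), axis=-1)

    def ijk_to_flat(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.asarray(ijk)
        return np.ravel_multi_index((ijk[..., 0], ijk[..., 1], ijk[..., 2]), self.shape)

    def voxel_centres_mm(self, flat: np.ndarray) -> np.ndarray:
        """mm coordinates of voxel centres through the affine."""
        ijk = self.flat_to_ijk(flat).astype(float)
        aff = self.affine_array
        return ijk @ aff[:3, :3].T + aff[:3, 3]

    # -- equality ---------------------------------------------------------
    def same_as(self, other: "GridSpace") -> bool:
        return (
            self.shape == other.shape
            and self.spacing == other.spacing
            and np.allclose(self.affine_array, other.affine_array)
        )

    def require_same(self, other: "GridSpace", what: str = "volume") -> None:
        if not self.same_as(other):
            raise GridMismatchError(
                f"{what}: grid mismatch (shape {other.shape} spacing {other.spacing} "
                f"vs expected shape {self.shape} spacing {self.spacing})"
            )


class VoxelMask:
    """A set of voxels on a grid, stored as a boolean volume.

    ``indices`` gives the canonical stable ordering (C-order flat index,
    ascending) used by every masked array in the package.
    """

    def __init__(self, grid: GridSpace, data: np.ndarray):
        data = np.asarray(data)
        if data.dtype == bool and data.shape == grid.shape:
            vol = data
        elif data.shape == grid.shape:
            vol = data.astype(bool)
        else:  # flat indices
            vol = np.zeros(grid.shape, dtype=bool)
            flat = np.asarray(data, dtype=np.intp).ravel()
            if flat.size and (flat.min() < 0 or flat.max() >= grid.n_voxels):
                raise ValueError("mask indices outside grid")
            vol.ravel()[flat] = True
        self.grid = grid
        self.volume = vol

    @classmethod
    def from_indices(cls, grid: GridSpace, flat: np.ndarray) -> "VoxelMask":
        m = cls(grid, np.zeros(grid.shape, dtype=bool))
        m.volume.ravel()[np.asarray(flat, dtype=np.intp)] = True
        return m

    @property
    def indices(self) -> np.ndarray:
        return np.flatnonzero(self.volume.ravel())

    @property
    def n_voxels(self) -> int:
        return int(self.volume.sum())

    def __len__(self) -> int:
        return self.n_voxels

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, VoxelMask)
            and self.grid.same_as(other.grid)
            and bool(np.array_equal(self.volume, other.volume))
        )

    def __contains__(self, flat: int) -> bool:
        return bool(self.volume.ravel()[flat])

    def issubset(self, other: "VoxelMask") -> bool:
        return bool(np.all(~self.volume | other.volume))

    def intersect(self, other: "VoxelMask") -> "VoxelMask":
        self.grid.require_same(other.grid, "mask intersection")
        return VoxelMask(self.grid, self.volume & other.volume)

    def union(self, other: "VoxelMask") -> "VoxelMask":
        self.grid.require_same(other.grid, "mask union")
        return VoxelMask(self.grid, self.volume | other.volume)

    def difference(self, other: "VoxelMask") -> "VoxelMask":
        self.grid.require_same(other.grid, "mask difference")
        return VoxelMask(self.grid, self.volume & ~other.volume)

    def empty(self) -> bool:
        return not self.volume.any()
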