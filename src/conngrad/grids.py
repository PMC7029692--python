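"""Sampling-grid primitives shared by every stage of the pipeline.

A :class:`VolumeGrid` fixes the voxel lattice (shape + affine) that all
masks, seed sets and output maps live on.  A :class:`SeedROI` additionally
fixes the *order* of the seed voxels — lexicographic in (i, j, k) — and
that order defines matrix row/column order everywhere downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class GridMismatchError(ValueError):
    """Two volumes that must share a grid do not."""


@dataclass(frozen=True)
class VolumeGrid:
    """A 3D voxel lattice with a voxel-to-mm affine."""

    shape: tuple[int, int, int]
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s <= 0 for s in shape):
            raise ValueError(f"shape must be 3 positive integers, got {self.shape}")
        object.__setattr__(self, "shape", shape)
        affine = np.eye(4) if self.affine is None else np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        affine = affine.copy()
        affine.flags.writeable = False
        object.__setattr__(self, "affine", affine)

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge lengths in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def voxels_to_mm(self, ijk: np.ndarray) -> np.ndarray:
        """Map (n, 3) voxel indices to (n, 3) mm coordinates."""
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        homog = np.column_stack([ijk, np.ones(len(ijk))])
        return (self.affine @ homog.T).T[:, :3]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, VolumeGrid):
            return NotImplemented
        return self.shape == other.shape and np.allclose(self.affine, other.affine)

    def __hash__(self) -> int:
        return hash((self.shape, self.affine.tobytes()))


def check_same_grid(a: VolumeGrid, b: VolumeGrid, what: str = "volumes") -> None:
    if a != b:
        raise GridMismatchError(
            f"{what} are on different grids: "
            f"shape/affine {a.shape}/{a.affine[:3, 3]} vs {b.shape}/{b.affine[:3, 3]}"
        )


@dataclass(frozen=True)
class BinaryMask:
    """Boolean volume on a grid."""

    grid: VolumeGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=bool)
        if values.shape != self.grid.shape:
            raise ValueError(
                f"mask values shape {values.shape} != grid shape {self.grid.shape}"
            )
        object.__setattr__(self, "values", values)

    @property
    def count(self) -> int:
        return int(self.values.sum())

    def voxel_indices(self) -> np.ndarray:
        """(n, 3) array of member voxel indices in lexicographic order."""
        return np.argwhere(self.values)  # argwhere is C-order = lexicographic


@dataclass(frozen=True)
class SeedROI:
    """Ordered seed voxel set; the order fixes matrix row order downstream.

    Voxels are stored (and enforced) in lexicographic (i, j, k) order.
    """

    grid: VolumeGrid
    voxels: np.ndarray  # (n, 3) int

    def __post_init__(self) -> None:
        voxels = np.asarray(self.voxels, dtype=np.int64)
        if voxels.ndim != 2 or voxels.shape[1] != 3:
            raise ValueError("voxels must be an (n, 3) index array")
        if len(voxels) == 0:
            raise ValueError("SeedROI must contain at least one voxel")
        if len(np.unique(voxels, axis=0)) != len(voxels):
            raise ValueError("SeedROI voxels must be unique")
        shape = np.asarray(self.grid.shape)
        if (voxels < 0).any() or (voxels >= shape).any():
            raise ValueError("SeedROI voxels outside the grid")
        order = np.lexsort((voxels[:, 2], voxels[:, 1], voxels[:, 0]))
        voxels = voxels[order]
        voxels.flags.writeable = False
        object.__setattr__(self, "voxels", voxels)

    def __len__(self) -> int:
        return len(self.voxels)

    @property
    def n_seeds(self) -> int:
        return len(self.voxels)

    def to_mask(self) -> BinaryMask:
        vol = np.zeros(self.grid.shape, dtype=bool)
        vol[tuple(self.voxels.T)] = True
        return BinaryMask(self.grid, vol)

    def mm_coordinates(self) -> np.ndarray:
        return self.grid.voxels_to_mm(self.voxels)

    def same_as(self, other: "SeedROI") -> bool:
        return self.grid == other.grid and np.array_equal(self.voxels, other.voxels)


def roi_from_mask(mask: BinaryMask) -> SeedROI:
    """Build a SeedROI from the true voxels of a mask (lexicographic order)."""
    idx = mask.voxel_indices()
    if len(idx) == 0:
        raise ValueError("cannot build a SeedROI from an empty mask")
    return SeedROI(mask.grid, idx)
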