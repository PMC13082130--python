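"""Voxel grid geometry shared by phantoms, reconstruction, and metrics."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VoxelGrid"]


@dataclass(frozen=True)
class VoxelGrid:
    """A voxel-centered Cartesian grid.

    Axes are (x, y, z) = (left-right, anterior-posterior, superior-inferior).
    World coordinates are in millimetres with the volume center at the
    origin unless an explicit ``origin`` (coordinate of voxel (0,0,0)) is
    given.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] | None = None

    def __post_init__(self):
        if len(self.shape) != 3 or any(n < 1 for n in self.shape):
            raise ValueError(f"invalid grid shape {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("grid spacing must be positive")
        if self.origin is None:
            origin = tuple(-(n // 2) * s for n, s in zip(self.shape, self.spacing))
            object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def nvoxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def fov_mm(self) -> tuple[float, float, float]:
        return tuple(n * s for n, s in zip(self.shape, self.spacing))

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centers along one axis (mm)."""
        return self.origin[axis] + np.arange(self.shape[axis]) * self.spacing[axis]

    def coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable world-coordinate arrays (mm) for the full grid."""
        x = self.axis_coords(0)[:, None, None]
        y = self.axis_coords(1)[None, :, None]
        z = self.axis_coords(2)[None, None, :]
        return x, y, z

    def dense_coords(self) -> np.ndarray:
        """(nx*ny*nz, 3) array of voxel-center world coordinates (mm)."""
        x, y, z = np.meshgrid(self.axis_coords(0), self.axis_coords(1),
                              self.axis_coords(2), indexing="ij")
        return np.stack([x.ravel(), y.ravel(), z.ravel()], axis=1)

    def world_to_index(self, points_mm: np.ndarray) -> np.ndarray:
        """Continuous voxel indices for world-space points."""
        points_mm = np.asarray(points_mm, dtype=np.float64)
        return (points_mm - np.asarray(self.origin)) / np.asarray(self.spacing)

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.asarray(idx, dtype=np.float64)
        return idx * np.asarray(self.spacing) + np.asarray(self.origin)

    def downsample_inplane(self, factor: int = 2) -> "VoxelGrid":
        """Coarsen the in-plane (x, y) resolution, preserving FOV and z."""
        nx, ny, nz = self.shape
        sx, sy, sz = self.spacing
        return VoxelGrid(shape=(max(1, nx // factor), max(1, ny // factor), nz),
                         spacing=(sx * factor, sy * factor, sz))

    def affine(self) -> np.ndarray:
        """RAS affine for NIfTI export."""
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = self.spacing
        aff[:3, 3] = self.origin
        return aff
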