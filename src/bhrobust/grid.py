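"""Voxel grid geometry shared by every volume and mask in a phantom.

Axis convention: index axes (0, 1, 2) correspond to the patient axes
left-right (LR), anterior-posterior (AP) and cranio-caudal (CC).
World coordinates are in mm with ``world = origin + index * spacing``
(0-based voxel indices).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

MIN_SHAPE = 16


class GeometryError(ValueError):
    """Raised when a requested geometry is impossible (e.g. tumor outside lung)."""


@dataclass(frozen=True)
class VoxelGrid:
    """Regular 3D voxel lattice: shape (voxels), spacing and origin (mm)."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = (3.0, 3.0, 3.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if len(self.shape) != 3 or len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("VoxelGrid requires 3D shape/spacing/origin")
        if any(s < MIN_SHAPE for s in self.shape):
            raise ValueError(f"grid shape must be >= {MIN_SHAPE} voxels per axis, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def extent_mm(self) -> np.ndarray:
        """Physical size of the grid (mm) per axis."""
        return np.asarray(self.shape) * np.asarray(self.spacing)

    @property
    def center_mm(self) -> np.ndarray:
        """World coordinate of the grid center."""
        return np.asarray(self.origin) + (np.asarray(self.shape) - 1) * np.asarray(self.spacing) / 2.0

    def coords(self, axis: int) -> np.ndarray:
        """1D world coordinates of voxel centers along one axis."""
        return self.origin[axis] + np.arange(self.shape[axis]) * self.spacing[axis]

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Sparse broadcastable world-coordinate arrays (X, Y, Z)."""
        return np.meshgrid(self.coords(0), self.coords(1), self.coords(2),
                           indexing="ij", sparse=True)

    def world_to_index(self, points_mm: np.ndarray) -> np.ndarray:
        """Continuous (fractional) voxel indices for world points (..., 3)."""
        p = np.asarray(points_mm, dtype=float)
        return (p - np.asarray(self.origin)) / np.asarray(self.spacing)

    def index_to_world(self, indices: np.ndarray) -> np.ndarray:
        idx = np.asarray(indices, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def affine(self) -> np.ndarray:
        """4x4 voxel-to-world affine (for NIfTI export)."""
        a = np.eye(4)
        a[:3, :3] = np.diag(self.spacing)
        a[:3, 3] = self.origin
        return a

    def validate_volume(self, volume: np.ndarray) -> None:
        if tuple(volume.shape) != self.shape:
            raise ValueError(f"volume shape {volume.shape} does not match grid {self.shape}")
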