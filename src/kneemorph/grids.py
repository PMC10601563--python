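"""Core spatial containers shared by every pipeline stage.

Canonical orientation: array axes (i, j, k) map to world axes
(x, y, z) = (medial->lateral, posterior->anterior, inferior->superior),
right handed, with world coordinates in mm located at voxel centers:

    world = origin + index * spacing

"Inferior" is therefore the -z direction, the sagittal plane has normal x,
and an axial slice is a fixed-k plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh as _trimesh


@dataclass
class VoxelGrid:
    """A 3-D intensity lattice in Hounsfield units.

    Parameters
    ----------
    intensities : (nx, ny, nz) float array
        Radiodensity in HU.
    spacing : (3,) float array
        Voxel edge lengths in mm, strictly positive.
    origin : (3,) float array
        World coordinate (mm) of the center of voxel (0, 0, 0).
    """

    intensities: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 3 or self.intensities.size == 0:
            raise ValueError("intensities must be a non-empty 3-D array")
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be strictly positive")
        if self.origin is None:
            self.origin = np.zeros(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def world_coordinates(self, indices: np.ndarray) -> np.ndarray:
        """Map (N, 3) voxel indices to (N, 3) world coordinates in mm."""
        return self.origin + np.asarray(indices, dtype=float) * self.spacing

    def index_coordinates(self, points: np.ndarray) -> np.ndarray:
        """Map (N, 3) world points (mm) to fractional voxel indices."""
        return (np.asarray(points, dtype=float) - self.origin) / self.spacing


@dataclass
class Mask:
    """Binary voxel selection congruent with a :class:`VoxelGrid` lattice."""

    selection: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.selection = np.asarray(self.selection).astype(bool)
        if self.selection.ndim != 3:
            raise ValueError("mask selection must be 3-D")
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be strictly positive")
        if self.origin is None:
            self.origin = np.zeros(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.selection.shape  # type: ignore[return-value]

    @property
    def count(self) -> int:
        """Number of selected voxels."""
        return int(self.selection.sum())

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def is_congruent(self, other: "Mask | VoxelGrid") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )


@dataclass
class TriMesh:
    """Closed triangulated surface with vertices in mm."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def to_trimesh(self) -> _trimesh.Trimesh:
        return _trimesh.Trimesh(
            vertices=self.vertices, faces=self.faces, process=False
        )

    @classmethod
    def from_trimesh(cls, mesh: _trimesh.Trimesh) -> "TriMesh":
        return cls(vertices=np.asarray(mesh.vertices), faces=np.asarray(mesh.faces))

    def is_closed(self) -> bool:
        """True iff every edge is shared by exactly two triangles."""
        return bool(self.to_trimesh().is_watertight)
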