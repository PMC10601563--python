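"""Landmark-based rigid registration of the MRI frame into the CT frame.

The two acquisitions image the same fixated knee; paired anatomical bone
landmarks identified in both scans determine a least-squares rigid
transform (rotation + translation, no scaling, no reflection) by the
closed-form SVD (Kabsch) solution. The CT frame is the reference: the
canonical direction is MRI -> CT.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grids import Mask, TriMesh, VoxelGrid


@dataclass
class RigidTransform:
    """Proper rigid transform x -> R @ x + t (mm)."""

    rotation: np.ndarray
    translation: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        if self.translation is None:
            self.translation = np.zeros(3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.allclose(self.rotation.T @ self.rotation, np.eye(3), atol=1e-9):
            raise ValueError("rotation must be orthonormal")
        if not np.isclose(np.linalg.det(self.rotation), 1.0, atol=1e-9):
            raise ValueError("rotation must be proper (det +1, no reflection)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_euler(cls, angles_deg, translation) -> "RigidTransform":
        """Intrinsic x-y-z Euler rotation (degrees) plus translation (mm)."""
        from scipy.spatial.transform import Rotation

        rot = Rotation.from_euler("xyz", np.asarray(angles_deg, float), degrees=True)
        return cls(rot.as_matrix(), np.asarray(translation, float))

    def apply_points(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        rot_inv = self.rotation.T
        return RigidTransform(rot_inv, -rot_inv @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return self o other (apply ``other`` first)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def matrix(self) -> np.ndarray:
        """Homogeneous 4x4 matrix."""
        mat = np.eye(4)
        mat[:3, :3] = self.rotation
        mat[:3, 3] = self.translation
        return mat

    @classmethod
    def from_matrix(cls, mat: np.ndarray) -> "RigidTransform":
        mat = np.asarray(mat, dtype=float).reshape(4, 4)
        return cls(mat[:3, :3], mat[:3, 3])


def fit_rigid(source_points: np.ndarray, target_points: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares rigid transform mapping source landmarks onto targets.

    Closed-form SVD solution with reflection correction. Returns the
    transform and the RMS residual (mm) after applying it.

    Raises
    ------
    ValueError
        If fewer than 3 pairs are given or the configuration is collinear.
    """
    src = np.asarray(source_points, dtype=float).reshape(-1, 3)
    tgt = np.asarray(target_points, dtype=float).reshape(-1, 3)
    if src.shape != tgt.shape:
        raise ValueError("landmark lists must be paired (equal length)")
    if len(src) < 3:
        raise ValueError("degenerate landmark configuration: need >= 3 paired points")
    src_c = src - src.mean(axis=0)
    tgt_c = tgt - tgt.mean(axis=0)
    # collinearity check: second singular value of the centered cloud
    if np.linalg.svd(src_c, compute_uv=False)[1] < 1e-9 * max(1.0, np.abs(src_c).max()):
        raise ValueError("degenerate landmark configuration: points are collinear")
    u, _, vt = np.linalg.svd(src_c.T @ tgt_c)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = tgt.mean(axis=0) - rot @ src.mean(axis=0)
    transform = RigidTransform(rot, trans)
    resid = transform.apply_points(src) - tgt
    rmsd = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return transform, rmsd


def apply_transform(
    transform: RigidTransform,
    obj: "np.ndarray | TriMesh | Mask",
    target_lattice: "Mask | VoxelGrid | None" = None,
):
    """Map points, a mesh, or a mask through a rigid transform.

    Points and meshes are mapped exactly. A mask is resampled by nearest
    neighbor into ``target_lattice`` (required), which keeps it binary.
    """
    if isinstance(obj, TriMesh):
        return TriMesh(transform.apply_points(obj.vertices), obj.faces.copy())
    if isinstance(obj, Mask):
        if target_lattice is None:
            raise ValueError("mask resampling requires a target lattice")
        return _resample_mask(transform, obj, target_lattice)
    return transform.apply_points(np.asarray(obj))


def _resample_mask(transform: RigidTransform, mask: Mask, target) -> Mask:
    inv = transform.inverse()
    shape = target.shape
    idx = np.indices(shape).reshape(3, -1).T.astype(float)
    world_tgt = target.origin + idx * target.spacing
    world_src = inv.apply_points(world_tgt)
    src_idx = (world_src - mask.origin) / mask.spacing
    sampled = ndimage.map_coordinates(
        mask.selection.astype(np.float32), src_idx.T, order=0, mode="constant", cval=0.0
    )
    sel = sampled.reshape(shape) > 0.5
    return Mask(sel, np.asarray(target.spacing), np.asarray(target.origin))


@dataclass
class FusionReport:
    """Pairwise overlap audit of fused parts."""

    overlaps: dict[tuple[str, str], int]
    tolerance_voxels: int
    passed: bool
    warnings: list[str]

    def failing_pairs(self) -> list[tuple[str, str]]:
        return [pair for pair, n in self.overlaps.items() if n > self.tolerance_voxels]


def validate_fusion(parts: dict[str, Mask], tolerance_voxels: int = 0) -> FusionReport:
    """Check that no two fused part masks overlap (anatomy is respected).

    Overlap counts above zero but within tolerance pass with a warning.
    """
    from .maskops import check_overlap

    names = list(parts)
    overlaps: dict[tuple[str, str], int] = {}
    warnings: list[str] = []
    passed = True
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            n = check_overlap(parts[a], parts[b])
            overlaps[(a, b)] = n
            if n > tolerance_voxels:
                passed = False
            elif n > 0:
                warnings.append(f"{a}/{b}: {n} overlapping voxels within tolerance")
    return FusionReport(overlaps, tolerance_voxels, passed, warnings)
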