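"""Segmentation post-processing on binary masks.

Thresholding, morphological erosion, overlap checking, surface extraction
and volume/surface computation. These are the mask-level steps performed
after (manual or synthetic) per-part segmentation: an HU window delimits a
part of interest, masks are checked for mutual overlap, each mask is turned
into a closed triangulated surface, and volume (mm^3) / surface (mm^2) are
computed from the 3-D objects.

The erosion structuring element is the 6-connected (face-adjacent) 3-D
cross applied in 3-D — "pixel" is read as "voxel" since the source volumes
are (near-)isotropic. A per-slice 2-D variant can be had by eroding each
slice independently, but is not what this pipeline does.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage import measure

from .grids import Mask, TriMesh, VoxelGrid

#: 6-connected structuring element (faces only)
_STRUCT_6 = ndimage.generate_binary_structure(3, 1)


def threshold_mask(grid: VoxelGrid, lo: float, hi: float) -> Mask:
    """Select voxels whose intensity lies in the inclusive window [lo, hi] HU."""
    if lo > hi:
        raise ValueError(f"invalid HU window: lo={lo} > hi={hi}")
    sel = (grid.intensities >= lo) & (grid.intensities <= hi)
    return Mask(sel, grid.spacing, grid.origin)


def erode_mask(mask: Mask, radius_voxels: int) -> Mask:
    """Erode by the 6-connected ball of the given radius (0 is identity)."""
    if radius_voxels < 0:
        raise ValueError("erosion radius must be >= 0")
    if radius_voxels == 0 or not mask.selection.any():
        return Mask(mask.selection.copy(), mask.spacing, mask.origin)
    eroded = ndimage.binary_erosion(
        mask.selection, structure=_STRUCT_6, iterations=radius_voxels
    )
    return Mask(eroded, mask.spacing, mask.origin)


def check_overlap(a: Mask, b: Mask) -> int:
    """Number of voxels selected in both masks (must share a lattice)."""
    if a.shape != b.shape:
        raise ValueError(f"mask shape mismatch: {a.shape} vs {b.shape}")
    return int(np.logical_and(a.selection, b.selection).sum())


def extract_surface(mask: Mask, smooth: bool = False, smooth_iterations: int = 10) -> TriMesh:
    """Triangulate the mask boundary into a closed, outward-oriented mesh.

    Marching cubes runs on the zero-padded mask so the surface is always
    closed. Optional Laplacian smoothing (off by default — the quantitative
    volume/surface figures are taken from the unsmoothed surface) preserves
    closedness and is meant for export/visualisation meshes.
    """
    if not mask.selection.any():
        raise ValueError("cannot extract a surface from an empty mask")
    padded = np.pad(mask.selection.astype(np.float32), 1)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=tuple(mask.spacing))
    # undo the 1-voxel pad, then move into world coordinates
    verts = verts - mask.spacing + mask.origin
    tm = TriMesh(vertices=verts, faces=faces).to_trimesh()
    tm.fix_normals()
    if smooth:
        import trimesh.smoothing

        trimesh.smoothing.filter_laplacian(tm, iterations=smooth_iterations)
    return TriMesh.from_trimesh(tm)


def mask_volume(mask: Mask) -> float:
    """Mask volume in mm^3: voxel count times voxel volume."""
    return mask.count * mask.voxel_volume


def mesh_volume(mesh: TriMesh) -> float:
    """Enclosed volume in mm^3 by signed tetrahedron sum (requires a closed mesh)."""
    tm = mesh.to_trimesh()
    if not tm.is_watertight:
        raise ValueError("mesh is not closed; volume is undefined")
    return float(abs(tm.volume))


def mesh_area(mesh: TriMesh) -> float:
    """Total triangle area in mm^2."""
    return float(mesh.to_trimesh().area)


def genus(mesh: TriMesh) -> int:
    """Topological genus from the Euler characteristic of a closed mesh."""
    tm = mesh.to_trimesh()
    return int(1 - tm.euler_number / 2)
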