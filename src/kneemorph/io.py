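"""Volume, mesh and table I/O.

NIfTI (via nibabel) is the primary volume dialect; DICOM series (via
pydicom) are read-only. Meshes are binary STL (via trimesh) and tables are
UTF-8 CSV with a header row (via pandas). All round trips are lossless at
the stated precision (float64 for tables, format-native for volumes).
"""

from __future__ import annotations

import os
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import trimesh as _trimesh

from .grids import Mask, TriMesh, VoxelGrid

_SUPPORTED = ".nii, .nii.gz (NIfTI) or a directory of DICOM files"


def save_volume(grid: VoxelGrid, path: str | os.PathLike) -> None:
    """Write a :class:`VoxelGrid` as NIfTI (.nii or .nii.gz)."""
    path = Path(path)
    if not (path.name.endswith(".nii") or path.name.endswith(".nii.gz")):
        raise ValueError(f"unsupported volume format {path.suffix!r}; supported: {_SUPPORTED}")
    affine = np.eye(4)
    affine[:3, :3] = np.diag(grid.spacing)
    affine[:3, 3] = grid.origin
    img = nib.Nifti1Image(np.asarray(grid.intensities, dtype=np.float32), affine)
    img.header.set_zooms(tuple(grid.spacing))
    nib.save(img, str(path))


def load_volume(path: str | os.PathLike) -> VoxelGrid:
    """Read a NIfTI file or a DICOM series directory into a :class:`VoxelGrid`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if path.is_dir():
        return _load_dicom_series(path)
    if path.name.endswith(".nii") or path.name.endswith(".nii.gz"):
        img = nib.load(str(path))
        affine = img.affine
        data = np.asarray(img.dataobj, dtype=np.float64)
        spacing = np.linalg.norm(affine[:3, :3], axis=0)
        origin = affine[:3, 3]
        return VoxelGrid(intensities=data, spacing=spacing, origin=origin)
    raise ValueError(f"unsupported volume format {path.suffix!r}; supported: {_SUPPORTED}")


def _load_dicom_series(directory: Path) -> VoxelGrid:
    """Assemble an axial DICOM series; slice spacing must be consistent."""
    import pydicom

    files = sorted(p for p in directory.iterdir() if p.suffix.lower() in (".dcm", ".ima", ""))
    if not files:
        raise ValueError(f"no DICOM files found in {directory}")
    slices = [pydicom.dcmread(str(p)) for p in files]
    slices.sort(key=lambda ds: float(ds.ImagePositionPatient[2]))
    zpos = np.array([float(ds.ImagePositionPatient[2]) for ds in slices])
    if len(zpos) > 1:
        steps = np.diff(zpos)
        if np.ptp(steps) > 1e-3 * np.abs(steps).mean():
            raise ValueError("inconsistent slice spacing in DICOM series")
        dz = float(steps.mean())
    else:
        dz = float(getattr(slices[0], "SliceThickness", 1.0))
    ds0 = slices[0]
    dy, dx = (float(v) for v in ds0.PixelSpacing)
    vols = np.stack(
        [ds.pixel_array * float(getattr(ds, "RescaleSlope", 1.0))
         + float(getattr(ds, "RescaleIntercept", 0.0)) for ds in slices],
        axis=-1,
    )
    # pydicom pixel_array is (row, col) = (y, x); transpose to (x, y, z)
    data = np.transpose(vols, (1, 0, 2))
    origin = np.array(
        [float(ds0.ImagePositionPatient[0]), float(ds0.ImagePositionPatient[1]), zpos[0]]
    )
    return VoxelGrid(intensities=data, spacing=np.array([dx, dy, dz]), origin=origin)


def save_mask(mask: Mask, path: str | os.PathLike) -> None:
    """Write a binary mask as a 0/1 NIfTI payload."""
    save_volume(
        VoxelGrid(mask.selection.astype(np.float32), mask.spacing, mask.origin), path
    )


def load_mask(path: str | os.PathLike) -> Mask:
    grid = load_volume(path)
    return Mask(grid.intensities > 0.5, grid.spacing, grid.origin)


def save_mesh(mesh: TriMesh, path: str | os.PathLike) -> None:
    """Write a triangle mesh as binary STL."""
    mesh.to_trimesh().export(str(path))


def load_mesh(path: str | os.PathLike) -> TriMesh:
    # STL is a triangle soup; merge duplicated vertices so closedness survives
    loaded = _trimesh.load(str(path), force="mesh", process=True)
    return TriMesh.from_trimesh(loaded)


def save_table(rows: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a table as UTF-8 CSV with header, preserving column order."""
    rows.to_csv(path, index=False)


def load_table(path: str | os.PathLike, required_columns: list[str] | None = None) -> pd.DataFrame:
    """Read a CSV table; optionally enforce a set of required columns."""
    table = pd.read_csv(path)
    if required_columns is not None:
        missing = [c for c in required_columns if c not in table.columns]
        if missing:
            raise ValueError(f"malformed table header; missing columns: {missing}")
    return table
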