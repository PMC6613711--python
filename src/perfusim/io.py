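"""NIfTI readers/writers with the package's canonical axis conventions.

Volumes are kept in plain axis-aligned voxel index space; NIfTI affines are
honoured for voxel size only and rotational affines are rejected with a
clear message (input data are expected to be co-registered and axis
aligned).
"""

from __future__ import annotations

import warnings

import nibabel as nib
import numpy as np

from .grid import VoxelGrid


def _grid_from_img(img) -> VoxelGrid:
    aff = img.affine
    if aff is None:
        raise ValueError("NIfTI image has no affine: voxel size metadata missing")
    R = np.asarray(aff[:3, :3], dtype=float)
    off = R - np.diag(np.diag(R))
    if np.max(np.abs(off)) > 1e-4 * max(np.max(np.abs(R)), 1e-12):
        raise ValueError("rotated/oblique NIfTI affines are not supported; "
                         "resample the volume to an axis-aligned grid first")
    zooms = np.abs(np.diag(R))
    if np.any(zooms <= 0):
        raise ValueError("voxel size metadata missing or degenerate")
    shape = img.shape[:3]
    return VoxelGrid(tuple(int(s) for s in shape), tuple(float(z) for z in zooms))


def read_volume(path) -> tuple[np.ndarray, VoxelGrid]:
    """Read a 3D volume and its grid (voxel sizes in mm)."""
    img = nib.load(str(path))
    grid = _grid_from_img(img)
    data = np.asanyarray(img.dataobj)
    if data.ndim > 3:
        data = data[..., 0]
    return np.ascontiguousarray(data), grid


def read_mask(path) -> tuple[np.ndarray, VoxelGrid]:
    """Read a binary mask; non-binary volumes are thresholded at 0.5."""
    data, grid = read_volume(path)
    vals = np.unique(data)
    if not np.all(np.isin(vals, (0, 1))):
        warnings.warn(f"{path}: volume is not binary; thresholding at 0.5")
    return data > 0.5, grid


def write_volume(path, data: np.ndarray, grid: VoxelGrid):
    """Write a volume with a diagonal affine from the grid's voxel size."""
    aff = np.diag(list(grid.voxel_size) + [1.0])
    arr = np.asarray(data)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    nib.save(nib.Nifti1Image(arr, aff), str(path))
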