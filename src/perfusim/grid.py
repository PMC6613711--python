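"""Regular voxel grids and the porous tissue domain.

The tissue (an organ mask on a regular grid) is modelled as two parallel
porous compartments — arterial and venous — each with its own porosity
``phi`` (the blood volume fraction, CBV in neuroimaging terms) and
permeability ``k`` [m^2].  Perfusion is the volume flux transiting from the
arterial to the venous compartment, ``P = alpha * (p_a - p_v)`` with the
proportionality field ``alpha`` [m s kg^-1].

All physical positions and voxel sizes are stored in millimetres; solvers
convert to SI internally.  Fields are defined on the full grid but are only
ever read inside the organ mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

MM = 1e-3  # mm -> m

#: converts perfusion from s^-1 to the clinical unit ml/min/100ml
PERFUSION_UNIT = 6000.0


@dataclass(frozen=True)
class VoxelGrid:
    """A regular axis-aligned voxel lattice.

    Parameters
    ----------
    shape : (nx, ny, nz) number of voxels per axis.
    voxel_size : physical edge lengths per axis [mm].
    origin : physical position of the centre of voxel (0, 0, 0) [mm].
    """

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if len(self.shape) != 3 or any(int(n) < 1 for n in self.shape):
            raise ValueError(f"grid shape must be three entries >= 1, got {self.shape}")
        if len(self.voxel_size) != 3 or any(h <= 0 for h in self.voxel_size):
            raise ValueError(f"voxel sizes must be positive, got {self.voxel_size}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "voxel_size", tuple(float(h) for h in self.voxel_size))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def fov(self) -> tuple[float, float, float]:
        """Field of view per axis [mm] (= shape * voxel size)."""
        return tuple(n * h for n, h in zip(self.shape, self.voxel_size))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size))

    @property
    def voxel_volume_m3(self) -> float:
        return self.voxel_volume_mm3 * MM**3

    @property
    def diagonal_mm(self) -> float:
        """Length of one voxel's space diagonal [mm]."""
        return float(np.linalg.norm(self.voxel_size))

    def index_to_physical(self, idx) -> np.ndarray:
        """Voxel index (array-like, (...,3)) -> voxel-centre position [mm]."""
        idx = np.asarray(idx, dtype=float)
        return idx * np.asarray(self.voxel_size) + np.asarray(self.origin)

    def physical_to_index(self, pos) -> np.ndarray:
        """Physical position [mm] -> fractional voxel index."""
        pos = np.asarray(pos, dtype=float)
        return (pos - np.asarray(self.origin)) / np.asarray(self.voxel_size)

    def nearest_voxel(self, pos) -> tuple[int, int, int]:
        idx = np.rint(self.physical_to_index(pos)).astype(int)
        idx = np.clip(idx, 0, np.asarray(self.shape) - 1)
        return tuple(int(i) for i in idx)

    @property
    def effective_dim(self) -> int:
        """2 for single-slice (quasi-2D) grids, else 3."""
        return 2 if any(n == 1 for n in self.shape) else 3


def _as_field(value, shape) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        return np.full(shape, float(arr))
    if arr.shape != tuple(shape):
        raise ValueError(f"field shape {arr.shape} does not match grid {shape}")
    return arr


@dataclass
class TissueDomain:
    """Organ mask plus the per-voxel two-compartment flow parameters.

    ``mask`` is the organ region Omega_B (union of grey and white matter for
    a brain).  ``phi_a``/``phi_v`` are porosities [-], ``k_a``/``k_v``
    permeabilities [m^2], ``alpha`` the perfusion proportionality factor
    [m s kg^-1], ``mu`` the constant blood viscosity [Pa s].  Scalars are
    broadcast to fields.  Values outside the mask are never read.
    """

    grid: VoxelGrid
    mask: np.ndarray
    phi_a: np.ndarray = 0.05
    phi_v: np.ndarray = 0.10
    k_a: np.ndarray = 1.0e-12
    k_v: np.ndarray = 5.0e-12
    alpha: np.ndarray = 1.0e-6
    mu: float = 3.0e-3
    labels: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.shape != self.grid.shape:
            raise ValueError("mask shape does not match grid")
        if not self.mask.any():
            raise ValueError("tissue mask is empty")
        shape = self.grid.shape
        for name in ("phi_a", "phi_v", "k_a", "k_v", "alpha"):
            setattr(self, name, _as_field(getattr(self, name), shape))
        if self.mu <= 0:
            raise ValueError("viscosity must be positive")
        m = self.mask
        for name in ("phi_a", "phi_v"):
            f = getattr(self, name)
            if np.any(f[m] < 0) or np.any(f[m] > 1):
                raise ValueError(f"{name} must lie in [0, 1] on the mask")
        for name in ("k_a", "k_v"):
            if np.any(getattr(self, name)[m] <= 0):
                raise ValueError(f"{name} must be positive on the mask")
        if np.any(self.alpha[m] < 0):
            raise ValueError("alpha must be nonnegative on the mask")

    @property
    def n_masked(self) -> int:
        return int(self.mask.sum())

    @property
    def volume_m3(self) -> float:
        return self.n_masked * self.grid.voxel_volume_m3

    def boundary_voxels(self) -> np.ndarray:
        """Mask voxels on the tissue/background interface (6-connectivity),
        including mask voxels on the image boundary."""
        eroded = ndimage.binary_erosion(
            self.mask, structure=ndimage.generate_binary_structure(3, 1),
            border_value=0)
        return self.mask & ~eroded

    def hull_boundary_voxels(self) -> np.ndarray:
        """Boundary of the convex hull of the tissue mask.

        Root terminals of a vascular network live where the vessels cross
        this surface.
        """
        from skimage.morphology import convex_hull_image

        flat_axes = tuple(a for a in range(3) if self.grid.shape[a] == 1)
        if flat_axes:
            # quasi-2D: qhull cannot build a 3D hull from coplanar points
            hull2d = convex_hull_image(np.squeeze(self.mask, axis=flat_axes))
            hull = hull2d.reshape(self.mask.shape)
            eroded = ndimage.binary_erosion(
                hull2d, structure=ndimage.generate_binary_structure(2, 1),
                border_value=0).reshape(self.mask.shape)
        else:
            hull = convex_hull_image(self.mask)
            eroded = ndimage.binary_erosion(
                hull, structure=ndimage.generate_binary_structure(3, 1),
                border_value=0)
        return hull & ~eroded

    def distance_to_boundary_mm(self, positions, use_hull: bool = False) -> np.ndarray:
        """Euclidean distance [mm] from physical positions to the nearest
        tissue (or hull) boundary voxel centre."""
        bnd = self.hull_boundary_voxels() if use_hull else self.boundary_voxels()
        pts = self.grid.index_to_physical(np.argwhere(bnd))
        positions = np.atleast_2d(np.asarray(positions, dtype=float))
        from scipy.spatial import cKDTree

        d, _ = cKDTree(pts).query(positions)
        return d


def masked_gaussian_smooth(field: np.ndarray, mask: np.ndarray, grid: VoxelGrid,
                           radius_mm: float = 2.5, sigma_mm: float = 1.5) -> np.ndarray:
    """Smooth a parameter field by a truncated Gaussian restricted to the mask.

    Emulates MR partial-volume mixing at tissue interfaces: piecewise-constant
    per-tissue parameter maps are blurred (kernel radius ``radius_mm``,
    standard deviation ``sigma_mm``) with renormalisation over the mask so no
    weight leaks into the background.  Axes with a single voxel are skipped.
    """
    mask = mask.astype(bool)
    sigmas = []
    for ax in range(3):
        if grid.shape[ax] == 1:
            sigmas.append(0.0)
        else:
            sigmas.append(sigma_mm / grid.voxel_size[ax])
    truncate = radius_mm / sigma_mm
    f = np.where(mask, field, 0.0)
    num = ndimage.gaussian_filter(f, sigma=sigmas, truncate=truncate)
    den = ndimage.gaussian_filter(mask.astype(float), sigma=sigmas, truncate=truncate)
    out = np.array(field, dtype=float)
    good = mask & (den > 0)
    out[good] = num[good] / den[good]
    return out
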