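"""Coupling of 1D network flow to 3D tissue flow via support kernels.

A terminal of the vascular graph would act as a point (Dirac) source in the
Darcy continuum, which is singular both physically and numerically.  Instead
its flow is spread over a ball of radius ``epsilon`` using a smooth,
compactly supported bump kernel

    eta(x) = C * exp(1 / (|x|^2 - 1))   for |x| < 1,  0 otherwise,
    eta_eps(x) = eps^-n * eta(x / eps),

which is C^infinity, vanishes outside the support, and integrates to one.
``epsilon`` represents the reach of the sub-resolution arteriole/venule tree
feeding the tissue around the terminal.

On the discrete grid the kernel is evaluated at voxel centres, clipped to the
organ mask, and then renormalised so that the *discrete* integral over the
mask is exactly one — this makes terminal mass balance hold to machine
precision even when the support is truncated by the organ boundary.

The closure that determines each terminal's flow couples the node pressure
to the kernel-weighted mean tissue pressure:

    q_k = (gamma / mu) * (p_node_k - sum_j w_j |Omega_j| p_j)

with the user-set resistance parameter ``gamma`` [m^3] of the unresolved
network beyond the terminal.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import integrate

from .grid import TissueDomain
from .network import VesselNetwork


def _bump(r2: np.ndarray) -> np.ndarray:
    """Unnormalised bump exp(1/(r^2-1)) on r^2 < 1, 0 outside (r2 = |x|^2)."""
    r2 = np.asarray(r2, dtype=float)
    out = np.zeros_like(r2)
    inside = r2 < 1.0
    with np.errstate(divide="ignore"):
        out[inside] = np.exp(1.0 / (r2[inside] - 1.0))
    return out


@lru_cache(maxsize=None)
def eta_normalization(dim: int) -> float:
    """Normalisation constant C of the bump so its integral over the unit
    ball in ``dim`` dimensions is one.  No closed form exists; computed by
    adaptive radial quadrature."""
    if dim not in (1, 2, 3):
        raise ValueError("dimension must be 1, 2 or 3")
    surface = {1: 2.0, 2: 2.0 * np.pi, 3: 4.0 * np.pi}[dim]
    val, _ = integrate.quad(lambda r: r ** (dim - 1) * np.exp(1.0 / (r * r - 1.0)),
                            0.0, 1.0, limit=200)
    return 1.0 / (surface * val)


def shape_eta(x, dim: int = 3) -> np.ndarray:
    """Normalised shape function eta(x); ``x`` is (..., dim) dimensionless."""
    x = np.asarray(x, dtype=float)
    r2 = np.sum(np.atleast_2d(x) ** 2, axis=-1) if x.ndim > 0 else x**2
    r2 = np.sum(np.asarray(x, dtype=float) ** 2, axis=-1)
    return eta_normalization(dim) * _bump(r2)


@dataclass
class TerminalKernel:
    """Discrete support weights of one interior terminal.

    ``flat_idx`` are full-grid flat voxel indices inside the mask with
    nonzero weight; ``weights`` [m^-3] satisfy sum(weights) * voxel_volume
    = 1 exactly.
    """

    node_id: int
    flat_idx: np.ndarray
    weights: np.ndarray
    epsilon_mm: float

    def integral(self, voxel_volume_m3: float) -> float:
        return float(self.weights.sum() * voxel_volume_m3)

    def as_field(self, shape) -> np.ndarray:
        f = np.zeros(int(np.prod(shape)))
        f[self.flat_idx] = self.weights
        return f.reshape(shape)


def kernel_weights(position_mm, domain: TissueDomain, epsilon_mm: float,
                   node_id: int = -1) -> TerminalKernel:
    """Discrete, mask-clipped, exactly renormalised kernel of one terminal.

    Distances are Euclidean in physical coordinates (anisotropic voxels
    respected).  Raises if the epsilon-ball misses the organ mask entirely
    ("orphan terminal").  The constant prefactors C and eps^-n cancel in the
    discrete renormalisation, so only the bump profile matters here.
    """
    if epsilon_mm <= 0:
        raise ValueError("epsilon must be positive")
    grid = domain.grid
    pos = np.asarray(position_mm, dtype=float)
    h = np.asarray(grid.voxel_size)
    lo = np.maximum(np.floor((pos - grid.origin - epsilon_mm) / h).astype(int), 0)
    hi = np.minimum(np.ceil((pos - grid.origin + epsilon_mm) / h).astype(int) + 1,
                    np.asarray(grid.shape))
    if np.any(lo >= hi):
        raise ValueError(f"orphan terminal {node_id}: support outside the grid")
    axes = [grid.origin[a] + np.arange(lo[a], hi[a]) * h[a] for a in range(3)]
    dx = [axes[a] - pos[a] for a in range(3)]
    r2 = (dx[0][:, None, None] ** 2 + dx[1][None, :, None] ** 2
          + dx[2][None, None, :] ** 2) / epsilon_mm**2
    eta = _bump(r2)
    sub_mask = domain.mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    eta[~sub_mask] = 0.0
    nz = np.nonzero(eta)
    if len(nz[0]) == 0:
        # support smaller than a voxel or clipped away: fall back to the
        # nearest masked voxel (Dirac limit) if one is inside epsilon
        masked = np.argwhere(domain.mask)
        d = np.linalg.norm(grid.index_to_physical(masked) - pos, axis=1)
        i = int(np.argmin(d))
        if d[i] >= max(epsilon_mm, grid.diagonal_mm):
            raise ValueError(f"orphan terminal {node_id}: epsilon-ball does not "
                             "intersect the tissue mask")
        flat = np.array([np.ravel_multi_index(masked[i], grid.shape)])
        return TerminalKernel(node_id, flat, np.array([1.0 / grid.voxel_volume_m3]),
                              epsilon_mm)
    idx = np.stack([nz[0] + lo[0], nz[1] + lo[1], nz[2] + lo[2]], axis=1)
    flat = np.ravel_multi_index((idx[:, 0], idx[:, 1], idx[:, 2]), grid.shape)
    vals = eta[nz]
    weights = vals / (vals.sum() * grid.voxel_volume_m3)
    return TerminalKernel(node_id, flat, weights, epsilon_mm)


def build_kernels(network: VesselNetwork, domain: TissueDomain,
                  epsilon_mm: float) -> dict[int, TerminalKernel]:
    """One kernel per interior terminal of the network."""
    kernels = {}
    for nid in network.terminals:
        kernels[nid] = kernel_weights(network.nodes[nid].position, domain,
                                      epsilon_mm, node_id=nid)
    return kernels


@dataclass
class ClosureRelation:
    """Linear pressure-continuity constraint of one terminal:
    ``q_k = coef * (p_node - sum_i tissue_coeffs[i] * p[flat_idx[i]])``
    with ``coef = gamma / mu`` [m^3 / (Pa s)] and tissue coefficients
    ``w_i |Omega_i|`` summing to one."""

    node_id: int
    coef: float
    flat_idx: np.ndarray
    tissue_coeffs: np.ndarray

    def evaluate(self, p_node: float, pressure_field: np.ndarray) -> float:
        """Terminal flow [m^3/s] for a given node pressure and tissue
        pressure field (full grid array)."""
        p_mean = float(pressure_field.reshape(-1)[self.flat_idx] @ self.tissue_coeffs)
        return self.coef * (p_node - p_mean)


def continuity_closure(network: VesselNetwork, kernels: dict[int, TerminalKernel],
                       gamma: float, mu: float,
                       voxel_volume_m3: float) -> dict[int, ClosureRelation]:
    """Build the closure relation for every interior terminal."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    out = {}
    for nid in network.terminals:
        ker = kernels[nid]
        out[nid] = ClosureRelation(nid, gamma / mu, ker.flat_idx,
                                   ker.weights * voxel_volume_m3)
    return out
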