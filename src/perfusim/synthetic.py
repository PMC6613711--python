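"""Synthetic organ geometries with known ground truth.

Generates ellipsoidal tissue masks containing paired, interdigitated
arterial and venous branching trees whose roots touch the tissue boundary —
the same topology class as a real vascular dataset (a quasi-2D tongue, a 3D
brain) but with the exact graph (nodes, edges, lengths, radii) known by
construction, so extraction, flow, tracer and sensitivity can all be
validated without any external data.

All generators are deterministic given their seed.  Quasi-2D scenarios are
3D arrays of thickness one voxel, matching the convention of single-slice
organ masks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import SimulationConfig, preset
from .grid import TissueDomain, VoxelGrid, masked_gaussian_smooth
from .network import INTERIOR, ROOT_TERMINAL, TERMINAL, VesselNetwork


@dataclass(frozen=True)
class TreeSpec:
    """Recipe for one recursive binary tree, in physical [mm] coordinates."""

    root_mm: tuple[float, float, float]
    direction: tuple[float, float, float]
    depth: int = 3
    branch_length_mm: float = 12.0
    length_decay: float = 0.65
    root_radius_mm: float = 0.8
    radius_decay: float = 0.72
    angle_deg: float = 35.0
    jitter_deg: float = 5.0
    seed: int = 0


def make_tissue(shape, voxel_size_mm, kind: str = "ellipse2d", seed: int = 0,
                config: SimulationConfig | None = None,
                smooth: bool = False) -> TissueDomain:
    """Ellipsoidal tissue mask with per-tissue parameter fields.

    Kinds: ``ellipse2d`` (single-slice), ``ellipsoid3d``, ``two-tissue``
    (3D ellipsoid with an inner 'white matter' core and an outer 'grey
    matter' shell whose alpha is 1.6x higher, emulating the grey/white
    perfusion contrast).
    """
    shape = tuple(int(s) for s in shape)
    if min(s for s in shape if s > 1) < 16:
        raise ValueError(f"degenerate shape {shape}")
    grid = VoxelGrid(shape, tuple(voxel_size_mm))
    cfg = config if config is not None else preset("frog")
    center = 0.5 * (np.asarray(grid.fov) - np.asarray(grid.voxel_size))
    semi = 0.45 * np.asarray(grid.fov)
    idx = np.indices(shape, dtype=float)
    pos = [idx[a] * grid.voxel_size[a] for a in range(3)]
    if kind == "ellipse2d":
        if shape[2] != 1:
            raise ValueError("ellipse2d requires a single-slice grid")
        r2 = ((pos[0] - center[0]) / semi[0]) ** 2 + ((pos[1] - center[1]) / semi[1]) ** 2
    elif kind in ("ellipsoid3d", "two-tissue"):
        if shape[2] == 1:
            raise ValueError(f"{kind} requires a 3D grid")
        r2 = sum(((pos[a] - center[a]) / semi[a]) ** 2 for a in range(3))
    else:
        raise ValueError(f"unknown tissue kind {kind!r}")
    mask = r2 <= 1.0
    alpha = np.full(shape, cfg.alpha)
    labels = None
    if kind == "two-tissue":
        inner = r2 <= 0.6**2
        labels = np.zeros(shape, dtype=np.int8)
        labels[mask] = 2          # grey shell
        labels[inner] = 1         # white core
        alpha[mask] = cfg.alpha * cfg.alpha_grey_ratio
        alpha[inner] = cfg.alpha
    dom = TissueDomain(grid, mask, phi_a=cfg.phi_a, phi_v=cfg.phi_v,
                       k_a=cfg.k_a, k_v=cfg.k_v, alpha=alpha, mu=cfg.mu,
                       labels=labels)
    if smooth:
        dom.alpha = masked_gaussian_smooth(dom.alpha, mask, grid,
                                           cfg.smoothing_radius_mm,
                                           cfg.smoothing_sigma_mm)
    return dom


def _rotate(v, axis, angle):
    axis = axis / np.linalg.norm(axis)
    c, s = np.cos(angle), np.sin(angle)
    return (v * c + np.cross(axis, v) * s + axis * (axis @ v) * (1 - c))


def _grow(rng, p, d, length, radius, depth, spec, planar, segments, nodes,
          parent_node):
    """Recursive binary growth; appends (p0, p1, r, node_j, node_k)."""
    q = p + d * length
    nid = len(nodes)
    nodes.append((q, TERMINAL if depth == 0 else INTERIOR))
    segments.append((p, q, radius, parent_node, nid))
    if depth == 0:
        return
    ang = np.deg2rad(spec.angle_deg)
    jit = np.deg2rad(spec.jitter_deg)
    if planar:
        axis = np.array([0.0, 0.0, 1.0])
        axes = (axis, axis)
        angles = (ang + rng.uniform(-jit, jit), -(ang + rng.uniform(-jit, jit)))
    else:
        # branch in a plane spanned by d and a random perpendicular
        perp = np.cross(d, rng.standard_normal(3))
        while np.linalg.norm(perp) < 1e-8:
            perp = np.cross(d, rng.standard_normal(3))
        axis = np.cross(d, perp / np.linalg.norm(perp))
        axis /= np.linalg.norm(axis)
        axes = (axis, axis)
        angles = (ang + rng.uniform(-jit, jit), -(ang + rng.uniform(-jit, jit)))
    for axis_i, a in zip(axes, angles):
        child_d = _rotate(d, axis_i, a)
        child_d /= np.linalg.norm(child_d)
        _grow(rng, q, child_d, length * spec.length_decay,
              radius * spec.radius_decay, depth - 1, spec, planar,
              segments, nodes, nid)


def _segment_axis_voxels(grid: VoxelGrid, p0, p1):
    """Ordered, deduplicated voxel indices along a straight segment."""
    L = np.linalg.norm(p1 - p0)
    nstep = max(2, int(np.ceil(L / (0.5 * min(grid.voxel_size)))) + 1)
    ts = np.linspace(0.0, 1.0, nstep)
    pts = p0[None, :] + ts[:, None] * (p1 - p0)[None, :]
    idx = np.rint(grid.physical_to_index(pts)).astype(int)
    idx = np.clip(idx, 0, np.asarray(grid.shape) - 1)
    keep = np.ones(len(idx), bool)
    keep[1:] = np.any(idx[1:] != idx[:-1], axis=1)
    return idx[keep]


def _stamp_tube(mask_out, grid: VoxelGrid, p0, p1, radius_mm):
    """Set voxels with distance-to-segment <= radius (physical coords)."""
    h = np.asarray(grid.voxel_size)
    lo = np.floor((np.minimum(p0, p1) - radius_mm) / h).astype(int)
    hi = np.ceil((np.maximum(p0, p1) + radius_mm) / h).astype(int) + 1
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, np.asarray(grid.shape))
    if np.any(lo >= hi):
        return
    ax = [np.arange(lo[a], hi[a]) * h[a] for a in range(3)]
    X = np.stack(np.meshgrid(*ax, indexing="ij"), axis=-1)
    d = p1 - p0
    L2 = float(d @ d)
    w = X - p0
    t = np.clip((w @ d) / max(L2, 1e-30), 0.0, 1.0)
    closest = p0 + t[..., None] * d
    dist = np.linalg.norm(X - closest, axis=-1)
    sub = mask_out[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    sub |= dist <= radius_mm


def make_tree(spec: TreeSpec, domain: TissueDomain,
              compartment: str = "a") -> tuple[np.ndarray, VesselNetwork]:
    """Rasterise a recursive binary tree and return (mask, ground truth).

    The returned network carries the exact node positions/classes, edge
    lengths, radii and medial axes used for rasterisation; the root node is
    a root terminal, the leaves are interior terminals, bifurcations are
    interior nodes.
    """
    grid = domain.grid
    planar = grid.effective_dim == 2
    rng = np.random.default_rng(spec.seed)
    root = np.asarray(spec.root_mm, dtype=float)
    d = np.asarray(spec.direction, dtype=float)
    d = d / np.linalg.norm(d)
    if planar:
        d[2] = 0.0
        d /= np.linalg.norm(d)
        root = root.copy()
        root[2] = grid.origin[2]  # quasi-2D trees live in the slice plane
    nodes: list[tuple[np.ndarray, str]] = [(root, ROOT_TERMINAL)]
    segments: list[tuple] = []
    _grow(rng, root, d, spec.branch_length_mm, spec.root_radius_mm,
          spec.depth, spec, planar, segments, nodes, 0)

    net = VesselNetwork(compartment)
    for pos, cls in nodes:
        net.add_node(pos, cls)
    mask = np.zeros(grid.shape, dtype=bool)
    min_r = 0.5 * min(v for v, s in zip(grid.voxel_size, grid.shape) if s > 1)
    for p0, p1, r, j, k in segments:
        r = max(r, min_r)  # keep every branch rasterisable
        axis = _segment_axis_voxels(grid, p0, p1)
        net.add_edge(j, k, float(np.linalg.norm(p1 - p0)), r, axis)
        _stamp_tube(mask, grid, p0, p1, r)
    if not mask.any():
        raise ValueError("tree escaped the domain entirely")
    return mask, net


@dataclass
class SimulationBundle:
    """Everything an end-to-end run needs: geometry, graphs, parameters."""

    domain: TissueDomain
    arterial: VesselNetwork
    venous: VesselNetwork
    vessel_mask_a: np.ndarray
    vessel_mask_v: np.ndarray
    config: SimulationConfig
    roi: np.ndarray | None = None


def make_paired_scenario(seed: int = 0, kind: str = "frog-like",
                         base_shape=None, resolution_scale: int = 1,
                         config: SimulationConfig | None = None,
                         depth: int = 3) -> SimulationBundle:
    """Tissue + interdigitated arterial and venous trees + parameters.

    ``frog-like``: quasi-2D elliptical organ (40 x 33 x 1 mm field of view)
    with both roots entering from the bottom edge, run at the quasi-2D
    parameter preset.  ``brain-like``: two-tissue 3D ellipsoid at the 3D
    preset.  ``resolution_scale`` refines the in-plane grid while keeping
    the physical geometry, parameters and ground-truth graphs identical —
    the scale-invariance experiment.
    """
    s = int(resolution_scale)
    if kind == "frog-like":
        cfg = config if config is not None else preset("frog")
        if base_shape is None:
            base_shape = (120, 100, 1)
        shape = (base_shape[0] * s, base_shape[1] * s, 1)
        fov = (40.0, 33.0, 1.0)
        vox = tuple(f / n for f, n in zip(fov, shape))
        dom = make_tissue(shape, vox, "ellipse2d", seed=seed, config=cfg)
        center = 0.5 * (np.asarray(dom.grid.fov) - np.asarray(vox))
        semi = 0.45 * np.asarray(fov)

        def boundary_point(theta_deg):
            th = np.deg2rad(theta_deg)
            p = center + np.array([semi[0] * np.cos(th), semi[1] * np.sin(th), 0.0])
            p[2] = 0.0
            return p

        ra = boundary_point(255.0)
        rv = boundary_point(285.0)
        spec_a = TreeSpec(tuple(ra), tuple(center - ra), depth=depth,
                          branch_length_mm=11.0, root_radius_mm=0.8, seed=seed * 2 + 1)
        spec_v = TreeSpec(tuple(rv), tuple(center - rv), depth=depth,
                          branch_length_mm=11.0, root_radius_mm=1.0,
                          angle_deg=32.0, seed=seed * 2 + 2)
        mask_a, net_a = make_tree(spec_a, dom, "a")
        mask_v, net_v = make_tree(spec_v, dom, "v")
        # fixed physical ROI (central patch) for scale-invariance studies
        roi = np.zeros(shape, bool)
        i0 = dom.grid.physical_to_index(center - np.array([8.0, 7.0, 0.0]))
        i1 = dom.grid.physical_to_index(center + np.array([8.0, 7.0, 0.0]))
        roi[int(i0[0]):int(i1[0]) + 1, int(i0[1]):int(i1[1]) + 1, :] = True
    elif kind == "brain-like":
        cfg = config if config is not None else preset("brain")
        if base_shape is None:
            base_shape = (36, 36, 32)
        if depth == 3:
            depth = 4
        shape = tuple(int(b * s) for b in base_shape)
        fov = (96.0, 96.0, 80.0)
        vox = tuple(f / n for f, n in zip(fov, shape))
        dom = make_tissue(shape, vox, "two-tissue", seed=seed, config=cfg,
                          smooth=True)
        center = 0.5 * (np.asarray(dom.grid.fov) - np.asarray(vox))
        semi = 0.45 * np.asarray(fov)
        ra = center + np.array([0.0, -semi[1], 0.0])
        rv = center + np.array([semi[0] * np.cos(np.deg2rad(60.0)),
                                semi[1] * np.sin(np.deg2rad(60.0)), 0.0])
        # shallow penetration + wide tangential spread keeps most terminals
        # in the cortical (grey) shell, as pial supply does in a real brain
        spec_a = TreeSpec(tuple(ra), tuple(center - ra), depth=depth,
                          branch_length_mm=12.0, length_decay=0.85,
                          root_radius_mm=2.2, angle_deg=65.0,
                          seed=seed * 2 + 1)
        spec_v = TreeSpec(tuple(rv), tuple(center - rv), depth=depth,
                          branch_length_mm=11.5, length_decay=0.85,
                          root_radius_mm=2.6, angle_deg=62.0,
                          seed=seed * 2 + 2)
        mask_a, net_a = make_tree(spec_a, dom, "a")
        mask_v, net_v = make_tree(spec_v, dom, "v")
        roi = None
    else:
        raise ValueError(f"unknown scenario kind {kind!r}")
    net_a.compute_node_volumes(mask_a, dom)
    net_v.compute_node_volumes(mask_v, dom)
    return SimulationBundle(dom, net_a, net_v, mask_a, mask_v, cfg, roi)
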