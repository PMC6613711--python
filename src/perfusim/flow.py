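"""Coupled Hagen-Poiseuille / two-compartment Darcy pressure solver.

The stationary flow model consists of, per compartment beta in {a, v}:

* voxel mass balance on the organ mask (finite-volume TPFA for the Darcy
  term, with no-flow Neumann conditions on the organ boundary)::

      sum_j t_ij (p_i - p_j)  +/- alpha_i (p_a,i - p_v,i) |O_i|
          - sum_k q_k w_k(x_i) |O_i| = 0

  (+ for arterial, - for venous; the perfusion P = alpha (p_a - p_v) is the
  sink of the arterial and the source of the venous compartment),

* Kirchhoff balance at interior network junctions, Dirichlet pressures at
  root terminals, the Hagen-Poiseuille flow definition at interior
  terminals, and

* the pressure-continuity closure coupling each terminal flow to the
  kernel-weighted mean tissue pressure (see :mod:`perfusim.coupling`).

Terminal flows are kept as explicit unknowns.  Substituting the closure into
the voxel rows (as the block form of the eliminated system suggests) creates
a dense coupling between every voxel pair inside a terminal's support; with
the explicit flow unknowns the matrix stays sparse and the two forms are
algebraically identical.

The unknown vector is ``[p_a voxels, p_v voxels, node pressures a, node
pressures v, terminal flows a, terminal flows v]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .coupling import TerminalKernel, build_kernels
from .grid import MM, PERFUSION_UNIT, TissueDomain
from .network import ROOT_TERMINAL, TERMINAL, VesselNetwork


def tpfa_transmissibilities(domain: TissueDomain, compartment: str):
    """Face transmissibilities of the masked TPFA discretisation.

    Returns ``(i, j, t)``: masked-voxel ordinals of the two cells sharing
    each interior face and the transmissibility ``t`` [m^3 Pa^-1 s^-1],
    the harmonic mean of the half-cell conductivities ``lambda = k/mu``
    times face area over centre distance.  Faces to unmasked voxels carry no
    flow (Neumann boundary).
    """
    k = domain.k_a if compartment == "a" else domain.k_v
    lam = k / domain.mu  # [m^2 / (Pa s)]
    mask = domain.mask
    ordinal = -np.ones(domain.grid.shape, dtype=np.int64)
    ordinal[mask] = np.arange(domain.n_masked)
    h = [s * MM for s in domain.grid.voxel_size]
    rows_i, rows_j, ts = [], [], []
    for ax in range(3):
        if domain.grid.shape[ax] == 1:
            continue
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[ax] = slice(None, -1)
        sl_hi[ax] = slice(1, None)
        sl_lo, sl_hi = tuple(sl_lo), tuple(sl_hi)
        both = mask[sl_lo] & mask[sl_hi]
        if not both.any():
            continue
        area = np.prod([h[a] for a in range(3) if a != ax])
        d = h[ax] / 2.0
        lam_i = lam[sl_lo][both]
        lam_j = lam[sl_hi][both]
        t = area / (d / lam_i + d / lam_j)
        rows_i.append(ordinal[sl_lo][both])
        rows_j.append(ordinal[sl_hi][both])
        ts.append(t)
    if not rows_i:
        return (np.zeros(0, np.int64), np.zeros(0, np.int64), np.zeros(0))
    return (np.concatenate(rows_i), np.concatenate(rows_j), np.concatenate(ts))


@dataclass
class CoupledSystem:
    """Assembled sparse linear problem ``A x = d`` plus index bookkeeping."""

    A: sp.csr_matrix
    d: np.ndarray
    domain: TissueDomain
    arterial: VesselNetwork
    venous: VesselNetwork
    kernels_a: dict[int, TerminalKernel]
    kernels_v: dict[int, TerminalKernel]
    mask_flat: np.ndarray           # full-grid flat index per masked ordinal
    node_offset: dict[str, int]     # compartment -> first node unknown
    node_order: dict[str, list[int]]
    q_offset: dict[str, int]
    q_order: dict[str, list[int]]
    n_masked: int
    gamma: dict[str, float] = field(default_factory=dict)
    p0: dict[str, float] = field(default_factory=dict)

    def node_index(self, comp: str, node_id: int) -> int:
        return self.node_offset[comp] + self.node_order[comp].index(node_id)

    def q_index(self, comp: str, node_id: int) -> int:
        return self.q_offset[comp] + self.q_order[comp].index(node_id)


def assemble_coupled_system(domain: TissueDomain, arterial: VesselNetwork,
                            venous: VesselNetwork,
                            kernels_a: dict[int, TerminalKernel],
                            kernels_v: dict[int, TerminalKernel],
                            gamma_a: float, gamma_v: float,
                            p_a0: float, p_v0: float) -> CoupledSystem:
    """Assemble the coupled TPFA + network + closure system.

    ``p_a0``/``p_v0`` [Pa] are the Dirichlet pressures imposed at every
    arterial / venous root terminal.
    """
    if gamma_a <= 0 or gamma_v <= 0:
        raise ValueError("gamma must be positive")
    mask = domain.mask
    n = domain.n_masked
    V = domain.grid.voxel_volume_m3
    flat_to_ord = -np.ones(domain.grid.n_voxels, dtype=np.int64)
    mask_flat = np.flatnonzero(mask.reshape(-1))
    flat_to_ord[mask_flat] = np.arange(n)

    nets = {"a": arterial, "v": venous}
    kers = {"a": kernels_a, "v": kernels_v}
    gammas = {"a": gamma_a, "v": gamma_v}
    p0 = {"a": p_a0, "v": p_v0}
    alpha_m = domain.alpha[mask]
    if not np.any(alpha_m > 0):
        for comp, net in nets.items():
            if not net.root_terminals:
                raise ValueError(f"floating compartment {comp!r}: alpha is zero "
                                 "and the network has no root terminal")
    if not arterial.root_terminals and not venous.root_terminals:
        raise ValueError("floating compartment: no root terminal in either network")

    node_order = {c: sorted(nets[c].nodes) for c in "av"}
    q_order = {c: sorted(nets[c].terminals) for c in "av"}
    node_offset = {"a": 2 * n, "v": 2 * n + len(node_order["a"])}
    q_offset = {"a": node_offset["v"] + len(node_order["v"])}
    q_offset["v"] = q_offset["a"] + len(q_order["a"])
    size = q_offset["v"] + len(q_order["v"])

    rows, cols, vals = [], [], []
    rhs = np.zeros(size)

    def add(r, c, v):
        rows.append(np.asarray(r, dtype=np.int64).reshape(-1))
        cols.append(np.asarray(c, dtype=np.int64).reshape(-1))
        vals.append(np.asarray(v, dtype=float).reshape(-1))

    # Darcy TPFA blocks
    for comp, off in (("a", 0), ("v", n)):
        fi, fj, t = tpfa_transmissibilities(domain, comp)
        add(off + fi, off + fi, t)
        add(off + fi, off + fj, -t)
        add(off + fj, off + fj, t)
        add(off + fj, off + fi, -t)
    # perfusion exchange alpha (p_a - p_v) |O_i|
    aV = alpha_m * V
    iv = np.arange(n)
    add(iv, iv, aV)            # arterial row, p_a
    add(iv, n + iv, -aV)       # arterial row, p_v
    add(n + iv, iv, -aV)       # venous row, p_a
    add(n + iv, n + iv, aV)    # venous row, p_v

    for comp in "av":
        net = nets[comp]
        voff = 0 if comp == "a" else n
        noff = node_offset[comp]
        order = node_order[comp]
        pos = {nid: i for i, nid in enumerate(order)}
        qpos = {nid: i for i, nid in enumerate(q_order[comp])}
        mu = domain.mu
        for nid in order:
            r = noff + pos[nid]
            ncls = net.nodes[nid].node_class
            if ncls == ROOT_TERMINAL:
                add(r, r, 1.0)
                rhs[r] = p0[comp]
            elif ncls == TERMINAL:
                # node row: Hagen-Poiseuille flow definition
                # kappa_jk (p_k - p_j) + q_k = 0
                (ei,) = net.incident_edges(nid)
                e = net.edges[ei]
                j = e.k if e.j == nid else e.j
                kap = e.conductance(mu)
                qidx = q_offset[comp] + qpos[nid]
                add(r, r, kap)
                add(r, noff + pos[j], -kap)
                add(r, qidx, 1.0)
                # q row: pressure-continuity closure
                # q_k - (gamma/mu)(p_node_k - sum_i c_i p_i) = 0
                coef = gammas[comp] / mu
                ker = kers[comp][nid]
                add(qidx, qidx, 1.0)
                add(qidx, r, -coef)
                tis = flat_to_ord[ker.flat_idx]
                add(np.full(len(tis), qidx), voff + tis, coef * ker.weights * V)
                # kernel source in the voxel balance rows: -q_k w_i |O_i|
                add(voff + tis, np.full(len(tis), qidx), -ker.weights * V)
            else:  # interior junction: Kirchhoff
                for ei in net.incident_edges(nid):
                    e = net.edges[ei]
                    j = e.k if e.j == nid else e.j
                    kap = e.conductance(mu)
                    add(r, r, kap)
                    add(r, noff + pos[j], -kap)

    A = sp.csr_matrix((np.concatenate(vals),
                       (np.concatenate(rows), np.concatenate(cols))),
                      shape=(size, size))
    return CoupledSystem(A, rhs, domain, arterial, venous, kernels_a, kernels_v,
                         mask_flat, node_offset, node_order, q_offset, q_order, n,
                         gamma=dict(gammas), p0=dict(p0))


@dataclass
class PressureSolution:
    """Solved pressures, terminal/edge flows and mass-balance audit."""

    p_a: np.ndarray
    p_v: np.ndarray
    node_pressures: dict[str, dict[int, float]]
    terminal_flows: dict[str, dict[int, float]]
    root_flows: dict[str, dict[int, float]]
    residual_norm: float
    iterations: int
    system: CoupledSystem = field(repr=False)

    @property
    def domain(self) -> TissueDomain:
        return self.system.domain

    def mass_balance(self) -> dict[str, float]:
        """Global audit: arterial root inflow, venous root outflow and the
        mask integral of the perfusion must all coincide."""
        dom = self.domain
        V = dom.grid.voxel_volume_m3
        m = dom.mask
        total_P = float(np.sum(dom.alpha[m] * (self.p_a[m] - self.p_v[m])) * V)
        a_in = float(sum(self.root_flows["a"].values()))
        v_out = float(-sum(self.root_flows["v"].values()))
        scale = max(abs(a_in), abs(v_out), abs(total_P), 1e-300)
        return {
            "arterial_root_inflow_m3_s": a_in,
            "venous_root_outflow_m3_s": v_out,
            "total_perfusion_m3_s": total_P,
            "rel_err_inflow_outflow": abs(a_in - v_out) / scale,
            "rel_err_inflow_perfusion": abs(a_in - total_P) / scale,
        }

    def perfusion_field(self) -> np.ndarray:
        """Perfusion P = alpha (p_a - p_v) [s^-1] (nan outside the mask)."""
        dom = self.domain
        P = np.full(dom.grid.shape, np.nan)
        m = dom.mask
        P[m] = dom.alpha[m] * (self.p_a[m] - self.p_v[m])
        return P

    def perfusion_clinical(self) -> np.ndarray:
        """Perfusion in ml/min/100ml."""
        return self.perfusion_field() * PERFUSION_UNIT

    def mean_perfusion_clinical(self, roi: np.ndarray | None = None) -> float:
        P = self.perfusion_clinical()
        m = self.domain.mask if roi is None else (self.domain.mask & roi)
        return float(np.nanmean(P[m]))


def equilibrate(A: sp.spmatrix, d: np.ndarray, sweeps: int = 3):
    """Balanced row/column scaling: ``A2 = Dr A Dc``, ``b = Dr d``.

    The raw matrix mixes voxel-balance rows (~1e-13), network rows (~1e-10)
    and unit Dirichlet rows; a few alternating sweeps of geometric-mean
    (square-root of the max-abs) scaling on rows and columns bring the
    condition number down by several orders of magnitude more than a single
    one-sided pass, which matters because the pressure level of the tissue
    is only weakly anchored through the terminal closure.  The solution of
    the original system is ``Dc y`` where ``A2 y = b``.
    """
    r_tot = np.ones(A.shape[0])
    c_tot = np.ones(A.shape[1])
    A2 = A.copy().tocsr()
    for _ in range(sweeps):
        r = np.sqrt(np.asarray(abs(A2).max(axis=1).todense()).reshape(-1))
        r[r == 0] = 1.0
        A2 = sp.diags(1.0 / r) @ A2
        r_tot *= r
        c = np.sqrt(np.asarray(abs(A2).max(axis=0).todense()).reshape(-1))
        c[c == 0] = 1.0
        A2 = A2 @ sp.diags(1.0 / c)
        c_tot *= c
    Dr = sp.diags(1.0 / r_tot)
    Dc = sp.diags(1.0 / c_tot)
    return A2.tocsc(), Dr @ d, Dr, Dc


def _dirac_kernels(kernels: dict[int, TerminalKernel],
                   voxel_volume_m3: float) -> dict[int, TerminalKernel]:
    """Collapse each kernel onto its peak voxel (preconditioner aid)."""
    out = {}
    for nid, k in kernels.items():
        i = int(np.argmax(k.weights))
        out[nid] = TerminalKernel(nid, k.flat_idx[i:i + 1],
                                  np.array([1.0 / voxel_volume_m3]), k.epsilon_mm)
    return out


def solve_pressure(system: CoupledSystem, method: str = "direct",
                   tol: float = 1e-6, maxiter: int = 2000,
                   precond_matrix: sp.spmatrix | None = None) -> PressureSolution:
    """Solve the assembled system for pressures and back-substitute flows.

    ``method='direct'`` uses a complete sparse LU factorisation (the default
    at desk scale); ``'gmres'`` uses GMRES with a complete LU of
    ``precond_matrix`` (by default the same matrix with every support kernel
    collapsed to a point source — same sparsity as the pure TPFA + network
    problem, so it factorises quickly, while staying spectrally close to the
    full operator).  Rows/columns are max-abs equilibrated before either
    solve because voxel, node and closure rows live on very different
    scales.
    """
    A, d = system.A, system.d
    A2, b, Dr, Dc = equilibrate(A, d)
    iterations = 0
    if method == "direct":
        lu = spla.splu(A2)
        y = lu.solve(b)
        for _ in range(2):  # iterative refinement sharpens the audit
            y = y + lu.solve(b - A2 @ y)
    elif method == "gmres":
        if precond_matrix is None:
            V = system.domain.grid.voxel_volume_m3
            ps = assemble_coupled_system(
                system.domain, system.arterial, system.venous,
                _dirac_kernels(system.kernels_a, V),
                _dirac_kernels(system.kernels_v, V),
                system.gamma["a"], system.gamma["v"],
                system.p0["a"], system.p0["v"])
            precond_matrix = ps.A
        P2 = (Dr @ precond_matrix @ Dc).tocsc()
        lu = spla.splu(P2)
        M = spla.LinearOperator(A2.shape, lu.solve)
        counter = {"n": 0}

        def cb(_):
            counter["n"] += 1

        y, info = spla.gmres(A2, b, M=M, rtol=min(tol * 1e-2, 1e-10), atol=0.0,
                             restart=150, maxiter=maxiter, callback=cb,
                             callback_type="pr_norm")
        iterations = counter["n"]
        if info != 0:
            res = np.linalg.norm(A2 @ y - b) / max(np.linalg.norm(b), 1e-300)
            raise RuntimeError(f"GMRES did not converge (info={info}, "
                               f"relative residual {res:.3e})")
    else:
        raise ValueError(f"unknown method {method!r}")
    x = Dc @ y
    resid = np.linalg.norm(A @ x - d) / max(np.linalg.norm(d), 1e-300)
    if resid > max(tol, 1e-8) * 100:
        raise RuntimeError(f"linear solve failed: relative residual {resid:.3e}")

    dom = system.domain
    n = system.n_masked
    p_a = np.full(dom.grid.shape, np.nan).reshape(-1)
    p_v = np.full(dom.grid.shape, np.nan).reshape(-1)
    p_a[system.mask_flat] = x[:n]
    p_v[system.mask_flat] = x[n:2 * n]
    p_a = p_a.reshape(dom.grid.shape)
    p_v = p_v.reshape(dom.grid.shape)

    nets = {"a": system.arterial, "v": system.venous}
    node_pressures: dict[str, dict[int, float]] = {}
    terminal_flows: dict[str, dict[int, float]] = {}
    root_flows: dict[str, dict[int, float]] = {}
    for comp in "av":
        net = nets[comp]
        off = system.node_offset[comp]
        order = system.node_order[comp]
        np_map = {nid: float(x[off + i]) for i, nid in enumerate(order)}
        node_pressures[comp] = np_map
        for nid, p in np_map.items():
            net.nodes[nid].pressure = p
        for e in net.edges:
            e.flow = e.conductance(dom.mu) * (np_map[e.j] - np_map[e.k])
        qoff = system.q_offset[comp]
        terminal_flows[comp] = {nid: float(x[qoff + i])
                                for i, nid in enumerate(system.q_order[comp])}
        rf = {}
        for nid in net.root_terminals:
            (ei,) = net.incident_edges(nid)
            e = net.edges[ei]
            j = e.k if e.j == nid else e.j
            # flow entering the network through the root (positive = inflow)
            rf[nid] = e.conductance(dom.mu) * (np_map[nid] - np_map[j])
        root_flows[comp] = rf

    return PressureSolution(p_a, p_v, node_pressures, terminal_flows, root_flows,
                            float(resid), iterations, system)


def solve_coupled_flow(domain: TissueDomain, arterial: VesselNetwork,
                       venous: VesselNetwork, *, epsilon_mm: float,
                       gamma_a: float, gamma_v: float,
                       p_a0: float, p_v0: float,
                       method: str = "direct", tol: float = 1e-6,
                       kernels_a=None, kernels_v=None) -> PressureSolution:
    """Convenience front end: build kernels, assemble, solve."""
    if kernels_a is None:
        kernels_a = build_kernels(arterial, domain, epsilon_mm)
    if kernels_v is None:
        kernels_v = build_kernels(venous, domain, epsilon_mm)
    system = assemble_coupled_system(domain, arterial, venous, kernels_a,
                                     kernels_v, gamma_a, gamma_v, p_a0, p_v0)
    return solve_pressure(system, method=method, tol=tol)
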