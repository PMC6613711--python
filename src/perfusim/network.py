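"""Vascular networks as undirected graphs of nodes and tubular edges.

Flow through each edge obeys the Hagen-Poiseuille law: the conductance of a
straight tube of radius R and length L carrying a laminar Newtonian flow is
``kappa = pi R^4 / (8 mu L)`` and the flow is ``q = kappa * (p_j - p_k)``.

Degree-1 nodes are *terminals*.  A terminal sitting on the organ boundary
(where the vessel crosses into the tissue) is a *root terminal* and carries a
pressure (Dirichlet) boundary condition; a terminal inside the organ is an
*interior terminal* and exchanges fluid with the porous tissue.  Nodes of
degree >= 2 are *interior* junctions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .grid import MM, TissueDomain

INTERIOR = "interior"
TERMINAL = "terminal"
ROOT_TERMINAL = "root_terminal"
NODE_CLASSES = (INTERIOR, TERMINAL, ROOT_TERMINAL)


def edge_conductance(radius_mm: float, length_mm: float, mu: float) -> float:
    """Hagen-Poiseuille conductance ``pi R^4 / (8 mu L)`` [m^3 Pa^-1 s^-1].

    Radius and length in mm, viscosity in Pa s.
    """
    if radius_mm <= 0 or length_mm <= 0 or mu <= 0:
        raise ValueError("radius, length and viscosity must be positive")
    R = radius_mm * MM
    L = length_mm * MM
    return float(np.pi * R**4 / (8.0 * mu * L))


@dataclass
class VesselNode:
    id: int
    position: np.ndarray  # [mm]
    node_class: str = INTERIOR
    volume_m3: float = 0.0  # filled by compute_node_volumes
    pressure: float = np.nan  # [Pa], filled by the flow solver

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.node_class not in NODE_CLASSES:
            raise ValueError(f"unknown node class {self.node_class!r}")


@dataclass
class VesselEdge:
    j: int
    k: int
    length_mm: float
    radius_mm: float
    medial_axis: np.ndarray = field(default_factory=lambda: np.zeros((0, 3), int))
    flow: float = np.nan  # [m^3 s^-1], positive j -> k, filled by the solver

    def __post_init__(self):
        if self.j == self.k:
            raise ValueError("self-loop edge")
        if self.length_mm <= 0 or self.radius_mm <= 0:
            raise ValueError("edge length and radius must be positive")
        self.medial_axis = np.asarray(self.medial_axis, dtype=int).reshape(-1, 3)

    def conductance(self, mu: float) -> float:
        return edge_conductance(self.radius_mm, self.length_mm, mu)

    def volume_m3(self) -> float:
        """Tube volume pi R^2 L (used when no vessel mask is available)."""
        return float(np.pi * (self.radius_mm * MM) ** 2 * (self.length_mm * MM))


class VesselNetwork:
    """Undirected vascular graph for one compartment ('a' or 'v')."""

    def __init__(self, compartment: str = "a"):
        if compartment not in ("a", "v"):
            raise ValueError("compartment must be 'a' or 'v'")
        self.compartment = compartment
        self.nodes: dict[int, VesselNode] = {}
        self.edges: list[VesselEdge] = []
        self._adj: dict[int, list[int]] = {}  # node id -> list of edge indices

    # -- construction ------------------------------------------------------

    def add_node(self, position, node_class: str = INTERIOR, node_id: int | None = None) -> int:
        nid = max(self.nodes, default=-1) + 1 if node_id is None else int(node_id)
        if nid in self.nodes:
            raise ValueError(f"duplicate node id {nid}")
        self.nodes[nid] = VesselNode(nid, position, node_class)
        self._adj[nid] = []
        return nid

    def add_edge(self, j: int, k: int, length_mm: float, radius_mm: float,
                 medial_axis=None) -> int:
        if j not in self.nodes or k not in self.nodes:
            raise KeyError("edge endpoints must reference existing nodes")
        e = VesselEdge(j, k, length_mm, radius_mm,
                       medial_axis if medial_axis is not None else np.zeros((0, 3), int))
        self.edges.append(e)
        idx = len(self.edges) - 1
        self._adj[j].append(idx)
        self._adj[k].append(idx)
        return idx

    # -- queries -----------------------------------------------------------

    def degree(self, node_id: int) -> int:
        return len(self._adj[node_id])

    def incident_edges(self, node_id: int) -> list[int]:
        return list(self._adj[node_id])

    def neighbors(self, node_id: int) -> list[int]:
        out = []
        for ei in self._adj[node_id]:
            e = self.edges[ei]
            out.append(e.k if e.j == node_id else e.j)
        return out

    def nodes_of_class(self, node_class: str) -> list[int]:
        return [i for i, n in self.nodes.items() if n.node_class == node_class]

    @property
    def terminals(self) -> list[int]:
        """Interior terminals (degree-1 nodes inside the organ)."""
        return self.nodes_of_class(TERMINAL)

    @property
    def root_terminals(self) -> list[int]:
        return self.nodes_of_class(ROOT_TERMINAL)

    def is_connected(self) -> bool:
        if not self.nodes:
            return False
        seen = set()
        stack = [next(iter(self.nodes))]
        while stack:
            n = stack.pop()
            if n in seen:
                continue
            seen.add(n)
            stack.extend(m for m in self.neighbors(n) if m not in seen)
        return len(seen) == len(self.nodes)

    def validate(self):
        if not self.is_connected():
            raise ValueError("vessel network is not connected")
        for nid in self.nodes:
            n = self.nodes[nid]
            if n.node_class in (TERMINAL, ROOT_TERMINAL) and self.degree(nid) != 1:
                raise ValueError(f"terminal node {nid} has degree {self.degree(nid)}")

    # -- node classification ----------------------------------------------

    def classify_nodes(self, domain: TissueDomain, use_hull: bool = True,
                       tol_mm: float | None = None) -> "VesselNetwork":
        """Assign node classes by degree and position.

        Degree-1 nodes within one voxel diagonal of the organ (convex-hull)
        boundary become root terminals; other degree-1 nodes become interior
        terminals; degree->=2 nodes are interior junctions.  Discrete masks
        never meet a continuous boundary exactly, hence the one-diagonal
        tolerance.
        """
        if not self.nodes:
            raise ValueError("empty network")
        self_connected = self.is_connected()
        if not self_connected:
            raise ValueError("vessel network is not connected")
        deg1 = [i for i in self.nodes if self.degree(i) == 1]
        if not deg1:
            raise ValueError("no terminals: network has no degree-1 nodes")
        tol = domain.grid.diagonal_mm if tol_mm is None else tol_mm
        positions = np.array([self.nodes[i].position for i in deg1])
        dists = domain.distance_to_boundary_mm(positions, use_hull=use_hull)
        n_root = 0
        for nid in self.nodes:
            if self.degree(nid) >= 2:
                self.nodes[nid].node_class = INTERIOR
        for nid, d in zip(deg1, dists):
            if d <= tol:
                self.nodes[nid].node_class = ROOT_TERMINAL
                n_root += 1
            else:
                self.nodes[nid].node_class = TERMINAL
        if n_root == 0:
            raise ValueError("no pressurized inlet/outlet: no degree-1 node lies "
                             "on the tissue boundary")
        return self

    # -- node volumes ------------------------------------------------------

    def compute_node_volumes(self, vessel_mask: np.ndarray | None, domain: TissueDomain):
        """Assign junction-region volumes |N_k| to nodes.

        With a vessel mask: every mask voxel is assigned to its nearest
        feature among node centres and edge-interior medial-axis points; the
        node volume is the volume of the voxels it wins, floored at one voxel.
        Without a mask: a sphere of the mean incident radius.
        """
        grid = domain.grid
        if vessel_mask is None or not np.asarray(vessel_mask).any():
            for nid, node in self.nodes.items():
                radii = [self.edges[ei].radius_mm for ei in self._adj[nid]]
                r = float(np.mean(radii)) if radii else grid.voxel_size[0]
                node.volume_m3 = max(4.0 / 3.0 * np.pi * (r * MM) ** 3,
                                     grid.voxel_volume_m3)
            return
        from scipy.spatial import cKDTree

        pts = []
        owner = []  # node id or -1 for edge interior
        for nid, node in self.nodes.items():
            pts.append(node.position)
            owner.append(nid)
        for e in self.edges:
            if len(e.medial_axis) > 2:
                interior = grid.index_to_physical(e.medial_axis[1:-1])
                pts.extend(interior)
                owner.extend([-1] * len(interior))
        tree = cKDTree(np.asarray(pts, dtype=float))
        vox = np.argwhere(np.asarray(vessel_mask, dtype=bool))
        _, nearest = tree.query(grid.index_to_physical(vox))
        owner = np.asarray(owner)
        counts = {nid: 0 for nid in self.nodes}
        for o in owner[nearest]:
            if o >= 0:
                counts[int(o)] += 1
        for nid, node in self.nodes.items():
            node.volume_m3 = max(counts[nid], 1) * grid.voxel_volume_m3

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "compartment": self.compartment,
            "nodes": [
                {
                    "id": int(n.id),
                    "position_mm": [float(x) for x in n.position],
                    "class": n.node_class,
                    "volume_m3": float(n.volume_m3),
                    "pressure_pa": None if np.isnan(n.pressure) else float(n.pressure),
                }
                for n in self.nodes.values()
            ],
            "edges": [
                {
                    "j": int(e.j),
                    "k": int(e.k),
                    "length_mm": float(e.length_mm),
                    "radius_mm": float(e.radius_mm),
                    "medial_axis": e.medial_axis.tolist(),
                    "flow_m3_s": None if np.isnan(e.flow) else float(e.flow),
                }
                for e in self.edges
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VesselNetwork":
        net = cls(d.get("compartment", "a"))
        for nd in d["nodes"]:
            net.add_node(nd["position_mm"], nd.get("class", INTERIOR), node_id=nd["id"])
            net.nodes[nd["id"]].volume_m3 = nd.get("volume_m3", 0.0) or 0.0
            if nd.get("pressure_pa") is not None:
                net.nodes[nd["id"]].pressure = nd["pressure_pa"]
        for ed in d["edges"]:
            ei = net.add_edge(ed["j"], ed["k"], ed["length_mm"], ed["radius_mm"],
                              np.asarray(ed.get("medial_axis", []), int).reshape(-1, 3))
            if ed.get("flow_m3_s") is not None:
                net.edges[ei].flow = ed["flow_m3_s"]
        return net

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_json(cls, path) -> "VesselNetwork":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_networkx(self):
        """Export to a networkx graph (inspection / GraphML)."""
        import networkx as nx

        g = nx.Graph(compartment=self.compartment)
        for n in self.nodes.values():
            g.add_node(n.id, x=float(n.position[0]), y=float(n.position[1]),
                       z=float(n.position[2]), node_class=n.node_class)
        for e in self.edges:
            g.add_edge(e.j, e.k, length_mm=float(e.length_mm),
                       radius_mm=float(e.radius_mm))
        return g
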