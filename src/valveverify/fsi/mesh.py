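"""Structured triangular meshes for the 2D channel-with-leaflet geometry.

The fluid domain is a rectangular channel; the leaflet (flap) is a
grid-aligned rectangle attached to the bottom wall.  Fluid and solid meshes
are cut from the same structured grid so interface nodes match one-to-one.

Boundary tags follow the valve-simulation convention:
fluid: ``inflow`` (x = 0), ``outflow`` (x = L), ``inside`` (channel walls),
``leaflets`` (fluid-structure interface); solid: ``outside`` (clamped base),
``interface`` (wetted surface).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Mesh2D:
    nodes: np.ndarray  # (n, 2) m
    triangles: np.ndarray  # (m, 3) int, counter-clockwise
    node_tags: dict = field(default_factory=dict)  # tag -> node index array
    boundary_edges: dict = field(default_factory=dict)  # tag -> (k, 2) node pairs

    def __post_init__(self):
        if np.any(self.areas() <= 0):
            raise ValueError("mesh has non-positive triangle areas")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def areas(self, nodes: np.ndarray | None = None) -> np.ndarray:
        x = (self.nodes if nodes is None else nodes)[self.triangles]
        return 0.5 * ((x[:, 1, 0] - x[:, 0, 0]) * (x[:, 2, 1] - x[:, 0, 1])
                      - (x[:, 2, 0] - x[:, 0, 0]) * (x[:, 1, 1] - x[:, 0, 1]))

    def min_edge(self) -> float:
        x = self.nodes[self.triangles]
        e = np.concatenate([x[:, 1] - x[:, 0], x[:, 2] - x[:, 1], x[:, 0] - x[:, 2]])
        return float(np.linalg.norm(e, axis=1).min())

    def char_length(self) -> float:
        """Mean element size sqrt(2*area)."""
        return float(np.sqrt(2.0 * self.areas().mean()))


def _structured_grid(length: float, height: float, nx: int, ny: int):
    xs = np.linspace(0.0, length, nx + 1)
    ys = np.linspace(0.0, height, ny + 1)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel()])

    def nid(i, j):
        return i * (ny + 1) + j

    return xs, ys, nodes, nid


def _cell_triangles(i, j, nid):
    """Two CCW triangles of cell (i, j); diagonal alternates by parity."""
    a, b, c, d = nid(i, j), nid(i + 1, j), nid(i + 1, j + 1), nid(i, j + 1)
    if (i + j) % 2 == 0:
        return [(a, b, c), (a, c, d)]
    return [(a, b, d), (b, c, d)]


def rect_mesh(length: float, height: float, nx: int, ny: int) -> Mesh2D:
    """Structured triangulated rectangle with alternating diagonals."""
    _, _, nodes, nid = _structured_grid(length, height, nx, ny)
    tris = []
    for i in range(nx):
        for j in range(ny):
            tris.extend(_cell_triangles(i, j, nid))
    mesh = Mesh2D(nodes, np.array(tris, dtype=int))
    x, y = nodes[:, 0], nodes[:, 1]
    tol = 1e-12 * max(length, height)
    mesh.node_tags = {
        "inflow": np.where(np.abs(x) < tol)[0],
        "outflow": np.where(np.abs(x - length) < tol)[0],
        "inside": np.where((np.abs(y) < tol) | (np.abs(y - height) < tol))[0],
        "leaflets": np.array([], dtype=int),
    }
    mesh.boundary_edges = _tag_boundary_edges(mesh)
    return mesh


def _boundary_edge_list(triangles: np.ndarray) -> np.ndarray:
    """Edges that belong to exactly one triangle, oriented as in the triangle."""
    edges = {}
    for tri in triangles:
        for k in range(3):
            e = (int(tri[k]), int(tri[(k + 1) % 3]))
            key = (min(e), max(e))
            if key in edges:
                edges.pop(key)
            else:
                edges[key] = e
    return np.array(list(edges.values()), dtype=int).reshape(-1, 2)


def _tag_boundary_edges(mesh: Mesh2D) -> dict:
    """Assign each boundary edge to exactly one tag.

    Priority: an edge whose both endpoints are interface (leaflet) nodes is
    a leaflet edge; otherwise inflow/outflow/wall by endpoint tags.
    """
    bedges = _boundary_edge_list(mesh.triangles)
    tags = {t: [] for t in ("inflow", "outflow", "inside", "leaflets")}
    sets = {t: set(mesh.node_tags.get(t, [])) for t in tags}
    for e in bedges:
        a, b = int(e[0]), int(e[1])
        in_leaf = (a in sets["leaflets"]) + (b in sets["leaflets"])
        if in_leaf == 2:
            tags["leaflets"].append((a, b))
        elif in_leaf == 1 and (a in sets["inside"] or b in sets["inside"]):
            # flap-surface edge meeting the wall at the clamped corner
            tags["leaflets"].append((a, b))
        elif a in sets["inflow"] and b in sets["inflow"]:
            tags["inflow"].append((a, b))
        elif a in sets["outflow"] and b in sets["outflow"]:
            tags["outflow"].append((a, b))
        else:
            tags["inside"].append((a, b))
    return {t: np.array(v, dtype=int).reshape(-1, 2) for t, v in tags.items()}


@dataclass
class ChannelGeometry:
    """2D channel with one grid-aligned flexible flap on the bottom wall.

    All lengths in metres.  Flap position/size are snapped to the grid so
    fluid and solid meshes share interface nodes exactly.
    """

    length: float = 0.08
    height: float = 0.02
    nx: int = 32
    ny: int = 10
    flap_x: float = 0.03  # left edge of flap at the wall
    flap_width: float = 0.005
    flap_height: float = 0.012
    flap_lean_cells: int = 0  # columns the flap shifts downstream per cell row

    def cell_size(self) -> tuple[float, float]:
        return self.length / self.nx, self.height / self.ny


def channel_with_flap(geom: ChannelGeometry) -> tuple[Mesh2D, Mesh2D, np.ndarray, np.ndarray]:
    """Fluid mesh with a flap notch plus the matching solid flap mesh.

    Returns (fluid_mesh, solid_mesh, fluid_interface_nodes,
    solid_interface_nodes); the two interface index arrays are aligned
    one-to-one (identical coordinates).
    """
    dx, dy = geom.cell_size()
    i0 = int(round(geom.flap_x / dx))
    iw = max(int(round(geom.flap_width / dx)), 1)
    jh = max(int(round(geom.flap_height / dy)), 1)
    if jh >= geom.ny:
        raise ValueError("flap must leave a gap below the opposite wall")
    lean = geom.flap_lean_cells
    if lean > 0 and iw < lean + 1:
        raise ValueError("a leaning flap needs flap_width >= (lean+1) cells so "
                         "successive rows stay edge-connected")
    _, _, nodes, nid = _structured_grid(geom.length, geom.height, geom.nx, geom.ny)

    flap_cells = {(i0 + lean * j + di, j) for j in range(jh) for di in range(iw)}
    if max(i for i, _ in flap_cells) >= geom.nx:
        raise ValueError("leaning flap exceeds the channel length")
    fl_tris, so_tris = [], []
    for i in range(geom.nx):
        for j in range(geom.ny):
            tris = _cell_triangles(i, j, nid)
            (so_tris if (i, j) in flap_cells else fl_tris).extend(tris)

    fluid = _submesh(nodes, np.array(fl_tris, dtype=int))
    solid = _submesh(nodes, np.array(so_tris, dtype=int))

    # interface: solid boundary nodes not on the clamped base (y = 0)
    so_bedges = _boundary_edge_list(solid.triangles)
    so_bnodes = np.unique(so_bedges)
    base = so_bnodes[np.abs(solid.nodes[so_bnodes, 1]) < 1e-12]
    iface_solid = np.setdiff1d(so_bnodes, base)
    solid.node_tags = {"outside": base, "interface": iface_solid}
    solid.boundary_edges = {}

    # match fluid nodes to solid interface nodes by coordinates
    iface_coords = solid.nodes[iface_solid]
    iface_fluid = _match_nodes(fluid.nodes, iface_coords)

    x, y = fluid.nodes[:, 0], fluid.nodes[:, 1]
    tol = 1e-12
    leaf = set(iface_fluid.tolist())
    fl_bnodes = np.unique(_boundary_edge_list(fluid.triangles))
    inflow = fl_bnodes[np.abs(x[fl_bnodes]) < tol]
    outflow = fl_bnodes[np.abs(x[fl_bnodes] - geom.length) < tol]
    walls = np.array([n for n in fl_bnodes
                      if (abs(y[n]) < tol or abs(y[n] - geom.height) < tol)
                      and n not in set(inflow) | set(outflow) | leaf], dtype=int)
    fluid.node_tags = {"inflow": inflow, "outflow": outflow, "inside": walls,
                       "leaflets": iface_fluid}
    fluid.boundary_edges = _tag_boundary_edges(fluid)
    return fluid, solid, iface_fluid, iface_solid


def _submesh(nodes: np.ndarray, triangles: np.ndarray) -> Mesh2D:
    used = np.unique(triangles)
    remap = -np.ones(len(nodes), dtype=int)
    remap[used] = np.arange(len(used))
    return Mesh2D(nodes[used].copy(), remap[triangles])


def _match_nodes(nodes: np.ndarray, coords: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    out = np.empty(len(coords), dtype=int)
    for k, c in enumerate(coords):
        d = np.linalg.norm(nodes - c, axis=1)
        j = int(np.argmin(d))
        if d[j] > tol:
            raise ValueError("interface discretisations do not match one-to-one")
        out[k] = j
    return out
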