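"""Linear (P1) triangular finite-element operators.

Vectorised assembly of the scalar operators the fractional-step solver
needs: stiffness, lumped/consistent mass, weak gradient, convection, and
boundary flux integrals.  Velocity components and pressure share the same
P1 space; the discrete projection uses the weak-gradient matrix G and its
transpose as (minus the) divergence, so the corrected velocity is exactly
discretely divergence-free when the pressure operator is G^T M_l^{-1} G.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp


def p1_gradients(nodes: np.ndarray, triangles: np.ndarray):
    """Per-element area and basis-function gradients.

    Returns (areas (m,), b (m, 3, 2)) with b[e, i] = grad of basis i on
    element e (constant per element).
    """
    x = nodes[triangles]
    v1 = x[:, 1] - x[:, 0]
    v2 = x[:, 2] - x[:, 0]
    det = v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0]
    areas = 0.5 * det
    b = np.empty((len(triangles), 3, 2))
    b[:, 1, 0] = v2[:, 1] / det
    b[:, 1, 1] = -v2[:, 0] / det
    b[:, 2, 0] = -v1[:, 1] / det
    b[:, 2, 1] = v1[:, 0] / det
    b[:, 0] = -b[:, 1] - b[:, 2]
    return areas, b


def _assemble(rows, cols, vals, n):
    return sp.csr_matrix((np.asarray(vals).ravel(),
                          (np.asarray(rows).ravel(), np.asarray(cols).ravel())),
                         shape=(n, n))


@dataclass
class P1Operators:
    """Assembled scalar operators on one mesh configuration."""

    K: sp.csr_matrix  # stiffness  int grad phi_i . grad phi_j
    M_lumped: np.ndarray  # (n,) lumped mass
    Gx: sp.csr_matrix  # int phi_i d_x phi_j
    Gy: sp.csr_matrix
    areas: np.ndarray
    grads: np.ndarray  # (m, 3, 2)
    n: int

    def convection(self, triangles: np.ndarray, w: np.ndarray) -> sp.csr_matrix:
        """C[i,j] = int phi_i (w . grad phi_j), w element-averaged."""
        we = w[triangles].mean(axis=1)  # (m, 2)
        wb = np.einsum("ek,ejk->ej", we, self.grads)  # (m, 3)
        vals = (self.areas / 3.0)[:, None, None] * wb[:, None, :] * np.ones((1, 3, 1))
        rows = np.repeat(triangles[:, :, None], 3, axis=2)
        cols = np.repeat(triangles[:, None, :], 3, axis=1)
        return _assemble(rows, cols, vals, self.n)


def build_operators(nodes: np.ndarray, triangles: np.ndarray,
                    diffusivity: np.ndarray | float = 1.0) -> P1Operators:
    n = len(nodes)
    areas, b = p1_gradients(nodes, triangles)
    if np.any(areas <= 0):
        raise ValueError("non-positive element area during assembly")
    kappa = np.broadcast_to(np.asarray(diffusivity, dtype=float), areas.shape)

    rows = np.repeat(triangles[:, :, None], 3, axis=2)
    cols = np.repeat(triangles[:, None, :], 3, axis=1)

    k_vals = (kappa * areas)[:, None, None] * np.einsum("eik,ejk->eij", b, b)
    K = _assemble(rows, cols, k_vals, n)

    gx_vals = (areas / 3.0)[:, None, None] * np.broadcast_to(b[:, None, :, 0], (len(areas), 3, 3))
    gy_vals = (areas / 3.0)[:, None, None] * np.broadcast_to(b[:, None, :, 1], (len(areas), 3, 3))
    Gx = _assemble(rows, cols, gx_vals, n)
    Gy = _assemble(rows, cols, gy_vals, n)

    M_lumped = np.zeros(n)
    np.add.at(M_lumped, triangles.ravel(), np.repeat(areas / 3.0, 3))
    return P1Operators(K=K, M_lumped=M_lumped, Gx=Gx, Gy=Gy, areas=areas, grads=b, n=n)


def element_velocity_gradient(ops: P1Operators, triangles: np.ndarray,
                              u: np.ndarray) -> np.ndarray:
    """(m, 2, 2) velocity gradient per element, [a, k] = d u_a / d x_k."""
    return np.einsum("eja,ejk->eak", u[triangles], ops.grads)


def _edge_owner_map(triangles: np.ndarray) -> dict:
    """(sorted edge) -> (element index, opposite local vertex) for boundary lookup."""
    owners = {}
    for ei, tri in enumerate(triangles):
        for k in range(3):
            a, b = int(tri[k]), int(tri[(k + 1) % 3])
            owners[(min(a, b), max(a, b))] = (ei, int(tri[(k + 2) % 3]))
    return owners


def boundary_normals(nodes: np.ndarray, triangles: np.ndarray, edges: np.ndarray):
    """Outward unit normals and lengths of boundary edges.

    Orientation is taken from the owning triangle: the normal points away
    from the triangle's opposite vertex, i.e. out of the fluid domain —
    robust for non-convex domains (channel with a leaflet notch).
    """
    owners = _edge_owner_map(triangles)
    p0, p1 = nodes[edges[:, 0]], nodes[edges[:, 1]]
    tang = p1 - p0
    lengths = np.linalg.norm(tang, axis=1)
    nrm = np.column_stack([tang[:, 1], -tang[:, 0]]) / lengths[:, None]
    mid = 0.5 * (p0 + p1)
    opp = np.array([owners[(min(int(a), int(b)), max(int(a), int(b)))][1] for a, b in edges])
    flip = np.einsum("ek,ek->e", nrm, nodes[opp] - mid) > 0
    nrm[flip] *= -1.0
    return nrm, lengths


def boundary_edge_elements(triangles: np.ndarray, edges: np.ndarray) -> np.ndarray:
    owners = _edge_owner_map(triangles)
    return np.array([owners[(min(int(a), int(b)), max(int(a), int(b)))][0] for a, b in edges],
                    dtype=int)


def boundary_flux(nodes: np.ndarray, triangles: np.ndarray, edges: np.ndarray,
                  u: np.ndarray) -> float:
    """Integral of u . n_out over the tagged boundary (trapezoid per edge)."""
    nrm, lengths = boundary_normals(nodes, triangles, edges)
    un = 0.5 * (np.einsum("ek,ek->e", u[edges[:, 0]], nrm)
                + np.einsum("ek,ek->e", u[edges[:, 1]], nrm))
    return float(np.sum(un * lengths))


def boundary_flux_vector(nodes: np.ndarray, triangles: np.ndarray, edges: np.ndarray,
                         u_bc: np.ndarray) -> np.ndarray:
    """Per-pressure-node weak boundary flux int phi_i (u_bc . n_out) ds.

    This is the boundary term of the integrated-by-parts divergence; the
    projection must balance the interior divergence against it wherever the
    boundary moves with a prescribed velocity.
    """
    f = np.zeros(len(nodes))
    if len(edges) == 0:
        return f
    nrm, lengths = boundary_normals(nodes, triangles, edges)
    una = np.einsum("ek,ek->e", u_bc[edges[:, 0]], nrm)
    unb = np.einsum("ek,ek->e", u_bc[edges[:, 1]], nrm)
    # int over edge of phi_a (u.n) with linear u.n: l (2 una + unb) / 6
    np.add.at(f, edges[:, 0], lengths * (2.0 * una + unb) / 6.0)
    np.add.at(f, edges[:, 1], lengths * (una + 2.0 * unb) / 6.0)
    return f
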