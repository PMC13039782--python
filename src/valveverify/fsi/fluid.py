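"""Fractional-step incompressible flow solver with ALE convection.

Three sub-steps per time step on P1 elements (BDF2 in time):

1. predictor: (I - dt nu_eff Lap + dt (u_L - u_m) . grad) u* =
   2 u^n - 1/2 u^{n-1} - (dt/rho) grad p^n, with u_L = 2 u^n - u^{n-1};
2. pressure Poisson for p^{n+1} - p^n from the divergence of u*, iterated
   with the velocity for up to 10 sub-iterations;
3. correction (3/2) u^{n+1} = u* + (dt/rho) grad(p^n - p^{n+1}).

Velocity Dirichlet data lives on the walls (zero) and the leaflet
interface (solid velocity); pressure Dirichlet data is the transvalvular
pressure difference at the inflow and zero at the outflow, with zero
normal pressure gradient elsewhere.

The pressure operator is the discrete projection operator
G^T diag(M)^{-1} G, blended with the consistent P1 Laplacian to suppress
the equal-order chequerboard pressure modes; the velocity/pressure
sub-iterations then drive the discrete divergence to the projection
tolerance despite the blending.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .assembly import P1Operators, boundary_flux_vector, build_operators
from .mesh import Mesh2D


@dataclass
class FluidBC:
    """Dirichlet data for one time step.

    velocity maps node-tag -> (k, 2) array or a single 2-vector; pressure
    maps node-tag -> scalar.
    """

    velocity: dict = field(default_factory=dict)
    pressure: dict = field(default_factory=dict)

    def predictor_scaled(self) -> "FluidBC":
        """Velocity data scaled by 3/2 for the predictor/projection stage.

        The correction multiplies by 2/3 (BDF2), so imposing 1.5x the
        physical boundary velocity on u* makes the corrected velocity hit
        the physical value exactly and keeps the interface contribution to
        the discrete divergence consistent.
        """
        scaled = {tag: 1.5 * np.asarray(v, dtype=float) for tag, v in self.velocity.items()}
        return FluidBC(velocity=scaled, pressure=dict(self.pressure))


@dataclass
class FluidState:
    u: np.ndarray  # (n, 2) m/s at t^n
    u_prev: np.ndarray  # (n, 2) at t^{n-1}
    p: np.ndarray  # (n,) Pa
    u_mesh: np.ndarray  # (n, 2) ALE mesh velocity
    rho: float = 1000.0
    mu: float = 1.0e-3
    nu_t: np.ndarray | float = 0.0  # eddy viscosity per element

    @property
    def nu(self) -> float:
        return self.mu / self.rho

    @classmethod
    def zeros(cls, n: int, rho: float = 1000.0, mu: float = 1.0e-3) -> "FluidState":
        return cls(np.zeros((n, 2)), np.zeros((n, 2)), np.zeros(n), np.zeros((n, 2)),
                   rho=rho, mu=mu)


def _dirichlet_velocity(mesh: Mesh2D, bc: FluidBC):
    """(node indices, (k,2) values) of all velocity Dirichlet data."""
    idx, vals = [], []
    for tag, v in bc.velocity.items():
        nodes = mesh.node_tags.get(tag, np.array([], dtype=int))
        if len(nodes) == 0:
            continue
        v = np.asarray(v, dtype=float)
        if v.ndim == 1:
            v = np.tile(v, (len(nodes), 1))
        idx.append(nodes)
        vals.append(v)
    if not idx:
        return np.array([], dtype=int), np.zeros((0, 2))
    idx = np.concatenate(idx)
    vals = np.concatenate(vals)
    _, first = np.unique(idx, return_index=True)
    return idx[first], vals[first]


def _apply_dirichlet(A: sp.csr_matrix, rhs: np.ndarray, idx: np.ndarray, vals: np.ndarray):
    """Row/column elimination of Dirichlet dofs (symmetrically)."""
    if len(idx) == 0:
        return A.tocsr(), rhs
    n = A.shape[0]
    x0 = np.zeros(n)
    x0[idx] = vals
    rhs = rhs - A @ x0
    mask = np.ones(n, dtype=bool)
    mask[idx] = False
    d = sp.diags(mask.astype(float))
    A2 = (d @ A @ d).tolil()
    A2[idx, idx] = 1.0
    rhs[idx] = vals
    return A2.tocsr(), rhs


def predictor_velocity(mesh: Mesh2D, ops: P1Operators, state: FluidState, dt: float,
                       bc: FluidBC, forcing: np.ndarray | None = None) -> np.ndarray:
    """Solve the BDF2 predictor for u*, component by component."""
    u_L = 2.0 * state.u - state.u_prev
    w = u_L - state.u_mesh
    nu_eff = state.nu + np.asarray(state.nu_t)
    K = build_operators(mesh.nodes, mesh.triangles, diffusivity=nu_eff).K \
        if np.ndim(state.nu_t) > 0 else state.nu * ops.K
    C = ops.convection(mesh.triangles, w)
    M = sp.diags(ops.M_lumped)
    # u* carries the 3/2 BDF2 scaling (the correction divides by 3/2), so the
    # implicit viscous/convective terms act on (2/3) u* = u^{n+1}
    A = M + (2.0 / 3.0) * dt * (K + C)

    grad_p = np.column_stack([ops.Gx @ state.p, ops.Gy @ state.p])
    rhs_common = ops.M_lumped[:, None] * (2.0 * state.u - 0.5 * state.u_prev) \
        - (dt / state.rho) * grad_p
    if forcing is not None:
        rhs_common = rhs_common + dt * ops.M_lumped[:, None] * forcing

    idx, vals = _dirichlet_velocity(mesh, bc)
    if len(idx) == 0:
        raise ValueError("no velocity Dirichlet data; predictor system is singular")
    u_star = np.empty_like(state.u)
    Als, _ = _apply_dirichlet(A, rhs_common[:, 0].copy(), idx, vals[:, 0])
    lu = spla.splu(Als.tocsc())
    for k in range(2):
        _, rhs_k = _apply_dirichlet(A, rhs_common[:, k].copy(), idx, vals[:, k])
        u_star[:, k] = lu.solve(rhs_k)
    return u_star


def divergence_residual(ops: P1Operators, u: np.ndarray) -> np.ndarray:
    """Weak divergence G^T u (per pressure node)."""
    return ops.Gx.T @ u[:, 0] + ops.Gy.T @ u[:, 1]


def _pressure_system(mesh: Mesh2D, ops: P1Operators, free_vel: np.ndarray,
                     stab_coeff: float, added_mass_diag: np.ndarray | None):
    Minv = np.where(free_vel, 1.0 / ops.M_lumped, 0.0)
    D = sp.diags(Minv)
    A = ops.Gx.T @ D @ ops.Gx + ops.Gy.T @ D @ ops.Gy
    # rows with (numerically) no divergence control before stabilisation:
    # pressure nodes whose whole velocity patch is Dirichlet
    weak = np.where(A.diagonal() <= 1e-10 * A.diagonal().max())[0]
    if stab_coeff > 0:
        # stabilise with the consistent-Laplacian defect K - A: it vanishes
        # to O(h^2) on smooth pressure modes but is O(1) on the chequerboard
        # modes of the lumped projection operator on equal-order elements
        A = (1.0 - stab_coeff) * A + stab_coeff * ops.K
    if added_mass_diag is not None:
        A = A + sp.diags(added_mass_diag)
    return A.tocsr(), weak


def pressure_poisson(mesh: Mesh2D, ops: P1Operators, u_star: np.ndarray, p_n: np.ndarray,
                     dt: float, state: FluidState, bc: FluidBC,
                     max_subiters: int = 10, tol: float = 1e-10,
                     stab_coeff: float = 0.0,
                     added_mass_diag: np.ndarray | None = None,
                     bc_flux: np.ndarray | None = None) -> np.ndarray:
    """Solve for p^{n+1} such that the corrected velocity is divergence-free.

    Iterates between the pressure increment and the (provisionally
    corrected) velocity for up to ``max_subiters`` passes, stopping when the
    relative discrete divergence drops below ``tol``.  ``bc_flux`` is the
    weak boundary flux of the prescribed (Dirichlet) boundary velocity; the
    interior divergence must balance it where the boundary moves, so it is
    subtracted from the projection residual.
    """
    n = ops.n
    p_idx, p_vals = [], []
    for tag, val in bc.pressure.items():
        nodes = mesh.node_tags.get(tag, np.array([], dtype=int))
        p_idx.append(nodes)
        p_vals.append(np.full(len(nodes), float(val)))
    if not p_idx or sum(len(i) for i in p_idx) == 0:
        raise ValueError("all-Neumann pressure problem: nullspace not fixed")
    p_idx = np.concatenate(p_idx)
    p_vals = np.concatenate(p_vals)

    v_idx, _ = _dirichlet_velocity(mesh, bc)
    free_vel = np.ones(n, dtype=bool)
    free_vel[v_idx] = False

    A, weak = _pressure_system(mesh, ops, free_vel, stab_coeff, added_mass_diag)
    dp_target = p_vals - p_n[p_idx]

    # pressure nodes whose entire velocity patch is Dirichlet (e.g. the
    # corner where a leaflet meets the wall) carry no divergence control;
    # pin their increment to zero instead of leaving a near-null row
    weak = np.setdiff1d(weak, p_idx)
    if len(weak):
        p_idx = np.concatenate([p_idx, weak])
        p_vals = np.concatenate([p_vals, p_n[weak]])
        dp_target = np.concatenate([dp_target, np.zeros(len(weak))])

    flux = np.zeros(n) if bc_flux is None else bc_flux
    lu = None
    p_new = p_n.copy()
    u_work = u_star.copy()
    unorm = max(np.linalg.norm(ops.M_lumped[:, None] * u_star), 1e-30)
    free_p = np.ones(n, dtype=bool)
    free_p[p_idx] = False
    for it in range(max_subiters):
        r = divergence_residual(ops, u_work) - flux
        dp_d = dp_target if it == 0 else np.zeros(len(p_idx))
        Ab, rb = _apply_dirichlet(A, (state.rho / dt) * r, p_idx, dp_d)
        if lu is None:
            lu = spla.splu(Ab.tocsc())
        dp = lu.solve(rb)
        p_new = p_new + dp
        gd = np.column_stack([ops.Gx @ dp, ops.Gy @ dp])
        upd = -(dt / state.rho) * gd / ops.M_lumped[:, None]
        upd[~free_vel] = 0.0
        u_work = u_work + upd
        r = divergence_residual(ops, u_work) - flux
        if np.linalg.norm(r[free_p]) <= tol * unorm:
            break
    return p_new


def correct_velocity(u_star: np.ndarray, p_n: np.ndarray, p_np1: np.ndarray, dt: float,
                     ops: P1Operators, rho: float,
                     dirichlet: tuple | None = None) -> np.ndarray:
    """(3/2) u^{n+1} = u* + (dt/rho) grad(p^n - p^{n+1}), with Dirichlet
    velocity values reimposed afterwards."""
    gd = np.column_stack([ops.Gx @ (p_n - p_np1), ops.Gy @ (p_n - p_np1)])
    u_new = (2.0 / 3.0) * (u_star + (dt / rho) * gd / ops.M_lumped[:, None])
    if dirichlet is not None:
        idx, vals = dirichlet
        u_new[idx] = vals
    return u_new


def fluid_step(mesh: Mesh2D, state: FluidState, dt: float, bc: FluidBC,
               ops: P1Operators | None = None, max_subiters: int = 10,
               stab_coeff: float = 0.0,
               added_mass_diag: np.ndarray | None = None) -> FluidState:
    """One full fractional step; returns the advanced state.

    Note the correction rescales by 2/3 (BDF2); Dirichlet velocity data is
    reimposed exactly after the correction.
    """
    ops = ops or build_operators(mesh.nodes, mesh.triangles)
    bc_star = bc.predictor_scaled()
    u_star = predictor_velocity(mesh, ops, state, dt, bc_star)
    # weak boundary flux of the imposed (predictor-scaled) Dirichlet velocity
    idx_s, vals_s = _dirichlet_velocity(mesh, bc_star)
    bc_flux = None
    if len(idx_s) and np.any(vals_s != 0.0):
        u_bc = np.zeros_like(state.u)
        u_bc[idx_s] = vals_s
        edges = [e for tag, e in mesh.boundary_edges.items() if len(e)]
        if edges:
            bc_flux = boundary_flux_vector(mesh.nodes, mesh.triangles,
                                           np.concatenate(edges), u_bc)
    p_new = pressure_poisson(mesh, ops, u_star, state.p, dt, state, bc_star,
                             max_subiters=max_subiters, stab_coeff=stab_coeff,
                             added_mass_diag=added_mass_diag, bc_flux=bc_flux)
    idx, vals = _dirichlet_velocity(mesh, bc)
    u_new = correct_velocity(u_star, state.p, p_new, dt, ops, state.rho, (idx, vals))
    return FluidState(u=u_new, u_prev=state.u.copy(), p=p_new, u_mesh=state.u_mesh,
                      rho=state.rho, mu=state.mu, nu_t=state.nu_t)
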