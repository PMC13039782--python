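"""Strong partitioned fluid-structure coupling with line search.

Each time step alternates fluid solve -> interface traction transfer ->
implicit solid step -> interface displacement transfer -> ALE mesh update,
inside a fixed-point (Newton-Raphson-style) loop that converges when the
normalised change of the interface displacement between successive
iterations falls below epsilon.  A golden-section line search on the
displacement increment scale s in [0, 1] minimises the out-of-balance
interface force (solid internal reaction minus applied fluid force), which
damps the added-mass feedback at density ratio ~ 1.

Optionally the pressure operator is augmented on interface nodes with a
solid-inertia contribution (the added-mass treatment), which locally
relaxes the incompressibility constraint near the interface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .assembly import P1Operators, build_operators, boundary_normals, element_velocity_gradient
from .fluid import FluidBC, FluidState, fluid_step
from .mesh import Mesh2D
from .solid import NeoHookeanSolid, SolidState, newmark_solid_step


@dataclass
class CouplingConfig:
    dt: float = 2.0e-4  # s
    epsilon: float = 1.0e-4  # normalised interface-displacement convergence
    max_newton_iters: int = 25
    max_pressure_subiters: int = 10
    line_search: bool = True
    line_search_evals: int = 8
    initial_relaxation: float = 0.2  # Aitken start value
    newmark_gamma: float = 0.6
    newmark_beta: float = 0.4
    smagorinsky_constant: float = 0.18
    les: bool = False
    les_filter_width: float = 5.0e-4  # m
    added_mass: bool = False
    stab_coeff: float = 0.15
    min_gap_frac: float = 0.02  # leaflet tip stop, fraction of channel height
    # documented-only: the reference 3D contact parameters (mortar contact,
    # thickness 0.1 mm, stiffness scale 0.005, max penetration 0.06 mm) are
    # out of scope in 2D; closure is limited by the minimum-gap stop instead
    contact_reference: tuple = (1.0e-4, 0.005, 6.0e-5)


def interface_traction_forces(mesh: Mesh2D, ops: P1Operators,
                              state: FluidState) -> np.ndarray:
    """Nodal fluid forces on the leaflet interface (per unit depth).

    Traction t = (-p I + mu (grad u + grad u^T)) n with n pointing from the
    fluid into the solid; edge integrals are lumped to edge endpoints.
    """
    edges = mesh.boundary_edges.get("leaflets", np.zeros((0, 2), dtype=int))
    f = np.zeros((mesh.n_nodes, 2))
    if len(edges) == 0:
        return f
    # fluid-outward normals point into the solid; the solid's outward normal
    # (Cauchy convention for the traction ON the solid) is their negative
    nrm, lengths = boundary_normals(mesh.nodes, mesh.triangles, edges)
    nrm = -nrm
    grad = element_velocity_gradient(ops, mesh.triangles, state.u)
    # map each interface edge to its adjacent fluid element
    edge_elem = _edges_to_elements(mesh.triangles, edges)
    for e, (a, b) in enumerate(edges):
        el = edge_elem[e]
        gu = grad[el]
        tau = state.mu * (gu + gu.T)
        p_edge = 0.5 * (state.p[a] + state.p[b])
        t = (-p_edge * np.eye(2) + tau) @ nrm[e]
        f[a] += 0.5 * lengths[e] * t
        f[b] += 0.5 * lengths[e] * t
    return f


def _edges_to_elements(triangles: np.ndarray, edges: np.ndarray) -> np.ndarray:
    lookup = {}
    for ei, tri in enumerate(triangles):
        for k in range(3):
            key = (min(int(tri[k]), int(tri[(k + 1) % 3])), max(int(tri[k]), int(tri[(k + 1) % 3])))
            lookup[key] = ei
    return np.array([lookup[(min(int(a), int(b)), max(int(a), int(b)))] for a, b in edges])


_ELASTICITY_CACHE = {}


def move_mesh(mesh: Mesh2D, reference_nodes: np.ndarray, interface_nodes: np.ndarray,
              interface_disp: np.ndarray, dt: float,
              E: float = 1.0, nu: float = 0.3) -> tuple[np.ndarray, np.ndarray]:
    """Propagate interface displacement into the fluid interior.

    Solves a (compressible) linear elasticity problem on the reference
    configuration with Dirichlet data: the given displacement on the
    interface, zero on all other boundaries.  Returns (new node positions,
    mesh velocity).  Raises on element inversion (re-meshing is out of
    scope).
    """
    key = id(mesh.triangles)
    if key not in _ELASTICITY_CACHE:
        _ELASTICITY_CACHE.clear()
        _ELASTICITY_CACHE[key] = _linear_elasticity_matrix(reference_nodes, mesh.triangles, E, nu)
    K = _ELASTICITY_CACHE[key]

    n = len(reference_nodes)
    fixed = []
    for tag in ("inflow", "outflow", "inside"):
        fixed.append(mesh.node_tags.get(tag, np.array([], dtype=int)))
    fixed = np.setdiff1d(np.concatenate(fixed), interface_nodes)
    disp = np.zeros((n, 2))
    disp[interface_nodes] = interface_disp

    dir_idx = np.concatenate([interface_nodes, fixed])
    dofs = np.ones(2 * n, dtype=bool)
    dofs[2 * dir_idx] = False
    dofs[2 * dir_idx + 1] = False
    x0 = disp.ravel()
    rhs = -(K @ x0)[dofs]
    sol = spla.spsolve(K[dofs][:, dofs].tocsc(), rhs)
    disp_full = x0.copy()
    disp_full[dofs] = sol
    new_nodes = reference_nodes + disp_full.reshape(-1, 2)

    areas = mesh.areas(new_nodes)
    if np.any(areas <= 0):
        raise RuntimeError("mesh motion inverted a fluid element; aborting (no re-meshing)")
    u_mesh = (new_nodes - mesh.nodes) / dt
    return new_nodes, u_mesh


def _linear_elasticity_matrix(nodes: np.ndarray, triangles: np.ndarray,
                              E: float, nu: float) -> sp.csr_matrix:
    from .assembly import p1_gradients
    areas, b = p1_gradients(nodes, triangles)
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    m = len(triangles)
    Ke = np.zeros((m, 6, 6))
    for i in range(3):
        for j in range(3):
            bi, bj = b[:, i], b[:, j]  # (m,2)
            dot = np.einsum("ek,ek->e", bi, bj)
            for a in range(2):
                for c in range(2):
                    val = (lam * bi[:, a] * bj[:, c]
                           + mu * bi[:, c] * bj[:, a]
                           + (mu * dot if a == c else 0.0))
                    Ke[:, 2 * i + a, 2 * j + c] = areas * val
    dof = (2 * triangles[:, :, None] + np.arange(2)[None, None, :]).reshape(m, 6)
    rows = np.repeat(dof[:, :, None], 6, axis=2)
    cols = np.repeat(dof[:, None, :], 6, axis=1)
    n2 = 2 * len(nodes)
    return sp.csr_matrix((Ke.ravel(), (rows.ravel(), cols.ravel())), shape=(n2, n2))


def _golden_section(fun, lo: float = 0.0, hi: float = 1.0, evals: int = 8) -> float:
    """Minimise a scalar function on [lo, hi] with at most ``evals`` calls."""
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = fun(c), fun(d)
    used = 2
    while used < evals:
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = fun(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = fun(d)
        used += 1
    return c if fc < fd else d


def couple_step(fluid_mesh: Mesh2D, reference_nodes: np.ndarray,
                fluid_state: FluidState, solid: NeoHookeanSolid, solid_state: SolidState,
                iface_fluid: np.ndarray, iface_solid: np.ndarray,
                cfg: CouplingConfig, bc: FluidBC,
                channel_height: float | None = None,
                verbose: bool = False) -> tuple[FluidState, SolidState, int]:
    """Advance the coupled system by one time step.

    ``fluid_mesh.nodes`` holds the current (deformed) configuration;
    ``reference_nodes`` the undeformed one.  Returns the new fluid and
    solid states and the number of coupling iterations used.
    """
    dt = cfg.dt
    nodes_tn = fluid_mesh.nodes.copy()  # configuration at time t^n
    u_tn = solid_state.u.copy()
    u_prev_iter = solid_state.u.copy()
    accepted_solid = solid_state
    new_fluid = fluid_state
    u_mesh = fluid_state.u_mesh

    for it in range(1, cfg.max_newton_iters + 1):
        ops = build_operators(fluid_mesh.nodes, fluid_mesh.triangles)
        nu_t = 0.0
        if cfg.les:
            from .les import smagorinsky_nu_t
            grad = element_velocity_gradient(ops, fluid_mesh.triangles, fluid_state.u)
            nu_t = smagorinsky_nu_t(grad, cfg.smagorinsky_constant, cfg.les_filter_width)

        # leaflet velocity Dirichlet data: the discrete interface velocity of
        # the current iterate (consistent with the ALE mesh velocity, which
        # keeps the interface contribution to the divergence controllable)
        v_iface = (accepted_solid.u[iface_solid] - u_tn[iface_solid]) / dt
        bc_it = FluidBC(velocity={**bc.velocity, "leaflets": v_iface},
                        pressure=dict(bc.pressure))
        am_diag = None
        if cfg.added_mass:
            # interface compliance: moving solid mass m_s under a pressure
            # acting on edge length l changes the local divergence by
            # dt l^2 / m_s * dp; folded into the pressure operator this is
            # rho_f l^2 / m_s on interface rows
            ell = np.zeros(fluid_mesh.n_nodes)
            edges = fluid_mesh.boundary_edges.get("leaflets", np.zeros((0, 2), dtype=int))
            if len(edges):
                p0, p1 = fluid_mesh.nodes[edges[:, 0]], fluid_mesh.nodes[edges[:, 1]]
                L = np.linalg.norm(p1 - p0, axis=1)
                np.add.at(ell, edges[:, 0], 0.5 * L)
                np.add.at(ell, edges[:, 1], 0.5 * L)
            am_diag = np.zeros(fluid_mesh.n_nodes)
            am_diag[iface_fluid] = (fluid_state.rho * ell[iface_fluid] ** 2
                                    / np.maximum(solid.mass[iface_solid], 1e-30))
        st = FluidState(fluid_state.u, fluid_state.u_prev, fluid_state.p,
                        u_mesh, fluid_state.rho, fluid_state.mu, nu_t)
        # with the added-mass compliance active the projection is solved in a
        # single pass, so the interface relaxation is not iterated away
        subiters = 1 if cfg.added_mass else cfg.max_pressure_subiters
        new_fluid = fluid_step(fluid_mesh, st, dt, bc_it, ops=ops,
                               max_subiters=subiters,
                               stab_coeff=cfg.stab_coeff, added_mass_diag=am_diag)

        f_iface_fluid = interface_traction_forces(fluid_mesh, ops, new_fluid)
        f_solid = np.zeros((solid.mesh.n_nodes, 2))
        f_solid[iface_solid] = f_iface_fluid[iface_fluid]

        trial = newmark_solid_step(solid, solid_state, f_solid, dt,
                                   cfg.newmark_gamma, cfg.newmark_beta)
        delta = trial.u - u_prev_iter

        if len(iface_solid) == 0 or np.linalg.norm(delta) == 0:
            accepted_solid = trial
            break

        # Aitken dynamic relaxation of the fixed-point increment: without it
        # the Gauss-Seidel exchange diverges at density ratio ~ 1
        if it == 1:
            omega = cfg.initial_relaxation
        else:
            dr = (delta - delta_prev).ravel()
            denom = float(dr @ dr)
            if denom > 0:
                omega = -omega * float(delta_prev.ravel() @ dr) / denom
            omega = float(np.clip(omega, 0.02, 1.0))
        delta_prev = delta.copy()
        delta_rel = omega * delta

        s = 1.0
        if cfg.line_search:
            # out-of-balance force of the time-discrete system (inertia
            # included) along the relaxed increment
            u_pred = (solid_state.u + dt * solid_state.v
                      + dt * dt * (0.5 - cfg.newmark_beta) * solid_state.a)
            c0 = 1.0 / (cfg.newmark_beta * dt * dt)
            free = solid._free_mask()

            def out_of_balance(s_):
                u_try = u_prev_iter + s_ * delta_rel
                try:
                    f_int = solid.internal_force(u_try)
                except FloatingPointError:
                    return np.inf
                resid = (np.repeat(solid.mass, 2) * (c0 * (u_try - u_pred)).ravel()
                         + f_int.ravel() - f_solid.ravel())[free]
                return float(np.linalg.norm(resid))
            s = _golden_section(out_of_balance, 0.0, 1.0, cfg.line_search_evals)
            s = float(np.clip(s, 0.0, 1.0))
            if out_of_balance(s) > out_of_balance(1.0):
                s = 1.0

        u_new = u_prev_iter + s * delta_rel
        if channel_height is not None:
            u_new = _gap_stop(solid, u_new, channel_height, cfg.min_gap_frac)
        accepted_solid = SolidState(u_new, trial.v, trial.a, trial.rho)

        # ALE mesh update on the accepted interface displacement; mesh
        # velocity is measured against the time-t^n configuration
        iface_disp = u_new[iface_solid]
        new_nodes, _ = move_mesh(fluid_mesh, reference_nodes, iface_fluid,
                                 iface_disp, dt)
        u_mesh = (new_nodes - nodes_tn) / dt
        fluid_mesh.nodes = new_nodes
        new_fluid.u_mesh = u_mesh

        # absolute floor ~ 0.1 nm per node keeps the rigid limit (vanishing
        # displacement) from dividing noise by noise
        floor = 1e-10 * np.sqrt(len(u_new))
        change = np.linalg.norm(u_new - u_prev_iter) / max(np.linalg.norm(u_new), floor)
        if verbose:
            print(f"    it {it}: change={change:.3e} s={s:.3f} "
                  f"|u|={np.abs(u_new).max():.3e} p={np.abs(new_fluid.p).max():.1f}")
        u_prev_iter = u_new.copy()
        if change < cfg.epsilon:
            break
    else:
        raise RuntimeError(
            f"coupling did not converge in {cfg.max_newton_iters} iterations "
            f"(last normalised change {change:.3e})")

    # consistent Newmark velocity/acceleration for the accepted displacement
    accepted_solid = _newmark_consistent(accepted_solid, solid_state, dt,
                                         cfg.newmark_gamma, cfg.newmark_beta)
    return new_fluid, accepted_solid, it


def _gap_stop(solid: NeoHookeanSolid, u: np.ndarray, height: float, min_gap_frac: float) -> np.ndarray:
    """Scale the displacement so the leaflet tip keeps a minimum gap."""
    y_new = solid.mesh.nodes[:, 1] + u[:, 1]
    y_max = float(y_new.max())
    limit = (1.0 - min_gap_frac) * height
    if y_max <= limit:
        return u
    y_ref = solid.mesh.nodes[:, 1][np.argmax(y_new)]
    scale = (limit - y_ref) / max(y_max - y_ref, 1e-30)
    return u * max(scale, 0.0)


def _newmark_consistent(state: SolidState, old: SolidState, dt: float,
                        gamma: float, beta: float) -> SolidState:
    u_pred = old.u + dt * old.v + dt * dt * (0.5 - beta) * old.a
    a_new = (state.u - u_pred) / (beta * dt * dt)
    v_new = old.v + dt * ((1.0 - gamma) * old.a + gamma * a_new)
    return SolidState(state.u, v_new, a_new, state.rho)
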