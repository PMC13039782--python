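"""Nonlinear structural dynamics: neo-Hookean plane strain, implicit Newmark.

The leaflet is modelled as a compressible neo-Hookean solid in plane
strain, with strain energy per unit volume

    W(F) = G/2 (tr(F^T F) - 2 - 2 ln J) + lambda/2 (ln J)^2,   J = det F,

discretised with linear triangles (constant deformation gradient per
element).  Time integration is the implicit Newmark scheme with gamma = 0.6
and beta = 0.4; gamma > 1/2 adds numerical (high-frequency) damping, which
the coupling relies on.  Each step solves the nonlinear balance with a full
Newton loop using the analytic material tangent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .assembly import p1_gradients
from .mesh import Mesh2D


@dataclass
class SolidState:
    u: np.ndarray  # (n, 2) displacement m
    v: np.ndarray  # (n, 2) velocity
    a: np.ndarray  # (n, 2) acceleration
    rho: float = 1000.0

    @classmethod
    def zeros(cls, n: int, rho: float = 1000.0) -> "SolidState":
        return cls(np.zeros((n, 2)), np.zeros((n, 2)), np.zeros((n, 2)), rho=rho)

    def copy(self) -> "SolidState":
        return SolidState(self.u.copy(), self.v.copy(), self.a.copy(), self.rho)


@dataclass
class NeoHookeanSolid:
    """Assembled-on-demand neo-Hookean plane-strain model on a fixed mesh."""

    mesh: Mesh2D
    G: np.ndarray  # per-element shear modulus, Pa
    nu: np.ndarray  # per-element Poisson ratio
    rho: float = 1000.0
    clamped: np.ndarray = None  # node indices with u = 0

    areas: np.ndarray = field(init=False)
    grads: np.ndarray = field(init=False)
    mass: np.ndarray = field(init=False)  # lumped nodal mass per unit depth

    def __post_init__(self):
        m = len(self.mesh.triangles)
        self.G = np.broadcast_to(np.asarray(self.G, dtype=float), (m,)).copy()
        self.nu = np.broadcast_to(np.asarray(self.nu, dtype=float), (m,)).copy()
        if np.any(self.nu >= 0.5) or np.any(self.nu <= 0):
            raise ValueError("Poisson ratio must lie in (0, 0.5)")
        self.areas, self.grads = p1_gradients(self.mesh.nodes, self.mesh.triangles)
        self.mass = np.zeros(self.mesh.n_nodes)
        np.add.at(self.mass, self.mesh.triangles.ravel(),
                  np.repeat(self.rho * self.areas / 3.0, 3))
        if self.clamped is None:
            self.clamped = self.mesh.node_tags.get("outside", np.array([], dtype=int))

    @property
    def lam(self) -> np.ndarray:
        return 2.0 * self.G * self.nu / (1.0 - 2.0 * self.nu)

    def _free_mask(self) -> np.ndarray:
        mask = np.ones(2 * self.mesh.n_nodes, dtype=bool)
        mask[2 * self.clamped] = False
        mask[2 * self.clamped + 1] = False
        return mask

    def deformation_gradients(self, u: np.ndarray) -> np.ndarray:
        """F = I + du/dX per element, (m, 2, 2)."""
        gradu = np.einsum("eja,ejk->eak", u[self.mesh.triangles], self.grads)
        F = np.broadcast_to(np.eye(2), gradu.shape).copy()
        return F + gradu

    def strain_energy(self, u: np.ndarray) -> float:
        F = self.deformation_gradients(u)
        J = np.linalg.det(F)
        if np.any(J <= 0):
            return np.inf
        trC = np.einsum("eab,eab->e", F, F)
        W = 0.5 * self.G * (trC - 2.0 - 2.0 * np.log(J)) + 0.5 * self.lam * np.log(J) ** 2
        return float(np.sum(self.areas * W))

    def internal_force(self, u: np.ndarray) -> np.ndarray:
        """Nodal internal force vector (n, 2); raises if an element inverts."""
        F = self.deformation_gradients(u)
        J = np.linalg.det(F)
        if np.any(J <= 0):
            raise FloatingPointError("inverted solid element (det F <= 0)")
        Finv = np.linalg.inv(F)
        FinvT = np.transpose(Finv, (0, 2, 1))
        lnJ = np.log(J)
        P = (self.G[:, None, None] * (F - FinvT)
             + (self.lam * lnJ)[:, None, None] * FinvT)  # 1st Piola-Kirchhoff
        fe = np.einsum("e,eak,ejk->eja", self.areas, P, self.grads)
        f = np.zeros((self.mesh.n_nodes, 2))
        np.add.at(f, self.mesh.triangles.ravel(), fe.reshape(-1, 2))
        return f

    def tangent(self, u: np.ndarray) -> sp.csr_matrix:
        """Material+geometric tangent d f_int / d u, (2n, 2n)."""
        F = self.deformation_gradients(u)
        J = np.linalg.det(F)
        Finv = np.linalg.inv(F)
        FinvT = np.transpose(Finv, (0, 2, 1))
        lnJ = np.log(J)
        m = len(self.mesh.triangles)
        eye = np.eye(2)
        # A_{acbd} = dP_ac / dF_bd
        A = (self.G[:, None, None, None, None] * np.einsum("ab,cd->acbd", eye, eye)[None]
             + (self.G - self.lam * lnJ)[:, None, None, None, None]
             * np.einsum("ead,ecb->eacbd", FinvT, Finv)
             + self.lam[:, None, None, None, None]
             * np.einsum("eca,edb->eacbd", Finv, Finv))
        # element stiffness: K[(i,a),(j,b)] = area * A_{acbd} b_ic b_jd
        Ke = np.einsum("e,eacbd,eic,ejd->eiajb", self.areas, A, self.grads, self.grads)
        n2 = 2 * self.mesh.n_nodes
        dof = (2 * self.mesh.triangles[:, :, None] + np.arange(2)[None, None, :])  # (m,3,2)
        rows = np.repeat(dof.reshape(m, 6)[:, :, None], 6, axis=2)
        cols = np.repeat(dof.reshape(m, 6)[:, None, :], 6, axis=1)
        vals = Ke.reshape(m, 6, 6)
        return sp.csr_matrix((vals.ravel(), (rows.ravel(), cols.ravel())), shape=(n2, n2))

    def static_solve(self, f_ext: np.ndarray, u0: np.ndarray | None = None,
                     n_load_steps: int = 5, tol: float = 1e-9,
                     max_newton: int = 30) -> np.ndarray:
        """Quasi-static equilibrium f_int(u) = f_ext with load stepping."""
        u = np.zeros((self.mesh.n_nodes, 2)) if u0 is None else u0.copy()
        free = self._free_mask()
        fnorm = max(np.linalg.norm(f_ext), 1e-30)
        for step in range(1, n_load_steps + 1):
            target = f_ext * (step / n_load_steps)
            for _ in range(max_newton):
                r = (self.internal_force(u) - target).ravel()[free]
                if np.linalg.norm(r) <= tol * fnorm:
                    break
                K = self.tangent(u)[free][:, free]
                du = spla.spsolve(K.tocsc(), -r)
                u = self._update(u, du, free)
            else:
                raise RuntimeError("static Newton loop did not converge")
        return u

    def _update(self, u, du_free, free, relax: float = 1.0):
        full = np.zeros(2 * self.mesh.n_nodes)
        full[free] = du_free
        return u + relax * full.reshape(-1, 2)


def newmark_solid_step(model: NeoHookeanSolid, state: SolidState, f_ext: np.ndarray,
                       dt: float, gamma: float = 0.6, beta: float = 0.4,
                       tol: float = 1e-8, max_newton: int = 30) -> SolidState:
    """One implicit Newmark step of M a + f_int(u) = f_ext.

    Newmark kinematics: u_{n+1} = u_n + dt v_n + dt^2 [(1/2-beta) a_n
    + beta a_{n+1}]; v_{n+1} = v_n + dt [(1-gamma) a_n + gamma a_{n+1}].
    Newton iterates on u_{n+1} with effective stiffness K_T + M/(beta dt^2).
    Raises RuntimeError with the residual history on non-convergence.
    """
    free = model._free_mask()
    n = model.mesh.n_nodes
    M = np.repeat(model.mass, 2)  # lumped, per dof
    u_pred = state.u + dt * state.v + dt * dt * (0.5 - beta) * state.a
    u = state.u.copy()
    c0 = 1.0 / (beta * dt * dt)
    scale = max(np.linalg.norm(f_ext), np.linalg.norm(M[::2, None] * state.a), 1e-30)
    history = []
    for _ in range(max_newton):
        a_new = c0 * (u - u_pred)
        r = (M * a_new.ravel() + model.internal_force(u).ravel() - f_ext.ravel())[free]
        rn = np.linalg.norm(r)
        history.append(rn)
        scale = max(scale, history[0])
        if rn <= tol * scale:
            break
        # stagnation at round-off (very stiff material): accept once the
        # residual has dropped far and stops improving
        if len(history) > 3 and rn >= 0.5 * min(history[:-1]) and min(history) <= 1e-4 * scale:
            break
        K = model.tangent(u) + sp.diags(c0 * M)
        du = spla.spsolve(K[free][:, free].tocsc(), -r)
        u = model._update(u, du, free)
    else:
        raise RuntimeError(f"Newmark Newton loop did not converge; residuals {history}")
    a_new = c0 * (u - u_pred)
    v_new = state.v + dt * ((1.0 - gamma) * state.a + gamma * a_new)
    out = SolidState(u, v_new, a_new, state.rho)
    out.u[model.clamped] = 0.0
    return out


def mechanical_energy(model: NeoHookeanSolid, state: SolidState) -> float:
    """Kinetic plus strain energy (per unit depth)."""
    kin = 0.5 * float(np.sum(model.mass[:, None] * state.v**2))
    return kin + model.strain_energy(state.u)
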