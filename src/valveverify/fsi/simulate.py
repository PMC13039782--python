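"""Time-domain driver for the 2D channel-with-leaflet FSI problem.

Prescribes the transvalvular pressure difference at the inflow (Dirichlet),
zero pressure at the outflow, no-slip walls and the leaflet interface
velocity from the solid, and marches the strongly coupled scheme over a
given number of cardiac cycles.  Records inlet/outlet flow per unit depth,
a valve-opening proxy (tip gap and projected open width), coupling
iteration counts and a mass-conservation diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..traces import TimeTrace
from ..units import MMHG_TO_PA, WATER_DENSITY, WATER_DYNAMIC_VISCOSITY
from .assembly import boundary_flux, build_operators
from .coupling import CouplingConfig, couple_step
from .fluid import FluidBC, FluidState, fluid_step
from .mesh import ChannelGeometry, channel_with_flap, rect_mesh
from .solid import NeoHookeanSolid, SolidState


@dataclass
class SimulationResult:
    t: np.ndarray
    q_in: np.ndarray  # m^2/s (per unit depth)
    q_out: np.ndarray
    gap: np.ndarray  # m, leaflet tip to opposite wall
    open_width: np.ndarray  # m, projected open width of the channel
    iterations: np.ndarray
    diagnostics: dict = field(default_factory=dict)
    status: str = "ok"

    def q_in_trace(self) -> TimeTrace:
        return TimeTrace(self.t, self.q_in, "m^2/s")

    def stroke_area(self) -> float:
        """Cycle integral of positive inlet flow (m^2 per unit depth)."""
        return float(np.trapezoid(np.maximum(self.q_in, 0.0), self.t))


def _mass_conservation(t, q_in, q_out) -> float:
    vin = np.trapezoid(q_in, t)
    vout = np.trapezoid(q_out, t)
    if abs(vin) < 1e-30:
        return 0.0
    return abs(vin - vout) / abs(vin)


def run_simulation(geom: ChannelGeometry, material, dp_trace: TimeTrace,
                   cfg: CouplingConfig, n_cycles: int | None = None,
                   rigid_leaflet: bool = False,
                   rho: float = WATER_DENSITY, mu: float = WATER_DYNAMIC_VISCOSITY,
                   dp_in_mmhg: bool = True) -> SimulationResult:
    """March the coupled (or rigid-leaflet) problem through dp_trace.

    ``material`` is a :class:`~valveverify.calibration.MaterialSpec`;
    ``dp_trace`` is the inflow pressure difference (mmHg by default).  The
    trace is sampled at the solver time step by linear interpolation.  On a
    solver failure the traces computed so far are returned with
    ``status='failed: ...'``.
    """
    fluid_mesh, solid_mesh, iface_fluid, iface_solid = channel_with_flap(geom)
    reference_nodes = fluid_mesh.nodes.copy()
    n = fluid_mesh.n_nodes
    scale = MMHG_TO_PA if dp_in_mmhg else 1.0

    G_el, nu_el = material.element_moduli(len(solid_mesh.triangles))
    solid = NeoHookeanSolid(solid_mesh, G_el, nu_el, rho=material.density)
    solid_state = SolidState.zeros(solid_mesh.n_nodes, rho=material.density)
    fluid_state = FluidState.zeros(n, rho=rho, mu=mu)

    t_end = dp_trace.t[-1]
    steps = int(np.floor(t_end / cfg.dt))
    in_edges = fluid_mesh.boundary_edges["inflow"]
    out_edges = fluid_mesh.boundary_edges["outflow"]
    tip0 = solid_mesh.nodes[:, 1].max()

    ts, q_in, q_out, gaps, widths, iters = [], [], [], [], [], []
    status = "ok"
    try:
        for k in range(1, steps + 1):
            t = k * cfg.dt
            dp_pa = float(np.interp(t, dp_trace.t, dp_trace.value)) * scale
            bc = FluidBC(velocity={"inside": np.zeros(2)},
                         pressure={"inflow": dp_pa, "outflow": 0.0})
            if rigid_leaflet:
                bc.velocity["leaflets"] = np.zeros(2)
                fluid_state = fluid_step(fluid_mesh, fluid_state, cfg.dt, bc,
                                         max_subiters=cfg.max_pressure_subiters,
                                         stab_coeff=cfg.stab_coeff)
                nit = 1
            else:
                fluid_state, solid_state, nit = couple_step(
                    fluid_mesh, reference_nodes, fluid_state, solid, solid_state,
                    iface_fluid, iface_solid, cfg, bc, channel_height=geom.height)

            ts.append(t)
            u = fluid_state.u
            # inflow normal points out of the domain; flow INTO the channel is -u.n
            q_in.append(-boundary_flux(fluid_mesh.nodes, fluid_mesh.triangles, in_edges, u))
            q_out.append(boundary_flux(fluid_mesh.nodes, fluid_mesh.triangles, out_edges, u))
            tip_y = (solid_mesh.nodes[:, 1] + solid_state.u[:, 1]).max() if not rigid_leaflet else tip0
            gaps.append(geom.height - tip_y)
            widths.append(geom.height - tip_y)
            iters.append(nit)
    except RuntimeError as exc:
        status = f"failed: {exc}"

    ts = np.array(ts)
    q_in = np.array(q_in)
    q_out = np.array(q_out)
    diag = {"mass_conservation_discrepancy": _mass_conservation(ts, q_in, q_out)
            if len(ts) > 1 else np.nan,
            "mean_coupling_iterations": float(np.mean(iters)) if iters else np.nan,
            "dt": cfg.dt}
    return SimulationResult(ts, q_in, q_out, np.array(gaps), np.array(widths),
                            np.array(iters), diag, status)


def timestep_sensitivity(geom: ChannelGeometry, material, dp_trace: TimeTrace,
                         cfg: CouplingConfig, **kw) -> dict:
    """Relative change of mean inlet flow when the time step is halved."""
    base = run_simulation(geom, material, dp_trace, cfg, **kw)
    cfg_half = CouplingConfig(**{**cfg.__dict__, "dt": cfg.dt / 2.0})
    half = run_simulation(geom, material, dp_trace, cfg_half, **kw)
    qm_base = float(np.mean(np.maximum(base.q_in, 0.0)))
    qm_half = float(np.mean(np.maximum(half.q_in, 0.0)))
    rel = abs(qm_half - qm_base) / max(abs(qm_base), 1e-30)
    return {"q_mean_dt": qm_base, "q_mean_dt_half": qm_half,
            "relative_change": rel, "dt": cfg.dt}


def poiseuille_reference(height: float, dp_dx: float, mu: float, y: np.ndarray) -> np.ndarray:
    """Analytic steady plane-Poiseuille profile u(y) for a given -dp/dx."""
    return 0.5 * (-dp_dx) / mu * y * (height - y)


def steady_channel_flow(length: float, height: float, nx: int, ny: int,
                        dp: float, mu: float = 1.0e-3, rho: float = 1000.0,
                        dt: float = 1.0e-3, n_steps: int = 400,
                        stab_coeff: float = 0.0) -> tuple:
    """Drive a straight channel with a constant pressure drop to steady state.

    Returns (mesh, final FluidState).  Used for the Poiseuille recovery
    check and as the rigid-reference configuration.
    """
    mesh = rect_mesh(length, height, nx, ny)
    state = FluidState.zeros(mesh.n_nodes, rho=rho, mu=mu)
    bc = FluidBC(velocity={"inside": np.zeros(2)},
                 pressure={"inflow": dp, "outflow": 0.0})
    ops = build_operators(mesh.nodes, mesh.triangles)
    for _ in range(n_steps):
        state = fluid_step(mesh, state, dt, bc, ops=ops, stab_coeff=stab_coeff)
    return mesh, state
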