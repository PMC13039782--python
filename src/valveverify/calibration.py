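"""Leaflet stiffness calibration by stroke-volume matching.

The leaflet shear modulus G is the one free material parameter; a stiffer
valve opens less and ejects a smaller stroke volume, so SV(G) is monotone
decreasing over the physical bracket and the calibration is a bracketed
root search on SV(G) - SV_target.  Bisection with secant acceleration is
used because each forward evaluation is an expensive (and possibly noisy)
coupled simulation: every accepted step must stay inside the bracket.

Also here: the two-material (calcified) leaflet description and the
Poisson-ratio adjustment that keeps the bulk modulus of the stiff
calcified regions equal to that of the surrounding tissue, which mixed
(volume-averaged) element formulations require.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np


@dataclass
class MaterialSpec:
    """Neo-Hookean leaflet material, optionally with calcified sub-regions."""

    shear_modulus: float  # Pa
    poisson_ratio: float
    density: float = 1000.0  # kg/m^3
    calcified_element_mask: np.ndarray | None = None
    shear_modulus_calc: float | None = None
    poisson_ratio_calc: float | None = None

    def __post_init__(self):
        if self.shear_modulus <= 0:
            raise ValueError("shear modulus must be positive")
        if not 0.0 < self.poisson_ratio < 0.5:
            raise ValueError("Poisson ratio must lie in (0, 0.5)")

    @property
    def youngs_modulus(self) -> float:
        return 2.0 * self.shear_modulus * (1.0 + self.poisson_ratio)

    def element_moduli(self, n_elements: int) -> tuple[np.ndarray, np.ndarray]:
        """Per-element (G, nu) arrays honouring the calcified mask."""
        G = np.full(n_elements, self.shear_modulus)
        nu = np.full(n_elements, self.poisson_ratio)
        if self.calcified_element_mask is not None and self.shear_modulus_calc is not None:
            m = np.asarray(self.calcified_element_mask, dtype=bool)
            G[m] = self.shear_modulus_calc
            nu[m] = (self.poisson_ratio_calc if self.poisson_ratio_calc is not None
                     else self.poisson_ratio)
        return G, nu


@dataclass
class CalibrationResult:
    G_hat: float  # Pa
    iterations: int
    evaluations: list = field(default_factory=list)  # (G, SV) pairs
    converged: bool = False
    tolerance: float = 1.0  # mL


def bulk_modulus(G: float, nu: float) -> float:
    """K = 2G(1+nu) / (3(1-2nu))."""
    return 2.0 * G * (1.0 + nu) / (3.0 * (1.0 - 2.0 * nu))


def poisson_for_bulk_match(G_tissue: float, nu_tissue: float, G_calc: float) -> float:
    """Poisson ratio giving the calcified material the tissue bulk modulus.

    Solves K(G_calc, nu) = K(G_tissue, nu_tissue), linear in nu:
    nu = (3K - 2G_calc) / (6K + 2G_calc).
    """
    if G_tissue <= 0 or G_calc <= 0:
        raise ValueError("shear moduli must be positive")
    if not 0.0 < nu_tissue < 0.5:
        raise ValueError("nu_tissue must lie in (0, 0.5)")
    K = bulk_modulus(G_tissue, nu_tissue)
    nu = (3.0 * K - 2.0 * G_calc) / (6.0 * K + 2.0 * G_calc)
    if not 0.0 < nu < 0.5:
        raise ValueError(f"no admissible Poisson ratio: got {nu:.4f}")
    return nu


def assign_calcified_material(mask: np.ndarray, G_tissue: float, nu_tissue: float,
                              G_calc: float, density: float = 1000.0) -> MaterialSpec:
    """Two-material leaflet spec with bulk-modulus-matched calcifications.

    Calcified regions share the tissue density; their Poisson ratio is
    reduced so both materials have the same compression modulus.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return MaterialSpec(G_tissue, nu_tissue, density)
    return MaterialSpec(G_tissue, nu_tissue, density,
                        calcified_element_mask=mask,
                        shear_modulus_calc=G_calc,
                        poisson_ratio_calc=poisson_for_bulk_match(G_tissue, nu_tissue, G_calc))


def modulus_relative_difference(G_a: float, G_b: float) -> float:
    """|G_a - G_b| / G_a, the first argument being the reference."""
    return abs(G_a - G_b) / G_a


def calibrate_shear_modulus(sv_target: float, forward: Callable[[float], float],
                            bounds: tuple[float, float], tol: float = 1.0,
                            max_evals: int = 20) -> CalibrationResult:
    """Find G with SV(G) = sv_target by bracketed bisection/secant search.

    ``forward`` maps shear modulus (Pa) to stroke volume (mL).  SV must be
    monotone decreasing over ``bounds``; this is verified from the bracket
    endpoints and violated monotonicity is an error.  Every forward
    evaluation is logged.
    """
    g_lo, g_hi = bounds
    if g_lo >= g_hi:
        raise ValueError("bounds must satisfy lo < hi")
    evals = []

    def f(G):
        sv = forward(G)
        evals.append((G, sv))
        return sv - sv_target

    f_lo, f_hi = f(g_lo), f(g_hi)
    if f_lo + tol < f_hi:
        raise ValueError("stroke volume is not decreasing in G over the bracket")
    if abs(f_lo) <= tol:
        return CalibrationResult(g_lo, 0, evals, True, tol)
    if abs(f_hi) <= tol:
        return CalibrationResult(g_hi, 0, evals, True, tol)
    if not (f_hi <= 0.0 <= f_lo):
        raise ValueError(
            f"target {sv_target} mL outside bracket [{f_hi + sv_target:.2f}, "
            f"{f_lo + sv_target:.2f}] mL")

    it = 0
    side = 0  # Illinois bookkeeping: which endpoint was updated last
    w_lo, w_hi = f_lo, f_hi  # (possibly down-weighted) endpoint values
    while len(evals) < max_evals:
        it += 1
        # secant (false-position) proposal with Illinois down-weighting of the
        # stale endpoint, so one-sided convergence cannot stagnate; fall back
        # to bisection if the proposal hugs the bracket edge
        denom = w_hi - w_lo
        g_sec = (g_lo * w_hi - g_hi * w_lo) / denom if denom != 0 else None
        margin = 0.01 * (g_hi - g_lo)
        g_new = g_sec if (g_sec is not None and g_lo + margin < g_sec < g_hi - margin) \
            else 0.5 * (g_lo + g_hi)
        f_new = f(g_new)
        if abs(f_new) <= tol:
            return CalibrationResult(g_new, it, evals, True, tol)
        if f_new > 0:  # SV too large -> valve too soft -> raise lower bound
            g_lo, f_lo, w_lo = g_new, f_new, f_new
            if side == 1:
                w_hi *= 0.5
            side = 1
        else:
            g_hi, f_hi, w_hi = g_new, f_new, f_new
            if side == -1:
                w_lo *= 0.5
            side = -1
    g_best, sv_best = min(evals, key=lambda gv: abs(gv[1] - sv_target))
    return CalibrationResult(g_best, it, evals, abs(sv_best - sv_target) <= tol, tol)


def cross_validate(calibrate_on: str, evaluate_on: Sequence[str],
                   forward: Callable[[float, str], float],
                   targets: dict, bounds: tuple[float, float],
                   tol: float = 1.0) -> dict:
    """Calibrate G on one condition and evaluate the others with it.

    ``forward(G, condition)`` returns the condition's stroke volume (mL);
    ``targets`` maps condition to its target SV.  Returns the calibration
    result plus one row per evaluated condition with the achieved SV, the
    relative error and a 10% within-uncertainty flag.
    """
    cal = calibrate_shear_modulus(targets[calibrate_on],
                                  lambda G: forward(G, calibrate_on), bounds, tol)
    rows = []
    for cond in evaluate_on:
        sv = forward(cal.G_hat, cond)
        tgt = targets[cond]
        rows.append({"condition": cond, "sv": sv, "sv_target": tgt,
                     "rel_error": abs(sv - tgt) / abs(tgt),
                     "within_10pct": abs(sv - tgt) <= 0.10 * abs(tgt)})
    return {"calibrated_on": calibrate_on, "G_hat": cal.G_hat,
            "calibration": cal, "rows": rows}
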