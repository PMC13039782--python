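"""Smagorinsky sub-grid model and the Pope LES-quality criterion."""

from __future__ import annotations

import numpy as np


def smagorinsky_nu_t(grad_u: np.ndarray, c_s: float = 0.18, delta: float = 5.0e-4) -> np.ndarray:
    """Eddy viscosity nu_t = (C_s Delta)^2 |S| per element.

    ``grad_u`` is (m, 2, 2) with [a, k] = d u_a / d x_k; |S| = sqrt(2 S:S)
    with S the symmetric velocity gradient.
    """
    S = 0.5 * (grad_u + np.transpose(grad_u, (0, 2, 1)))
    Smag = np.sqrt(2.0 * np.einsum("eab,eab->e", S, S))
    return (c_s * delta) ** 2 * Smag


def pope_ratio(C: float = 1.5, delta: float = 5.0e-4, L: float = 1.3e-2) -> float:
    """Sub-grid to total turbulent kinetic energy ratio.

    k_SGS / k = (3/2) C (Delta / (pi L))^(2/3) for Pope's constant C, LES
    filter width Delta and characteristic length L (same length units).
    A good LES keeps this below 0.2 (at least 80% of the energy resolved).
    """
    return 1.5 * C * (delta / (np.pi * L)) ** (2.0 / 3.0)
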