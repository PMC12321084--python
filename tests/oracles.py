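"""Independent brute-force oracles used to cross-check the simulator."""

from __future__ import annotations

import numpy as np


def euler_batch(
    strategies: np.ndarray,
    biomass: np.ndarray,
    c_init: np.ndarray,
    K: float,
    depletion_tol: float = 1e-6,
    dt: float = 1e-4,
    max_time: float = 1e4,
):
    """Fixed-step forward-Euler integration of the batch growth equations.

    Same termination rule as the adaptive integrator: stop when the total
    nutrient falls below ``depletion_tol * c0``.  Returns (c, biomass).
    """
    c = c_init.astype(float).copy()
    rho = biomass.astype(float).copy()
    c0 = c.sum()
    t = 0.0
    while c.sum() >= depletion_tol * c0:
        monod = np.maximum(c, 0.0) / (K + np.maximum(c, 0.0))
        j = strategies * monod
        dc = -rho @ j
        drho = rho * j.sum(axis=1)
        c += dt * dc
        rho += dt * drho
        np.clip(c, 0.0, None, out=c)
        t += dt
        if t > max_time:
            raise RuntimeError("euler oracle did not deplete")
    return c, rho
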