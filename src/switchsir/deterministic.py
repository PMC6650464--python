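"""Deterministic skeleton: fixed-step integration and the invariant region.

The frozen-regime ODE system is integrated with the classical 4th-order
Runge-Kutta scheme at a fixed step.  A fixed step (rather than an adaptive
solver) keeps runs bit-reproducible and exposes a clean convergence-order
test surface.  The flow preserves the region

    Gamma = { (S, I) >= 0 : Lambda/(mu+gamma+epsilon) <= S+I <= Lambda/mu },

and I = 0 is invariant; a negative undershoot of I within a step is clamped
back to 0 and counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from . import _kernels
from .model_core import RegimeParameters, _check_positive, _check_state

logger = logging.getLogger(__name__)

__all__ = ["OdeTrajectory", "integrate", "invariant_region_check"]


@dataclass(frozen=True)
class OdeTrajectory:
    """Uniform-grid solution of the frozen-regime deterministic system."""

    times: np.ndarray
    S: np.ndarray
    I: np.ndarray
    params: RegimeParameters
    h: float
    dt: float
    n_clamps: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.times, "S": self.S, "I": self.I})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def integrate(p: RegimeParameters, h: float, S0: float, I0: float,
              T: float, dt: float) -> OdeTrajectory:
    """RK4-integrate the deterministic system from (S0, I0) over [0, T].

    The horizon is snapped to a whole number of steps (n = round(T/dt)).
    I0 = 0 propagates exactly: the infected axis is invariant.  A non-finite
    state aborts with a diagnostic.
    """
    _check_state(S0, I0)
    _check_positive(T=T, dt=dt, h=h)
    n_steps = int(round(T / dt))
    if n_steps < 1:
        raise ValueError(f"T={T} shorter than one step dt={dt}")
    S = np.empty(n_steps + 1)
    I = np.empty(n_steps + 1)
    n_clamps, bad_step = _kernels.rk4_kernel(
        float(S0), float(I0), p.Lambda, p.mu, p.beta, p.alpha, p.gamma,
        p.epsilon, float(h), float(dt), n_steps, S, I)
    if bad_step >= 0:
        raise ArithmeticError(
            f"non-finite state at t={bad_step * dt:.6g} "
            f"(step {bad_step}); last finite state "
            f"S={S[bad_step - 1]!r}, I={I[bad_step - 1]!r}")
    if n_clamps:
        logger.info("clamped negative I undershoot to 0 on %d step(s)",
                    n_clamps)
    times = np.arange(n_steps + 1) * dt
    return OdeTrajectory(times=times, S=S, I=I, params=p, h=float(h),
                         dt=float(dt), n_clamps=int(n_clamps))


@dataclass(frozen=True)
class RegionViolation:
    index: int
    time: float
    total: float
    lower: float
    upper: float


def invariant_region_check(traj: OdeTrajectory,
                           p: Optional[RegimeParameters] = None,
                           tol: float = 1e-6
                           ) -> tuple[bool, Optional[RegionViolation]]:
    """Check Lambda/(mu+gamma+epsilon) - tol <= S+I <= Lambda/mu + tol
    at every stored point.

    Returns (ok, first_violation).  Meaningful for trajectories started
    inside the region; violations within floating/discretization tolerance
    are reported, not silently accepted.
    """
    p = traj.params if p is None else p
    lower = p.Lambda / p.removal_rate
    upper = p.Lambda / p.mu
    total = traj.S + traj.I
    bad = (total < lower - tol) | (total > upper + tol)
    if not bad.any():
        return True, None
    i = int(np.argmax(bad))
    return False, RegionViolation(index=i, time=float(traj.times[i]),
                                  total=float(total[i]), lower=lower,
                                  upper=upper)
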