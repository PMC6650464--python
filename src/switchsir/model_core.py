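"""Model definition: parameters, incidence family, vector field, thresholds.

The model is an SIR epidemic (recovered compartment dropped — it does not
feed back) whose transmission term is ratio-dependent,

    g(S, I) = beta * S^h * I / (S^h + alpha * I^h),

so the force of infection saturates in I/S (crowding / behavioural change).
Environmental variability enters two ways: a continuous-time Markov chain
r(t) switches the whole parameter set between N regimes (telegraph noise),
and a single Brownian motion perturbs the transmission coefficient (white
noise, intensity sigma^2), entering S and I with opposite sign so that the
diffusion is degenerate: S+I carries no noise.

Closed-form threshold quantities:

* per-regime deterministic R0_i = beta_i / (mu_i + gamma_i + epsilon_i);
* stochastic reproduction number
      R0S = sum_i pi_i beta_i / sum_i pi_i (mu_i+gamma_i+epsilon_i+sigma_i^2/2),
  R0S > 1 implies an ergodic stationary distribution (persistence);
* extinction index
      Rbar = sum_i pi_i beta_i^2/(2 sigma_i^2) / sum_i pi_i (mu_i+gamma_i+epsilon_i),
  Rbar < 1 implies almost-sure extinction, as does R0S < 1 together with
  sigma_i^2 <= beta_i for every regime,

where pi is the stationary distribution of the switching chain.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import _kernels
from . import regime_chain

logger = logging.getLogger(__name__)

__all__ = [
    "RegimeParameters",
    "SwitchingModel",
    "ThresholdReport",
    "Equilibria",
    "ratio_dependent_incidence",
    "general_incidence",
    "drift",
    "diffusion",
    "diffusion_gradient_product",
    "deterministic_R0",
    "equilibria",
    "stochastic_R0S",
    "extinction_index_Rbar",
    "classify_dynamics",
]


def _check_state(S: float, I: float) -> None:
    if not (np.isfinite(S) and np.isfinite(I)):
        raise ValueError(f"non-finite state (S={S}, I={I})")
    if S < 0 or I < 0:
        raise ValueError(f"S and I must be non-negative, got (S={S}, I={I})")


def _check_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not np.isfinite(value) or value <= 0:
            raise ValueError(f"{name} must be strictly positive, got {value}")


@dataclass(frozen=True)
class RegimeParameters:
    """Rate constants of one environmental regime.

    Lambda : influx into the susceptible class (individuals/time)
    mu     : natural death rate (1/time)
    beta   : transmission coefficient (1/time)
    alpha  : inhibition (psychological-effect) parameter, dimensionless
    gamma  : recovery rate (1/time)
    epsilon: disease-induced death rate (1/time)
    sigma2 : white-noise intensity sigma^2 on beta (1/time); sigma2 = 0
             recovers the deterministic regime
    """

    Lambda: float
    mu: float
    beta: float
    alpha: float
    gamma: float
    epsilon: float
    sigma2: float = 0.0

    def __post_init__(self) -> None:
        _check_positive(Lambda=self.Lambda, mu=self.mu, beta=self.beta,
                        alpha=self.alpha, gamma=self.gamma,
                        epsilon=self.epsilon)
        if not np.isfinite(self.sigma2) or self.sigma2 < 0:
            raise ValueError(f"sigma2 must be >= 0, got {self.sigma2}")

    @property
    def sigma(self) -> float:
        return math.sqrt(self.sigma2)

    @property
    def removal_rate(self) -> float:
        """Total per-capita removal rate from the infected class."""
        return self.mu + self.gamma + self.epsilon


@dataclass(frozen=True)
class SwitchingModel:
    """N regimes, a CTMC generator, and the shared incidence exponent h.

    The generator's rows must sum to zero and its positive-rate digraph must
    be strongly connected (irreducible) — only irreducibility is assumed, not
    positivity of every off-diagonal rate.  h < 1 is accepted with a warning:
    the incidence family is usually stated for h >= 1, but the worked
    two-regime example uses h = 0.002.
    """

    regimes: tuple[RegimeParameters, ...]
    generator: np.ndarray
    h: float
    l: Optional[float] = None

    def __init__(self, regimes: Sequence[RegimeParameters],
                 generator: np.ndarray, h: float,
                 l: Optional[float] = None) -> None:
        regimes = tuple(regimes)
        if len(regimes) < 1:
            raise ValueError("need at least one regime")
        G = regime_chain.validate_generator(generator)
        if G.shape[0] != len(regimes):
            raise ValueError(
                f"generator is {G.shape[0]}x{G.shape[0]} but there are "
                f"{len(regimes)} regimes")
        if not regime_chain.is_irreducible(G):
            raise ValueError("generator is not irreducible")
        _check_positive(h=h)
        if h < 1:
            warnings.warn(
                f"incidence exponent h={h} < 1 lies outside the usual h >= 1 "
                "range; proceeding (the reference parameterization uses "
                "h = 0.002)", UserWarning, stacklevel=2)
        if l is not None:
            _check_positive(l=l)
        object.__setattr__(self, "regimes", regimes)
        object.__setattr__(self, "generator", G)
        object.__setattr__(self, "h", float(h))
        object.__setattr__(self, "l", None if l is None else float(l))

    @property
    def n_regimes(self) -> int:
        return len(self.regimes)

    def stationary_distribution(self) -> np.ndarray:
        return regime_chain.stationary_distribution(self.generator)

    def param_matrix(self) -> np.ndarray:
        """Packed (N, 7) float matrix for the numba kernels (sigma, not sigma2)."""
        out = np.empty((self.n_regimes, 7))
        for i, p in enumerate(self.regimes):
            out[i] = (p.Lambda, p.mu, p.beta, p.alpha, p.gamma, p.epsilon,
                      p.sigma)
        return out

    def thresholds(self) -> "ThresholdReport":
        return classify_dynamics(self)


# ---------------------------------------------------------------------------
# incidence family and the vector field of the switching SDE
# ---------------------------------------------------------------------------

def ratio_dependent_incidence(S: float, I: float, beta: float, alpha: float,
                              h: float) -> float:
    """Transmission rate beta*S^h*I/(S^h + alpha*I^h).

    Defined as 0 on the boundary (I = 0, or S = 0 with I > 0), the continuous
    limit for h > 0.  Always within [0, beta*I].
    """
    _check_state(S, I)
    _check_positive(beta=beta, alpha=alpha, h=h)
    return float(_kernels.incidence_core(S, I, beta, alpha, h))


def general_incidence(S: float, I: float, beta: float, alpha: float,
                      h: float, l: float) -> float:
    """Two-exponent ratio-dependent incidence beta*S^(h-l+1)*I^l/(S^h+alpha*I^h).

    With l = 1 this reduces to :func:`ratio_dependent_incidence`; with
    alpha = h = l = 1 it is the standard (frequency-dependent) incidence
    beta*S*I/(S+I).
    """
    _check_state(S, I)
    _check_positive(beta=beta, alpha=alpha, h=h, l=l)
    if I == 0.0 or S == 0.0:
        return 0.0
    return float(beta * S ** (h - l + 1.0) * I ** l / (S ** h + alpha * I ** h))


def drift(S: float, I: float, p: RegimeParameters, h: float) -> tuple[float, float]:
    """Drift (dS/dt, dI/dt) of the frozen-regime system.

    aS = Lambda - mu*S - g(S,I), aI = g(S,I) - (mu+gamma+epsilon)*I; hence
    aS + aI = Lambda - mu*(S+I) - (gamma+epsilon)*I identically.
    """
    _check_state(S, I)
    aS, aI = _kernels.drift_core(S, I, p.Lambda, p.mu, p.beta, p.alpha,
                                 p.gamma, p.epsilon, h)
    return float(aS), float(aI)


def diffusion(S: float, I: float, p: RegimeParameters, h: float) -> tuple[float, float]:
    """Diffusion (bS, bI) w.r.t. the single Brownian motion; bI = -bS."""
    _check_state(S, I)
    bS = _kernels.diffusion_S_core(S, I, p.sigma, p.alpha, h)
    return float(bS), float(-bS)


def diffusion_gradient_product(S: float, I: float, p: RegimeParameters,
                               h: float) -> tuple[float, float]:
    """Milstein correction vector (b . grad) b, analytic; (0,0) on the axes."""
    _check_state(S, I)
    cS = _kernels.correction_S_core(S, I, p.sigma, p.alpha, h)
    return float(cS), float(-cS)


# ---------------------------------------------------------------------------
# equilibria of the deterministic skeleton
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Equilibria:
    """Equilibria of the frozen-regime deterministic system."""

    disease_free: tuple[float, float]
    endemic: Optional[tuple[float, float]]
    note: Optional[str] = None


def deterministic_R0(p: RegimeParameters) -> float:
    """Basic reproduction number beta/(mu+gamma+epsilon) of one regime."""
    return p.beta / p.removal_rate


def equilibria(p: RegimeParameters, h: float, tol: float = 1e-10) -> Equilibria:
    """Disease-free and (when R0 > 1) endemic equilibrium.

    The endemic point solves the drift balance: I* = k S* with
    k = ((R0-1)/alpha)^(1/h), and Lambda - mu S* - (mu+gamma+epsilon) I* = 0,
    i.e. S* = Lambda/(mu + k(mu+gamma+epsilon)).  k is evaluated in log space;
    if it overflows the double range the endemic equilibrium is reported as
    not representable.  The computed point is verified against the drift
    field to absolute tolerance `tol`.
    """
    _check_positive(h=h)
    E0 = (p.Lambda / p.mu, 0.0)
    R0 = deterministic_R0(p)
    if R0 <= 1.0:
        return Equilibria(disease_free=E0, endemic=None)
    log_k = math.log((R0 - 1.0) / p.alpha) / h
    if log_k > math.log(np.finfo(float).max) - 10.0:
        return Equilibria(
            disease_free=E0, endemic=None,
            note=(f"endemic equilibrium not representable: I*/S* ratio "
                  f"exp({log_k:.1f}) overflows double precision"))
    k = math.exp(log_k)
    S_star = p.Lambda / (p.mu + k * p.removal_rate)
    I_star = k * S_star
    residual = max(abs(a) for a in drift(S_star, I_star, p, h))
    note = None
    if residual > tol:
        note = (f"endemic equilibrium drift residual {residual:.3e} exceeds "
                f"tolerance {tol:.1e}")
        logger.warning(note)
    return Equilibria(disease_free=E0, endemic=(S_star, I_star), note=note)


# ---------------------------------------------------------------------------
# threshold quantities of the switching system
# ---------------------------------------------------------------------------

def _resolve_pi(model: SwitchingModel, pi) -> np.ndarray:
    if pi is None:
        return model.stationary_distribution()
    pi = np.asarray(pi, dtype=float)
    if pi.shape != (model.n_regimes,):
        raise ValueError(
            f"pi must have length {model.n_regimes}, got shape {pi.shape}")
    if abs(pi.sum() - 1.0) > 1e-10:
        raise ValueError(f"pi must sum to 1, got {pi.sum()!r}")
    if np.any(pi < 0):
        raise ValueError("pi must be non-negative")
    return pi


def stochastic_R0S(model: SwitchingModel, pi=None) -> float:
    """Stochastic reproduction number of the switching system.

    R0S = sum_i pi_i beta_i / sum_i pi_i (mu_i + gamma_i + epsilon_i +
    sigma_i^2/2).  With one regime and sigma = 0 this is the deterministic R0.
    """
    pi = _resolve_pi(model, pi)
    num = sum(w * p.beta for w, p in zip(pi, model.regimes))
    den = sum(w * (p.removal_rate + p.sigma2 / 2.0)
              for w, p in zip(pi, model.regimes))
    return float(num / den)


def extinction_index_Rbar(model: SwitchingModel, pi=None) -> float:
    """Extinction index sum_i pi_i beta_i^2/(2 sigma_i^2) / sum_i pi_i (removal)_i.

    Undefined (raises) when any regime has sigma^2 = 0.
    """
    pi = _resolve_pi(model, pi)
    for i, p in enumerate(model.regimes):
        if p.sigma2 == 0.0:
            raise ValueError(
                f"extinction index is undefined: regime {i + 1} has sigma2 = 0")
    num = sum(w * p.beta ** 2 / (2.0 * p.sigma2)
              for w, p in zip(pi, model.regimes))
    den = sum(w * p.removal_rate for w, p in zip(pi, model.regimes))
    return float(num / den)


@dataclass(frozen=True)
class ThresholdReport:
    """Closed-form thresholds and the persistence/extinction classification.

    classification:
      * 'persistent'  — R0S > 1: unique ergodic stationary distribution;
      * 'extinct_i'   — Rbar < 1: almost-sure extinction (large noise);
      * 'extinct_ii'  — R0S < 1 and sigma_i^2 <= beta_i for all i;
      * 'indeterminate' — none of the sufficient conditions applies.
    extinct_i takes precedence over extinct_ii when both hold.
    """

    pi: np.ndarray
    R0_per_regime: np.ndarray
    R0S: float
    Rbar: Optional[float]
    noise_dominance: np.ndarray
    classification: str
    notes: tuple[str, ...] = field(default_factory=tuple)

    def to_dict(self) -> dict:
        return {
            "pi": self.pi.tolist(),
            "R0_per_regime": self.R0_per_regime.tolist(),
            "R0S": self.R0S,
            "Rbar": self.Rbar,
            "noise_dominance": [bool(b) for b in self.noise_dominance],
            "classification": self.classification,
            "notes": list(self.notes),
        }


def classify_dynamics(model: SwitchingModel) -> ThresholdReport:
    """Evaluate all thresholds and classify the long-run dynamics.

    Pure function of the model: pi is computed from the generator by a
    deterministic linear solve, so repeated calls agree bit-for-bit.
    """
    pi = model.stationary_distribution()
    R0 = np.array([deterministic_R0(p) for p in model.regimes])
    r0s = stochastic_R0S(model, pi)
    all_sigma_pos = all(p.sigma2 > 0 for p in model.regimes)
    rbar = extinction_index_Rbar(model, pi) if all_sigma_pos else None
    dominance = np.array([p.sigma2 <= p.beta for p in model.regimes])
    notes: list[str] = []
    if r0s > 1.0:
        classification = "persistent"
    elif rbar is not None and rbar < 1.0:
        classification = "extinct_i"
    elif r0s < 1.0 and bool(dominance.all()):
        classification = "extinct_ii"
    else:
        classification = "indeterminate"
    if not all_sigma_pos:
        notes.append("extinction index Rbar undefined (some sigma2 = 0)")
    return ThresholdReport(pi=pi, R0_per_regime=R0, R0S=r0s, Rbar=rbar,
                           noise_dominance=dominance,
                           classification=classification,
                           notes=tuple(notes))
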