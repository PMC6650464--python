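"""Continuous-time Markov chain machinery for the environmental regime.

The regime process r(t) lives on {1, ..., N} with generator G = (g_ij):
off-diagonal entries are jump rates, g_ii = -sum_{j != i} g_ij.  Only
irreducibility is assumed — strong connectivity of the digraph of strictly
positive rates — not positivity of every off-diagonal entry.  An irreducible
chain has a unique stationary distribution pi with pi G = 0, sum pi = 1,
pi > 0, equal to its long-run occupation fractions.

Path sampling is exact: the holding time in state i is Exponential(-g_ii)
and the next state is j with probability g_ij / (-g_ii).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "RegimePath",
    "validate_generator",
    "is_irreducible",
    "stationary_distribution",
    "sample_path",
    "occupation_fractions",
]

ROW_SUM_TOL = 1e-12


def validate_generator(rates) -> np.ndarray:
    """Validate a CTMC generator matrix and return it as a float array.

    Checks: square, finite, off-diagonal entries >= 0, every row sums to 0
    within 1e-12 (scaled by the largest rate).
    """
    G = np.array(rates, dtype=float)
    if G.ndim != 2 or G.shape[0] != G.shape[1]:
        raise ValueError(f"generator must be square, got shape {G.shape}")
    if not np.all(np.isfinite(G)):
        raise ValueError("generator contains non-finite entries")
    off = G[~np.eye(G.shape[0], dtype=bool)]
    if off.size and off.min() < 0:
        raise ValueError("generator has negative off-diagonal entries")
    scale = max(1.0, float(np.abs(G).max()) if G.size else 1.0)
    row_sums = G.sum(axis=1)
    bad = np.abs(row_sums) > ROW_SUM_TOL * scale
    if np.any(bad):
        i = int(np.argmax(bad))
        raise ValueError(
            f"generator row {i} sums to {row_sums[i]!r}, expected 0")
    return G


def is_irreducible(G) -> bool:
    """True iff the digraph of strictly positive off-diagonal rates is
    strongly connected (an N=1 chain is irreducible)."""
    G = np.asarray(G, dtype=float)
    n = G.shape[0]
    if n == 1:
        return True
    mask = (G > 0) & ~np.eye(n, dtype=bool)
    n_comp, _ = connected_components(csr_matrix(mask.astype(np.int8)),
                                     directed=True, connection="strong")
    return n_comp == 1


def stationary_distribution(G) -> np.ndarray:
    """Solve pi G = 0, sum pi = 1 by a deterministic linear solve.

    One balance equation is replaced by the normalization constraint, which
    avoids eigen-solver sign/ordering ambiguity.  Requires irreducibility.
    """
    G = validate_generator(G)
    if not is_irreducible(G):
        raise ValueError("generator is reducible; stationary distribution "
                         "is not unique")
    n = G.shape[0]
    A = G.T.copy()
    A[-1, :] = 1.0
    b = np.zeros(n)
    b[-1] = 1.0
    pi = np.linalg.solve(A, b)
    residual = np.abs(pi @ G).max()
    if residual > 1e-10:
        raise ArithmeticError(
            f"stationary solve residual {residual:.3e} exceeds 1e-10")
    if np.any(pi <= 0):
        raise ArithmeticError("stationary distribution has non-positive "
                              "entries; generator may be ill-conditioned")
    return pi


@dataclass(frozen=True)
class RegimePath:
    """Piecewise-constant, right-continuous CTMC realization on [0, horizon].

    ``states[j]`` (1-based labels) holds on ``[jump_times[j], jump_times[j+1])``;
    ``jump_times[0] == 0`` and the last jump time is < horizon.
    """

    jump_times: np.ndarray
    states: np.ndarray
    horizon: float

    def __post_init__(self) -> None:
        jt = np.asarray(self.jump_times, dtype=float)
        st = np.asarray(self.states, dtype=np.int64)
        if jt.size == 0 or jt[0] != 0.0:
            raise ValueError("jump_times must start at 0")
        if jt.size != st.size:
            raise ValueError("jump_times and states must have equal length")
        if np.any(np.diff(jt) <= 0):
            raise ValueError("jump_times must be strictly increasing")
        if jt[-1] >= self.horizon:
            raise ValueError("last jump time must be < horizon")
        if st.size > 1 and np.any(st[1:] == st[:-1]):
            raise ValueError("consecutive states must differ")
        object.__setattr__(self, "jump_times", jt)
        object.__setattr__(self, "states", st)

    @property
    def n_jumps(self) -> int:
        return self.states.size - 1

    def durations(self) -> np.ndarray:
        """Length of each constant segment; sums to the horizon."""
        bounds = np.append(self.jump_times, self.horizon)
        return np.diff(bounds)

    def state_at(self, t: float) -> int:
        """Right-continuous state at time t in [0, horizon]."""
        if t < 0 or t > self.horizon:
            raise ValueError(f"t={t} outside [0, {self.horizon}]")
        idx = int(np.searchsorted(self.jump_times, t, side="right")) - 1
        return int(self.states[idx])


def _as_rng(rng: Union[int, np.random.Generator, None]) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def sample_path(G, r0: int, T: float, rng=None) -> RegimePath:
    """Exact CTMC path: exponential holding times, embedded-chain jumps.

    r0 is the 1-based initial state; a state with zero exit rate (N = 1)
    is absorbing.  Passing the same seeded generator reproduces the path
    bit-for-bit.
    """
    G = validate_generator(G)
    n = G.shape[0]
    if not (1 <= r0 <= n):
        raise ValueError(f"initial state r0={r0} not in 1..{n}")
    if T <= 0:
        raise ValueError(f"horizon T must be positive, got {T}")
    rng = _as_rng(rng)
    times = [0.0]
    states = [int(r0)]
    t = 0.0
    i = r0 - 1
    while True:
        rate = -G[i, i]
        if rate <= 0.0:
            break  # absorbing
        t += rng.exponential(1.0 / rate)
        if t >= T:
            break
        # embedded chain: jump to j != i w.p. G[i, j] / rate
        probs = G[i].copy()
        probs[i] = 0.0
        probs /= rate
        u = rng.random()
        j = int(np.searchsorted(np.cumsum(probs), u, side="right"))
        j = min(j, n - 1)
        times.append(t)
        states.append(j + 1)
        i = j
    return RegimePath(jump_times=np.array(times), states=np.array(states),
                      horizon=float(T))


def occupation_fractions(path: RegimePath, n_states: int | None = None) -> np.ndarray:
    """Fraction of [0, horizon] spent in each state; sums to 1.

    n_states defaults to the largest state label seen on the path.
    """
    if n_states is None:
        n_states = int(path.states.max())
    frac = np.zeros(n_states)
    np.add.at(frac, path.states - 1, path.durations())
    frac /= frac.sum()
    return frac
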