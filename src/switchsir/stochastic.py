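"""Milstein simulation of the regime-switching SIR SDE.

The switching diffusion is simulated in two exact layers: the CTMC regime
path is sampled first (exponential holding times, embedded-chain jumps),
then within each constant-regime segment the SDE is advanced by the
Milstein scheme,

    X' = X + a dt + b dB + (1/2) (b . grad) b (dB^2 - dt),

with the final sub-step of each segment truncated at the jump time so the
parameters switch exactly there.  The noise is scalar (one Brownian motion
drives both components with opposite sign), so the scheme attains strong
order 1 with the analytic correction alone — no Levy areas.  Because the
diffusion is degenerate, S+I evolves by the drift only; the implementation
enforces that cancellation per step.

Boundary policy (discretization artifacts only — the exact solution stays
positive): I below 1e-12 is absorbed to 0 permanently; a step taking
S <= 0 is retried once with a fresh Brownian increment, then clamped to
1e-12 and counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import _kernels, regime_chain
from .model_core import RegimeParameters, SwitchingModel, _check_positive, _check_state

logger = logging.getLogger(__name__)

__all__ = [
    "Trajectory",
    "EnsembleSummary",
    "StrongOrderResult",
    "milstein_step",
    "simulate_path",
    "simulate_ensemble",
    "strong_order_estimate",
    "l1_histogram_distance",
]


def milstein_step(S: float, I: float, p: RegimeParameters, h: float,
                  dt: float, dB: float) -> tuple[float, float]:
    """One raw Milstein update (no boundary policy).

    With sigma = 0 this is the deterministic Euler step; with dB = +-sqrt(dt)
    the correction term vanishes and the update equals Euler-Maruyama.  The
    I-component is computed from the conservation identity
    S'+I' = S+I+(aS+aI) dt, which the degenerate noise satisfies exactly.
    """
    _check_state(S, I)
    if not np.isfinite(dB):
        raise ValueError(f"dB must be finite, got {dB}")
    _check_positive(dt=dt)
    Sn, In = _kernels.milstein_core(S, I, p.Lambda, p.mu, p.beta, p.alpha,
                                    p.gamma, p.epsilon, p.sigma, h, dt, dB)
    return float(Sn), float(In)


@dataclass(frozen=True)
class Trajectory:
    """Uniform-grid sample of one simulated path of (S, I, r)."""

    times: np.ndarray
    S: np.ndarray
    I: np.ndarray
    regime: np.ndarray  # 1-based regime label at each output time
    seed: Optional[int]
    dt: float
    n_s_clamps: int = 0
    absorbed_at: Optional[float] = None  # time I first hit 0, if ever

    @property
    def extinct(self) -> bool:
        return self.I[-1] == 0.0

    def regime_occupation(self, n_states: int) -> np.ndarray:
        """Empirical occupation fractions of the regime column."""
        counts = np.bincount(self.regime - 1, minlength=n_states)
        return counts / counts.sum()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.times, "S": self.S, "I": self.I,
                             "regime": self.regime})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _rng_from(ss: np.random.SeedSequence) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(ss))


def simulate_path(model: SwitchingModel, S0: float, I0: float, r0: int = 1,
                  T: float = 1000.0, dt: float = 0.01,
                  seed: Optional[int] = None,
                  spawn_key: tuple = ()) -> Trajectory:
    """Simulate one path of the switching SDE on a uniform output grid.

    The seed determines both the regime path and the Brownian increments
    (two independent sub-streams), so (model, inputs, seed) fully determines
    every output array.  ``spawn_key`` is the counter-based sub-stream
    selector used by :func:`simulate_ensemble` (path k of an ensemble with
    master seed s is exactly ``simulate_path(..., seed=s, spawn_key=(k,))``).
    """
    _check_state(S0, I0)
    if S0 <= 0:
        raise ValueError(f"S0 must be positive, got {S0}")
    _check_positive(T=T, dt=dt)
    if dt >= T:
        raise ValueError(f"dt={dt} must be smaller than T={T}")
    ss = np.random.SeedSequence(seed, spawn_key=spawn_key)
    chain_ss, brown_ss = ss.spawn(2)
    path = regime_chain.sample_path(model.generator, r0, T,
                                    _rng_from(chain_ss))
    n_steps = int(round(T / dt))
    S = np.empty(n_steps + 1)
    I = np.empty(n_steps + 1)
    reg0 = np.empty(n_steps + 1, dtype=np.int64)
    n_clamps, absorbed_idx = _kernels.simulate_path_kernel(
        float(S0), float(I0), model.param_matrix(), model.h, float(dt),
        n_steps, path.jump_times, path.states - 1, _rng_from(brown_ss),
        S, I, reg0)
    if n_clamps:
        logger.debug("clamped S at the positivity floor on %d sub-step(s)",
                     n_clamps)
    return Trajectory(times=np.arange(n_steps + 1) * dt, S=S, I=I,
                      regime=reg0 + 1, seed=seed, dt=float(dt),
                      n_s_clamps=int(n_clamps),
                      absorbed_at=None if absorbed_idx < 0
                      else float(absorbed_idx * dt))


# ---------------------------------------------------------------------------
# ensembles and empirical-density diagnostics
# ---------------------------------------------------------------------------

#: histogram windows used for the stationarity diagnostic, as fractions of T
STATIONARITY_WINDOWS = {
    "early": (0.0, 0.25),
    "mid_late": (0.5, 0.75),
    "late": (0.75, 1.0),
}


@dataclass(frozen=True)
class EnsembleSummary:
    """Monte-Carlo summary of an ensemble of switching-SDE paths.

    ``histograms`` are per-regime 2-D histograms of (S, I) accumulated over
    the analysis window, each normalized to unit mass (the empirical
    counterpart of the regime-conditional invariant density).
    ``window_counts`` keeps raw per-regime counts for the three stationarity
    windows (fractions of T: early [0, T/4], mid_late [T/2, 3T/4], late
    [3T/4, T]).
    """

    n_paths: int
    extinction_fraction: float
    mean_time_average_I: float
    window: tuple[float, float]
    extinction_floor: float
    s_edges: np.ndarray
    i_edges: np.ndarray
    histograms: dict
    window_counts: dict
    I_final: np.ndarray
    time_average_I: np.ndarray
    n_s_clamps: int = 0

    def stationarity_diagnostic(self) -> dict:
        """L1 distances between empirical densities on time windows.

        Convergence to an invariant density shows as the two late windows
        being closer to each other than an early window is to a late one.
        """
        return {
            "late_vs_late": l1_histogram_distance(
                self.window_counts["mid_late"], self.window_counts["late"]),
            "early_vs_late": l1_histogram_distance(
                self.window_counts["early"], self.window_counts["late"]),
        }

    def to_dict(self) -> dict:
        return {
            "n_paths": self.n_paths,
            "extinction_fraction": self.extinction_fraction,
            "mean_time_average_I": self.mean_time_average_I,
            "window": list(self.window),
            "extinction_floor": self.extinction_floor,
            "s_edges": self.s_edges.tolist(),
            "i_edges": self.i_edges.tolist(),
            "histograms": {str(k): v.tolist()
                           for k, v in self.histograms.items()},
            "stationarity": self.stationarity_diagnostic(),
            "n_s_clamps": self.n_s_clamps,
        }


def l1_histogram_distance(counts_a: dict, counts_b: dict) -> float:
    """L1 distance between two regime-stacked empirical densities.

    Each argument maps regime label -> 2-D count array; counts are jointly
    normalized to unit total mass (sum over regimes and bins), mirroring
    sum_i iint |u_a - u_b| dx dy.
    """
    regimes = sorted(set(counts_a) | set(counts_b))
    a = np.concatenate([np.asarray(counts_a[r], dtype=float).ravel()
                        for r in regimes])
    b = np.concatenate([np.asarray(counts_b[r], dtype=float).ravel()
                        for r in regimes])
    if a.sum() == 0 or b.sum() == 0:
        raise ValueError("empty histogram; cannot form a density")
    return float(np.abs(a / a.sum() - b / b.sum()).sum())


def simulate_ensemble(model: SwitchingModel, S0: float, I0: float,
                      r0: int = 1, T: float = 1000.0, dt: float = 0.01,
                      n_paths: int = 200, seed: Optional[int] = None,
                      extinction_floor: float = 1e-4,
                      window: Optional[tuple[float, float]] = None,
                      bins: int = 40,
                      s_range: tuple[float, float] = (0.0, 3.5),
                      i_range: tuple[float, float] = (0.0, 3.5),
                      ) -> EnsembleSummary:
    """Simulate independent paths and summarize their empirical law.

    Per-path seeds are derived from the master seed by spawn keys, so
    growing n_paths extends the ensemble without changing earlier paths.
    A path counts as extinct when I(T) < extinction_floor.  The analysis
    window defaults to [T/2, T].
    """
    if n_paths < 1:
        raise ValueError(f"n_paths must be >= 1, got {n_paths}")
    if window is None:
        window = (T / 2.0, T)
    w0, w1 = window
    if not (0.0 <= w0 < w1 <= T):
        raise ValueError(f"window {window} not inside [0, {T}]")
    edges_s = np.linspace(*s_range, bins + 1)
    edges_i = np.linspace(*i_range, bins + 1)
    n_regimes = model.n_regimes
    hist = {r: np.zeros((bins, bins)) for r in range(1, n_regimes + 1)}
    win_counts = {name: {r: np.zeros((bins, bins))
                         for r in range(1, n_regimes + 1)}
                  for name in STATIONARITY_WINDOWS}
    I_final = np.empty(n_paths)
    tavg = np.empty(n_paths)
    total_clamps = 0
    for k in range(n_paths):
        traj = simulate_path(model, S0, I0, r0, T, dt, seed=seed,
                             spawn_key=(k,))
        total_clamps += traj.n_s_clamps
        I_final[k] = traj.I[-1]
        sel = (traj.times >= w0) & (traj.times <= w1)
        tavg[k] = traj.I[sel].mean()
        _accumulate(hist, traj, sel, edges_s, edges_i)
        for name, (f0, f1) in STATIONARITY_WINDOWS.items():
            wsel = (traj.times >= f0 * T) & (traj.times <= f1 * T)
            _accumulate(win_counts[name], traj, wsel, edges_s, edges_i)
    histograms = {}
    for r, counts in hist.items():
        mass = counts.sum()
        histograms[r] = counts / mass if mass > 0 else counts
    return EnsembleSummary(
        n_paths=n_paths,
        extinction_fraction=float((I_final < extinction_floor).mean()),
        mean_time_average_I=float(tavg.mean()),
        window=(float(w0), float(w1)),
        extinction_floor=float(extinction_floor),
        s_edges=edges_s, i_edges=edges_i,
        histograms=histograms, window_counts=win_counts,
        I_final=I_final, time_average_I=tavg,
        n_s_clamps=total_clamps)



def _accumulate(store: dict, traj: Trajectory, sel: np.ndarray,
                edges_s: np.ndarray, edges_i: np.ndarray) -> None:
    for r in store:
        m = sel & (traj.regime == r)
        if m.any():
            counts, _, _ = np.histogram2d(traj.S[m], traj.I[m],
                                          bins=(edges_s, edges_i))
            store[r] += counts


# ---------------------------------------------------------------------------
# strong-order diagnostic
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StrongOrderResult:
    """Coupled-refinement strong-convergence fit."""

    order: float
    dts: tuple[float, ...]
    errors: tuple[float, ...]  # mean endpoint error vs the finest resolution


def strong_order_estimate(model: SwitchingModel, S0: float, I0: float,
                          r0: int, T: float, dt_list: Sequence[float],
                          n_paths: int, seed: Optional[int] = None
                          ) -> StrongOrderResult:
    """Estimate the strong convergence order of the path integrator.

    For each sample path one Brownian path and one regime path are frozen on
    the finest grid (regime jump times snapped to that grid so every
    resolution splits its steps at identical, grid-aligned jump times);
    coarse Brownian increments are sums of fine ones.  The returned order is
    the log-log regression slope of the mean endpoint error against dt, the
    finest resolution serving as the reference.
    """
    dts = [float(d) for d in dt_list]
    if len(dts) < 3 or any(b >= a for a, b in zip(dts, dts[1:])):
        raise ValueError("dt_list must be a decreasing sequence of >= 3 steps")
    fine = dts[-1]
    ratios = [d / fine for d in dts]
    if any(abs(r - round(r)) > 1e-9 for r in ratios):
        raise ValueError(f"dt_list {dts} is not nested: every step must be "
                         "an integer multiple of the finest")
    n_sub = [int(round(r)) for r in ratios]
    n_fine = int(round(T / fine))
    if abs(n_fine * fine - T) > 1e-9 * max(1.0, T):
        raise ValueError(f"T={T} is not a whole number of finest steps")
    params = model.param_matrix()
    endpoints = np.empty((len(dts), n_paths, 2))
    for k in range(n_paths):
        ss = np.random.SeedSequence(seed, spawn_key=(k,))
        chain_ss, brown_ss = ss.spawn(2)
        path = regime_chain.sample_path(model.generator, r0, T,
                                        _rng_from(chain_ss))
        jump_idx, jump_states = _snap_jumps(path, fine, n_fine)
        dW = _rng_from(brown_ss).normal(0.0, np.sqrt(fine), n_fine)
        cumW = np.concatenate(([0.0], np.cumsum(dW)))
        for lev, m in enumerate(n_sub):
            endpoints[lev, k] = _kernels.driven_endpoint_kernel(
                float(S0), float(I0), params, model.h, fine, m, cumW,
                jump_idx, jump_states)
    diff = endpoints[:-1] - endpoints[-1]
    errors = np.sqrt((diff ** 2).sum(axis=2)).mean(axis=1)
    slope = np.polyfit(np.log(dts[:-1]),
                       np.log(np.maximum(errors, 1e-300)), 1)[0]
    return StrongOrderResult(order=float(slope), dts=tuple(dts),
                             errors=tuple(float(e) for e in errors))


def _snap_jumps(path: regime_chain.RegimePath, dt_fine: float,
                n_fine: int) -> tuple[np.ndarray, np.ndarray]:
    """Snap jump times to fine-grid indices, dropping collapsed segments."""
    idx = np.round(path.jump_times / dt_fine).astype(np.int64)
    idx = np.clip(idx, 0, n_fine)
    keep_idx = [0]
    keep_state = [int(path.states[0]) - 1]
    for j in range(1, idx.size):
        if idx[j] >= n_fine:
            break
        if idx[j] == keep_idx[-1]:
            keep_state[-1] = int(path.states[j]) - 1  # zero-length segment
        else:
            keep_idx.append(int(idx[j]))
            keep_state.append(int(path.states[j]) - 1)
    return (np.array(keep_idx, dtype=np.int64),
            np.array(keep_state, dtype=np.int64))
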