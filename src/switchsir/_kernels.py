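"""Numba-compiled numerical cores.

Scalar cores (`incidence_core`, `drift_core`, ...) are the single source of
truth for the model's vector field; the Python wrappers in `model_core` and
the path loops below all call them, so unit-level and path-level arithmetic
agree bit-for-bit.

Parameter rows are packed as ``(Lambda, mu, beta, alpha, gamma, epsilon,
sigma)`` — note sigma, not sigma^2, so kernels never take square roots.
Regime indices are 0-based inside kernels; public APIs are 1-based.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# column layout of the packed per-regime parameter matrix
LAM, MU, BETA, ALPHA, GAMMA, EPS, SIGMA = 0, 1, 2, 3, 4, 5, 6

# stepping floor: I below this is absorbed to 0, S below this is clamped
STEP_FLOOR = 1e-12


@njit(cache=True)
def incidence_core(S, I, beta, alpha, h):
    """beta*S^h*I / (S^h + alpha*I^h); 0 on the axes (continuous limit)."""
    if I <= 0.0 or S <= 0.0:
        return 0.0
    Sh = S ** h
    Ih = I ** h
    D = Sh + alpha * Ih
    if D == 0.0:  # both powers underflowed
        return 0.0
    return beta * Sh * I / D


@njit(cache=True)
def drift_core(S, I, Lam, mu, beta, alpha, gamma, eps, h):
    g = incidence_core(S, I, beta, alpha, h)
    aS = Lam - mu * S - g
    aI = g - (mu + gamma + eps) * I
    return aS, aI


@njit(cache=True)
def diffusion_S_core(S, I, sigma, alpha, h):
    """S-component of the diffusion; the I-component is its negative."""
    if I <= 0.0 or S <= 0.0 or sigma == 0.0:
        return 0.0
    Sh = S ** h
    Ih = I ** h
    D = Sh + alpha * Ih
    if D == 0.0:
        return 0.0
    return -sigma * Sh * I / D


@njit(cache=True)
def correction_S_core(S, I, sigma, alpha, h):
    """S-component of the Milstein correction (b . grad) b.

    With b = (-f, +f), f = sigma*S^h*I/(S^h + alpha*I^h):
        cS = f*(df/dS) - f*(df/dI),  cI = -cS.
    Partials are analytic; 0 on the axes by the same continuity convention.
    For h < 1 the S-partial carries S^(h-1), which overflows doubles at
    subnormal S; a non-representable correction is reported as 0 (it is
    unusable for stepping there anyway — see the validity guard).
    """
    if I <= 0.0 or S <= 0.0 or sigma == 0.0:
        return 0.0
    Sh = S ** h
    Ih = I ** h
    D = Sh + alpha * Ih
    if D == 0.0:
        return 0.0
    f = sigma * Sh * I / D
    fS = sigma * I * h * (Sh / S) * alpha * Ih / (D * D)
    fI = sigma * Sh * (D - alpha * h * Ih) / (D * D)
    c = f * (fS - fI)
    if not np.isfinite(c):
        return 0.0
    return c


@njit(cache=True)
def milstein_core(S, I, Lam, mu, beta, alpha, gamma, eps, sigma, h, dt, dB):
    """One raw Milstein update (no boundary policy).

    X' = X + a dt + b dB + 0.5 c (dB^2 - dt).  Because the diffusion is
    degenerate (bI = -bS, cI = -cS) the noise cancels in S+I; the I-update is
    taken from the conservation identity S'+I' = S+I+(aS+aI) dt so the
    cancellation is enforced, not merely approximated.
    """
    aS, aI = drift_core(S, I, Lam, mu, beta, alpha, gamma, eps, h)
    b = diffusion_S_core(S, I, sigma, alpha, h)
    c = correction_S_core(S, I, sigma, alpha, h)
    v = b * dB + 0.5 * c * (dB * dB - dt)
    Sn = S + aS * dt + v
    if v == 0.0:
        In = I + aI * dt
    else:
        In = (S + I + (aS + aI) * dt) - Sn
    return Sn, In


@njit(cache=True)
def _raw_step(S, I, row, h, sub_dt, dB):
    """Milstein substep with the correction-validity guard.

    For h < 1 the diffusion derivative is singular at S = 0 (db/dS ~
    S^(h-1)) while the model legitimately drives S to extremely small
    values, so near the boundary the correction coefficient (b . grad) b
    explodes and the stochastic-Taylor linearization behind Milstein is
    invalid.  The correction is therefore applied only where it is an
    actual correction — |c| sqrt(dt) <= |b| — and the sub-step degrades to
    Euler-Maruyama otherwise (the guard region vanishes as dt -> 0, so the
    strong order away from the degeneracy is unaffected).
    """
    aS, aI = drift_core(S, I, row[LAM], row[MU], row[BETA], row[ALPHA],
                        row[GAMMA], row[EPS], h)
    b = diffusion_S_core(S, I, row[SIGMA], row[ALPHA], h)
    c = correction_S_core(S, I, row[SIGMA], row[ALPHA], h)
    if abs(c) * np.sqrt(sub_dt) > abs(b):
        c = 0.0
    v = b * dB + 0.5 * c * (dB * dB - sub_dt)
    Sn = S + aS * sub_dt + v
    if v == 0.0:
        In = I + aI * sub_dt
    else:
        In = (S + I + (aS + aI) * sub_dt) - Sn
    return Sn, In


@njit(cache=True)
def _policy_step(S, I, row, h, sub_dt, dB, resampled_dB, allow_resample):
    """Milstein substep with the boundary policy applied.

    Returns (S', I', used_resample, clamped):
      * I' < STEP_FLOOR -> absorbed to exactly 0 (caller makes it permanent);
      * S' <= 0 -> retry once with `resampled_dB` (if allowed), then clamp
        to STEP_FLOOR and flag.
    """
    Sn, In = _raw_step(S, I, row, h, sub_dt, dB)
    used = False
    if Sn <= 0.0 and allow_resample:
        Sn, In = _raw_step(S, I, row, h, sub_dt, resampled_dB)
        used = True
    clamped = False
    if Sn <= 0.0:
        Sn = STEP_FLOOR
        clamped = True
    if In < STEP_FLOOR:
        In = 0.0
    return Sn, In, used, clamped


@njit(cache=True)
def simulate_path_kernel(S0, I0, params, h, dt, n_steps,
                         jump_times, jump_states, rng,
                         out_S, out_I, out_regime):
    """Milstein path on the uniform output grid with exact CTMC switching.

    `jump_times`/`jump_states` (0-based states) describe the pre-sampled
    regime path: state jump_states[j] holds on [jump_times[j], jump_times[j+1]).
    Steps of length dt are split at jump times so parameters switch exactly
    there; each sub-increment is N(0, sub_dt).  Returns (n_clamps, absorbed_at)
    where absorbed_at is the output index at which I first became 0 (-1 if
    never).
    """
    S = S0
    I = I0
    seg = 0
    n_seg = jump_times.shape[0]
    n_clamps = 0
    absorbed_at = -1
    out_S[0] = S
    out_I[0] = I
    out_regime[0] = jump_states[0]
    t = 0.0
    for k in range(1, n_steps + 1):
        t_target = k * dt
        while True:
            # next regime jump strictly inside (t, t_target]?
            if seg + 1 < n_seg and jump_times[seg + 1] <= t_target:
                t_next = jump_times[seg + 1]
                switching = True
            else:
                t_next = t_target
                switching = False
            sub_dt = t_next - t
            if sub_dt > 0.0:
                row = params[jump_states[seg]]
                sq = np.sqrt(sub_dt)
                dB = rng.normal(0.0, 1.0) * sq
                dB2 = rng.normal(0.0, 1.0) * sq
                S, I, used, clamped = _policy_step(S, I, row, h, sub_dt, dB,
                                                   dB2, True)
                if clamped:
                    n_clamps += 1
                if I == 0.0 and absorbed_at < 0:
                    absorbed_at = k
            t = t_next
            if switching:
                seg += 1
            else:
                break
        out_S[k] = S
        out_I[k] = I
        out_regime[k] = jump_states[seg]
    return n_clamps, absorbed_at


@njit(cache=True)
def driven_endpoint_kernel(S0, I0, params, h, dt_fine, n_sub,
                           cumW, jump_idx, jump_states):
    """Endpoint of a Milstein path driven by a frozen Brownian path.

    Used by the strong-order diagnostic.  The fine grid has spacing dt_fine;
    the scheme steps with n_sub fine cells per step, splitting at regime
    jumps whose times sit on the fine grid (`jump_idx`, in fine-cell units).
    Brownian increments over [i0, i1) fine cells are cumW[i1]-cumW[i0], so
    refinements share one Brownian path exactly.  No resampling is possible
    in driven mode; S-clamps apply directly.
    """
    n_fine = cumW.shape[0] - 1
    S = S0
    I = I0
    seg = 0
    n_seg = jump_idx.shape[0]
    i = 0
    dummy = 0.0
    while i < n_fine:
        i_target = i + n_sub
        if i_target > n_fine:
            i_target = n_fine
        while True:
            if seg + 1 < n_seg and jump_idx[seg + 1] <= i_target:
                i_next = jump_idx[seg + 1]
                switching = True
            else:
                i_next = i_target
                switching = False
            if i_next > i:
                sub_dt = (i_next - i) * dt_fine
                dB = cumW[i_next] - cumW[i]
                row = params[jump_states[seg]]
                S, I, _, _ = _policy_step(S, I, row, h, sub_dt, dB, dummy,
                                          False)
            i = i_next
            if switching:
                seg += 1
            else:
                break
        # loop advances i to i_target
    return S, I


@njit(cache=True)
def rk4_kernel(S0, I0, Lam, mu, beta, alpha, gamma, eps, h, dt, n_steps,
               out_S, out_I):
    """Classical fixed-step 4th-order integration of the deterministic flow.

    Negative undershoot of I is clamped to 0 (I = 0 is invariant for the
    exact flow); returns (n_clamps, first_nonfinite_step or -1).
    """
    S = S0
    I = I0
    out_S[0] = S
    out_I[0] = I
    n_clamps = 0
    for k in range(1, n_steps + 1):
        k1S, k1I = drift_core(S, I, Lam, mu, beta, alpha, gamma, eps, h)
        k2S, k2I = drift_core(S + 0.5 * dt * k1S, I + 0.5 * dt * k1I,
                              Lam, mu, beta, alpha, gamma, eps, h)
        k3S, k3I = drift_core(S + 0.5 * dt * k2S, I + 0.5 * dt * k2I,
                              Lam, mu, beta, alpha, gamma, eps, h)
        k4S, k4I = drift_core(S + dt * k3S, I + dt * k3I,
                              Lam, mu, beta, alpha, gamma, eps, h)
        S = S + dt * (k1S + 2.0 * k2S + 2.0 * k3S + k4S) / 6.0
        I = I + dt * (k1I + 2.0 * k2I + 2.0 * k3I + k4I) / 6.0
        if I < 0.0:
            I = 0.0
            n_clamps += 1
        if not (np.isfinite(S) and np.isfinite(I)):
            return n_clamps, k
        out_S[k] = S
        out_I[k] = I
    return n_clamps, -1
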