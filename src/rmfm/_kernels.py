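"""Numba-compiled integration kernels.

Hot loops for the Euler–Maruyama integration of the mean-field gating
equations and the explicit-Euler Balloon–Windkessel hemodynamics. These are
implementation details; the public surface lives in `dynamics` and
`hemodynamics`.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# switch to the series expansion of u / (1 - exp(-d*u)) near u = 0
_SING_TOL = 1e-6


@njit(cache=True, fastmath=False)
def _h_scalar(x: float, a: float, b: float, d: float) -> float:
    u = a * x - b
    if abs(u) < _SING_TOL:
        # u/(1-e^{-du}) = 1/d + u/2 + d u^2/12 + O(u^4)
        return 1.0 / d + 0.5 * u + d * u * u / 12.0
    return u / (1.0 - np.exp(-d * u))


@njit(cache=True)
def firing_rate_vec(x: np.ndarray, a: float, b: float, d: float) -> np.ndarray:
    out = np.empty_like(x)
    for i in range(x.size):
        out[i] = _h_scalar(x[i], a, b, d)
    return out


@njit(cache=True)
def integrate_neural(
    S0: np.ndarray,          # (N,) initial gating
    C: np.ndarray,           # (N, N) normalized SC, zero diagonal
    w: np.ndarray,           # (N,) recurrent strengths
    I: np.ndarray,           # (N,) external inputs, nA
    G: float,
    sigma: float,
    J: float,
    a: float,
    b: float,
    d: float,
    tau_s: float,
    r_kin: float,
    dt: float,
    noise: np.ndarray,       # (T, N) standard normals; sigma=0 path ignores it
) -> np.ndarray:
    """Euler–Maruyama integration of dS = [-S/tau + r(1-S)H(x)]dt + sigma dW.

    Returns the (T+1, N) trajectory including the initial state. S is
    clipped to [0, 1] after every step (gating fraction contract).
    """
    T = noise.shape[0]
    N = S0.size
    out = np.empty((T + 1, N))
    S = S0.copy()
    for i in range(N):
        if S[i] < 0.0:
            S[i] = 0.0
        elif S[i] > 1.0:
            S[i] = 1.0
        out[0, i] = S[i]
    sq = sigma * np.sqrt(dt)
    for t in range(T):
        coupling = C @ S          # (N,)
        for i in range(N):
            x = w[i] * J * S[i] + G * J * coupling[i] + I[i]
            drift = -S[i] / tau_s + r_kin * (1.0 - S[i]) * _h_scalar(x, a, b, d)
            s_new = S[i] + dt * drift + sq * noise[t, i]
            if s_new < 0.0:
                s_new = 0.0
            elif s_new > 1.0:
                s_new = 1.0
            S[i] = s_new
            out[t + 1, i] = s_new
    return out


@njit(cache=True)
def integrate_bold(
    Z: np.ndarray,        # (T, N) neural drive (gating trajectory)
    dt: float,
    kappa: float,
    gamma_f: float,
    tau_v: float,
    alpha: float,
    rho: float,
    V0: float,
    k1: float,
    k2: float,
    k3: float,
) -> np.ndarray:
    """Explicit-Euler Balloon–Windkessel, state (s, f, v, q) per region.

    Returns the (T, N) BOLD signal. Raises nothing; the caller checks
    for NaNs (flagged as integration failure).
    """
    T, N = Z.shape
    y = np.empty((T, N))
    inv_alpha = 1.0 / alpha
    for i in range(N):
        s = 0.0
        f = 1.0
        v = 1.0
        q = 1.0
        for t in range(T):
            z = Z[t, i]
            E = 1.0 - (1.0 - rho) ** (1.0 / f)
            v_ia = v ** inv_alpha
            ds = z - kappa * s - gamma_f * (f - 1.0)
            df = s
            dv = (f - v_ia) / tau_v
            dq = (f * E / rho - v_ia * q / v) / tau_v
            s += dt * ds
            f += dt * df
            v += dt * dv
            q += dt * dq
            if f < 1e-6:
                f = 1e-6
            if v < 1e-6:
                v = 1e-6
            y[t, i] = V0 * (k1 * (1.0 - q) + k2 * (1.0 - q / v) + k3 * (1.0 - v))
    return y
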