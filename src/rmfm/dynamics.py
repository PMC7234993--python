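"""Relaxed mean-field neural-mass dynamics on a structural connectome.

Each cortical region i is reduced to a single average synaptic gating
variable S_i in [0, 1] obeying the coupled stochastic differential
equations of the reduced Wong–Wang mean-field lineage:

    dS_i/dt = -S_i / tau_s + r (1 - S_i) H(x_i) + sigma * nu_i(t)
    H(x)    = (a x - b) / (1 - exp(-d (a x - b)))
    x_i     = w_i J S_i + G J sum_j C_ij S_j + I_i

with x_i the total input current (nA), H the population firing rate (Hz),
C the normalized structural connectome, G the global coupling, w_i the
region-specific recurrent excitation–inhibition, and I_i the excitatory
external (subcortical) input. The "relaxed" variant lets w_i and I_i vary
per region; the classical variant holds them constant.

The inter-regional sum runs over j != i (the diagonal of C is zero by
invariant); recurrent self-input is carried exclusively by the w_i term.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from .connectomes import StructuralConnectome

__all__ = [
    "MfmGlobalParams",
    "MfmRegionalParams",
    "NeuralTrajectory",
    "FixedPointResult",
    "firing_rate",
    "firing_rate_derivative",
    "input_current",
    "simulate_neural",
    "find_fixed_point",
]

# Synaptic coupling and sigmoid constants of the mean-field reduction.
# a is a gain in Hz/nA (dimensional consistency of H with x in nA).
DEFAULT_J = 0.2609    # nA
DEFAULT_A = 270.0     # Hz / nA
DEFAULT_B = 108.0     # Hz
DEFAULT_D = 0.154     # s
# Kinetic constants of the NMDA gating reduction (standard reduced
# Wong-Wang values; not free parameters of the inversion).
DEFAULT_TAU_S = 0.1   # s
DEFAULT_R_KIN = 0.641


@dataclass(frozen=True)
class MfmGlobalParams:
    """Global model parameters shared by all regions.

    Attributes
    ----------
    G : float
        Global coupling scaling inter-regional signal flow.
    sigma : float
        Amplitude of the uncorrelated Gaussian noise drive.
    J : float
        Synaptic coupling (nA).
    a, b, d : float
        Firing-rate sigmoid gain (Hz/nA), threshold (Hz) and slope (s).
    tau_s : float
        Synaptic gating time constant (s).
    r_kin : float
        Kinetic rate of the gating equation (dimensionless).
    dt : float
        Euler–Maruyama step (s); must satisfy dt <= tau_s / 10.
    """

    G: float = 1.0
    sigma: float = 0.02
    J: float = DEFAULT_J
    a: float = DEFAULT_A
    b: float = DEFAULT_B
    d: float = DEFAULT_D
    tau_s: float = DEFAULT_TAU_S
    r_kin: float = DEFAULT_R_KIN
    dt: float = 0.001

    def __post_init__(self) -> None:
        for name in ("sigma", "J", "a", "b", "d", "tau_s", "r_kin", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.G < 0:
            raise ValueError("G must be non-negative")
        if self.dt > self.tau_s / 10 + 1e-15:
            raise ValueError(
                f"dt={self.dt} too large for tau_s={self.tau_s}; need dt <= tau_s/10"
            )

    def with_(self, **kw) -> "MfmGlobalParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class MfmRegionalParams:
    """Region-wise parameters: recurrent strength w_i and external input I_i."""

    w: np.ndarray
    I: np.ndarray

    def __post_init__(self) -> None:
        w = np.atleast_1d(np.asarray(self.w, dtype=float))
        I = np.atleast_1d(np.asarray(self.I, dtype=float))
        if w.shape != I.shape or w.ndim != 1:
            raise ValueError("w and I must be 1-D vectors of equal length")
        if not (np.all(np.isfinite(w)) and np.all(np.isfinite(I))):
            raise ValueError("regional parameters must be finite")
        if np.any(w < 0) or np.any(I < 0):
            raise ValueError("regional parameters must be non-negative")
        w.setflags(write=False)
        I.setflags(write=False)
        object.__setattr__(self, "w", w)
        object.__setattr__(self, "I", I)

    @property
    def n_regions(self) -> int:
        return self.w.size

    @classmethod
    def uniform(cls, n: int, w: float, I: float) -> "MfmRegionalParams":
        return cls(w=np.full(n, float(w)), I=np.full(n, float(I)))


@dataclass(frozen=True)
class NeuralTrajectory:
    """Time-by-region synaptic gating trajectory S_i(t), entries in [0, 1]."""

    S: np.ndarray
    dt: float
    burn_in_steps: int = 0

    def __post_init__(self) -> None:
        S = np.asarray(self.S, dtype=float)
        if S.ndim != 2:
            raise ValueError("trajectory must be a T x N matrix")
        if S.size and (S.min() < -1e-12 or S.max() > 1 + 1e-12):
            raise ValueError("gating values must lie in [0, 1]")
        object.__setattr__(self, "S", S)

    @property
    def n_regions(self) -> int:
        return self.S.shape[1]

    @property
    def duration(self) -> float:
        return (self.S.shape[0] - 1) * self.dt


def firing_rate(x, a: float = DEFAULT_A, b: float = DEFAULT_B,
                d: float = DEFAULT_D):
    """Population firing rate H(x) = (a x - b) / (1 - exp(-d (a x - b))).

    Numerically stable across the removable singularity at a x = b, where
    the series limit H = 1/d + u/2 + d u^2/12 (u = a x - b) is used.
    Accepts scalars or arrays; returns Hz.
    """
    x_arr = np.atleast_1d(np.asarray(x, dtype=float))
    out = _kernels.firing_rate_vec(x_arr.ravel(), a, b, d).reshape(x_arr.shape)
    return float(out[0]) if np.isscalar(x) or np.ndim(x) == 0 else out


def firing_rate_derivative(x, a: float = DEFAULT_A, b: float = DEFAULT_B,
                           d: float = DEFAULT_D):
    """dH/dx, used by the Newton polish of the fixed-point solver."""
    u = a * np.asarray(x, dtype=float) - b
    small = np.abs(u) < 1e-6
    u_safe = np.where(small, 1.0, u)
    e = np.exp(-d * u_safe)
    dH_du = np.where(
        small,
        0.5 + d * u / 6.0,
        (1.0 - e - u_safe * d * e) / (1.0 - e) ** 2,
    )
    return a * dH_du


def input_current(
    S: np.ndarray,
    regional: MfmRegionalParams,
    g: MfmGlobalParams,
    C: StructuralConnectome | np.ndarray,
) -> np.ndarray:
    """Total input current x_i = w_i J S_i + G J sum_j C_ij S_j + I_i (nA)."""
    S = np.asarray(S, dtype=float)
    Cw = C.weights if isinstance(C, StructuralConnectome) else np.asarray(C, float)
    if S.shape[0] != regional.n_regions or Cw.shape[0] != S.shape[0]:
        raise ValueError("dimension mismatch between S, parameters and connectome")
    return regional.w * g.J * S + g.G * g.J * (Cw @ S) + regional.I


def _noise_array(n_steps: int, n_regions: int, seed: int) -> np.ndarray:
    return np.random.default_rng(seed).standard_normal((n_steps, n_regions))


def simulate_neural(
    C: StructuralConnectome,
    g: MfmGlobalParams,
    regional: MfmRegionalParams,
    duration: float,
    seed: int = 0,
    init_S: float | np.ndarray = 0.1,
    burn_in: float = 0.0,
    noise: np.ndarray | None = None,
) -> NeuralTrajectory:
    """Integrate the gating equations by Euler–Maruyama.

    Parameters
    ----------
    duration : float
        Total simulated time in seconds, including ``burn_in``.
    seed : int
        Seed for the Gaussian increments; identical (inputs, seed) give a
        bit-identical trajectory.
    init_S : float or array
        Initial gating, scalar broadcast or per-region vector; default 0.1.
    burn_in : float
        Initial transient (s), recorded in ``burn_in_steps`` for downstream
        removal; the returned trajectory still contains it.
    noise : ndarray, optional
        Pre-drawn (n_steps, N) standard normals; overrides ``seed``. Used
        by the inversion's common-random-number scheme.
    """
    N = C.n_regions
    if regional.n_regions != N:
        raise ValueError("regional parameter length does not match connectome")
    n_steps = int(round(duration / g.dt))
    if burn_in > duration:
        raise ValueError("burn_in exceeds duration")
    S0 = np.broadcast_to(np.asarray(init_S, dtype=float), (N,)).copy()
    if noise is None:
        noise = _noise_array(n_steps, N, seed)
    elif noise.shape != (n_steps, N):
        raise ValueError(f"noise must have shape {(n_steps, N)}")
    S = _kernels.integrate_neural(
        S0, np.ascontiguousarray(C.weights), regional.w.copy(), regional.I.copy(),
        g.G, g.sigma, g.J, g.a, g.b, g.d, g.tau_s, g.r_kin, g.dt, noise,
    )
    return NeuralTrajectory(S=S, dt=g.dt, burn_in_steps=int(round(burn_in / g.dt)))


@dataclass(frozen=True)
class FixedPointResult:
    """Equilibrium gating state of the noise-free system."""

    S: np.ndarray
    residual: float
    converged: bool
    n_iterations: int


def find_fixed_point(
    C: StructuralConnectome,
    g: MfmGlobalParams,
    regional: MfmRegionalParams,
    init: np.ndarray | float = 0.1,
    max_iter: int = 5000,
    tol: float = 1e-12,
) -> FixedPointResult:
    """Solve 0 = -S/tau_s + r (1 - S) H(x(S)) for the deterministic skeleton.

    Damped fixed-point iteration on S = tau_s r H / (1 + tau_s r H),
    followed by Newton polishing with the analytic Jacobian. Serves as the
    independent oracle for the sigma=0 integrator. Non-convergence is
    flagged, not raised.
    """
    N = C.n_regions
    S = np.broadcast_to(np.asarray(init, dtype=float), (N,)).astype(float).copy()
    if S.min() < 0 or S.max() > 1:
        raise ValueError("init must lie in [0, 1]")
    tau, r = g.tau_s, g.r_kin

    def drift(S):
        x = input_current(S, regional, g, C)
        return -S / tau + r * (1.0 - S) * firing_rate(x, g.a, g.b, g.d), x

    beta = 0.5
    n_it = 0
    for n_it in range(1, max_iter + 1):
        x = input_current(S, regional, g, C)
        H = firing_rate(x, g.a, g.b, g.d)
        target = tau * r * H / (1.0 + tau * r * H)
        S_new = np.clip((1 - beta) * S + beta * target, 0.0, 1.0)
        if np.max(np.abs(S_new - S)) < 1e-13:
            S = S_new
            break
        S = S_new
    # Newton polish: F(S) = -S/tau + r(1-S)H(x(S))
    Cw = C.weights
    for _ in range(50):
        F, x = drift(S)
        res = float(np.max(np.abs(F)))
        if res < tol:
            break
        H = firing_rate(x, g.a, g.b, g.d)
        Hp = firing_rate_derivative(x, g.a, g.b, g.d)
        dx_dS = g.G * g.J * Cw + np.diag(regional.w * g.J)
        Jac = (-np.eye(N) / tau - np.diag(np.atleast_1d(r * H))
               + (r * (1.0 - S) * Hp)[:, None] * dx_dS)
        try:
            step = np.linalg.solve(Jac, -np.atleast_1d(F))
        except np.linalg.LinAlgError:
            break
        S = np.clip(S + step, 0.0, 1.0)
    F, _ = drift(S)
    res = float(np.max(np.abs(F)))
    return FixedPointResult(S=S, residual=res, converged=res < 1e-10,
                            n_iterations=n_it)
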