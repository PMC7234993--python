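"""Balloon–Windkessel hemodynamic forward model.

Converts regional synaptic gating trajectories into simulated BOLD. Per
region the standard four-state system is integrated with explicit Euler at
the neural step size:

    ds/dt = z - kappa s - gamma_f (f - 1)        vasodilatory signal
    df/dt = s                                     blood inflow
    tau_v dv/dt = f - v^(1/alpha)                 venous volume
    tau_v dq/dt = f E(f)/rho - v^(1/alpha) q / v  deoxyhemoglobin

with E(f) = 1 - (1 - rho)^(1/f) the oxygen extraction, z = S_i(t) the
neural drive, initial state (0, 1, 1, 1), and BOLD readout

    y = V0 (k1 (1 - q) + k2 (1 - q/v) + k3 (1 - v)).

Default constants are the canonical hemodynamic set (kappa=0.65 1/s,
gamma_f=0.41 1/s, tau_v=0.98 s, alpha=0.32, rho=0.34, V0=0.02, k1=7 rho,
k2=2, k3=2 rho - 0.2). The model is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .dynamics import NeuralTrajectory

__all__ = ["HemodynamicParams", "BoldSeries", "simulate_bold",
           "downsample_to_tr", "bold_steady_state"]


class HemodynamicIntegrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class HemodynamicParams:
    kappa: float = 0.65      # signal decay rate, 1/s
    gamma_f: float = 0.41    # flow-dependent elimination, 1/s
    tau_v: float = 0.98      # hemodynamic transit time, s
    alpha: float = 0.32      # vessel stiffness exponent
    rho: float = 0.34        # resting oxygen extraction fraction
    V0: float = 0.02         # resting venous volume fraction
    k1: float = field(default=7 * 0.34)
    k2: float = 2.0
    k3: float = field(default=2 * 0.34 - 0.2)
    tr: float = 2.0          # output sampling interval, s

    def __post_init__(self) -> None:
        for name in ("kappa", "gamma_f", "tau_v", "V0", "tr"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 < self.rho < 1:
            raise ValueError("rho must lie in (0, 1)")


@dataclass(frozen=True)
class BoldSeries:
    """Time-by-region BOLD signal sampled every ``tr`` seconds."""

    y: np.ndarray
    tr: float
    burn_in_steps: int = 0

    def __post_init__(self) -> None:
        y = np.asarray(self.y, dtype=float)
        if y.ndim != 2:
            raise ValueError("BOLD series must be a T x N matrix")
        if not np.all(np.isfinite(y)):
            raise ValueError("BOLD series contains non-finite values")
        object.__setattr__(self, "y", y)

    @property
    def n_regions(self) -> int:
        return self.y.shape[1]


def simulate_bold(traj: NeuralTrajectory, h: HemodynamicParams | None = None
                  ) -> BoldSeries:
    """Integrate the hemodynamic states driven by the gating trajectory.

    Returns a BOLD series at the neural step size (``tr = traj.dt``); use
    :func:`downsample_to_tr` to resample to scan resolution. Raises
    :class:`HemodynamicIntegrationError` naming the first offending region
    if the state diverges.
    """
    h = h or HemodynamicParams()
    Z = np.ascontiguousarray(traj.S)
    y = _kernels.integrate_bold(Z, traj.dt, h.kappa, h.gamma_f, h.tau_v,
                                h.alpha, h.rho, h.V0, h.k1, h.k2, h.k3)
    bad = ~np.isfinite(y)
    if bad.any():
        t, i = np.argwhere(bad)[0]
        raise HemodynamicIntegrationError(
            f"non-finite hemodynamic state in region {i} at step {t}"
        )
    return BoldSeries(y=y, tr=traj.dt, burn_in_steps=traj.burn_in_steps)


def downsample_to_tr(bold: BoldSeries, tr: float) -> BoldSeries:
    """Discard burn-in, then keep every (tr / dt)-th sample."""
    dt = bold.tr
    ratio = tr / dt
    if abs(ratio - round(ratio)) > 1e-9 * max(1.0, ratio):
        raise ValueError(f"tr={tr} is not an integer multiple of dt={dt}")
    stride = int(round(ratio))
    y = bold.y[bold.burn_in_steps:]
    return BoldSeries(y=y[::stride], tr=tr, burn_in_steps=0)


def bold_steady_state(z: float, h: HemodynamicParams | None = None):
    """Closed-form steady state of the hemodynamic system for constant drive.

    Setting the derivatives to zero: s = 0, f = 1 + z / gamma_f,
    v = f^alpha, q = f E(f)/rho * v^(1 - 1/alpha). Returns
    ``(s, f, v, q, y)``. Used as an independent oracle for the integrator.
    """
    h = h or HemodynamicParams()
    f = 1.0 + z / h.gamma_f
    v = f ** h.alpha
    E = 1.0 - (1.0 - h.rho) ** (1.0 / f)
    q = f * E / h.rho * v ** (1.0 - 1.0 / h.alpha)
    y = h.V0 * (h.k1 * (1 - q) + h.k2 * (1 - q / v) + h.k3 * (1 - v))
    return 0.0, f, v, q, y
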