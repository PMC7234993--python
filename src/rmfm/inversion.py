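"""Model inversion: estimate (G, sigma, w_i, I_i) from empirical FC.

Global coupling G, noise amplitude sigma, and the region-specific
recurrent excitation–inhibition w_i and subcortical input I_i are
estimated by maximizing the Pearson similarity between simulated and
empirical functional connectivity.

The scheme alternates an expectation-like step (simulate FC at the current
parameters, with common random numbers so the stochastic objective is a
deterministic function of the parameters) with a maximization-like step (a
damped Gauss–Newton update on the upper-triangle FC residual, using a
finite-difference Jacobian). A proposal is accepted only if the
similarity objective improves; otherwise damping is increased and the
step is retried.

The descent is staged: a first block update frees only the global
parameters and the subcortical inputs I_i (whose FC signature is strong
and well conditioned), then a joint update frees all parameters. Fitting
everything at once from a flat start lets the recurrent weights w_i
absorb the input pattern early — a compensation local optimum separated
from the true basin by a saturated (rejected) region of parameter space;
pinning I first avoids that trap. The best of several random restarts is
returned, together with the raw SC–FC baseline correlation the fit
should exceed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectomes import FunctionalConnectome, StructuralConnectome, normalize_sc
from .dynamics import MfmGlobalParams, MfmRegionalParams, simulate_neural
from .fc import fc_similarity, sc_fc_baseline, upper_triangle, fisher_z, \
    inverse_fisher_z
from .hemodynamics import HemodynamicParams, simulate_bold, downsample_to_tr, \
    HemodynamicIntegrationError

__all__ = ["FitConfig", "FitResult", "objective", "simulate_fc",
           "fit_rmfm", "contrast_ready_params", "realization_seed"]

DEFAULT_BOUNDS = {
    "G": (0.0, 5.0),
    "sigma": (1e-3, 0.1),
    "w": (0.0, 2.0),
    "I": (0.0, 0.5),
}

# Resting-state cortex works in the low-activity branch of the bistable
# gating dynamics; candidates that drive any region's time-mean gating
# above this value are rejected by the inversion (keeps the search on the
# physiological manifold, away from wrong-branch local optima).
SATURATION_GUARD = 0.65


@dataclass(frozen=True)
class FitConfig:
    """Tunable knobs of the inversion.

    ``sim_duration_s`` is the simulated time per objective evaluation
    (including ``burn_in_s``); ``noise_realizations`` simulations with
    distinct, but fixed, noise streams are averaged (Fisher-z mean) per
    evaluation. ``fd_step`` is the finite-difference perturbation as a
    fraction of each parameter's bound width.
    """

    n_outer_iterations: int = 25
    n_random_inits: int = 1
    sim_duration_s: float = 148.0
    burn_in_s: float = 8.0
    base_seed: int = 0
    bounds: dict = field(default_factory=lambda: dict(DEFAULT_BOUNDS))
    fd_step: float = 0.02
    damping: float = 1.0
    tol: float = 1e-6
    noise_realizations: int = 4
    dt: float = 0.01
    tr: float = 2.0
    init_S: float = 0.1
    max_damping_retries: int = 6

    def __post_init__(self) -> None:
        if self.n_outer_iterations < 1:
            raise ValueError("n_outer_iterations must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        for name, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ValueError(f"bounds for {name} must satisfy low < high")
        if self.burn_in_s >= self.sim_duration_s:
            raise ValueError("burn_in_s must be smaller than sim_duration_s")


@dataclass(frozen=True)
class FitResult:
    """Output of :func:`fit_rmfm`.

    ``global_params`` carries the fitted G and sigma; ``regional_params``
    the fitted per-region w and I. ``objective_trace`` is the accepted
    (non-decreasing) similarity per outer iteration; ``baseline`` the raw
    SC–FC correlation; ``param_se`` a linearized Gauss–Newton standard
    error per parameter (same packing order as ``param_names``).
    """

    global_params: MfmGlobalParams
    regional_params: MfmRegionalParams
    objective_trace: np.ndarray
    best_similarity: float
    baseline: float
    converged: bool
    seed_used: int
    parcellation: object = None
    param_se: np.ndarray | None = None
    param_names: tuple = ()
    n_evaluations: int = 0
    config: FitConfig | None = None

    def __post_init__(self) -> None:
        trace = np.asarray(self.objective_trace, dtype=float)
        object.__setattr__(self, "objective_trace", trace)
        if trace.size and not np.isclose(self.best_similarity, trace.max()):
            raise ValueError("best_similarity must equal the trace maximum")
        if trace.size and np.any(np.diff(trace) < -1e-12):
            raise ValueError("objective trace must be non-decreasing")


# ---------------------------------------------------------------------------
# parameter packing: theta = [G, sigma, w_0..w_{N-1}, I_0..I_{N-1}]

def _pack(G: float, sigma: float, w: np.ndarray, I: np.ndarray) -> np.ndarray:
    return np.concatenate([[G, sigma], w, I])


def _unpack(theta: np.ndarray, n: int):
    return float(theta[0]), float(theta[1]), theta[2:2 + n], theta[2 + n:]


def _bound_arrays(bounds: dict, n: int):
    lo = np.concatenate([[bounds["G"][0], bounds["sigma"][0]],
                         np.full(n, bounds["w"][0]), np.full(n, bounds["I"][0])])
    hi = np.concatenate([[bounds["G"][1], bounds["sigma"][1]],
                         np.full(n, bounds["w"][1]), np.full(n, bounds["I"][1])])
    return lo, hi


def realization_seed(base_seed: int, k: int) -> int:
    """Stable per-realization seed derived from the base seed."""
    return int(np.random.SeedSequence([int(base_seed), int(k)])
               .generate_state(1)[0] % (2 ** 31))


class _NoiseCache:
    """Pre-drawn common random numbers, shared across objective calls."""

    def __init__(self) -> None:
        self._store: dict = {}

    def get(self, seed: int, n_steps: int, n_regions: int) -> np.ndarray:
        key = (seed, n_steps, n_regions)
        if key not in self._store:
            rng = np.random.default_rng(seed)
            self._store[key] = rng.standard_normal((n_steps, n_regions))
        return self._store[key]


def simulate_fc(
    theta: np.ndarray,
    sc: StructuralConnectome,
    cfg: FitConfig,
    template: MfmGlobalParams | None = None,
    hemo: HemodynamicParams | None = None,
    noise_cache: _NoiseCache | None = None,
    return_activity: bool = False,
):
    """Forward model: parameters -> simulated FC matrix (r-space).

    Runs the neural and hemodynamic simulations for each fixed noise
    realization, downsamples to the scan TR, computes Pearson FC, and
    averages the realizations in Fisher-z space. With
    ``return_activity=True`` also returns the per-region time-mean gating
    (maximum over realizations), used by the inversion's physiological
    regime guard.
    """
    n = sc.n_regions
    G, sigma, w, I = _unpack(theta, n)
    template = template or MfmGlobalParams()
    g = template.with_(G=G, sigma=sigma, dt=cfg.dt)
    regional = MfmRegionalParams(w=np.clip(w, 0, None), I=np.clip(I, 0, None))
    hemo = hemo or HemodynamicParams(tr=cfg.tr)
    cache = noise_cache or _NoiseCache()
    n_steps = int(round(cfg.sim_duration_s / cfg.dt))
    zs = []
    mean_S = np.zeros(n)
    for k in range(cfg.noise_realizations):
        seed = realization_seed(cfg.base_seed, k)
        noise = cache.get(seed, n_steps, n)
        traj = simulate_neural(sc, g, regional, cfg.sim_duration_s, seed=seed,
                               init_S=cfg.init_S, burn_in=cfg.burn_in_s,
                               noise=noise)
        mean_S = np.maximum(mean_S, traj.S[traj.burn_in_steps:].mean(axis=0))
        bold = simulate_bold(traj, hemo)
        sampled = downsample_to_tr(bold, cfg.tr)
        r = np.corrcoef(sampled.y, rowvar=False)
        np.fill_diagonal(r, 1.0)
        zs.append(fisher_z(np.clip(r, -1, 1)))
    r = inverse_fisher_z(np.mean(zs, axis=0))
    np.fill_diagonal(r, 1.0)
    if return_activity:
        return r, mean_S
    return r


def objective(
    theta: np.ndarray,
    sc: StructuralConnectome,
    emp_fc: FunctionalConnectome,
    cfg: FitConfig,
    noise_cache: _NoiseCache | None = None,
) -> tuple[float, np.ndarray | None]:
    """Similarity objective at ``theta``: Pearson r between the simulated
    and empirical upper-triangle FC. Returns ``(similarity, sim_fc)``;
    a simulation blow-up, or any region saturating out of the
    physiological low-activity regime (time-mean gating above
    ``SATURATION_GUARD``), yields ``(-1.0, None)`` — a rejected step."""
    try:
        sim, mean_S = simulate_fc(theta, sc, cfg, noise_cache=noise_cache,
                                  return_activity=True)
    except (HemodynamicIntegrationError, FloatingPointError, ValueError):
        return -1.0, None
    if np.max(mean_S) > SATURATION_GUARD:
        return -1.0, None
    tri = upper_triangle(sim)
    if np.std(tri) == 0:
        return -1.0, None
    emp_tri = upper_triangle(emp_fc.values)
    return float(np.corrcoef(tri, emp_tri)[0, 1]), sim


def _default_init(bounds: dict, n: int) -> np.ndarray:
    return _pack(0.5, 0.04, np.full(n, 0.5), np.full(n, 0.3)).clip(
        *_bound_arrays(bounds, n))


def _random_init(bounds: dict, n: int, rng: np.random.Generator) -> np.ndarray:
    lo, hi = _bound_arrays(bounds, n)
    centre = _default_init(bounds, n)
    jitter = rng.uniform(-0.15, 0.15, size=centre.size) * (hi - lo)
    return np.clip(centre + jitter, lo, hi)


# Finite-difference scales per parameter block, in natural units of each
# parameter (multiplied by cfg.fd_step). Kept well below the distance to
# the bistable transition in G so the Jacobian never straddles regimes.
_FD_SCALES = {"G": 1.0, "sigma": 0.1, "w": 2.0, "I": 0.5}


def _fd_steps(cfg: FitConfig, n: int) -> np.ndarray:
    return cfg.fd_step * np.concatenate([
        [_FD_SCALES["G"], _FD_SCALES["sigma"]],
        np.full(n, _FD_SCALES["w"]), np.full(n, _FD_SCALES["I"])])


def _standardize_unit(v: np.ndarray) -> np.ndarray:
    """Center and scale to unit Euclidean norm, so that the squared
    residual between two standardized triangles equals 2 (1 - r)."""
    c = v - v.mean()
    nrm = np.linalg.norm(c)
    return c / nrm if nrm > 0 else c


def _gauss_newton(theta0, sc, emp_tri, emp_fc, cfg, noise_cache,
                  free_mask=None):
    """One damped Gauss–Newton descent from theta0. Returns
    (theta, trace, converged, n_evals, J_at_best, resid_at_best).

    The residual is the difference of the standardized upper-triangle FC
    vectors, whose sum of squares is exactly 2 (1 - similarity) — the
    Gauss–Newton direction therefore climbs the same objective the
    acceptance rule checks. Parameters where ``free_mask`` is False are
    held at their theta0 values (their Jacobian column is zeroed, which
    pins the corresponding update coordinate at zero).
    """
    n = sc.n_regions
    lo, hi = _bound_arrays(cfg.bounds, n)
    step_scale = _fd_steps(cfg, n)
    if free_mask is not None:
        step_scale = np.where(free_mask, step_scale, 0.0)
    theta = np.clip(theta0, lo, hi)
    n_evals = 0
    emp_std = _standardize_unit(emp_tri)

    def evaluate(th):
        nonlocal n_evals
        n_evals += 1
        sim_val, sim_fc = objective(th, sc, emp_fc, cfg, noise_cache)
        resid = (None if sim_fc is None
                 else _standardize_unit(upper_triangle(sim_fc)) - emp_std)
        return sim_val, resid

    obj, resid = evaluate(theta)
    trace = [obj]
    lam = cfg.damping
    converged = False
    J = None
    for _ in range(cfg.n_outer_iterations):
        if resid is None:
            break
        m, p = resid.size, theta.size
        J = np.empty((m, p))
        for j in range(p):
            h = step_scale[j]
            if theta[j] + h > hi[j]:
                h = -h
            th = theta.copy()
            th[j] = np.clip(th[j] + h, lo[j], hi[j])
            actual = th[j] - theta[j]
            if actual == 0:
                J[:, j] = 0.0
                continue
            _, resid_j = evaluate(th)
            J[:, j] = 0.0 if resid_j is None else (resid_j - resid) / actual

        # several damped sub-steps reuse one Jacobian; each accepted move
        # must improve the similarity objective (monotone trace contract)
        iteration_gain = 0.0
        for _sub in range(4):
            JtJ = J.T @ J
            Jtr = J.T @ resid
            diag = np.diag(JtJ).copy()
            diag[diag < 1e-12] = 1e-12
            improved = False
            for _retry in range(cfg.max_damping_retries):
                try:
                    delta = np.linalg.solve(JtJ + lam * np.diag(diag), -Jtr)
                except np.linalg.LinAlgError:
                    lam *= 4.0
                    continue
                # expanding line search along the damped direction
                best = None
                for scale in (1.0, 2.0, 4.0):
                    th_new = np.clip(theta + scale * delta, lo, hi)
                    obj_new, resid_new = evaluate(th_new)
                    if obj_new > obj and (best is None or obj_new > best[0]):
                        best = (obj_new, th_new, resid_new)
                    if best is not None and obj_new <= best[0]:
                        break
                if best is not None:
                    gain = best[0] - obj
                    obj, theta, resid = best
                    iteration_gain += gain
                    lam = max(lam / 10.0, 1e-8)
                    improved = True
                    break
                lam *= 4.0
            if not improved or iteration_gain == 0.0:
                break
            if gain < cfg.tol:
                break
        trace.append(obj)
        if 0.0 < iteration_gain < cfg.tol:
            converged = True
            break
        if iteration_gain == 0.0 and lam > 1e8:
            converged = True
            break
    return theta, np.array(trace), converged, n_evals, J, resid


def fit_rmfm(
    sc: StructuralConnectome,
    emp_fc: FunctionalConnectome,
    cfg: FitConfig | None = None,
) -> FitResult:
    """Fit the relaxed mean-field model to an empirical FC matrix.

    The structural connectome is max-normalized if it is not already;
    the empirical FC must be in r-space with non-degenerate off-diagonal
    variance. Returns the best restart's :class:`FitResult`.
    """
    cfg = cfg or FitConfig()
    if emp_fc.space != "r":
        raise ValueError("empirical FC must be in r-space")
    if not sc.normalized:
        sc = normalize_sc(sc)
    emp_tri = upper_triangle(emp_fc.values)
    if np.std(emp_tri) == 0:
        raise ValueError("degenerate empirical FC: zero off-diagonal variance")
    baseline = sc_fc_baseline(sc, emp_fc)
    n = sc.n_regions
    noise_cache = _NoiseCache()
    rng = np.random.default_rng(realization_seed(cfg.base_seed, 10_000))

    # stage 1 frees the globals and the subcortical inputs only; stage 2
    # polishes everything jointly (see module docstring for why).
    stage1_mask = np.zeros(2 + 2 * n, dtype=bool)
    stage1_mask[:2] = True
    stage1_mask[2 + n:] = True

    best = None
    total_evals = 0
    for restart in range(cfg.n_random_inits):
        theta0 = (_default_init(cfg.bounds, n) if restart == 0
                  else _random_init(cfg.bounds, n, rng))
        theta1, trace1, _, n_evals1, _, _ = _gauss_newton(
            theta0, sc, emp_tri, emp_fc, cfg, noise_cache,
            free_mask=stage1_mask)
        theta, trace2, conv, n_evals2, J, resid = _gauss_newton(
            theta1, sc, emp_tri, emp_fc, cfg, noise_cache)
        trace = np.concatenate([trace1, trace2[1:]])
        total_evals += n_evals1 + n_evals2
        if best is None or trace[-1] > best[1][-1]:
            best = (theta, trace, conv, J, resid)

    theta, trace, conv, J, resid = best
    G, sigma, w, I = _unpack(theta, n)
    se = None
    if J is not None and resid is not None:
        m, p = J.shape
        dof = max(m - p, 1)
        s2 = float(resid @ resid) / dof
        cov = s2 * np.linalg.pinv(J.T @ J)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    names = (["G", "sigma"] + [f"w_{i}" for i in range(n)]
             + [f"I_{i}" for i in range(n)])
    return FitResult(
        global_params=MfmGlobalParams().with_(G=G, sigma=sigma, dt=cfg.dt),
        regional_params=MfmRegionalParams(w=w.copy(), I=I.copy()),
        objective_trace=np.maximum.accumulate(trace),
        best_similarity=float(np.max(trace)),
        baseline=baseline,
        converged=conv,
        seed_used=cfg.base_seed,
        parcellation=sc.parcellation,
        param_se=se,
        param_names=tuple(names),
        n_evaluations=total_evals,
        config=cfg,
    )


def contrast_ready_params(fit_a: FitResult, fit_b: FitResult) -> pd.DataFrame:
    """Region-aligned (w, I) pairs for two fitted cohorts, ready for the
    network-normalized parameter contrast."""
    na, nb = fit_a.regional_params.n_regions, fit_b.regional_params.n_regions
    if na != nb:
        raise ValueError(f"parcellation mismatch: {na} vs {nb} regions")
    if fit_a.parcellation is not None and fit_b.parcellation is not None:
        if not np.array_equal(fit_a.parcellation.networks,
                              fit_b.parcellation.networks):
            raise ValueError("parcellation mismatch: different network labels")
    return pd.DataFrame({
        "region_id": np.arange(na),
        "w_a": fit_a.regional_params.w,
        "w_b": fit_b.regional_params.w,
        "I_a": fit_a.regional_params.I,
        "I_b": fit_b.regional_params.I,
    })
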