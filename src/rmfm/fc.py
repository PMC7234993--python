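"""Functional-connectivity computation and comparison.

Pearson correlation matrices from regional time series, Fisher r-to-z
group averaging, the simulated-vs-empirical similarity objective used by
the inversion, the raw structure-function baseline correlation, and
seed-based (thalamo-cortical style) connectivity profiles with optional
global-signal regression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .connectomes import FunctionalConnectome, StructuralConnectome

__all__ = [
    "SeedConnectivityProfile",
    "compute_fc",
    "fisher_z",
    "inverse_fisher_z",
    "group_average_fc",
    "fc_similarity",
    "sc_fc_baseline",
    "seed_fc",
    "upper_triangle",
]

# guards atanh against +-1 from degenerate perfect correlations
_R_CLIP = 1.0 - 1e-7


@dataclass(frozen=True)
class SeedConnectivityProfile:
    """Fisher-z correlations between one seed series and every parcel."""

    z: np.ndarray
    seed_label: str = "seed"
    gsr: bool = False

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=float)
        if not np.all(np.isfinite(z)):
            raise ValueError("seed profile contains non-finite values")
        object.__setattr__(self, "z", z)


def upper_triangle(matrix: np.ndarray) -> np.ndarray:
    """Strictly-upper-triangle entries as a flat vector."""
    m = np.asarray(matrix)
    return m[np.triu_indices_from(m, k=1)]


def _check_series(ts: np.ndarray) -> np.ndarray:
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2:
        raise ValueError("time series must be a T x N matrix")
    if ts.shape[0] < 3:
        raise ValueError("need at least 3 time points")
    sd = ts.std(axis=0)
    if np.any(sd == 0):
        bad = int(np.nonzero(sd == 0)[0][0])
        raise ValueError(f"constant time series in region {bad}")
    return ts


def compute_fc(ts: np.ndarray, parcellation=None) -> FunctionalConnectome | np.ndarray:
    """Pearson correlation matrix of a T x N time-series matrix.

    Returns a validated :class:`FunctionalConnectome` when a parcellation
    is supplied, otherwise the raw N x N array.
    """
    ts = _check_series(ts)
    r = np.corrcoef(ts, rowvar=False)
    r = np.clip(0.5 * (r + r.T), -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    if parcellation is None:
        return r
    return FunctionalConnectome(values=r, parcellation=parcellation, space="r")


def fisher_z(r):
    """Variance-stabilizing transform z = atanh(r), with |r| clipped just
    inside 1 so perfect correlations stay finite."""
    r_arr = np.asarray(r, dtype=float)
    if np.any(np.abs(r_arr) > 1 + 1e-12):
        raise ValueError("correlations must lie in [-1, 1]")
    z = np.arctanh(np.clip(r_arr, -_R_CLIP, _R_CLIP))
    return float(z) if np.ndim(r) == 0 else z


def inverse_fisher_z(z):
    out = np.tanh(np.asarray(z, dtype=float))
    return float(out) if np.ndim(z) == 0 else out


def group_average_fc(fcs: list[FunctionalConnectome]) -> FunctionalConnectome:
    """Group-level connectome: mean in Fisher-z space, back-transformed to r."""
    if not fcs:
        raise ValueError("empty FC list")
    parc = fcs[0].parcellation
    for fc in fcs:
        if fc.space != "r":
            raise ValueError("group averaging expects r-space FC")
        if fc.parcellation.n_regions != parc.n_regions or not np.array_equal(
            fc.parcellation.networks, parc.networks
        ):
            raise ValueError("mixed parcellations in group average")
    zbar = np.mean([fisher_z(fc.values) for fc in fcs], axis=0)
    r = inverse_fisher_z(zbar)
    np.fill_diagonal(r, 1.0)
    return FunctionalConnectome(values=r, parcellation=parc, space="r")


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in correlation input")
    return float(np.corrcoef(x, y)[0, 1])


def fc_similarity(sim: FunctionalConnectome, emp: FunctionalConnectome) -> float:
    """Pearson correlation between the strictly-upper triangles of two FC
    matrices — the objective maximized by the model inversion."""
    if sim.n_regions != emp.n_regions:
        raise ValueError("parcellation mismatch")
    if sim.n_regions < 3:
        raise ValueError("need at least 3 regions")
    return _pearson(upper_triangle(sim.values), upper_triangle(emp.values))


def sc_fc_baseline(sc: StructuralConnectome, emp: FunctionalConnectome) -> float:
    """Raw structure-function coupling: correlation between upper-triangle
    SC weights and FC values. The reference the model fit must exceed."""
    if sc.n_regions != emp.n_regions:
        raise ValueError("parcellation mismatch")
    return _pearson(upper_triangle(sc.weights), upper_triangle(emp.values))


def _regress_out(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """OLS residual of y on [1, x]."""
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def seed_fc(seed_ts: np.ndarray, parcel_ts: np.ndarray, gsr: bool = False,
            seed_label: str = "seed") -> SeedConnectivityProfile:
    """Fisher-z profile of seed-to-parcel Pearson correlations.

    With ``gsr=True`` the mean-across-parcels ("global") signal is first
    regressed out of the seed and every parcel series by OLS, the standard
    global-signal-regression sensitivity analysis.
    """
    seed = np.asarray(seed_ts, dtype=float).ravel()
    ts = _check_series(parcel_ts)
    if seed.size != ts.shape[0]:
        raise ValueError("seed and parcel series lengths differ")
    if seed.std() == 0:
        raise ValueError("constant seed series")
    if gsr:
        gs = ts.mean(axis=1)
        seed = _regress_out(seed, gs)
        ts = np.column_stack([_regress_out(ts[:, i], gs) for i in range(ts.shape[1])])
        if seed.std() == 0 or np.any(ts.std(axis=0) == 0):
            raise ValueError("global-signal regression left a constant series")
    seed_c = seed - seed.mean()
    ts_c = ts - ts.mean(axis=0)
    r = (ts_c.T @ seed_c) / (np.linalg.norm(ts_c, axis=0) * np.linalg.norm(seed_c))
    return SeedConnectivityProfile(z=fisher_z(r), seed_label=seed_label, gsr=gsr)
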