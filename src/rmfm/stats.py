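"""Group-level statistics on parcel-wise features.

The statistical battery applied to subject-by-region feature tables
(cortical-thickness-like, diffusion-like, or seed-connectivity values):
hemisphere pooling by homologue flipping, z-scoring against controls,
covariate-adjusted general linear models with a group contrast,
max-statistic permutation control of the family-wise error rate
(Freedman–Lane scheme), Mahalanobis distance and Hotelling's T2 for
multivariate comparisons, and network-SD-normalized contrasts of fitted
model parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from .connectomes import Parcellation

__all__ = [
    "FeatureTable",
    "ContrastResult",
    "flip_to_ipsilateral",
    "zscore_vs_controls",
    "glm_contrast",
    "permutation_fwe",
    "mahalanobis_d",
    "hotelling_t2",
    "parameter_contrast",
]

GROUPS = ("HC", "GE", "TLE")


@dataclass(frozen=True)
class FeatureTable:
    """Subject-by-region values for one modality, plus per-subject covariates.

    ``covariates`` must contain columns ``group`` (HC/GE/TLE) and ``side``
    (left/right/none); ``age``, ``sex`` and any optional clinical columns
    (drug_response, onset, duration, hippocampal_volume) are used when a
    model requests them.
    """

    values: np.ndarray
    covariates: pd.DataFrame
    parcellation: Parcellation
    modality: str = "feature"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("values must be subjects x regions")
        if not np.all(np.isfinite(v)):
            raise ValueError("feature table contains missing/non-finite cells")
        if v.shape[0] != len(self.covariates):
            raise ValueError("values and covariates row counts differ")
        if v.shape[1] != self.parcellation.n_regions:
            raise ValueError("region count does not match parcellation")
        bad = set(self.covariates["group"]) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown group labels: {bad}")
        object.__setattr__(self, "values", v)

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    def group_mask(self, group: str) -> np.ndarray:
        return (self.covariates["group"] == group).to_numpy()


@dataclass(frozen=True)
class ContrastResult:
    """Per-region t statistics with uncorrected and FWE-corrected p values."""

    t: np.ndarray
    p_uncorrected: np.ndarray
    p_fwe: np.ndarray | None
    df: int
    model_terms: tuple
    contrast: tuple

    def __post_init__(self) -> None:
        p = np.asarray(self.p_uncorrected, float)
        if np.any((p < 0) | (p > 1)):
            raise ValueError("p values must lie in [0, 1]")
        if self.p_fwe is not None:
            pf = np.asarray(self.p_fwe, float)
            if np.any(pf + 1e-12 < p):
                raise ValueError("p_fwe must dominate p_uncorrected")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "region_id": np.arange(self.t.size),
            "t": self.t,
            "p": self.p_uncorrected,
        })
        if self.p_fwe is not None:
            df["p_fwe"] = self.p_fwe
        return df


def flip_to_ipsilateral(ft: FeatureTable) -> FeatureTable:
    """Swap left/right homologous parcels for subjects with ``side=right``.

    Pools patients so lesions align on one (left) hemisphere; subjects with
    side ``left`` or ``none`` are untouched. Requires complete homologue
    pairing; the operation is an involution.
    """
    hom = ft.parcellation.homologue_ids
    if np.any(hom < 0):
        missing = np.nonzero(hom < 0)[0]
        raise ValueError(f"regions without homologue: {missing.tolist()}")
    values = ft.values.copy()
    flip = (ft.covariates["side"] == "right").to_numpy()
    values[flip] = values[flip][:, hom]
    return replace(ft, values=values)


def zscore_vs_controls(ft: FeatureTable, control_group: str = "HC"
                       ) -> FeatureTable:
    """Per-region z-score against the control group (sample SD, ddof=1)."""
    mask = ft.group_mask(control_group)
    if mask.sum() < 3:
        raise ValueError("need at least 3 control subjects")
    mu = ft.values[mask].mean(axis=0)
    sd = ft.values[mask].std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = int(np.nonzero(sd == 0)[0][0])
        raise ValueError(f"zero control SD in region {bad}")
    return replace(ft, values=(ft.values - mu) / sd)


_SEX_CODES = {"M": 0.0, "F": 1.0, "male": 0.0, "female": 1.0}


def _encode_column(cov: pd.DataFrame, term: str) -> np.ndarray:
    col = cov[term]
    if col.dtype == object:
        if term == "sex":
            return col.map(_SEX_CODES).astype(float).to_numpy()
        raise ValueError(f"cannot encode non-numeric covariate {term!r}")
    return col.astype(float).to_numpy()


def _design(ft: FeatureTable, terms, contrast):
    """Build (X, Y, group column index) for the two-group GLM.

    The design is [intercept, covariates..., group indicator]; the
    indicator is 1 for the first group of the contrast, so t > 0 means
    contrast[0] > contrast[1].
    """
    ga, gb = contrast
    keep = ft.group_mask(ga) | ft.group_mask(gb)
    if keep.sum() < 3:
        raise ValueError("too few subjects in contrast groups")
    cov = ft.covariates.loc[keep].reset_index(drop=True)
    Y = ft.values[keep]
    cols = [np.ones(keep.sum())]
    for term in terms:
        cols.append(_encode_column(cov, term))
    cols.append((cov["group"] == ga).to_numpy(dtype=float))
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            f"rank-deficient design; collinear terms among {['intercept', *terms, 'group']}"
        )
    return X, Y, X.shape[1] - 1


def _ols_t(X: np.ndarray, Y: np.ndarray, col: int):
    """t statistic of one design column, vectorized over the regions in Y."""
    n, p = X.shape
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ (X.T @ Y)
    resid = Y - X @ beta
    df = n - p
    sigma2 = np.sum(resid ** 2, axis=0) / df
    se = np.sqrt(np.clip(sigma2 * XtX_inv[col, col], 1e-300, None))
    return beta[col] / se, df


def glm_contrast(ft: FeatureTable, terms=(), contrast=("TLE", "HC"),
                 ) -> ContrastResult:
    """Per-region OLS with covariates and a two-group contrast.

    With no covariates the t statistic reduces exactly to the classical
    pooled-variance two-sample t. p values are two-sided from the t
    distribution on the residual degrees of freedom.
    """
    terms = tuple(terms)
    X, Y, col = _design(ft, terms, contrast)
    t, df = _ols_t(X, Y, col)
    p = 2 * sps.t.sf(np.abs(t), df)
    return ContrastResult(t=t, p_uncorrected=p, p_fwe=None, df=df,
                          model_terms=terms, contrast=tuple(contrast))


def permutation_fwe(ft: FeatureTable, terms=(), contrast=("TLE", "HC"),
                    n_perm: int = 1000, seed: int = 0) -> ContrastResult:
    """Family-wise-error-corrected group contrast by max-|t| permutation.

    Freedman–Lane scheme: the outcome is residualized on the nuisance
    design (intercept + covariates), residual rows are permuted, nuisance
    fits are added back, and the group t statistic is recomputed; the
    maximum |t| across regions per permutation forms the null, giving
    p_fwe_i = (1 + #{max-null >= |t_i|}) / (n_perm + 1).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    terms = tuple(terms)
    X, Y, col = _design(ft, terms, contrast)
    t_obs, df = _ols_t(X, Y, col)
    p_unc = 2 * sps.t.sf(np.abs(t_obs), df)

    Z = np.delete(X, col, axis=1)                  # nuisance design
    Zpinv = np.linalg.pinv(Z)
    gamma = Zpinv @ Y
    fitted = Z @ gamma
    resid = Y - fitted

    n = X.shape[0]
    rng = np.random.default_rng(seed)
    XtX_inv = np.linalg.inv(X.T @ X)
    cgg = XtX_inv[col, col]
    pinvX = XtX_inv @ X.T
    max_null = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(n)
        Ystar = fitted + resid[perm]
        beta = pinvX @ Ystar
        r = Ystar - X @ beta
        sigma2 = np.sum(r ** 2, axis=0) / df
        tb = beta[col] / np.sqrt(np.clip(sigma2 * cgg, 1e-300, None))
        max_null[b] = np.max(np.abs(tb))
    p_fwe = (1 + np.sum(max_null[:, None] >= np.abs(t_obs)[None, :], axis=0)) \
        / (n_perm + 1)
    p_fwe = np.maximum(p_fwe, p_unc)  # enforce corrected >= uncorrected
    return ContrastResult(t=t_obs, p_uncorrected=p_unc, p_fwe=p_fwe, df=df,
                          model_terms=terms, contrast=tuple(contrast))


def mahalanobis_d(subject_features: np.ndarray, control_matrix: np.ndarray,
                  allow_pinv: bool = False) -> float:
    """Mahalanobis distance of one subject from the control distribution.

    sqrt((x - mu)' Sigma^-1 (x - mu)) with mean and covariance (ddof=1)
    estimated from the n_HC x M control matrix. A singular covariance
    raises unless ``allow_pinv`` permits a pseudo-inverse fallback.
    """
    x = np.asarray(subject_features, float).ravel()
    ctrl = np.asarray(control_matrix, float)
    n, m = ctrl.shape
    if x.size != m:
        raise ValueError("feature dimension mismatch")
    if n <= m:
        raise ValueError("need more controls than features")
    mu = ctrl.mean(axis=0)
    cov = np.cov(ctrl, rowvar=False, ddof=1).reshape(m, m)
    d = x - mu
    try:
        sol = np.linalg.solve(cov, d)
        if np.linalg.cond(cov) > 1e12:
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        if not allow_pinv:
            raise ValueError("singular control covariance; set allow_pinv=True")
        sol = np.linalg.pinv(cov) @ d
    return float(np.sqrt(d @ sol))


def hotelling_t2(group_a: np.ndarray, group_b: np.ndarray):
    """Two-sample Hotelling's T2 with pooled covariance.

    Returns ``(T2, F, p)`` where F = T2 (na+nb-M-1) / (M (na+nb-2)) is
    compared against F(M, na+nb-M-1). At M=1 this is exactly the square
    of the two-sample t statistic.
    """
    A = np.atleast_2d(np.asarray(group_a, float))
    B = np.atleast_2d(np.asarray(group_b, float))
    na, m = A.shape
    nb, mb = B.shape
    if m != mb:
        raise ValueError("feature dimension mismatch")
    if na + nb - 2 <= m:
        raise ValueError("too few subjects for the feature dimension")
    diff = A.mean(axis=0) - B.mean(axis=0)
    Sa = np.cov(A, rowvar=False, ddof=1).reshape(m, m)
    Sb = np.cov(B, rowvar=False, ddof=1).reshape(m, m)
    Sp = ((na - 1) * Sa + (nb - 1) * Sb) / (na + nb - 2)
    try:
        sol = np.linalg.solve(Sp, diff)
    except np.linalg.LinAlgError:
        raise ValueError("singular pooled covariance")
    t2 = float((na * nb) / (na + nb) * diff @ sol)
    dfd = na + nb - m - 1
    f = t2 * dfd / (m * (na + nb - 2))
    p = float(sps.f.sf(f, m, dfd))
    return t2, float(f), p


def parameter_contrast(pa: np.ndarray, pb: np.ndarray,
                       networks: np.ndarray) -> np.ndarray:
    """Network-SD-normalized difference of two cohorts' regional parameters.

    d_i = pa_i - pb_i, normalized by the sample SD of d over the regions of
    region i's network. A network whose differences have zero SD yields 0
    for identically-zero differences and NaN otherwise (flagged degenerate).
    Networks with fewer than 2 regions are rejected.
    """
    pa = np.asarray(pa, float)
    pb = np.asarray(pb, float)
    networks = np.asarray(networks)
    if pa.shape != pb.shape or pa.size != networks.size:
        raise ValueError("parameter vectors and network labels must align")
    d = pa - pb
    out = np.empty_like(d)
    for net in np.unique(networks):
        mask = networks == net
        if mask.sum() < 2:
            raise ValueError(f"network {net!r} has fewer than 2 regions")
        sd = d[mask].std(ddof=1)
        if sd == 0:
            out[mask] = 0.0 if np.allclose(d[mask], 0) else np.nan
        else:
            out[mask] = d[mask] / sd
    return out
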