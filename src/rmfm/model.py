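"""Model / Results front end for the relaxed mean-field analysis.

`RelaxedMeanFieldModel` is constructed from the data (a structural
connectome and an empirical functional connectome); `fit()` runs the
inversion and returns a `RmfmResults` carrying the estimated global and
regional parameters, their linearized standard errors, fit diagnostics,
and a `summary()` table. Forward simulation at arbitrary parameters hangs
off the model; simulation at the fitted parameters hangs off the results.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .connectomes import FunctionalConnectome, StructuralConnectome, \
    normalize_sc, read_matrix, read_parcellation
from .dynamics import MfmGlobalParams, MfmRegionalParams
from .inversion import FitConfig, FitResult, fit_rmfm, simulate_fc, _pack

__all__ = ["RelaxedMeanFieldModel", "RmfmResults"]


class RelaxedMeanFieldModel:
    """Whole-brain relaxed mean-field model bound to one (SC, FC) pair.

    Parameters
    ----------
    sc : StructuralConnectome
        Anatomical coupling substrate; max-normalized on construction if
        it is not already.
    emp_fc : FunctionalConnectome
        The empirical (target) functional connectome, r-space.
    config : FitConfig, optional
        Inversion settings; defaults are desk-scale.
    """

    def __init__(self, sc: StructuralConnectome, emp_fc: FunctionalConnectome,
                 config: FitConfig | None = None) -> None:
        if sc.n_regions != emp_fc.n_regions:
            raise ValueError("SC and FC parcel counts differ")
        self.sc = sc if sc.normalized else normalize_sc(sc)
        self.emp_fc = emp_fc
        self.config = config or FitConfig()

    @classmethod
    def from_files(cls, sc_path, fc_path, parcellation_path,
                   config: FitConfig | None = None) -> "RelaxedMeanFieldModel":
        parc = read_parcellation(parcellation_path)
        sc = read_matrix(sc_path, "sc", parc)
        fc = read_matrix(fc_path, "fc", parc)
        return cls(sc, fc, config)

    @property
    def n_regions(self) -> int:
        return self.sc.n_regions

    def simulate(self, global_params: MfmGlobalParams,
                 regional_params: MfmRegionalParams) -> FunctionalConnectome:
        """Forward-simulate FC at the given parameters (model settings for
        duration, step and TR come from ``self.config``)."""
        theta = _pack(global_params.G, global_params.sigma,
                      regional_params.w, regional_params.I)
        r = simulate_fc(theta, self.sc, self.config, template=global_params)
        return FunctionalConnectome(values=np.clip(r, -1, 1),
                                    parcellation=self.sc.parcellation, space="r")

    def fit(self) -> "RmfmResults":
        """Invert the model against the empirical FC."""
        return RmfmResults(self, fit_rmfm(self.sc, self.emp_fc, self.config))


class RmfmResults:
    """Estimates, uncertainties and diagnostics of one model inversion."""

    def __init__(self, model: RelaxedMeanFieldModel, fit: FitResult) -> None:
        self.model = model
        self._fit = fit

    # -- estimates ---------------------------------------------------------
    @property
    def params(self) -> pd.Series:
        """All fitted parameters as a named series (G, sigma, w_i, I_i)."""
        vals = np.concatenate([[self._fit.global_params.G,
                                self._fit.global_params.sigma],
                               self._fit.regional_params.w,
                               self._fit.regional_params.I])
        return pd.Series(vals, index=list(self._fit.param_names))

    @property
    def bse(self) -> pd.Series | None:
        """Linearized Gauss–Newton standard errors (same order as params)."""
        if self._fit.param_se is None:
            return None
        return pd.Series(self._fit.param_se, index=list(self._fit.param_names))

    @property
    def global_params(self) -> MfmGlobalParams:
        return self._fit.global_params

    @property
    def regional_params(self) -> MfmRegionalParams:
        return self._fit.regional_params

    def regional_frame(self) -> pd.DataFrame:
        """Region table of fitted w and I with network labels."""
        parc = self._fit.parcellation
        n = self._fit.regional_params.n_regions
        df = pd.DataFrame({
            "region_id": np.arange(n),
            "w": self._fit.regional_params.w,
            "I": self._fit.regional_params.I,
        })
        if parc is not None:
            order = np.argsort(parc.region_ids)
            df["network"] = parc.networks[order]
            df["hemisphere"] = parc.hemispheres[order]
        if self._fit.param_se is not None:
            df["w_se"] = self._fit.param_se[2:2 + n]
            df["I_se"] = self._fit.param_se[2 + n:]
        return df

    # -- diagnostics -------------------------------------------------------
    @property
    def similarity(self) -> float:
        """Best simulated-vs-empirical FC correlation achieved."""
        return self._fit.best_similarity

    @property
    def baseline(self) -> float:
        """Raw SC–FC correlation the fit should exceed."""
        return self._fit.baseline

    @property
    def objective_trace(self) -> np.ndarray:
        return self._fit.objective_trace

    @property
    def converged(self) -> bool:
        return self._fit.converged

    @property
    def fit_result(self) -> FitResult:
        return self._fit

    def simulate(self) -> FunctionalConnectome:
        """Forward-simulate FC at the fitted parameters."""
        return self.model.simulate(self._fit.global_params,
                                   self._fit.regional_params)

    def summary(self) -> str:
        """Plain-text summary of the inversion."""
        f = self._fit
        n = f.regional_params.n_regions
        lines = [
            "Relaxed Mean-Field Model Inversion".center(62),
            "=" * 62,
            f"{'No. regions:':<28}{n:>10d}",
            f"{'Objective evaluations:':<28}{f.n_evaluations:>10d}",
            f"{'Converged:':<28}{str(f.converged):>10}",
            f"{'FC similarity (fit):':<28}{f.best_similarity:>10.4f}",
            f"{'SC-FC baseline r:':<28}{f.baseline:>10.4f}",
            "-" * 62,
            f"{'Global coupling G:':<28}{f.global_params.G:>10.4f}",
            f"{'Noise amplitude sigma:':<28}{f.global_params.sigma:>10.4f}",
            f"{'mean w (recurrent E/I):':<28}{f.regional_params.w.mean():>10.4f}"
            f"  (sd {f.regional_params.w.std(ddof=1):.4f})",
            f"{'mean I (subcortical, nA):':<28}{f.regional_params.I.mean():>10.4f}"
            f"  (sd {f.regional_params.I.std(ddof=1):.4f})",
            "=" * 62,
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"<RmfmResults n={self._fit.regional_params.n_regions} "
                f"similarity={self.similarity:.3f} baseline={self.baseline:.3f}>")
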