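# rmfm — connectome-informed relaxed mean-field modelling

`rmfm` simulates whole-brain neural dynamics and BOLD functional
connectivity (FC) on a structural connectome (SC) with a relaxed mean-field
neural-mass model, inverts the model to estimate region-specific recurrent
excitation–inhibition (`w_i`) and subcortical input (`I_i`), and runs the
group-level statistical battery used in connectome epilepsy studies —
hemisphere flipping, z-scoring against controls, covariate-adjusted GLM
contrasts with permutation family-wise-error control, Mahalanobis and
Hotelling's T² multivariate tests, and network-SD-normalized parameter
contrasts. Every stage is exercised end to end on synthetic connectomes and
cohorts with known planted ground truth.

## Quick start (Python API)

```python
import numpy as np
from rmfm import (FitConfig, default_cohort_specs, default_global_truth,
                  fit_rmfm, generate_cohort_fc, group_average_fc,
                  make_ground_truth, make_synthetic_sc, normalize_sc)

# 1. Synthetic study: modular mirrored SC + ground-truth regional fields
sc, parc = make_synthetic_sc(n_regions=40, n_networks=4, seed=1)
sc = normalize_sc(sc)
g = default_global_truth()                      # G*, sigma*
truth = make_ground_truth(parc, spec=default_cohort_specs()["HC"], seed=2)

# 2. "Empirical" cohort FC from the forward model
fcs = generate_cohort_fc(sc, g, truth, n_subjects=4,
                         subject_noise_sd=0.0, seed=11)
emp_fc = group_average_fc(fcs)

# 3. Invert: estimate (G, sigma, w_i, I_i) by maximizing FC similarity
fit = fit_rmfm(sc, emp_fc, FitConfig(base_seed=11))
print(fit.best_similarity, fit.baseline)        # fit r vs raw SC-FC r
print(np.corrcoef(fit.regional_params.w, truth.w)[0, 1])
```

The statsmodels-style front end wraps the same computation:

```python
from rmfm import RelaxedMeanFieldModel

model = RelaxedMeanFieldModel(sc, emp_fc, config=FitConfig(base_seed=11))
results = model.fit()
print(results.summary())      # fit diagnostics + parameter overview
results.params                # named series: G, sigma, w_0.., I_0..
results.bse                   # linearized Gauss-Newton standard errors
results.regional_frame()      # per-region table with networks and SEs
```

## Command line

```bash
rmfm run --config run.yaml          # synth -> fit per cohort -> contrast -> stats
rmfm synth --preset tle-vs-ge --out study/ --seed 7
rmfm fit --sc sc.tsv --fc fc_HC.tsv --parc parc.tsv --out fit_HC --seed 11
rmfm contrast --features features_thickness.tsv --covars covars.tsv \
              --model sex,age --groups TLE,HC --nperm 1000 --seed 7
rmfm stats --fit-a fit_TLE.tsv --fit-b fit_HC.tsv --parc parc.tsv
```

`rmfm run` consumes a YAML configuration with a single `base_seed` (per-stage
seeds are derived at fixed offsets) and writes plain-text tables plus a
`manifest.json` recording the config hash, seeds, SHA-256 digests of every
output, and library versions. Re-running the same config reproduces every
output byte for byte. `rmfm.default_config()` returns a complete, runnable
configuration to start from.

## Package layout

| Module | Contents |
| --- | --- |
| `rmfm.connectomes` | `Parcellation`, `StructuralConnectome`, `FunctionalConnectome`, TSV/HDF5 I/O, `normalize_sc` |
| `rmfm.dynamics` | firing-rate function, Euler–Maruyama integrator, fixed-point oracle |
| `rmfm.hemodynamics` | Balloon–Windkessel BOLD model, TR resampling, closed-form steady state |
| `rmfm.fc` | FC computation, Fisher z, group averaging, similarity/baseline, seed FC with optional GSR |
| `rmfm.inversion` | staged damped Gauss–Newton inversion with common random numbers |
| `rmfm.model` | `RelaxedMeanFieldModel` / `RmfmResults` front end |
| `rmfm.stats` | flipping, z-scoring, GLM, permutation FWE, Mahalanobis, Hotelling T², parameter contrasts |
| `rmfm.synthetic` | SC/cohort/feature generators with planted effects |
| `rmfm.pipeline`, `rmfm.cli` | orchestration, manifest, `rmfm` CLI |

See `docs/methods.md` for the model equations, the inversion algorithm, the
synthetic study design, and known limitations.

## Tests and acceptance

```bash
pytest -q                                  # full suite (includes minute-scale fits)
python scripts/acceptance.py --seed 7 --out acceptance.json
```

`tests/test_acceptance.py` holds the seven headline properties (firing-rate
oracles, integrator and hemodynamic correctness, parameter recovery,
TLE/GE dissociation recovery, statistical calibration, FC oracles);
`scripts/acceptance.py` recomputes the corresponding quantities and writes
them to JSON.
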