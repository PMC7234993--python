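# Methods

This document records the model equations, the inversion algorithm, the
synthetic study design, the statistical conventions, and the known
limitations of the `rmfm` package.

## 1. Relaxed mean-field neural dynamics

Each cortical region `i` is reduced to one average synaptic gating variable
`S_i ∈ [0, 1]` obeying the reduced Wong–Wang mean-field equations:

```
dS_i/dt = -S_i/τ_s + r (1 - S_i) H(x_i) + σ ν_i(t)
H(x)    = (a x - b) / (1 - exp(-d (a x - b)))
x_i     = w_i J S_i + G J Σ_{j≠i} C_ij S_j + I_i
```

- `H` is the population firing rate (Hz) with gain `a = 270 Hz/nA`,
  threshold `b = 108 Hz` and slope `d = 0.154 s`. `H` has a removable
  singularity at `a x = b`; the implementation switches to the series limit
  `1/d + u/2 + d u²/12` (`u = a x − b`) near it, so `H(b/a) = 1/d`
  exactly.
- `J = 0.2609 nA` is the synaptic coupling; `C` is the structural
  connectome, max-normalized so its largest entry is 1 (this makes the
  fitted global coupling `G` comparable across connectomes).
- `τ_s = 0.1 s` and `r = 0.641` are the standard kinetic constants of this
  model lineage.
- The "relaxed" variant lets the recurrent strength `w_i` and the
  excitatory subcortical input `I_i` (nA) vary per region; these are the
  quantities the inversion estimates.
- Integration is Euler–Maruyama with reflective clipping of `S` to
  `[0, 1]`; `dt ≤ τ_s/10` is enforced. Identical inputs and seed give
  bit-identical trajectories.

The noise-free skeleton has a fixed-point solver (damped iteration plus
Newton polish) used as an independent oracle for the integrator.

### Bistability and the physiological branch

The gating dynamics are bistable: above a collective ignition threshold
(network-mean input around 0.29 nA at the adopted operating point) regions
jump to a saturated high-activity branch. Resting cortex is modelled on the
low-activity branch, so the inversion rejects any candidate whose simulated
time-mean gating exceeds 0.65 in any region (`SATURATION_GUARD`), treating
it like a simulation failure (objective −1). This keeps the search on the
physiological manifold and away from wrong-branch local optima.

## 2. Hemodynamics

Regional gating drives the standard four-state Balloon–Windkessel system
(vasodilatory signal, inflow, venous volume, deoxyhemoglobin) integrated
with explicit Euler at the neural step, with the canonical constants
κ=0.65 s⁻¹, γ_f=0.41 s⁻¹, τ_v=0.98 s, α=0.32, ρ=0.34, V0=0.02, k1=7ρ,
k2=2, k3=2ρ−0.2. BOLD is `y = V0 (k1(1−q) + k2(1−q/v) + k3(1−v))`,
downsampled to the scan TR (default 2 s) after burn-in removal. The system
has the closed-form constant-input steady state `f = 1 + z/γ_f`,
`v = f^α`, `q = f E(f)/ρ · v^{1−1/α}`, used as a test oracle.

## 3. Functional connectivity

FC is the Pearson correlation matrix of the downsampled BOLD series.
Group averaging is done in Fisher-z space (`atanh`, with r clipped at
±(1−1e−7)) and transformed back. The inversion objective is the Pearson
correlation between the strictly-upper triangles of simulated and empirical
FC; the reference it must beat is the raw SC–FC correlation
(`sc_fc_baseline`). Seed-based profiles correlate one seed series with
every parcel, optionally after OLS regression of the global (mean) signal
out of both.

## 4. Inversion

`fit_rmfm` estimates `θ = (G, σ, w_1..w_N, I_1..I_N)` by maximizing FC
similarity with an EM-flavored alternation:

- **E-like step** — simulate FC at the current parameters. The same
  pre-drawn noise streams (common random numbers keyed by
  `base_seed` × realization index) are reused across all objective
  evaluations, which turns the stochastic objective into a deterministic
  function of θ. `noise_realizations` simulations are averaged in
  Fisher-z space per evaluation.
- **M-like step** — a damped Gauss–Newton update on the residual between
  the standardized (centered, unit-norm) upper-triangle FC vectors, whose
  squared norm is exactly `2(1 − similarity)`. The Jacobian is finite
  differences with per-block step scales; several damped sub-steps reuse
  one Jacobian; each proposal runs a short expanding line search and is
  accepted only if the similarity improves (monotone trace contract),
  otherwise the damping is increased.

**Staged descent.** The descent runs in two stages: stage 1 frees the
globals `(G, σ)` and the inputs `I_i` while the `w_i` stay at their
initial value; stage 2 then frees everything jointly. Fitting all
parameters at once from a flat start lets `w` absorb the input pattern
early — a compensation local optimum that is separated from the true basin
by a saturated (guard-rejected) region of parameter space and that joint
Gauss–Newton cannot escape. Estimating `I` first at pinned `w` avoids the
trap; on the synthetic study this raises recovery of `w` from
r ≈ 0.25 (joint descent) to r ≈ 0.99.

The best of `n_random_inits` restarts is returned together with the
objective trace, the SC–FC baseline, and linearized Gauss–Newton standard
errors from the final Jacobian. `RelaxedMeanFieldModel` /
`RmfmResults` wrap this in a statsmodels-style `fit()` → results object
with `params`, `bse`, and `summary()`.

## 5. Synthetic study design

`make_synthetic_sc` draws a modular, hemispherically mirrored connectome:
contiguous network blocks mirrored across hemispheres, Bernoulli edges
denser within networks, log-normal weights stronger within networks, and
reliably strong homotopic edges; draws are redrawn (up to 10×) until
connected.

The ground-truth operating point is `G* = 0.9`, `σ* = 0.06` with base
regional fields `w = 0.5`, `I = 0.27 nA` plus seeded Gaussian jitter
(SD 0.2 on `w`, 0.03 on `I`). This point keeps every region on the
low-activity branch with moderate gating, which makes both regional fields
identifiable from FC: `w_i` acts through `w_i J S_i`, so its FC signature
vanishes when `S` is tiny, while the ignition threshold bounds the drive
from above. The jitter field is shared across cohorts of one seed, so
between-cohort differences carry exactly the planted network shifts:

- **TLE-like**: `w` +0.15 (limbic) / +0.10 (somatomotor), `I` −0.06 /
  −0.04 nA in the same networks; 40% of patients labelled right-sided.
- **GE-like**: `I` +0.02 nA in limbic and somatomotor, `w` unchanged. The
  GE increase is deliberately network-targeted and small enough to stay
  inside the stability margin to collective ignition; larger or
  whole-brain input increases tip the forward model off the physiological
  branch.

`generate_cohort_fc` simulates each subject on one of the common-random-
number streams of the generation seed — the same derivation the inversion
objective uses. Fitting the cohort's z-space group average with
`base_seed` equal to the generation seed and `noise_realizations` equal to
the subject count therefore targets a deterministic, exactly attainable
optimum (similarity 1 at the truth). The acceptance fixtures use
`subject_noise_sd = 0`, so the group target is exactly the forward model
at the known parameters.

`generate_feature_tables` produces subject×region tables (thickness-like,
FA-like, MD-like, seed-z) with N(0,1) controls and network-localized group
shifts in control-SD units, plus age/sex/side/clinical covariates.

## 6. Group statistics

- **Hemisphere pooling** — subjects labelled `side = right` have each
  region's value swapped with its contralateral homologue (an involution);
  `left`/`none` are untouched.
- **z-scoring** — per region against the control group, sample SD
  (ddof = 1; the package-wide convention).
- **GLM contrast** — per-region OLS on
  `[intercept, covariates…, group indicator]`; with no covariates the
  group t reduces exactly to the pooled-variance two-sample t.
- **Permutation FWE** — Freedman–Lane: residualize the outcome on the
  nuisance design, permute residual rows, add nuisance fits back,
  recompute the group t; the per-permutation max |t| across regions forms
  the null and `p_fwe = (1 + #{max ≥ |t_i|})/(n_perm + 1)`. This
  parcel-level permutation scheme replaces vertex-wise random-field-theory
  FWE, which requires surface geometry that is out of scope.
- **Multivariate** — Mahalanobis distance to the control distribution
  (singular covariance raises unless a pseudo-inverse is explicitly
  allowed) and two-sample Hotelling's T² with pooled covariance and the
  exact F conversion.
- **Parameter contrast** — `Δ_i = (p_a,i − p_b,i) / SD_network(i)` where
  the SD is the sample SD of the region-wise differences across the
  regions of region i's network. Because cohort-level fits provide no
  subject-level spread, this "SD within the corresponding network" is the
  only computable reading; it is scale-calibrated per network, so planted
  shifts appear as large |Δ| in shifted networks.

## 7. Statistical calibration

The acceptance battery verifies, under seeded simulation:
family-wise error of the max-|t| permutation test within [0.03, 0.07]
(200 global-null replicates, 500 permutations each); Hotelling type-I
error within [0.04, 0.06] (2000 null replicates, M=2, n=30+30);
T² = t² at M=1 to 1e−10; Mahalanobis = Euclidean under identity
covariance to 1e−12.

## 8. Known limitations

- **Subject-level parameter jitter defeats cohort-average recovery.** With
  `subject_noise_sd > 0` the group-average FC is no longer the forward
  model of any single parameter field, and at desk-scale simulation
  lengths the fit of the regional `w` field degrades sharply (the `I`
  field is more robust). The shipped study therefore plants cohort
  differences in the ground-truth fields and keeps subject jitter at zero
  for recovery scoring; subject jitter remains available for generating
  realistic spread in non-recovery analyses.
- **SC–FC baseline.** The synthetic study's raw SC–FC correlation is
  ≈ 0.30 at the adopted operating point (the identifiable regime); the
  baseline is reported by every fit rather than assumed.
- **Desk-scale defaults.** Simulation length (148 s per evaluation,
  4 noise realizations), 40 regions, and a single default start are chosen
  so a full three-cohort fit runs in minutes on one CPU; all are
  configurable.
- Fits are cohort-level (one fit per group-average SC/FC pair); there is
  no subject-level or hierarchical fitting, no delays on edges, and no
  scanner noise model beyond the neural σ.
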