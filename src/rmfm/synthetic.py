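"""Synthetic connectomes, cohorts, and feature tables with known truth.

Generates every input the pipeline needs, so simulation, inversion and the
statistical battery can be validated end-to-end against planted ground
truth: modular structural connectomes with hemispheric mirroring, regional
parameter fields for HC / GE / TLE-like cohorts encoding the qualitative
dissociation under study (TLE-like: reduced subcortical input and raised
recurrent excitation–inhibition confined to limbic/somatomotor networks;
GE-like: raised subcortical input in those same networks, recurrent
strength unchanged),
cohort FC via the forward model, and subject-by-region feature tables with
network-localized group effects.

All generators are pure functions of (arguments, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components

from .connectomes import Parcellation, StructuralConnectome, FunctionalConnectome, \
    normalize_sc
from .dynamics import MfmGlobalParams, MfmRegionalParams
from .inversion import DEFAULT_BOUNDS, FitConfig, realization_seed, simulate_fc, \
    _pack
from .stats import FeatureTable

__all__ = [
    "CohortSpec",
    "DEFAULT_NETWORKS",
    "default_cohort_specs",
    "default_global_truth",
    "make_synthetic_sc",
    "make_ground_truth",
    "generate_cohort_fc",
    "generate_feature_tables",
    "make_seed_series",
]

DEFAULT_NETWORKS = ("limbic", "somatomotor", "default", "control")

# Regional spread of the ground-truth parameter fields (gives the inversion
# a signal to recover); additive Gaussian, clipped to the inversion bounds.
W_JITTER_SD = 0.2
I_JITTER_SD = 0.03


def default_global_truth() -> MfmGlobalParams:
    """Ground-truth global parameters of the synthetic study.

    The operating point (G = 0.9, sigma = 0.06, with the base regional
    fields w = 0.5, I = 0.27 nA) keeps every region on the low-activity
    branch with moderate gating (time-mean S up to about 0.2), which is
    what makes both regional fields identifiable from FC: the recurrent
    weights act through w*J*S_i, so their FC signature vanishes when S is
    tiny, while the collective ignition to the saturated branch (at a
    network-mean input near 0.29 nA) bounds the drive from above. The
    point sits far enough below ignition that the cohort shifts the
    generators plant (including the GE-like +0.02 nA input increase)
    remain on the same branch.
    """
    return MfmGlobalParams(G=0.9, sigma=0.06, dt=0.01)


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for one cohort's ground-truth regional parameters.

    ``w_shift`` / ``i_shift`` map network labels to additive offsets of the
    recurrent strength (dimensionless) and the subcortical input (nA);
    unlisted networks get zero shift. ``side_fraction`` is the fraction of
    patients labelled with a right-sided focus (exercises homologue
    flipping).
    """

    name: str
    w_shift: dict = field(default_factory=dict)
    i_shift: dict = field(default_factory=dict)
    n_subjects: int = 20
    subject_noise_sd: float = 0.01
    side_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.n_subjects < 3:
            raise ValueError("n_subjects must be >= 3")
        for d in (self.w_shift, self.i_shift):
            if not all(np.isfinite(list(d.values())) if d else [True]):
                raise ValueError("shifts must be finite")


def default_cohort_specs() -> dict[str, CohortSpec]:
    """The three study cohorts with the planted effect directions."""
    return {
        "HC": CohortSpec(name="HC"),
        "TLE": CohortSpec(
            name="TLE",
            w_shift={"limbic": 0.15, "somatomotor": 0.10},
            i_shift={"limbic": -0.06, "somatomotor": -0.04},
            side_fraction=0.4,
        ),
        # The GE-like input increase targets the same networks the TLE
        # contrast is evaluated in, and its size (+0.02 nA) fits inside the
        # stability margin to the collective ignition of the saturated
        # branch (see default_global_truth); larger or whole-brain input
        # increases tip the forward model off the physiological branch.
        "GE": CohortSpec(
            name="GE",
            w_shift={},
            i_shift={"limbic": 0.02, "somatomotor": 0.02},
        ),
    }


def _mirrored_parcellation(n_regions: int, n_networks: int,
                           network_names=None) -> Parcellation:
    half = n_regions // 2
    per_net = half // n_networks
    names = list(network_names or DEFAULT_NETWORKS)[:n_networks]
    if len(names) < n_networks:
        names += [f"net{k}" for k in range(len(names), n_networks)]
    networks = np.array(
        [names[min(i // per_net, n_networks - 1)] for i in range(half)] * 2,
        dtype=object,
    )
    hemis = np.array(["left"] * half + ["right"] * half, dtype=object)
    hom = np.concatenate([np.arange(half) + half, np.arange(half)])
    region_names = np.array(
        [f"{networks[i]}_{'L' if i < half else 'R'}_{i % half}"
         for i in range(n_regions)], dtype=object)
    return Parcellation(
        region_ids=np.arange(n_regions),
        names=region_names,
        hemispheres=hemis,
        networks=networks,
        homologue_ids=hom,
    )


def make_synthetic_sc(
    n_regions: int = 40,
    n_networks: int = 4,
    p_within: float = 0.6,
    p_between: float = 0.15,
    weight_scale: float = 1.0,
    seed: int = 0,
    network_names=None,
    max_redraws: int = 10,
) -> tuple[StructuralConnectome, Parcellation]:
    """Modular, hemispherically mirrored random structural connectome.

    Regions split into left/right halves with symmetric homologue pairing;
    networks are contiguous blocks mirrored across hemispheres. Edges are
    Bernoulli (denser within networks), weights log-normal and stronger
    within networks, with reliable homotopic edges between homologue pairs.
    Redraws up to ``max_redraws`` times if the graph is disconnected.
    """
    if n_regions % 2 or n_regions < 2 * n_networks:
        raise ValueError("n_regions must be even and >= 2 * n_networks")
    if n_networks < 2 or (n_regions // 2) % n_networks:
        raise ValueError(
            "n_networks must be >= 2 and divide each hemisphere's region count"
        )
    parc = _mirrored_parcellation(n_regions, n_networks, network_names)
    nets = parc.networks
    rng = np.random.default_rng(seed)
    for _ in range(max_redraws):
        W = np.zeros((n_regions, n_regions))
        for i in range(n_regions):
            for j in range(i + 1, n_regions):
                within = nets[i] == nets[j]
                if parc.homologue_ids[i] == j:
                    p, boost = 0.9, 3.0
                elif within:
                    p, boost = p_within, 2.0
                else:
                    p, boost = p_between, 1.0
                if rng.uniform() < p:
                    W[i, j] = W[j, i] = boost * rng.lognormal(0.0, 0.6)
        W *= weight_scale
        n_comp, _ = connected_components((W > 0).astype(int), directed=False)
        if n_comp == 1:
            sc = StructuralConnectome(weights=W, parcellation=parc)
            return sc, parc
    raise RuntimeError(
        f"connectome disconnected after {max_redraws} redraws; raise p_between"
    )


def make_ground_truth(
    parcellation: Parcellation,
    base_w: float = 0.5,
    base_I: float = 0.27,
    spec: CohortSpec | None = None,
    seed: int = 0,
    w_jitter_sd: float = W_JITTER_SD,
    i_jitter_sd: float = I_JITTER_SD,
    bounds: dict | None = None,
) -> MfmRegionalParams:
    """Ground-truth regional parameter field for one cohort.

    w_i = base_w + w_shift(network(i)) + jitter, and likewise for I_i,
    clipped to the inversion bounds. The jitter field is drawn once per
    (parcellation, seed) and shared across cohorts of the same seed, so
    between-cohort differences carry exactly the planted network shifts.
    Errors if the shifts push more than 10% of regions out of bounds.
    """
    spec = spec or CohortSpec(name="HC")
    bounds = bounds or DEFAULT_BOUNDS
    for net in list(spec.w_shift) + list(spec.i_shift):
        if net not in set(parcellation.networks):
            raise ValueError(f"network {net!r} not in parcellation")
    n = parcellation.n_regions
    rng = np.random.default_rng(seed)
    w = base_w + rng.normal(0.0, w_jitter_sd, size=n)
    I = base_I + rng.normal(0.0, i_jitter_sd, size=n)
    for i, net in enumerate(parcellation.networks[np.argsort(parcellation.region_ids)]):
        w[i] += spec.w_shift.get(net, 0.0)
        I[i] += spec.i_shift.get(net, 0.0)
    (w_lo, w_hi), (i_lo, i_hi) = bounds["w"], bounds["I"]
    out_frac = np.mean((w < w_lo) | (w > w_hi) | (I < i_lo) | (I > i_hi))
    if out_frac > 0.10:
        raise ValueError(
            f"shifts push {out_frac:.0%} of regions outside the bounds"
        )
    return MfmRegionalParams(w=np.clip(w, w_lo, w_hi), I=np.clip(I, i_lo, i_hi))


def generate_cohort_fc(
    sc: StructuralConnectome,
    global_params: MfmGlobalParams,
    regional_params: MfmRegionalParams,
    n_subjects: int = 4,
    subject_noise_sd: float = 0.01,
    seed: int = 0,
    sim: FitConfig | None = None,
) -> list[FunctionalConnectome]:
    """Per-subject FC from the forward model with jittered regional fields.

    Subject k's noise stream is the k-th common-random-number stream of
    ``seed``, the same derivation the inversion objective uses; fitting
    with ``base_seed=seed`` and ``noise_realizations=n_subjects`` therefore
    targets the cohort average under matched noise, which makes synthetic
    recovery a well-posed deterministic problem.
    """
    sim = sim or FitConfig(base_seed=seed)
    if not sc.normalized:
        sc = normalize_sc(sc)
    n = sc.n_regions
    fcs = []
    for k in range(n_subjects):
        rng = np.random.default_rng(realization_seed(seed, 50_000 + k))
        w = regional_params.w + rng.normal(0.0, subject_noise_sd, n)
        I = regional_params.I + rng.normal(0.0, 0.4 * subject_noise_sd, n)
        theta = _pack(global_params.G, global_params.sigma,
                      np.clip(w, 0, None), np.clip(I, 0, None))
        cfg_k = FitConfig(
            base_seed=seed, noise_realizations=1,
            sim_duration_s=sim.sim_duration_s, burn_in_s=sim.burn_in_s,
            dt=sim.dt, tr=sim.tr, init_S=sim.init_S,
        )
        # subject k rides noise stream k of `seed`
        r = _simulate_fc_stream(theta, sc, cfg_k, stream=k)
        fcs.append(FunctionalConnectome(values=r, parcellation=sc.parcellation,
                                        space="r"))
    return fcs


def _simulate_fc_stream(theta, sc, cfg: FitConfig, stream: int) -> np.ndarray:
    """Simulate FC using noise stream ``stream`` of cfg.base_seed."""
    from .dynamics import simulate_neural
    from .hemodynamics import HemodynamicParams, simulate_bold, downsample_to_tr

    n = sc.n_regions
    G, sigma = float(theta[0]), float(theta[1])
    w, I = theta[2:2 + n], theta[2 + n:]
    g = MfmGlobalParams().with_(G=G, sigma=sigma, dt=cfg.dt)
    seed = realization_seed(cfg.base_seed, stream)
    traj = simulate_neural(sc, g, MfmRegionalParams(w=w, I=I),
                           cfg.sim_duration_s, seed=seed,
                           init_S=cfg.init_S, burn_in=cfg.burn_in_s)
    bold = simulate_bold(traj, HemodynamicParams(tr=cfg.tr))
    sampled = downsample_to_tr(bold, cfg.tr)
    r = np.corrcoef(sampled.y, rowvar=False)
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1, 1)


def generate_feature_tables(
    parcellation: Parcellation,
    effects: dict | None = None,
    n_per_group: int = 20,
    seed: int = 0,
    cohort_specs: dict[str, CohortSpec] | None = None,
    modalities=("thickness", "fa", "md", "seed_z"),
    age_slope: float = 0.0,
) -> dict[str, FeatureTable]:
    """Subject-by-region feature tables with network-localized group shifts.

    ``effects[modality][group][network]`` gives the planted shift in
    control-SD units. Controls are N(0, 1) per region; the default effect
    map plants limbic/somatomotor decreases of thickness-like and FA-like
    values and MD-like increases in the TLE-like cohort.
    """
    if effects is None:
        effects = {
            "thickness": {"TLE": {"limbic": -0.8, "somatomotor": -0.5}},
            "fa": {"TLE": {"limbic": -1.0, "somatomotor": -0.6}},
            "md": {"TLE": {"limbic": 0.9, "somatomotor": 0.5}},
            "seed_z": {"TLE": {"limbic": -0.7}, "GE": {"default": 0.5}},
        }
    cohort_specs = cohort_specs or default_cohort_specs()
    n_regions = parcellation.n_regions
    order = np.argsort(parcellation.region_ids)
    nets = parcellation.networks[order]
    rng = np.random.default_rng(seed)

    rows = []
    for group in ("HC", "GE", "TLE"):
        spec = cohort_specs.get(group, CohortSpec(name=group))
        for s in range(n_per_group):
            side = "none"
            if group == "TLE":
                side = "right" if rng.uniform() < spec.side_fraction else "left"
            rows.append({
                "subject_id": f"{group}_{s:03d}",
                "group": group,
                "age": float(rng.uniform(18, 60)),
                "sex": "F" if rng.uniform() < 0.5 else "M",
                "side": side,
                "drug_response": int(rng.uniform() < 0.5) if group != "HC" else 0,
                "onset": float(rng.uniform(5, 30)) if group != "HC" else np.nan,
                "duration": float(rng.uniform(1, 25)) if group != "HC" else np.nan,
                "hippocampal_volume": float(
                    rng.normal(-0.8 if group == "TLE" else 0.0, 1.0)),
            })
    covars = pd.DataFrame(rows)
    covars["onset"] = covars["onset"].fillna(0.0)
    covars["duration"] = covars["duration"].fillna(0.0)

    tables = {}
    for modality in modalities:
        values = rng.standard_normal((len(covars), n_regions))
        if age_slope:
            values += age_slope * (covars["age"].to_numpy()[:, None] - 39.0)
        for group, by_net in effects.get(modality, {}).items():
            gmask = (covars["group"] == group).to_numpy()
            for net, shift in by_net.items():
                values[np.ix_(gmask, nets == net)] += shift
        tables[modality] = FeatureTable(values=values, covariates=covars,
                                        parcellation=parcellation,
                                        modality=modality)
    return tables


def make_seed_series(parcel_ts: np.ndarray, source_regions, noise_sd: float = 0.2,
                     seed: int = 0) -> np.ndarray:
    """Subcortical-seed analogue: a noisy mixture of selected parcel series.

    Emulates a thalamic seed whose activity partially drives (or reflects)
    a subset of cortical parcels, for exercising seed-based connectivity.
    """
    ts = np.asarray(parcel_ts, float)
    rng = np.random.default_rng(seed)
    mix = ts[:, list(source_regions)].mean(axis=1)
    return mix + noise_sd * mix.std() * rng.standard_normal(ts.shape[0])
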