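"""End-to-end orchestration: synth -> fit per cohort -> contrast -> stats.

`run_full_pipeline` drives the whole analysis from a single YAML/dict
config with one base seed; per-stage seeds are derived at fixed offsets so
a run is fully reproducible. Every stage writes plain-text tables into the
configured output directory, and a `RunManifest` records the config hash,
seeds, output paths with SHA-256 digests, and library versions. A stage
failure aborts with the stage name after writing the partial manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .connectomes import write_matrix, write_parcellation
from .fc import group_average_fc
from .inversion import FitConfig, FitResult, fit_rmfm, contrast_ready_params
from .stats import (FeatureTable, flip_to_ipsilateral, parameter_contrast,
                    permutation_fwe, zscore_vs_controls)
from .synthetic import (default_cohort_specs, default_global_truth,
                        generate_cohort_fc, generate_feature_tables,
                        make_ground_truth, make_synthetic_sc)

__all__ = ["RunManifest", "PipelineError", "run_full_pipeline",
           "default_config", "validate_config"]

logger = logging.getLogger("rmfm.pipeline")

# fixed per-stage seed offsets from the config's base seed
_SEED_OFFSETS = {
    "sc": 0,
    "truth": 1,
    "cohort_fc": 2,
    "features": 3,
    "permutation": 4,
}

_REQUIRED_KEYS = {
    "base_seed": int,
    "out_dir": str,
    "synth": dict,
    "fit": dict,
    "stats": dict,
}


class PipelineError(RuntimeError):
    """Raised when a stage fails; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunManifest:
    """Record of one pipeline run (see module docstring)."""

    config_hash: str
    base_seed: int
    stage_seeds: dict
    outputs: dict = field(default_factory=dict)
    digests: dict = field(default_factory=dict)
    versions: dict = field(default_factory=dict)
    completed_stages: list = field(default_factory=list)
    status: str = "running"

    def record(self, stage: str, paths: list[Path]) -> None:
        self.outputs[stage] = [str(p) for p in paths]
        for p in paths:
            self.digests[str(p)] = _sha256(p)
        self.completed_stages.append(stage)

    def to_dict(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "base_seed": self.base_seed,
            "stage_seeds": self.stage_seeds,
            "outputs": self.outputs,
            "digests": self.digests,
            "versions": self.versions,
            "completed_stages": self.completed_stages,
            "status": self.status,
        }

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True)
                        + "\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def default_config() -> dict:
    """A complete, runnable configuration (desk-scale durations)."""
    return {
        "base_seed": 7,
        "out_dir": "rmfm_run",
        "synth": {
            "preset": "tle-vs-ge",
            "n_regions": 40,
            "n_networks": 4,
            "n_subjects_fc": 4,
            "subject_noise_sd": 0.0,
            "n_per_group_features": 20,
        },
        "fit": {
            "sim_duration_s": 148.0,
            "burn_in_s": 8.0,
            "noise_realizations": 4,
            "n_outer_iterations": 25,
            "dt": 0.01,
            "tr": 2.0,
            "bounds": {"G": [0.0, 5.0], "sigma": [1e-3, 0.1],
                       "w": [0.0, 2.0], "I": [0.0, 0.5]},
        },
        "contrast": {"networks": ["limbic", "somatomotor"]},
        "stats": {
            "modality": "thickness",
            "groups": ["TLE", "HC"],
            "model": ["sex", "age"],
            "n_perm": 500,
        },
    }


def validate_config(config: dict) -> dict:
    """Schema check; raises ValueError before any compute on bad config."""
    if not isinstance(config, dict):
        raise ValueError("config must be a mapping")
    for key, typ in _REQUIRED_KEYS.items():
        if key not in config:
            raise ValueError(f"config missing required key {key!r}")
        if not isinstance(config[key], typ):
            raise ValueError(f"config key {key!r} must be {typ.__name__}")
    if "bounds" not in config["fit"]:
        raise ValueError("config missing fit.bounds")
    bounds = config["fit"]["bounds"]
    for name in ("G", "sigma", "w", "I"):
        if name not in bounds:
            raise ValueError(f"fit.bounds missing entry {name!r}")
        lo, hi = bounds[name]
        if not lo < hi:
            raise ValueError(f"fit.bounds[{name!r}] must satisfy low < high")
    if int(config["base_seed"]) < 0 or int(config["base_seed"]) >= 2 ** 31 - 5:
        raise ValueError("base_seed must be in [0, 2^31 - 5)")
    return config


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    return validate_config(config)


def _config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()


def _fit_config(config: dict, base_seed: int) -> FitConfig:
    fc = dict(config["fit"])
    bounds = {k: tuple(v) for k, v in fc.pop("bounds").items()}
    return FitConfig(base_seed=base_seed, bounds=bounds, **fc)


def _write_frame(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_full_pipeline(config, log_level: int | None = None) -> RunManifest:
    """Run synth -> fit -> contrast -> stats from a config path or dict."""
    if log_level is not None:
        logger.setLevel(log_level)
    cfg = _load_config(config)
    base_seed = int(cfg["base_seed"])
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seeds = {k: base_seed + off for k, off in _SEED_OFFSETS.items()}
    manifest = RunManifest(
        config_hash=_config_hash(cfg),
        base_seed=base_seed,
        stage_seeds=seeds,
        versions={"rmfm": __version__, "numpy": np.__version__,
                  "pandas": pd.__version__},
    )
    manifest_path = out / "manifest.json"
    try:
        sc, parc, truths, group_fcs, tables = _stage_synth(cfg, seeds, out,
                                                           manifest)
        fits = _stage_fit(cfg, seeds, out, manifest, sc, group_fcs)
        _stage_contrast(cfg, out, manifest, parc, fits)
        _stage_stats(cfg, seeds, out, manifest, tables)
    except PipelineError:
        manifest.status = "failed"
        manifest.write(manifest_path)
        raise
    except Exception as exc:  # noqa: BLE001 - rewrap with stage context
        manifest.status = "failed"
        manifest.write(manifest_path)
        raise PipelineError("unknown", str(exc)) from exc
    manifest.status = "completed"
    manifest.write(manifest_path)
    logger.info("pipeline completed: %s", manifest_path)
    return manifest


def _stage_synth(cfg, seeds, out, manifest):
    try:
        s = cfg["synth"]
        sc, parc = make_synthetic_sc(
            n_regions=int(s.get("n_regions", 40)),
            n_networks=int(s.get("n_networks", 4)),
            seed=seeds["sc"],
        )
        specs = default_cohort_specs()
        g = default_global_truth()
        fit_cfg = _fit_config(cfg, seeds["cohort_fc"])
        paths = []
        p = out / "sc.tsv"
        write_matrix(sc, p)
        paths.append(p)
        p = out / "parc.tsv"
        write_parcellation(parc, p)
        paths.append(p)
        truths, group_fcs = {}, {}
        truth_json = {}
        for name, spec in specs.items():
            truths[name] = make_ground_truth(parc, spec=spec,
                                             seed=seeds["truth"])
            fcs = generate_cohort_fc(
                sc, g, truths[name],
                n_subjects=int(s.get("n_subjects_fc", 4)),
                subject_noise_sd=float(s.get("subject_noise_sd", 0.0)),
                seed=seeds["cohort_fc"], sim=fit_cfg,
            )
            group_fcs[name] = group_average_fc(fcs)
            p = out / f"fc_{name}.tsv"
            write_matrix(group_fcs[name], p)
            paths.append(p)
            truth_json[name] = {"w": truths[name].w.tolist(),
                                "I": truths[name].I.tolist()}
            logger.info("synth: cohort %s group FC written", name)
        truth_json["global"] = {"G": g.G, "sigma": g.sigma}
        p = out / "truth.json"
        p.write_text(json.dumps(truth_json, indent=2) + "\n")
        paths.append(p)
        tables = generate_feature_tables(
            parc, n_per_group=int(s.get("n_per_group_features", 20)),
            seed=seeds["features"], cohort_specs=specs,
        )
        for modality, table in tables.items():
            p = out / f"features_{modality}.tsv"
            frame = pd.DataFrame(
                table.values,
                columns=[f"region_{i}" for i in range(parc.n_regions)])
            frame.insert(0, "subject_id",
                         table.covariates["subject_id"].to_numpy())
            _write_frame(frame, p)
            paths.append(p)
        p = out / "covars.tsv"
        _write_frame(next(iter(tables.values())).covariates, p)
        paths.append(p)
        manifest.record("synth", paths)
        return sc, parc, truths, group_fcs, tables
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("synth", str(exc)) from exc


def _stage_fit(cfg, seeds, out, manifest, sc, group_fcs):
    try:
        fit_cfg = _fit_config(cfg, seeds["cohort_fc"])
        fits: dict[str, FitResult] = {}
        paths = []
        for name, fc in group_fcs.items():
            logger.info("fit: cohort %s starting", name)
            fits[name] = fit_rmfm(sc, fc, fit_cfg)
            for k, val in enumerate(fits[name].objective_trace):
                logger.info("fit: cohort=%s iteration=%d objective=%.6f",
                            name, k, val)
            f = fits[name]
            frame = pd.DataFrame({
                "region_id": np.arange(f.regional_params.n_regions),
                "w": f.regional_params.w,
                "I": f.regional_params.I,
            })
            p = out / f"fit_{name}.tsv"
            _write_frame(frame, p)
            paths.append(p)
            meta = {
                "G": f.global_params.G, "sigma": f.global_params.sigma,
                "best_similarity": f.best_similarity, "baseline": f.baseline,
                "converged": bool(f.converged),
                "n_evaluations": int(f.n_evaluations),
            }
            p = out / f"fit_{name}.json"
            p.write_text(json.dumps(meta, indent=2) + "\n")
            paths.append(p)
            logger.info("fit: cohort=%s similarity=%.4f baseline=%.4f",
                        name, f.best_similarity, f.baseline)
        manifest.record("fit", paths)
        return fits
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("fit", str(exc)) from exc


def _stage_contrast(cfg, out, manifest, parc, fits):
    try:
        nets = parc.networks[np.argsort(parc.region_ids)]
        paths = []
        for a, b in (("TLE", "HC"), ("GE", "HC")):
            if a not in fits or b not in fits:
                continue
            pairs = contrast_ready_params(fits[a], fits[b])
            dw = parameter_contrast(pairs["w_a"].to_numpy(),
                                    pairs["w_b"].to_numpy(), nets)
            dI = parameter_contrast(pairs["I_a"].to_numpy(),
                                    pairs["I_b"].to_numpy(), nets)
            frame = pd.DataFrame({
                "region_id": pairs["region_id"],
                "network": nets,
                "delta_w_norm": dw,
                "delta_I_norm": dI,
            })
            p = out / f"contrast_{a}_vs_{b}.tsv"
            _write_frame(frame, p)
            paths.append(p)
            logger.info("contrast: %s vs %s written", a, b)
        manifest.record("contrast", paths)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("contrast", str(exc)) from exc


def _stage_stats(cfg, seeds, out, manifest, tables):
    try:
        st = cfg["stats"]
        modality = st.get("modality", "thickness")
        table: FeatureTable = tables[modality]
        flipped = flip_to_ipsilateral(table)
        zscored = zscore_vs_controls(flipped)
        res = permutation_fwe(
            zscored,
            terms=tuple(st.get("model", ["sex", "age"])),
            contrast=tuple(st.get("groups", ["TLE", "HC"])),
            n_perm=int(st.get("n_perm", 500)),
            seed=seeds["permutation"],
        )
        frame = pd.DataFrame({
            "region_id": np.arange(res.t.size),
            "t": res.t,
            "p": res.p_uncorrected,
            "p_fwe": res.p_fwe,
        })
        p = out / f"stats_{modality}.tsv"
        _write_frame(frame, p)
        logger.info("stats: modality=%s n_sig_fwe=%d", modality,
                    int((res.p_fwe < 0.05).sum()))
        manifest.record("stats", [p])
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("stats", str(exc)) from exc
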