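"""Shared fixtures: small parcellations, connectomes and feature tables."""

import numpy as np
import pytest

from rmfm import (FunctionalConnectome, Parcellation, StructuralConnectome,
                  make_synthetic_sc, normalize_sc)


def mirrored_parcellation(n: int) -> Parcellation:
    """Parcellation pairing region i with i + n//2; an odd trailing region
    (if any) has no homologue."""
    half = n // 2
    hom = np.full(n, -1)
    hom[:half] = np.arange(half) + half
    hom[half:2 * half] = np.arange(half)
    return Parcellation(
        region_ids=np.arange(n),
        names=np.array([f"r{i}" for i in range(n)], dtype=object),
        hemispheres=np.array(["left"] * half + ["right"] * (n - half),
                             dtype=object),
        networks=np.array(["net_a" if i % 2 == 0 else "net_b"
                           for i in range(n)], dtype=object),
        homologue_ids=hom,
    )


@pytest.fixture
def parc6() -> Parcellation:
    return mirrored_parcellation(6)


@pytest.fixture
def sc6(parc6) -> StructuralConnectome:
    rng = np.random.default_rng(0)
    w = np.abs(rng.normal(1.0, 0.3, (6, 6)))
    w = 0.5 * (w + w.T)
    np.fill_diagonal(w, 0.0)
    return StructuralConnectome(weights=w, parcellation=parc6)


@pytest.fixture
def fc6(parc6) -> FunctionalConnectome:
    rng = np.random.default_rng(1)
    ts = rng.standard_normal((200, 6))
    r = np.corrcoef(ts, rowvar=False)
    np.fill_diagonal(r, 1.0)
    return FunctionalConnectome(values=r, parcellation=parc6, space="r")


@pytest.fixture(scope="session")
def sc16():
    sc, parc = make_synthetic_sc(n_regions=16, n_networks=4, seed=3)
    return normalize_sc(sc), parc


# ---------------------------------------------------------------------------
# The frozen 40-region synthetic study shared by the inversion and
# acceptance tests. Seeds (SC 1, truth jitter 2, FC/fit 11) were fixed at
# design time; the three cohort fits are expensive (minutes each), so they
# are computed once per session and reused.

@pytest.fixture(scope="session")
def study40():
    from rmfm import (default_cohort_specs, default_global_truth,
                      generate_cohort_fc, group_average_fc, make_ground_truth)

    sc, parc = make_synthetic_sc(n_regions=40, n_networks=4, seed=1)
    sc = normalize_sc(sc)
    g = default_global_truth()
    specs = default_cohort_specs()
    truths = {name: make_ground_truth(parc, spec=spec, seed=2)
              for name, spec in specs.items()}
    fcs = {}
    for name in ("HC", "TLE", "GE"):
        subject_fcs = generate_cohort_fc(sc, g, truths[name], n_subjects=4,
                                         subject_noise_sd=0.0, seed=11)
        fcs[name] = group_average_fc(subject_fcs)
    return {"sc": sc, "parc": parc, "global": g, "truths": truths, "fcs": fcs}


@pytest.fixture(scope="session")
def cohort_fits(study40):
    from rmfm import FitConfig, fit_rmfm

    cfg = FitConfig(base_seed=11)
    return {name: fit_rmfm(study40["sc"], study40["fcs"][name], cfg)
            for name in ("HC", "TLE", "GE")}
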