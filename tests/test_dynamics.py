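"""Neural-mass dynamics: firing-rate oracle values, integrator correctness
against the fixed-point oracle, determinism, boundedness, noise scaling."""

import numpy as np
import pytest

from rmfm import (MfmGlobalParams, MfmRegionalParams, StructuralConnectome,
                  find_fixed_point, firing_rate, input_current, simulate_neural)
from rmfm.dynamics import (DEFAULT_A, DEFAULT_B, DEFAULT_D, DEFAULT_J,
                           firing_rate_derivative)

from conftest import mirrored_parcellation


def _decoupled_sc(n: int) -> StructuralConnectome:
    parc = mirrored_parcellation(n)
    return StructuralConnectome(weights=np.zeros((n, n)), parcellation=parc)


class TestFiringRate:
    def test_threshold_limit(self):
        # H(b/a) = 1/d by L'Hopital at the removable singularity
        assert firing_rate(DEFAULT_B / DEFAULT_A) == pytest.approx(
            1.0 / DEFAULT_D, abs=1e-9)

    def test_near_singularity_continuity(self):
        x0 = DEFAULT_B / DEFAULT_A
        eps = 1e-8 / DEFAULT_A
        lo, mid, hi = firing_rate(x0 - eps), firing_rate(x0), firing_rate(x0 + eps)
        assert lo <= mid <= hi
        assert hi - lo < 1e-6

    def test_direct_evaluation_at_one_na(self):
        # a*1 - b = 162; H = 162 / (1 - exp(-0.154*162))
        u = DEFAULT_A * 1.0 - DEFAULT_B
        expected = u / (1.0 - np.exp(-DEFAULT_D * u))
        assert firing_rate(1.0) == pytest.approx(expected, rel=1e-12)

    def test_subthreshold_near_zero(self):
        # H(0) = -108 / (1 - exp(16.632)) ~ 6.47e-6 Hz
        assert firing_rate(0.0) == pytest.approx(
            -DEFAULT_B / (1.0 - np.exp(DEFAULT_D * DEFAULT_B)), rel=1e-9)
        assert 0 < firing_rate(0.0) < 1e-5

    def test_large_x_asymptote(self):
        # at a*x - b = 162 the asymptote H ~ a*x - b holds to 1e-6 relative
        assert abs(firing_rate(1.0) - 162.0) / 162.0 < 1e-6

    def test_monotone_on_grid(self):
        x = np.linspace(-1.0, 3.0, 10_000)
        h = firing_rate(x)
        assert np.all(np.diff(h) >= 0)
        assert np.all(h >= 0)

    def test_vector_matches_scalar(self):
        xs = np.array([0.0, 0.3, 0.4, 0.5, 1.0])
        np.testing.assert_allclose(firing_rate(xs),
                                   [firing_rate(float(x)) for x in xs],
                                   rtol=1e-13)

    def test_derivative_matches_finite_difference(self):
        for x in (0.1, 0.39, 0.4, 0.41, 0.8):
            h = 1e-7
            fd = (firing_rate(x + h) - firing_rate(x - h)) / (2 * h)
            assert firing_rate_derivative(x) == pytest.approx(fd, rel=1e-4)


class TestInputCurrent:
    def test_decoupled_zero_gating(self):
        sc = _decoupled_sc(2)
        reg = MfmRegionalParams(w=np.zeros(2), I=np.array([0.3, 0.3]))
        x = input_current(np.zeros(2), reg, MfmGlobalParams(), sc)
        np.testing.assert_allclose(x, [0.3, 0.3], atol=1e-15)

    def test_recurrent_term(self):
        sc = _decoupled_sc(2)
        reg = MfmRegionalParams(w=np.ones(2), I=np.zeros(2))
        x = input_current(np.array([0.5, 0.5]), reg, MfmGlobalParams(), sc)
        np.testing.assert_allclose(x, DEFAULT_J * 0.5, rtol=1e-15)

    def test_coupling_term_hand_evaluated(self):
        parc = mirrored_parcellation(2)
        C = StructuralConnectome(
            weights=np.array([[0.0, 1.0], [1.0, 0.0]]), parcellation=parc)
        reg = MfmRegionalParams(w=np.zeros(2), I=np.zeros(2))
        g = MfmGlobalParams(G=2.0)
        x = input_current(np.array([0.5, 0.25]), reg, g, C)
        np.testing.assert_allclose(
            x, [2 * DEFAULT_J * 0.25, 2 * DEFAULT_J * 0.5], rtol=1e-15)

    def test_dimension_mismatch(self):
        sc = _decoupled_sc(2)
        reg = MfmRegionalParams(w=np.zeros(3), I=np.zeros(3))
        with pytest.raises(ValueError):
            input_current(np.zeros(3), reg, MfmGlobalParams(), sc)


class TestSimulateNeural:
    def test_subthreshold_leak_stays_tiny(self):
        sc = _decoupled_sc(2)
        g = MfmGlobalParams(G=0.0, sigma=1e-9)
        reg = MfmRegionalParams(w=np.zeros(2), I=np.zeros(2))
        traj = simulate_neural(sc, g, reg, duration=10.0, seed=0, init_S=0.0)
        assert traj.S.max() < 1e-4

    def test_symmetric_pair_identical(self):
        parc = mirrored_parcellation(2)
        C = StructuralConnectome(
            weights=np.array([[0.0, 1.0], [1.0, 0.0]]), parcellation=parc)
        g = MfmGlobalParams(G=0.5, sigma=1e-12)
        reg = MfmRegionalParams.uniform(2, w=0.6, I=0.3)
        # identical noise column for both regions keeps the symmetry exact
        n_steps = int(round(5.0 / g.dt))
        col = np.random.default_rng(4).standard_normal(n_steps)
        noise = np.column_stack([col, col])
        traj = simulate_neural(C, g, reg, duration=5.0, noise=noise)
        np.testing.assert_allclose(traj.S[:, 0], traj.S[:, 1], atol=1e-13)

    def test_determinism(self):
        sc = _decoupled_sc(4)
        g = MfmGlobalParams(G=0.0, sigma=0.02)
        reg = MfmRegionalParams.uniform(4, w=0.5, I=0.3)
        a = simulate_neural(sc, g, reg, duration=3.0, seed=9)
        b = simulate_neural(sc, g, reg, duration=3.0, seed=9)
        assert np.array_equal(a.S, b.S)
        c = simulate_neural(sc, g, reg, duration=3.0, seed=10)
        assert not np.array_equal(a.S, c.S)

    def test_boundedness_under_strong_noise(self):
        sc = _decoupled_sc(4)
        g = MfmGlobalParams(G=0.0, sigma=0.5)
        reg = MfmRegionalParams.uniform(4, w=1.0, I=0.35)
        traj = simulate_neural(sc, g, reg, duration=5.0, seed=1)
        assert traj.S.min() >= 0.0
        assert traj.S.max() <= 1.0

    def test_dt_invariant_enforced(self):
        with pytest.raises(ValueError):
            MfmGlobalParams(dt=0.02)

    def test_sigma_zero_matches_fixed_point_five_fixtures(self):
        # acceptance-grade check: 5 seeded decoupled fixtures, terminal
        # state of the sigma~0 integrator vs the damped fixed-point oracle
        sc = _decoupled_sc(3)
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            reg = MfmRegionalParams(w=rng.uniform(0.2, 0.9, 3),
                                    I=rng.uniform(0.1, 0.3, 3))
            g = MfmGlobalParams(G=0.0, sigma=1e-12, dt=0.001)
            traj = simulate_neural(sc, g, reg, duration=20.0, seed=0,
                                   noise=np.zeros((20_000, 3)))
            fp = find_fixed_point(sc, g, reg, init=0.1)
            assert fp.converged
            np.testing.assert_allclose(traj.S[-1], fp.S, atol=1e-3)

    def test_halving_dt_changes_terminal_state_little(self):
        sc = _decoupled_sc(3)
        reg = MfmRegionalParams(w=np.array([0.3, 0.6, 0.9]),
                                I=np.array([0.15, 0.25, 0.3]))
        finals = []
        for dt in (0.001, 0.0005):
            g = MfmGlobalParams(G=0.0, sigma=1e-12, dt=dt)
            n_steps = int(round(20.0 / dt))
            traj = simulate_neural(sc, g, reg, duration=20.0,
                                   noise=np.zeros((n_steps, 3)))
            finals.append(traj.S[-1])
        rel = np.abs(finals[0] - finals[1]) / np.abs(finals[1])
        assert rel.max() < 1e-3

    def test_noise_scaling_of_stationary_variance(self):
        # decoupled sub-threshold region: Var(S) grows ~ sigma^2
        sc = _decoupled_sc(2)
        reg = MfmRegionalParams.uniform(2, w=0.3, I=0.2)
        var = {}
        for sigma in (0.01, 0.02):
            g = MfmGlobalParams(G=0.0, sigma=sigma)
            traj = simulate_neural(sc, g, reg, duration=60.0, seed=3)
            var[sigma] = traj.S[10_000:].var(axis=0).mean()
        ratio = var[0.02] / var[0.01]
        assert 3.0 < ratio < 5.0  # ideal 4, sampling tolerance


class TestFixedPoint:
    def test_zero_drive_near_zero(self):
        sc = _decoupled_sc(2)
        g = MfmGlobalParams(G=0.0)
        reg = MfmRegionalParams.uniform(2, w=0.0, I=0.0)
        fp = find_fixed_point(sc, g, reg)
        assert fp.converged
        assert np.all(fp.S <= 1e-6)

    def test_single_region_root_bracketing_oracle(self):
        from scipy.optimize import brentq
        g = MfmGlobalParams(G=0.0)
        w, I = 0.9, 0.3
        sc = _decoupled_sc(2)
        reg = MfmRegionalParams.uniform(2, w=w, I=I)

        def drift(s):
            x = w * g.J * s + I
            return -s / g.tau_s + g.r_kin * (1 - s) * firing_rate(x)

        root = brentq(drift, 0.0, 0.9)
        fp = find_fixed_point(sc, g, reg, init=0.1)
        assert fp.converged
        np.testing.assert_allclose(fp.S, root, atol=1e-4)

    def test_residual_contract(self):
        sc = _decoupled_sc(3)
        g = MfmGlobalParams(G=0.0)
        reg = MfmRegionalParams(w=np.array([0.2, 0.5, 0.8]),
                                I=np.array([0.1, 0.2, 0.3]))
        fp = find_fixed_point(sc, g, reg)
        assert fp.converged
        assert fp.residual < 1e-10

    def test_init_outside_unit_interval_rejected(self):
        sc = _decoupled_sc(2)
        with pytest.raises(ValueError):
            find_fixed_point(sc, MfmGlobalParams(),
                             MfmRegionalParams.uniform(2, 0.5, 0.3), init=1.5)


class TestRegionalParams:
    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            MfmRegionalParams(w=np.array([-0.1]), I=np.array([0.3]))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            MfmRegionalParams(w=np.zeros(2), I=np.zeros(3))

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            MfmRegionalParams(w=np.array([np.nan]), I=np.array([0.3]))
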