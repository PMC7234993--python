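"""Group statistics against textbook and library oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from rmfm import (FeatureTable, flip_to_ipsilateral, glm_contrast,
                  hotelling_t2, mahalanobis_d, parameter_contrast,
                  permutation_fwe, zscore_vs_controls)

from conftest import mirrored_parcellation


def _table(values, groups, sides=None, parc=None, age=None, sex=None):
    n = len(groups)
    cov = pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(n)],
        "group": groups,
        "side": sides if sides is not None else ["none"] * n,
        "age": age if age is not None else np.linspace(20, 60, n),
        "sex": sex if sex is not None else ["M", "F"] * (n // 2) + ["M"] * (n % 2),
    })
    values = np.asarray(values, float)
    parc = parc or mirrored_parcellation(values.shape[1])
    return FeatureTable(values=values, covariates=cov, parcellation=parc)


def _null_table(n_subjects, n_regions, rng, groups=("HC", "TLE")):
    labels = [groups[0]] * (n_subjects // 2) + [groups[1]] * (n_subjects // 2)
    return _table(
        rng.standard_normal((n_subjects, n_regions)), labels,
        age=rng.uniform(20, 60, n_subjects),
        sex=list(rng.choice(["M", "F"], n_subjects)),
    )


class TestFlip:
    def test_left_and_none_unchanged(self):
        v = np.arange(8.0).reshape(2, 4)
        ft = _table(v, ["TLE", "HC"], sides=["left", "none"])
        out = flip_to_ipsilateral(ft)
        np.testing.assert_array_equal(out.values, v)

    def test_right_swaps_homologues(self):
        parc = mirrored_parcellation(4)  # pairs (0,2), (1,3)
        v = np.array([[1.0, 2.0, 3.0, 4.0]])
        ft = _table(v, ["TLE"], sides=["right"], parc=parc)
        out = flip_to_ipsilateral(ft)
        np.testing.assert_array_equal(out.values, [[3.0, 4.0, 1.0, 2.0]])

    def test_involution_and_multiset_preserved(self):
        rng = np.random.default_rng(0)
        v = rng.standard_normal((6, 6))
        ft = _table(v, ["TLE"] * 6,
                    sides=["right", "left", "right", "none", "left", "right"])
        once = flip_to_ipsilateral(ft)
        twice = flip_to_ipsilateral(once)
        np.testing.assert_array_equal(twice.values, v)
        for i in range(6):
            assert sorted(once.values[i]) == sorted(v[i])

    def test_missing_homologue_rejected(self):
        from rmfm import Parcellation
        parc = Parcellation(region_ids=[0, 1], names=["a", "b"],
                            hemispheres=["left", "right"],
                            networks=["n", "n"], homologue_ids=[-1, -1])
        ft = _table(np.zeros((1, 2)), ["TLE"], sides=["right"], parc=parc)
        with pytest.raises(ValueError):
            flip_to_ipsilateral(ft)


class TestZscore:
    def test_controls_mean_zero_sd_one(self):
        rng = np.random.default_rng(1)
        groups = ["HC"] * 10 + ["TLE"] * 5
        ft = _table(rng.standard_normal((15, 4)), groups)
        out = zscore_vs_controls(ft)
        hc = out.values[:10]
        np.testing.assert_allclose(hc.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(hc.std(axis=0, ddof=1), 1.0, atol=1e-12)

    def test_patient_at_control_mean_is_zero(self):
        v = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0], [3.0, 4.0]])
        ft = _table(v, ["HC", "HC", "HC", "TLE"])
        out = zscore_vs_controls(ft)
        np.testing.assert_allclose(out.values[3], 0.0, atol=1e-12)

    def test_hand_computed_three_controls(self):
        v = np.array([[1.0], [2.0], [3.0], [4.0]])
        ft = _table(v, ["HC", "HC", "HC", "TLE"])
        out = zscore_vs_controls(ft)
        assert out.values[3, 0] == pytest.approx((4.0 - 2.0) / 1.0)

    def test_zero_control_sd_rejected(self):
        v = np.array([[1.0, 1.0], [1.0, 2.0], [1.0, 3.0]])
        ft = _table(v, ["HC", "HC", "HC"])
        with pytest.raises(ValueError, match="region 0"):
            zscore_vs_controls(ft)


class TestGlm:
    def test_no_covariates_equals_two_sample_t(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            ft = _null_table(20, 5, rng)
            res = glm_contrast(ft, terms=(), contrast=("TLE", "HC"))
            a = ft.values[ft.group_mask("TLE")]
            b = ft.values[ft.group_mask("HC")]
            t_ref, p_ref = sps.ttest_ind(a, b, equal_var=True)
            np.testing.assert_allclose(res.t, t_ref, atol=1e-10)
            np.testing.assert_allclose(res.p_uncorrected, p_ref, atol=1e-10)

    def test_matches_statsmodels_with_covariates(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(7)
        ft = _null_table(24, 3, rng)
        res = glm_contrast(ft, terms=("sex", "age"), contrast=("TLE", "HC"))
        sex = ft.covariates["sex"].map({"M": 0.0, "F": 1.0}).to_numpy()
        X = np.column_stack([
            np.ones(24), sex, ft.covariates["age"].to_numpy(),
            (ft.covariates["group"] == "TLE").to_numpy(float)])
        for j in range(3):
            fit = sm.OLS(ft.values[:, j], X).fit()
            assert res.t[j] == pytest.approx(fit.tvalues[3], abs=1e-10)
            assert res.p_uncorrected[j] == pytest.approx(fit.pvalues[3],
                                                         abs=1e-10)

    def test_confounded_design_rejected(self):
        rng = np.random.default_rng(3)
        groups = ["HC"] * 6 + ["TLE"] * 6
        ft = _table(rng.standard_normal((12, 3)), groups,
                    sex=["M"] * 6 + ["F"] * 6)
        with pytest.raises(ValueError, match="collinear"):
            glm_contrast(ft, terms=("sex",), contrast=("TLE", "HC"))


class TestPermutationFwe:
    def test_dominance_over_uncorrected(self):
        rng = np.random.default_rng(11)
        ft = _null_table(30, 8, rng)
        res = permutation_fwe(ft, terms=("age",), contrast=("TLE", "HC"),
                              n_perm=200, seed=5)
        assert np.all(res.p_fwe >= res.p_uncorrected - 1e-12)
        assert np.all((res.p_fwe >= 0) & (res.p_fwe <= 1))

    def test_small_n_perm_rejected(self):
        rng = np.random.default_rng(12)
        ft = _null_table(20, 4, rng)
        with pytest.raises(ValueError):
            permutation_fwe(ft, n_perm=50)

    def test_planted_effect_detected(self):
        # 2-SD effect in one region, n=40: detected in >= 90% of reps
        hits = 0
        n_reps = 30
        for rep in range(n_reps):
            rng = np.random.default_rng(1000 + rep)
            ft = _null_table(40, 10, rng)
            v = ft.values.copy()
            v[ft.group_mask("TLE"), 0] += 2.0
            ft = FeatureTable(values=v, covariates=ft.covariates,
                              parcellation=ft.parcellation)
            res = permutation_fwe(ft, terms=(), contrast=("TLE", "HC"),
                                  n_perm=500, seed=rep)
            hits += res.p_fwe[0] < 0.05
        assert hits / n_reps >= 0.9

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(13)
        ft = _null_table(20, 4, rng)
        a = permutation_fwe(ft, n_perm=200, seed=9)
        b = permutation_fwe(ft, n_perm=200, seed=9)
        np.testing.assert_array_equal(a.p_fwe, b.p_fwe)


class TestMahalanobis:
    def test_control_mean_is_zero(self):
        rng = np.random.default_rng(20)
        ctrl = rng.standard_normal((30, 4))
        assert mahalanobis_d(ctrl.mean(axis=0), ctrl) == pytest.approx(
            0.0, abs=1e-12)

    def test_identity_covariance_equals_euclidean(self):
        # exact identity covariance via a whitened control construction
        rng = np.random.default_rng(21)
        raw = rng.standard_normal((40, 3))
        raw -= raw.mean(axis=0)
        cov = np.cov(raw, rowvar=False, ddof=1)
        L = np.linalg.cholesky(cov)
        ctrl = raw @ np.linalg.inv(L).T  # sample covariance exactly identity
        x = np.array([1.0, -2.0, 0.5]) + ctrl.mean(axis=0)
        d = mahalanobis_d(x, ctrl)
        assert d == pytest.approx(np.linalg.norm([1.0, -2.0, 0.5]), abs=1e-12)

    def test_matches_closed_form_2x2(self):
        rng = np.random.default_rng(22)
        ctrl = rng.standard_normal((25, 2)) @ np.array([[1.0, 0.4], [0.0, 0.8]])
        x = np.array([0.7, -0.3])
        mu = ctrl.mean(axis=0)
        s = np.cov(ctrl, rowvar=False, ddof=1)
        det = s[0, 0] * s[1, 1] - s[0, 1] ** 2
        inv = np.array([[s[1, 1], -s[0, 1]], [-s[0, 1], s[0, 0]]]) / det
        d_ref = float(np.sqrt((x - mu) @ inv @ (x - mu)))
        assert mahalanobis_d(x, ctrl) == pytest.approx(d_ref, abs=1e-12)

    def test_singular_covariance_gated(self):
        ctrl = np.zeros((10, 2))
        ctrl[:, 0] = np.arange(10.0)
        ctrl[:, 1] = 2 * ctrl[:, 0]  # perfectly collinear
        with pytest.raises((ValueError, np.linalg.LinAlgError)):
            mahalanobis_d(np.array([1.0, 2.0]), ctrl)
        assert np.isfinite(
            mahalanobis_d(np.array([1.0, 2.0]), ctrl, allow_pinv=True))

    def test_too_few_controls_rejected(self):
        with pytest.raises(ValueError):
            mahalanobis_d(np.zeros(5), np.zeros((4, 5)))


class TestHotelling:
    def test_m1_equals_t_squared(self):
        rng = np.random.default_rng(30)
        a = rng.standard_normal((12, 1))
        b = rng.standard_normal((15, 1)) + 0.5
        t2, f, p = hotelling_t2(a, b)
        t_ref, p_ref = sps.ttest_ind(a[:, 0], b[:, 0], equal_var=True)
        assert t2 == pytest.approx(t_ref ** 2, abs=1e-10)
        assert p == pytest.approx(p_ref, abs=1e-10)

    def test_identical_groups_zero(self):
        rng = np.random.default_rng(31)
        a = rng.standard_normal((10, 2))
        t2, f, p = hotelling_t2(a, a)
        assert t2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            hotelling_t2(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_f_conversion(self):
        rng = np.random.default_rng(32)
        a, b = rng.standard_normal((20, 3)), rng.standard_normal((18, 3))
        t2, f, p = hotelling_t2(a, b)
        na, nb, m = 20, 18, 3
        assert f == pytest.approx(t2 * (na + nb - m - 1) / (m * (na + nb - 2)),
                                  rel=1e-12)


class TestParameterContrast:
    def test_equal_inputs_all_zero(self):
        nets = np.array(["a", "a", "b", "b"])
        p = np.array([1.0, 2.0, 3.0, 4.0])
        out = parameter_contrast(p, p, nets)
        np.testing.assert_array_equal(out, 0.0)

    def test_hand_computed_sample_sd(self):
        nets = np.array(["a", "a"])
        out = parameter_contrast(np.array([1.0, 3.0]), np.zeros(2), nets)
        np.testing.assert_allclose(out, [1 / np.sqrt(2), 3 / np.sqrt(2)],
                                   atol=1e-12)

    def test_shift_invariance(self):
        rng = np.random.default_rng(40)
        nets = np.array(["a"] * 3 + ["b"] * 3)
        pa, pb = rng.standard_normal(6), rng.standard_normal(6)
        base = parameter_contrast(pa, pb, nets)
        shifted = parameter_contrast(pa + 5.0, pb + 5.0, nets)
        np.testing.assert_allclose(base, shifted, atol=1e-12)

    def test_single_region_network_rejected(self):
        with pytest.raises(ValueError):
            parameter_contrast(np.zeros(3), np.zeros(3),
                               np.array(["a", "a", "b"]))

    def test_degenerate_nonzero_constant_difference_flagged(self):
        nets = np.array(["a", "a"])
        out = parameter_contrast(np.array([2.0, 2.0]), np.zeros(2), nets)
        assert np.all(np.isnan(out))
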