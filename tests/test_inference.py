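"""Permutation inference: pooled t, maxT correction, Huber IRLS, Manly scheme."""

from itertools import combinations

import numpy as np
import pytest

from permconnect import (
    HuberSettings,
    PermutationSettings,
    huber_fit,
    huber_residualize,
    interaction_regression,
    manly_permutation_pvalues,
    maxt_permutation_test,
    two_sample_t,
)


class TestTwoSampleT:
    def test_equal_means_give_zero(self):
        assert two_sample_t([1, 2, 3], [2, 1, 3]) == 0.0

    def test_hand_computed_value(self):
        # pooled sd = 1, se = sqrt(2/3), t = -3/se
        assert two_sample_t([1, 2, 3], [4, 5, 6]) == pytest.approx(-3.6742346, abs=1e-6)

    def test_antisymmetric_under_group_swap(self, rng):
        a, b = rng.normal(size=10), rng.normal(size=12)
        assert two_sample_t(a, b) == pytest.approx(-two_sample_t(b, a))

    def test_zero_pooled_variance_warns(self):
        with pytest.warns(UserWarning, match="pooled variance"):
            assert two_sample_t([2, 2], [2, 2]) == 0.0


class TestMaxTPermutation:
    def test_degenerate_identical_data_gives_p_one(self):
        X = np.ones((10, 4))
        labels = np.array(["A"] * 5 + ["B"] * 5)
        res = maxt_permutation_test(X, labels)
        assert all(r.observed_t == 0.0 for r in res)
        assert all(r.p_corrected == 1.0 for r in res)

    def test_exhaustive_enumeration_matches_brute_force(self, rng):
        X = rng.normal(size=(8, 3))
        X[:4, 0] += 2.5  # signal on edge 0
        labels = np.array(["A"] * 4 + ["B"] * 4)
        res = maxt_permutation_test(X, labels, PermutationSettings(n_permutations=100))
        maxts = []
        for idx in combinations(range(8), 4):
            mask = np.zeros(8, bool)
            mask[list(idx)] = True
            maxts.append(max(abs(two_sample_t(X[mask, e], X[~mask, e]))
                             for e in range(3)))
        maxts = np.array(maxts)
        for e, r in enumerate(res):
            t_obs = two_sample_t(X[:4, e], X[4:, e])
            assert r.observed_t == pytest.approx(t_obs, abs=1e-10)
            expected_p = (maxts >= abs(t_obs) - 1e-9).sum() / 70
            assert r.p_corrected == pytest.approx(expected_p, abs=1e-12)

    def test_p_never_below_add_one_bound(self, rng):
        X = rng.normal(size=(30, 5))
        X[:15] += 5.0  # huge effect everywhere
        labels = np.array(["A"] * 15 + ["B"] * 15)
        B = 199
        res = maxt_permutation_test(X, labels, PermutationSettings(n_permutations=B),
                                    exhaustive=False)
        assert min(r.p_corrected for r in res) == pytest.approx(1 / (B + 1))

    def test_corrected_p_dominates_uncorrected(self, rng):
        X = rng.normal(size=(24, 8))
        labels = np.array(["A"] * 12 + ["B"] * 12)
        maxt = maxt_permutation_test(X, labels,
                                     PermutationSettings(n_permutations=500, seed=3),
                                     exhaustive=False)
        raw = maxt_permutation_test(X, labels,
                                    PermutationSettings(n_permutations=500, seed=3,
                                                        correction="none"),
                                    exhaustive=False)
        for rm, rr in zip(maxt, raw):
            assert rm.p_corrected >= rr.p_corrected - 1e-12

    def test_seeded_runs_reproducible(self, rng):
        X = rng.normal(size=(20, 6))
        labels = np.array(["A"] * 10 + ["B"] * 10)
        s = PermutationSettings(n_permutations=300, seed=11)
        p1 = [r.p_corrected for r in maxt_permutation_test(X, labels, s, exhaustive=False)]
        p2 = [r.p_corrected for r in maxt_permutation_test(X, labels, s, exhaustive=False)]
        assert p1 == p2

    def test_small_group_rejected(self, rng):
        X = rng.normal(size=(5, 3))
        with pytest.raises(ValueError, match="at least 2"):
            maxt_permutation_test(X, np.array(["A", "B", "B", "B", "B"]))


class TestHuber:
    def test_perfect_linear_fit_gives_null_residuals(self, rng):
        age = rng.uniform(50, 90, size=40)
        y = 3.0 + 0.5 * age
        resid, conv = huber_residualize(y, age)
        assert conv and np.abs(resid).max() < 1e-4

    def test_matches_ols_without_outliers(self, rng):
        # asymptotic agreement: at large n the Huber fit of clean Gaussian
        # data reproduces OLS residuals within 1% RMS
        n = 20_000
        X = rng.normal(size=(n, 2))
        y = 1 + X @ [2.0, -1.0] + rng.normal(0, 1, n)
        resid_h, _ = huber_residualize(y, X)
        Xd = np.column_stack([np.ones(n), X])
        resid_ols = y - Xd @ np.linalg.lstsq(Xd, y, rcond=None)[0]
        rms = np.sqrt(np.mean((resid_h - resid_ols) ** 2))
        assert rms < 0.01 * np.sqrt(np.mean(resid_ols**2))

    def test_matches_sklearn_reference(self, rng):
        from sklearn.linear_model import HuberRegressor

        X = rng.normal(size=(60, 3))
        y = 1 + X @ [2.0, 1.5, -1.0] + rng.normal(0, 1, 60)
        y[:5] += 15.0  # gross outliers
        ours, conv = huber_fit(X, y)
        sk = HuberRegressor(epsilon=1.35, alpha=1e-3, tol=1e-8, max_iter=1000).fit(X, y)
        ref = np.r_[sk.intercept_, sk.coef_]
        assert conv
        np.testing.assert_allclose(ours, ref, atol=5e-4)

    def test_outlier_robustness_ordering(self, rng):
        X = rng.normal(size=(50, 1))
        y = 2 + 3 * X[:, 0] + rng.normal(0, 0.5, 50)
        y_out = y.copy()
        y_out[0] += 50.0
        clean = slice(1, None)
        resid_h_clean, _ = huber_residualize(y, X)
        resid_h_out, _ = huber_residualize(y_out, X)
        Xd = np.column_stack([np.ones(50), X])

        def ols_resid(v):
            return v - Xd @ np.linalg.lstsq(Xd, v, rcond=None)[0]

        shift_huber = np.abs(resid_h_out[clean] - resid_h_clean[clean]).mean()
        shift_ols = np.abs(ols_resid(y_out)[clean] - ols_resid(y)[clean]).mean()
        assert shift_huber < shift_ols

    def test_missing_covariates_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            huber_residualize(np.ones(3), np.array([1.0, np.nan, 2.0]))

    def test_settings_validation(self):
        with pytest.raises(ValueError):
            HuberSettings(epsilon=1.0)
        with pytest.raises(ValueError):
            HuberSettings(tol=0.0)


class TestInteractionRegression:
    def test_noise_free_exact_recovery(self, rng):
        edge = rng.normal(size=50)
        group = np.repeat([0.0, 1.0], 25)
        score = 2.0 + 1.5 * edge - 1.0 * group + 3.0 * edge * group
        coefs = interaction_regression(score, edge, group)
        assert coefs["intercept"] == pytest.approx(2.0, abs=1e-6)
        assert coefs["edge"] == pytest.approx(1.5, abs=1e-6)
        assert coefs["group"] == pytest.approx(-1.0, abs=1e-6)
        assert coefs["interaction"] == pytest.approx(3.0, abs=1e-6)

    def test_null_interaction_estimated_near_zero(self, rng):
        betas = []
        for rep in range(30):
            r = np.random.default_rng(rep)
            edge = r.normal(size=60)
            group = np.repeat([0.0, 1.0], 30)
            score = 1.0 + 0.5 * edge + r.normal(0, 1, 60)
            betas.append(interaction_regression(score, edge, group)["interaction"])
        # mean near 0, spread consistent with se ~ sqrt(4/60)
        assert abs(np.mean(betas)) < 0.15
        assert np.std(betas) < 0.5

    def test_group_coding_flip_identity(self, rng):
        edge = rng.normal(size=40)
        group = np.repeat([0.0, 1.0], 20)
        score = 1 + 2 * edge + 0.5 * group - 1.5 * edge * group + rng.normal(0, 0.1, 40)
        c = interaction_regression(score, edge, group)
        cf = interaction_regression(score, edge, 1 - group)
        assert cf["edge"] == pytest.approx(c["edge"] + c["interaction"], abs=1e-4)
        assert cf["interaction"] == pytest.approx(-c["interaction"], abs=1e-4)
        assert cf["group"] == pytest.approx(-c["group"], abs=1e-4)

    def test_constant_edge_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            interaction_regression(np.arange(10.0), np.ones(10),
                                   np.repeat([0.0, 1.0], 5))


class TestManlyPermutation:
    def test_single_permutation_p_values(self, rng):
        res = manly_permutation_pvalues(
            rng.normal(size=20), rng.normal(size=20), np.repeat([0.0, 1.0], 10),
            PermutationSettings(n_permutations=1, seed=5),
        )
        assert set(res.all_pvalues.values()) <= {0.5, 1.0}

    def test_strong_interaction_detected(self, rng):
        edge = rng.normal(size=60)
        group = np.repeat([0.0, 1.0], 30)
        score = 2.0 * edge * group + rng.normal(0, 1, 60)
        res = manly_permutation_pvalues(
            score, edge, group, PermutationSettings(n_permutations=500, seed=1))
        assert res.p_perm <= 0.01
        assert res.beta_interaction == pytest.approx(2.0, abs=0.5)

    def test_reproducible_under_seed(self, rng):
        args = (rng.normal(size=30), rng.normal(size=30), np.repeat([0.0, 1.0], 15))
        s = PermutationSettings(n_permutations=200, seed=9)
        assert (manly_permutation_pvalues(*args, s).all_pvalues
                == manly_permutation_pvalues(*args, s).all_pvalues)

    def test_bootstrap_ci_covers_strong_effect(self, rng):
        edge = rng.normal(size=80)
        group = np.repeat([0.0, 1.0], 40)
        score = 3.0 * edge * group + rng.normal(0, 0.5, 80)
        res = manly_permutation_pvalues(
            score, edge, group, PermutationSettings(n_permutations=50, seed=2),
            bootstrap_ci=200,
        )
        lo, hi = res.ci_95
        assert lo < 3.0 < hi


class TestCorrectedModelEquivalence:
    def test_residualizing_on_irrelevant_covariates_preserves_tests(self, rng):
        """When confound slopes are truly zero, testing Huber residuals must
        reproduce the raw-model t statistics up to small perturbations."""
        X = rng.normal(size=(40, 10))
        covs = rng.normal(size=(40, 2))  # independent of the edges
        labels = np.array(["A"] * 20 + ["B"] * 20)
        raw = maxt_permutation_test(X, labels,
                                    PermutationSettings(n_permutations=100, seed=0),
                                    exhaustive=False)
        Xres = np.column_stack([huber_residualize(X[:, j], covs)[0]
                                for j in range(X.shape[1])])
        corr = maxt_permutation_test(Xres, labels,
                                     PermutationSettings(n_permutations=100, seed=0),
                                     exhaustive=False)
        t_raw = np.array([r.observed_t for r in raw])
        t_corr = np.array([r.observed_t for r in corr])
        assert np.corrcoef(t_raw, t_corr)[0, 1] > 0.9
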