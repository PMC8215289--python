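"""QC and cleaning chain: FD, cosine basis, nuisance OLS, z-score, smooth, parcellate."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from permconnect import (
    NuisanceDesign,
    QCRecord,
    apply_fd_exclusion,
    build_cosine_basis,
    clean_subject,
    compute_framewise_displacement,
    gaussian_smooth,
    parcellate,
    regress_nuisance,
    zscore_series,
)
from permconnect.cleaning import FWHM_TO_SIGMA


class TestFramewiseDisplacement:
    def test_no_motion_gives_zero_fd(self):
        fd = compute_framewise_displacement(np.zeros((10, 6)))
        np.testing.assert_array_equal(fd, 0.0)

    def test_single_translation_step(self):
        motion = np.zeros((8, 6))
        motion[4:, 0] = 0.5  # 0.5 mm x-step between frames 3 and 4 (0-based)
        fd = compute_framewise_displacement(motion)
        expected = np.zeros(8)
        expected[4] = 0.5
        np.testing.assert_allclose(fd, expected)

    def test_rotation_converted_at_50mm_radius(self):
        motion = np.zeros((5, 6))
        motion[3:, 4] = 0.01  # 0.01 rad step -> 50 mm * 0.01 = 0.5 mm
        fd = compute_framewise_displacement(motion)
        assert fd[3] == pytest.approx(0.5)
        assert fd[[0, 1, 2, 4]].max() == 0.0

    def test_wrong_column_count_rejected(self):
        with pytest.raises(ValueError, match="T x 6"):
            compute_framewise_displacement(np.zeros((10, 5)))


class TestFDExclusion:
    @pytest.mark.parametrize(
        "mean_fd, kept",
        [(0.49, True), (0.51, False), (0.50, True)],  # strict > at the boundary
    )
    def test_threshold_rule(self, mean_fd, kept):
        rec = QCRecord(subject_id="s", mean_fd_mm=mean_fd, max_fd_mm=mean_fd)
        retained = apply_fd_exclusion([rec], threshold_mm=0.5)
        assert (len(retained) == 1) is kept
        assert rec.excluded is (not kept)


class TestCosineBasis:
    def test_study_acquisition_yields_seven_regressors(self):
        # frequencies k / (2*160*3.12) < 1/128  =>  k <= 7
        basis = build_cosine_basis(160, 3.12, 128.0)
        assert basis.shape == (160, 7)
        np.testing.assert_allclose(np.linalg.norm(basis, axis=0), 1.0)

    def test_infinite_cutoff_gives_empty_basis(self):
        assert build_cosine_basis(160, 3.12, np.inf).shape == (160, 0)

    def test_sub_nyquist_cutoff_warns_and_is_empty(self):
        with pytest.warns(UserWarning, match="Nyquist"):
            basis = build_cosine_basis(160, 3.12, 5.0)
        assert basis.shape == (160, 0)

    def test_slow_drift_removed_by_regression(self):
        T, tr = 160, 3.12
        t = np.arange(T) * tr
        drift = np.cos(2 * np.pi * t / 500.0)  # 500 s period, below the 128 s cutoff
        rng = np.random.default_rng(0)
        signal = rng.normal(size=T) + 3.0 * drift
        basis = build_cosine_basis(T, tr, 128.0)
        design = NuisanceDesign(T)
        for k in range(basis.shape[1]):
            design.add(f"cos{k}", basis[:, k])
        resid = regress_nuisance(signal, design)
        assert abs(np.corrcoef(resid, drift)[0, 1]) < 0.05


class TestRegressNuisance:
    def test_intercept_only_demeans(self):
        series = np.full(20, 5.0) + np.arange(20) * 0.0
        resid = regress_nuisance(series, NuisanceDesign(20))
        assert resid.mean() == pytest.approx(0.0, abs=1e-12)

    def test_series_equal_to_design_column_gives_zero_residual(self, rng):
        col = rng.normal(size=30)
        design = NuisanceDesign(30).add("x", col)
        resid = regress_nuisance(col, design)
        np.testing.assert_allclose(resid, 0.0, atol=1e-10)

    def test_matches_hat_matrix_oracle(self, rng):
        X = np.column_stack([np.ones(40), rng.normal(size=(40, 3))])
        y = rng.normal(size=40)
        H = X @ np.linalg.inv(X.T @ X) @ X.T
        expected = (np.eye(40) - H) @ y
        design = NuisanceDesign(40)
        for j in range(1, 4):
            design.add(f"x{j}", X[:, j])
        np.testing.assert_allclose(regress_nuisance(y, design), expected, atol=1e-10)

    def test_residuals_orthogonal_to_design(self, rng):
        design = NuisanceDesign(50)
        for j in range(4):
            design.add(f"x{j}", rng.normal(size=50))
        X, _ = design.matrix()
        resid = regress_nuisance(rng.normal(size=(50, 7)), design)
        assert np.abs(X.T @ resid).max() < 1e-8

    def test_duplicate_columns_pruned_with_warning(self, rng, caplog):
        col = rng.normal(size=25)
        design = NuisanceDesign(25).add("a", col).add("b", 2.0 * col)
        with caplog.at_level("WARNING"):
            X, names = design.matrix()
        assert "b" not in names and "a" in names
        assert any("rank-deficient" in r.getMessage() for r in caplog.records)

    def test_length_mismatch_rejected(self, rng):
        design = NuisanceDesign(10).add("x", rng.normal(size=10))
        with pytest.raises(ValueError, match="length"):
            regress_nuisance(rng.normal(size=12), design)


class TestZScore:
    def test_constant_series_maps_to_zero_with_warning(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            z = zscore_series(np.full(10, 3.0))
        np.testing.assert_array_equal(z, 0.0)

    def test_population_sd_convention(self):
        z = zscore_series(np.array([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(z, [-1.2247448, 0.0, 1.2247448], atol=1e-6)

    def test_idempotent_on_standardized_input(self, rng):
        x = zscore_series(rng.normal(size=100))
        np.testing.assert_allclose(zscore_series(x), x, atol=1e-12)

    @settings(deadline=None, max_examples=25)
    @given(st.lists(st.floats(-1e3, 1e3), min_size=3, max_size=50))
    def test_output_moments(self, values):
        x = np.asarray(values)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            z = zscore_series(x)
        assert np.all(np.isfinite(z))
        if x.std() > 1e-6 * max(1.0, np.abs(x).max()):
            assert z.mean() == pytest.approx(0.0, abs=1e-8)
            assert z.std() == pytest.approx(1.0, abs=1e-6)


class TestGaussianSmooth:
    def test_fwhm_zero_is_identity(self, rng):
        vol = rng.normal(size=(5, 5, 3, 4))
        np.testing.assert_array_equal(gaussian_smooth(vol, fwhm_mm=0.0), vol)

    def test_constant_field_unchanged_in_interior(self):
        vol = np.full((12, 12, 8, 2), 7.0)
        sm = gaussian_smooth(vol, fwhm_mm=6.0, voxel_size_mm=3.0)
        np.testing.assert_allclose(sm[4:8, 4:8, 3:5], 7.0, rtol=1e-3)

    def test_fwhm6_sigma_value(self):
        assert 6.0 * FWHM_TO_SIGMA == pytest.approx(2.5480, abs=1e-4)

    def test_mask_prevents_bleed_outside(self, rng):
        vol = rng.normal(size=(10, 10, 4, 3)) + 5
        mask = np.zeros((10, 10, 4))
        mask[2:8, 2:8, 1:3] = 1
        sm = gaussian_smooth(vol, fwhm_mm=6.0, voxel_size_mm=3.0, brain_mask=mask)
        assert np.all(sm[mask == 0] == 0.0)


class TestParcellate:
    def test_single_binary_parcel_identity(self, rng):
        maps = np.zeros((4, 4, 2, 1))
        maps[2, 2, 1, 0] = 1.0
        vol = rng.normal(size=(4, 4, 2, 15))
        ts = parcellate(vol, maps)
        np.testing.assert_allclose(ts.values[:, 0], vol[2, 2, 1, :])

    def test_disjoint_parcels_separate(self, rng):
        maps = np.zeros((4, 4, 1, 2))
        maps[0, 0, 0, 0] = 1.0
        maps[3, 3, 0, 1] = 1.0
        vol = rng.normal(size=(4, 4, 1, 10))
        ts = parcellate(vol, maps)
        np.testing.assert_allclose(ts.values[:, 0], vol[0, 0, 0, :])
        np.testing.assert_allclose(ts.values[:, 1], vol[3, 3, 0, :])

    def test_probabilistic_weighted_mean_two_voxel_oracle(self, rng):
        maps = np.zeros((2, 1, 1, 1))
        maps[0, 0, 0, 0] = 0.25
        maps[1, 0, 0, 0] = 0.75
        vol = rng.normal(size=(2, 1, 1, 12))
        ts = parcellate(vol, maps)
        expected = 0.25 * vol[0, 0, 0] + 0.75 * vol[1, 0, 0]
        np.testing.assert_allclose(ts.values[:, 0], expected)

    def test_all_zero_map_rejected_with_node_name(self):
        maps = np.zeros((3, 3, 1, 2))
        maps[0, 0, 0, 0] = 1.0
        with pytest.raises(ValueError, match="nodeB"):
            parcellate(np.zeros((3, 3, 1, 5)), maps, node_labels=["nodeA", "nodeB"])


class TestCleanChain:
    def test_noise_free_recovery_up_to_zscoring(self, rng):
        """With binary disjoint parcels, no nuisance and no smoothing, the
        cleaning chain returns exactly the z-scored planted node signals."""
        maps = np.zeros((6, 6, 2, 2))
        maps[1, 1, 0, 0] = 1.0
        maps[4, 4, 1, 1] = 1.0
        sig = rng.normal(size=(40, 2))
        vol = np.zeros((6, 6, 2, 40))
        vol[1, 1, 0] = sig[:, 0]
        vol[4, 4, 1] = sig[:, 1]
        ts = clean_subject(vol, NuisanceDesign(40), maps, fwhm_mm=0.0,
                           node_labels=["a", "b"])
        np.testing.assert_allclose(ts.values, zscore_series(sig), atol=1e-10)
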