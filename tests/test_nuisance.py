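import numpy as np
import pytest

from handsight.nuisance import (NuisanceModel, build_csf_mask, build_wm_mask,
                                compcor_eigenvectors, regress_nuisance)


class TestWmMask:
    def test_solid_cube_erodes_to_interior(self):
        intensity = np.zeros((9, 9, 9))
        std = np.zeros((9, 9, 9), dtype=bool)
        std[2:7, 2:7, 2:7] = True       # 5x5x5 cube
        intensity[std] = 10.0
        out = build_wm_mask(intensity, std, n_top=999, erode_voxels=1)
        assert out.sum() == 27           # 3x3x3 interior
        assert out[3:6, 3:6, 3:6].all()

    def test_isolated_singletons_vanish_under_erosion(self):
        intensity = np.zeros((8, 8, 8))
        std = np.ones((8, 8, 8), dtype=bool)
        intensity[1, 1, 1] = 5.0
        intensity[6, 6, 6] = 5.0
        out = build_wm_mask(intensity, std, n_top=2, erode_voxels=1)
        assert out.sum() == 0

    def test_n_top_larger_than_mask_keeps_whole_mask(self):
        intensity = np.random.default_rng(0).random((6, 6, 6))
        std = np.zeros((6, 6, 6), dtype=bool)
        std[1:5, 1:5, 1:5] = True
        full = build_wm_mask(intensity, std, n_top=10_000, erode_voxels=0)
        assert (full == std).all()


class TestCsfMask:
    def test_raster_increasing_selects_prefix(self):
        intensity = np.arange(4 * 3 * 2, dtype=float).reshape(4, 3, 2)
        out = build_csf_mask(intensity, n_bottom=5)
        assert list(np.nonzero(out.ravel())[0]) == [0, 1, 2, 3, 4]

    def test_all_voxels_when_n_equals_total(self):
        intensity = np.random.default_rng(1).random((3, 3, 3))
        assert build_csf_mask(intensity, n_bottom=27).all()

    def test_ties_resolved_by_linear_index_vs_exhaustive_sort(self):
        rng = np.random.default_rng(2)
        intensity = rng.integers(0, 4, (5, 5, 4)).astype(float)  # many ties
        n = 30
        out = build_csf_mask(intensity, n_bottom=n)
        flat = intensity.ravel()
        oracle = sorted(range(flat.size), key=lambda i: (flat[i], i))[:n]
        assert sorted(np.nonzero(out.ravel())[0]) == sorted(oracle)


class TestCompcor:
    def test_rank_one_data_single_component_explains_everything(self, rng):
        t = rng.normal(0, 1, 50)
        series = np.outer(t, rng.uniform(0.5, 2.0, 30))
        U = compcor_eigenvectors(series, k=5)
        assert U.shape[1] == 1  # rank 1: only one component available
        proj = series - np.outer(U[:, 0], U[:, 0] @ (series - series.mean(0)))
        demeaned = series - series.mean(0)
        explained = 1 - ((demeaned - np.outer(U[:, 0], U[:, 0] @ demeaned))
                         ** 2).sum() / (demeaned ** 2).sum()
        assert explained == pytest.approx(1.0, abs=1e-10)

    def test_block_is_orthonormal(self, rng):
        series = rng.normal(0, 1, (60, 40))
        U = compcor_eigenvectors(series, k=5)
        np.testing.assert_allclose(U.T @ U, np.eye(5), atol=1e-10)

    def test_span_matches_covariance_eigendecomposition_oracle(self, rng):
        # well-separated spectrum keeps both decompositions numerically crisp
        series = rng.normal(0, 0.1, (40, 25))
        for amp in (10.0, 8.0, 6.0, 5.0, 4.0):
            series += amp * np.outer(rng.normal(0, 1, 40),
                                     rng.uniform(0.5, 1, 25))
        k = 5
        U = compcor_eigenvectors(series, k=k)
        Xc = series - series.mean(axis=0)
        # eigenvectors of the T x T covariance, descending eigenvalue
        w, V = np.linalg.eigh(Xc @ Xc.T)
        V = V[:, np.argsort(w)[::-1][:k]]
        # sine-based principal angles (accurate for tiny angles, where
        # the arccos formulation bottoms out at one ulp ~3e-8)
        sines = np.linalg.svd(V - U @ (U.T @ V), compute_uv=False)
        angles = np.arcsin(np.clip(sines, 0, 1))
        assert angles.max() < 1e-8

    def test_explained_variance_nonincreasing(self, rng):
        series = rng.normal(0, 1, (50, 30)) + \
            np.outer(rng.normal(0, 2, 50), rng.uniform(0.5, 1, 30))
        U = compcor_eigenvectors(series, k=5)
        Xc = series - series.mean(axis=0)
        var = [((u @ Xc) ** 2).sum() for u in U.T]
        assert all(a >= b - 1e-10 for a, b in zip(var, var[1:]))


class TestRegressNuisance:
    def _model(self, rng, T):
        wm = compcor_eigenvectors(rng.normal(0, 1, (T, 20)), k=5)
        csf = compcor_eigenvectors(rng.normal(0, 1, (T, 15)), k=5)
        return NuisanceModel(wm_eigenvectors=wm, csf_eigenvectors=csf,
                             motion=rng.normal(0, 0.05, (T, 6)))

    def test_sixteen_regressors_and_residual_orthogonality(self, rng):
        T = 80
        model = self._model(rng, T)
        assert model.combined.shape == (T, 16)
        series = rng.normal(0, 1, (T, 12))
        resid, flagged = regress_nuisance(series, model)
        assert not flagged.any()
        # orthogonal to every nuisance column; z-scored per voxel
        assert np.abs(model.combined.T @ resid).max() < 1e-8
        np.testing.assert_allclose(resid.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(resid.std(axis=0, ddof=1), 1, atol=1e-12)

    def test_matches_projector_oracle(self, rng):
        T = 60
        model = self._model(rng, T)
        series = rng.normal(0, 1, (T, 8))
        resid, _ = regress_nuisance(series, model)
        X = np.column_stack([np.ones(T), model.combined])
        P = np.eye(T) - X @ np.linalg.inv(X.T @ X) @ X.T
        oracle = P @ series
        oracle = (oracle - oracle.mean(0)) / oracle.std(0, ddof=1)
        np.testing.assert_allclose(resid, oracle, atol=1e-10)

    def test_series_equal_to_nuisance_column_is_flagged(self, rng):
        T = 70
        model = self._model(rng, T)
        series = np.column_stack([model.combined[:, 0],
                                  rng.normal(0, 1, T)])
        resid, flagged = regress_nuisance(series, model)
        assert flagged[0] and not flagged[1]
        assert np.all(resid[:, 0] == 0)
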