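import numpy as np
import pandas as pd
import pytest

from handsight.glm import (DesignMatrix, build_design, double_gamma_hrf,
                           fit_glm, fixed_effects_combine, spike_volumes)


def _events(rows):
    return pd.DataFrame(rows, columns=["onset", "duration", "trial_type"])


class TestHrf:
    def test_zero_at_onset_and_peak_location(self):
        h = double_gamma_hrf(dt=0.1)
        assert h[0] == pytest.approx(0.0, abs=1e-8)
        assert h.max() == pytest.approx(1.0)
        peak_t = np.argmax(h) * 0.1
        assert 4.5 <= peak_t <= 5.5

    def test_no_undershoot_is_nonnegative(self):
        h = double_gamma_hrf(dt=0.1, undershoot_ratio=0.0)
        assert np.all(h >= -1e-12)

    def test_rejects_nonpositive_dt(self):
        with pytest.raises(ValueError):
            double_gamma_hrf(dt=0.0)


class TestBuildDesign:
    def test_no_events_no_spikes_roles(self, rng):
        motion = rng.normal(0, 0.001, (50, 6))
        d = build_design(None, motion, tr=2.0, n_vols=50, hp_cutoff_s=100.0)
        assert set(d.column_roles) == {"motion", "drift", "intercept"}
        assert d.column_roles.count("motion") == 6

    def test_single_event_regressor_peaks_after_hrf_delay(self):
        ev = _events([(0.0, 1.5, "stim")])
        d = build_design(ev, None, tr=0.5, n_vols=60, hp_cutoff_s=np.inf)
        col = d.values[:, d.column_labels.index("stim")]
        peak_s = np.argmax(col) * 0.5
        assert 4.0 <= peak_s <= 7.0

    def test_large_motion_jump_yields_one_hot_spike(self, rng):
        motion = rng.normal(0, 1e-4, (40, 6))
        motion[25:, 3] += 1.2  # 1.2 mm translation step between vols 24 and 25
        d = build_design(None, motion, tr=1.0, n_vols=40, hp_cutoff_s=np.inf)
        spikes = [j for j, r in enumerate(d.column_roles) if r == "spike"]
        assert len(spikes) == 1
        col = d.values[:, spikes[0]]
        assert col[25] == 1.0 and col.sum() == 1.0

    def test_subthreshold_rotation_not_flagged_but_large_is(self):
        motion = np.zeros((30, 6))
        motion[10:, 0] = 0.015  # 0.015 rad * 50 mm = 0.75 mm: below threshold
        assert spike_volumes(motion).size == 0
        motion[20:, 1] = 0.025  # 1.25 mm-equivalent
        assert list(spike_volumes(motion)) == [20]

    def test_event_past_scan_end_rejected(self):
        ev = _events([(58.0, 5.0, "stim")])
        with pytest.raises(ValueError, match="beyond scan"):
            build_design(ev, None, tr=1.0, n_vols=60, hp_cutoff_s=np.inf)


class TestFitGlm:
    def _toy(self, rng, T=60, V=5):
        ev = _events([(5.0, 1.5, "a"), (20.0, 1.5, "a"), (35.0, 1.5, "b"),
                      (48.0, 1.5, "b")])
        design = build_design(ev, None, tr=1.0, n_vols=T, hp_cutoff_s=np.inf)
        beta = rng.normal(0, 1, (design.n_regressors, V))
        noise = rng.normal(0, 0.5, (T, V))
        return design, beta, design.values @ beta + noise

    def test_matches_normal_equations_oracle(self, rng):
        design, _, data = self._toy(rng)
        X = design.values
        beta_oracle = np.linalg.inv(X.T @ X) @ X.T @ data
        c = np.zeros(design.n_regressors)
        c[0] = 1.0
        m = fit_glm(data, design, c)
        np.testing.assert_allclose(m.cope, beta_oracle[0], atol=1e-10)

    def test_noiseless_recovery_and_capped_z(self, rng):
        design, beta, _ = self._toy(rng)
        data = design.values @ beta
        c = np.zeros(design.n_regressors)
        c[1] = 1.0
        m = fit_glm(data, design, c)
        np.testing.assert_allclose(m.cope, beta[1], atol=1e-9)
        assert np.all(np.isfinite(m.z)) and np.all(np.abs(m.z) <= 40.0)

    def test_residuals_orthogonal_to_design(self, rng):
        design, _, data = self._toy(rng)
        X = design.values
        beta = np.linalg.pinv(X) @ data
        resid = data - X @ beta
        assert np.abs(X.T @ resid).max() < 1e-8

    def test_cope_linear_in_data(self, rng):
        design, _, d1 = self._toy(rng)
        _, _, d2 = self._toy(rng)
        c = np.zeros(design.n_regressors)
        c[0] = 1.0
        lhs = fit_glm(2.0 * d1 + 3.0 * d2, design, c).cope
        rhs = 2.0 * fit_glm(d1, design, c).cope + \
            3.0 * fit_glm(d2, design, c).cope
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)

    def test_identical_condition_columns_contrast_is_zero(self, rng):
        T = 40
        col = np.sin(np.arange(T) / 3.0) + 1.5
        X = np.column_stack([col, col, np.ones(T)])
        design = DesignMatrix(values=X, column_labels=["a", "b", "intercept"],
                              column_roles=["condition", "condition",
                                            "intercept"], tr=1.0)
        data = np.outer(col, np.ones(3)) + rng.normal(0, 0.1, (T, 3))
        # rank-deficient fit: the pseudoinverse splits the shared signal
        # evenly, so the difference contrast carries none of it
        m = fit_glm(data, design, np.array([1.0, -1.0, 0.0]))
        np.testing.assert_allclose(m.cope, 0.0, atol=1e-8)

    def test_dof_equals_T_minus_rank(self, rng):
        design, _, data = self._toy(rng)
        m = fit_glm(data, design, np.eye(design.n_regressors)[0])
        assert m.dof == data.shape[0] - np.linalg.matrix_rank(design.values)


class TestFixedEffects:
    def test_identical_runs_equal_single_run(self, rng):
        ev = _events([(4.0, 1.5, "a")])
        design = build_design(ev, None, tr=1.0, n_vols=40, hp_cutoff_s=np.inf)
        data = design.values @ rng.normal(0, 1, (design.n_regressors, 4)) \
            + rng.normal(0, 0.3, (40, 4))
        c = np.zeros(design.n_regressors)
        c[0] = 1.0
        m = fit_glm(data, design, c)
        comb = fixed_effects_combine([m, m, m])
        np.testing.assert_allclose(comb.cope, m.cope, atol=1e-12)

    def test_inverse_variance_weighting(self):
        from handsight.glm import ContrastMap
        a = ContrastMap(cope=np.array([1.0]), var_cope=np.array([1.0]),
                        z=np.array([1.0]), contrast_vector=np.array([1.0]),
                        dof=10)
        b = ContrastMap(cope=np.array([3.0]), var_cope=np.array([0.25]),
                        z=np.array([6.0]), contrast_vector=np.array([1.0]),
                        dof=10)
        comb = fixed_effects_combine([a, b])
        # weights 1 and 4: (1*1 + 4*3)/5
        assert comb.cope == pytest.approx(13.0 / 5.0)
        assert comb.var_cope == pytest.approx(1.0 / 5.0)
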