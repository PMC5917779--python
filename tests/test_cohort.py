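import hashlib

import numpy as np
import pytest

from handsight import io as hio
from handsight.cohort import (CohortConfig, build_labels, generate_cohort,
                              generate_subject_data, make_behaviour,
                              make_truth, plant_bivariate)


class TestPlantBivariate:
    def test_perfect_correlation_is_affine(self, rng):
        s = rng.normal(2.0, 3.0, 50)
        y = plant_bivariate(s, rho=1.0, noise_sd=0.0, seed=1)
        assert np.corrcoef(s, y)[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_zero_rho_large_sample(self, rng):
        s = rng.normal(0, 1, 5000)
        y = plant_bivariate(s, rho=0.0, seed=2)
        assert abs(np.corrcoef(s, y)[0, 1]) < 0.05

    def test_half_rho_empirical_recovery(self, rng):
        s = rng.normal(0, 1, 10_000)
        y = plant_bivariate(s, rho=0.5, seed=3)
        assert 0.48 <= np.corrcoef(s, y)[0, 1] <= 0.52

    def test_exact_at_default_noise(self, rng):
        s = rng.uniform(0, 5, 31)
        y = plant_bivariate(s, rho=0.55, seed=4)
        assert np.corrcoef(s, y)[0, 1] == pytest.approx(0.55, abs=1e-10)
        assert y.std() == pytest.approx(1.0, abs=1e-10)

    def test_constant_scores_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            plant_bivariate(np.ones(10), rho=0.5, seed=0)


class TestConfigValidation:
    def test_degenerate_configs_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(n_onehanders=0)
        with pytest.raises(ValueError):
            CohortConfig(rho_usage_activity=1.5)
        with pytest.raises(ValueError):
            CohortConfig(rho_usage_activity=1.0, noise_sd=0.0)
        with pytest.raises(ValueError):
            CohortConfig(grid_dims=(6, 6, 4))

    def test_unknown_keys_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            CohortConfig.from_dict({"n_onehanders": 8, "bogus": 1})

    def test_midline_half_integral_on_even_grid(self):
        assert CohortConfig().midline_x == 11.5


class TestBehaviouralCohort:
    def test_zero_inflation_produces_ties(self, small_config):
        beh = make_behaviour(small_config)
        oh = beh[beh.group == "one_hander"]
        items = oh[[f"mal_{i:02d}" for i in range(1, 28)]].to_numpy()
        assert (items.sum(axis=1) == 0).any()  # non-users exist
        assert items.sum(axis=1).max() > 0     # and users exist

    def test_item_range_and_wear_range(self, small_config):
        beh = make_behaviour(small_config)
        scored = beh[beh.wear_time.notna()]
        items = scored[[f"mal_{i:02d}" for i in range(1, 28)]].to_numpy()
        assert set(np.unique(items)) <= {0.0, 1.0, 2.0}
        assert scored.wear_time.between(0, 5).all()

    def test_truth_plants_exact_cohort_correlation(self, small_config):
        from handsight.behaviour import usage_table
        beh = make_behaviour(small_config)
        truth = make_truth(small_config, beh)
        scored = usage_table(beh)
        oh = scored[scored.group == "one_hander"]
        merged = oh.merge(truth, on="subject_id")
        r = np.corrcoef(merged.usage_score, merged.z_missing_true)[0, 1]
        assert r == pytest.approx(small_config.rho_usage_connectivity,
                                  abs=1e-10)

    def test_subject_stream_stable_under_cohort_resize(self, small_config):
        cfg_small = small_config
        cfg_big = CohortConfig(**{**cfg_small.to_dict(),
                                  "n_onehanders": cfg_small.n_onehanders + 3})
        a = make_behaviour(cfg_small)
        b = make_behaviour(cfg_big)
        first = a[a.subject_id == "sub-oh01"].iloc[0]
        again = b[b.subject_id == "sub-oh01"].iloc[0]
        assert (first == again).all()


class TestOnDiskCohort:
    def _digest(self, path):
        return hashlib.sha256(path.read_bytes()).hexdigest()

    def test_deterministic_and_round_trips(self, tmp_path):
        cfg = CohortConfig(n_onehanders=4, n_controls=4, grid_dims=(16, 16, 10),
                           n_vols_rest=60, n_vols_task=120, n_runs_task=2,
                           controls_missing_questionnaire=0,
                           controls_without_localizer=0, seed=9)
        d1 = generate_cohort(cfg, tmp_path / "a")
        d2 = generate_cohort(cfg, tmp_path / "b")
        assert self._digest(d1 / "behaviour.tsv") == \
            self._digest(d2 / "behaviour.tsv")
        bold = "sub-oh01/func/task-visual_run-1_bold.nii.gz"
        assert hio.load_nifti(d1 / bold).tobytes() == \
            hio.load_nifti(d2 / bold).tobytes()

        ev = hio.read_events(
            d1 / "sub-oh01/func/task-visual_run-1_events.tsv")
        assert {"onset", "duration", "trial_type"} <= set(ev.columns)
        assert len(ev) == 4 * cfg.trials_per_condition
        motion = hio.read_motion(
            d1 / "sub-oh01/func/task-rest_motion.par")
        assert motion.shape == (cfg.n_vols_rest, 6)

    def test_labels_mirror_symmetric(self):
        labels = build_labels((24, 24, 16))
        flipped = labels.visual_left[::-1, :, :]
        np.testing.assert_array_equal(flipped, labels.visual_right)
        np.testing.assert_array_equal(labels.sm_left[::-1, :, :],
                                      labels.sm_right)

    def test_compartments_disjoint(self):
        labels = build_labels((24, 24, 16))
        total = (labels.visual_left.astype(int) + labels.visual_right
                 + labels.sm_left + labels.sm_right + labels.wm + labels.csf)
        assert total.max() == 1


class TestSubjectData:
    def test_motion_contains_occasional_spikes(self, small_config):
        # spike probability 0.02/volume: across a cohort some must appear
        beh = make_behaviour(small_config)
        truth = make_truth(small_config, beh)
        labels = build_labels(small_config.grid_dims)
        from handsight.glm import spike_volumes
        count = 0
        for _, row in beh.head(4).iterrows():
            subj = generate_subject_data(
                small_config, row,
                truth.set_index("subject_id").loc[row.subject_id], labels)
            _, motion = subj.rest
            count += spike_volumes(motion).size
        assert count > 0
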