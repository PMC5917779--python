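import numpy as np
import pytest

from handsight.stats import (ancova_usage, commonality_two_predictor,
                             fisher_rz_compare, group_tests, part_correlation,
                             permutation_pvalue)


def _orthonormal_triplet(n=48, seed=0):
    """Three exactly orthonormal, zero-mean unit vectors."""
    rng = np.random.default_rng(seed)
    M = rng.normal(0, 1, (n, 3))
    M -= M.mean(axis=0)
    Q, _ = np.linalg.qr(M)
    Q -= Q.mean(axis=0)
    Q, _ = np.linalg.qr(Q)
    return Q[:, 0], Q[:, 1], Q[:, 2]


def _vectors_with_correlations(r_xy, r_xz, r_yz, n=48, seed=0):
    """Construct x, y, z whose empirical correlations match exactly."""
    e1, e2, e3 = _orthonormal_triplet(n, seed)
    x = e1
    z = r_xz * e1 + np.sqrt(1 - r_xz ** 2) * e2
    b = (r_yz - r_xy * r_xz) / np.sqrt(1 - r_xz ** 2)
    c = np.sqrt(1 - r_xy ** 2 - b ** 2)
    y = r_xy * e1 + b * e2 + c * e3
    return x, y, z


class TestPartCorrelation:
    def test_closed_form_worked_example(self):
        x, y, z = _vectors_with_correlations(0.6, 0.5, 0.5)
        res = part_correlation(x, y, z)
        assert res.r_part == pytest.approx((0.6 - 0.25) / np.sqrt(0.75),
                                           abs=1e-10)
        assert res.df == 46

    def test_orthogonal_covariate_reduces_to_plain_pearson(self):
        x, y, z = _vectors_with_correlations(0.4, 0.0, 0.0)
        res = part_correlation(x, y, z)
        assert res.r_part == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-10)

    def test_covariate_identical_to_measure_rejected(self, rng):
        y = rng.normal(0, 1, 20)
        with pytest.raises(ValueError, match="residual"):
            part_correlation(rng.normal(0, 1, 20), y, y)


class TestPermutationPvalue:
    def test_monotone_small_sample_matches_exhaustive_rate(self):
        # n = 4: of the 24 relabelings only identity and reversal reach
        # |r| = 1, so the tail rate is 1/12
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([0.2, 1.1, 1.9, 3.4])
        cov = np.array([0.01, -0.02, 0.015, -0.005])
        res = permutation_pvalue(x, y, cov, n_permutations=9999, seed=5)
        assert res.p_perm == pytest.approx(1.0 / 12.0, abs=0.015)

    def test_deterministic_given_seed(self, rng):
        x = rng.normal(0, 1, 25)
        y = 0.5 * x + rng.normal(0, 1, 25)
        cov = rng.normal(0, 1, 25)
        a = permutation_pvalue(x, y, cov, n_permutations=500, seed=42)
        b = permutation_pvalue(x, y, cov, n_permutations=500, seed=42)
        assert a.p_perm == b.p_perm

    def test_p_resolution_and_range(self, rng):
        x = rng.normal(0, 1, 15)
        y = rng.normal(0, 1, 15)
        cov = rng.normal(0, 1, 15)
        res = permutation_pvalue(x, y, cov, n_permutations=199, seed=0)
        assert 0 < res.p_perm <= 1
        assert (res.p_perm * 200) == pytest.approx(round(res.p_perm * 200))

    def test_invariant_to_joint_relabelling(self, rng):
        x = rng.normal(0, 1, 20)
        y = 0.4 * x + rng.normal(0, 1, 20)
        cov = rng.normal(0, 1, 20)
        perm = rng.permutation(20)
        a = permutation_pvalue(x, y, cov, n_permutations=9999, seed=7)
        b = permutation_pvalue(x[perm], y[perm], cov[perm],
                               n_permutations=9999, seed=7)
        assert a.r_part == pytest.approx(b.r_part, abs=1e-12)
        assert abs(a.p_perm - b.p_perm) < 0.02


class TestFisherRz:
    def test_group_comparison_active_prosthesis(self):
        cmp_ = fisher_rz_compare(0.51, 31, 0.03, 21, tails="one")
        assert cmp_.statistic == pytest.approx(1.76, abs=0.005)
        assert cmp_.p == pytest.approx(0.039, abs=0.001)

    def test_group_comparison_connectivity(self):
        cmp_ = fisher_rz_compare(0.55, 31, -0.28, 21, tails="one")
        assert cmp_.statistic == pytest.approx(3.0, abs=0.005)

    def test_within_group_two_tailed(self):
        cmp_ = fisher_rz_compare(0.51, 31, 0.33, 31, tails="two")
        assert cmp_.statistic == pytest.approx(0.82, abs=0.005)
        assert cmp_.p == pytest.approx(0.41, abs=0.005)

    def test_equal_correlations_give_zero(self):
        cmp_ = fisher_rz_compare(0.4, 20, 0.4, 25, tails="two")
        assert cmp_.statistic == 0.0
        assert cmp_.p == pytest.approx(1.0)

    def test_antisymmetry(self):
        a = fisher_rz_compare(0.5, 30, 0.2, 25, tails="two")
        b = fisher_rz_compare(0.2, 25, 0.5, 30, tails="two")
        assert a.statistic == pytest.approx(-b.statistic, abs=1e-12)

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            fisher_rz_compare(0.5, 3, 0.2, 25)


class TestCommonality:
    def test_summary_form_worked_example(self):
        part = commonality_two_predictor(R2_x=0.26, R2_z=0.22, r_xz=0.55,
                                         n=31)
        assert part.R2_full == pytest.approx(0.311, abs=0.001)
        assert part.shared == pytest.approx(0.169, abs=0.001)
        assert part.unique_x == pytest.approx(0.091, abs=0.001)
        assert part.unique_z == pytest.approx(0.051, abs=0.001)
        assert part.F_change_z == pytest.approx(2.07, abs=0.02)
        assert part.F_change_x == pytest.approx(3.70, abs=0.02)

    def test_orthogonal_predictors_share_nothing(self):
        part = commonality_two_predictor(R2_x=0.3, R2_z=0.2, r_xz=0.0)
        assert part.shared == pytest.approx(0.0, abs=1e-12)
        assert part.R2_full == pytest.approx(0.5, abs=1e-12)

    def test_identities_hold_exactly_for_data_input(self, rng):
        x = rng.normal(0, 1, 40)
        z = 0.5 * x + rng.normal(0, 1, 40)
        y = 0.4 * x + 0.3 * z + rng.normal(0, 1, 40)
        p = commonality_two_predictor(x, z, y)
        assert p.unique_x == pytest.approx(p.R2_full - p.R2_z, abs=1e-12)
        assert p.unique_z == pytest.approx(p.R2_full - p.R2_x, abs=1e-12)
        assert p.unique_x + p.unique_z + p.shared == pytest.approx(
            p.R2_full, abs=1e-12)

    def test_matches_nested_ols_oracle(self, rng):
        import statsmodels.api as sm
        x = rng.normal(0, 1, 35)
        z = 0.6 * x + rng.normal(0, 1, 35)
        y = 0.5 * x + 0.2 * z + rng.normal(0, 1, 35)
        p = commonality_two_predictor(x, z, y)
        r2 = {}
        for name, cols in (("full", [x, z]), ("x", [x]), ("z", [z])):
            X = sm.add_constant(np.column_stack(cols))
            r2[name] = sm.OLS(y, X).fit().rsquared
        assert p.R2_full == pytest.approx(r2["full"], abs=1e-10)
        assert p.unique_x == pytest.approx(r2["full"] - r2["z"], abs=1e-10)
        assert p.shared == pytest.approx(r2["x"] + r2["z"] - r2["full"],
                                         abs=1e-10)

    def test_collinear_predictors_rejected(self, rng):
        x = rng.normal(0, 1, 20)
        y = rng.normal(0, 1, 20)
        with pytest.raises(ValueError, match="collinear"):
            commonality_two_predictor(x, 2.0 * x + 1.0, y)


class TestAncova:
    def test_null_subgroup_F_near_one(self, rng):
        n = 400
        usage = rng.normal(0, 1, n)
        y = 0.5 * usage + rng.normal(0, 1, n)
        sub = rng.choice(["a", "b"], n)
        out = ancova_usage(y, usage, sub)
        assert out["subgroup"].statistic < 5.0
        assert out["usage"].p < 1e-6

    def test_exact_linear_usage(self, rng):
        usage = rng.normal(0, 1, 30)
        sub = np.repeat(["a", "b"], 15)
        out = ancova_usage(2.0 * usage, usage, sub)
        assert out["model"].extra["R2"] == pytest.approx(1.0, abs=1e-10)
        assert out["usage"].statistic > 1e6

    def test_matches_rss_decomposition_oracle(self, rng):
        n = 28
        usage = rng.normal(0, 1, n)
        sub = rng.choice(["a", "b"], n)
        y = 0.4 * usage + 0.3 * (sub == "a") + rng.normal(0, 1, n)
        out = ancova_usage(y, usage, sub)
        # partial F for usage by explicit nested RSS comparison
        X_full = np.column_stack([np.ones(n), usage, (sub == "a")])
        X_red = np.column_stack([np.ones(n), (sub == "a")])
        rss = lambda X: np.sum((y - X @ np.linalg.lstsq(X, y, rcond=None)[0])
                               ** 2)
        df_resid = n - 3
        F_oracle = (rss(X_red) - rss(X_full)) / (rss(X_full) / df_resid)
        assert out["usage"].statistic == pytest.approx(F_oracle, abs=1e-8)

    def test_single_level_subgroup_rejected(self, rng):
        with pytest.raises(ValueError):
            ancova_usage(rng.normal(0, 1, 10), rng.normal(0, 1, 10),
                         np.repeat("a", 10))


class TestGroupTests:
    def test_identical_samples(self, rng):
        a = rng.normal(0, 1, 12)
        assert group_tests(a, a.copy(), kind="t").statistic == pytest.approx(0)
        assert group_tests(a, a.copy(), kind="ks").statistic == pytest.approx(0)

    def test_fully_separated_samples_give_U_zero(self):
        out = group_tests([1.0, 2.0, 3.0], [4.0, 5.0, 6.0],
                          kind="mann_whitney")
        assert out.statistic == 0.0

    def test_t_matches_textbook_formula(self, rng):
        a = rng.normal(0, 1, 14)
        b = rng.normal(0.5, 1.2, 17)
        out = group_tests(a, b, kind="t")
        sp2 = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) \
            / (len(a) + len(b) - 2)
        t_oracle = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / len(a)
                                                          + 1 / len(b)))
        assert out.statistic == pytest.approx(t_oracle, abs=1e-10)
        assert out.dof == 29

    def test_U_matches_exhaustive_rank_count(self, rng):
        a = rng.normal(0, 1, 8)
        b = rng.normal(0.3, 1, 9)
        out = group_tests(a, b, kind="mann_whitney")
        u_oracle = sum((x > y) + 0.5 * (x == y) for x in a for y in b)
        assert out.statistic == pytest.approx(u_oracle)

    def test_ks_Z_statistic(self, rng):
        a = rng.normal(0, 1, 30)
        b = rng.normal(0.2, 1, 25)
        out = group_tests(a, b, kind="ks")
        assert out.extra["Z"] == pytest.approx(
            out.statistic * np.sqrt(30 * 25 / 55), abs=1e-12)

    def test_anova_2x2_returns_three_effects(self, rng):
        n = 40
        ga = np.repeat(["g1", "g2"], n // 2)
        gb = np.tile(["t1", "t2"], n // 2)
        y = rng.normal(0, 1, n) + 0.8 * (ga == "g1")
        out = group_tests(None, kind="anova2x2", values=y, factor_a=ga,
                          factor_b=gb)
        assert set(out.extra) == {"A", "B", "interaction"}
        assert out.extra["A"]["df"] == (1.0, 36.0)

    def test_shapiro_flags_heavy_tails(self, rng):
        heavy = rng.standard_cauchy(200)
        assert group_tests(heavy, kind="shapiro").p < 0.01
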