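"""Gated tests, correlations, multiplicity control, PANSS and cognition scoring."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from banditflame.cohort_stats import (
    adjusted_group_test,
    bh_adjust,
    bonferroni_threshold,
    cohens_d,
    composite_cognitive_score,
    gated_correlation,
    gated_group_test,
    panss_factors,
    partial_correlation,
)


class TestGatedGroupTest:
    def test_identical_groups_give_null_result(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 40)
        vals = np.concatenate([x, x])
        groups = np.array(["A"] * 40 + ["B"] * 40)
        r = gated_group_test(vals, groups)
        assert r.cohens_d == pytest.approx(0.0)
        assert r.p_value > 0.9

    def test_unit_effect_recovers_d_near_one(self):
        rng = np.random.default_rng(1)
        ds = []
        for _ in range(50):
            a = rng.normal(0, 1, 200)
            b = rng.normal(1, 1, 200)
            vals = np.concatenate([a, b])
            groups = np.array(["A"] * 200 + ["B"] * 200)
            ds.append(gated_group_test(vals, groups).cohens_d)
        assert abs(np.mean(ds) + 1.0) < 0.15  # d = (meanA - meanB) = -1

    def test_normal_data_routed_to_t_test(self):
        rng = np.random.default_rng(2)
        count = 0
        for _ in range(100):
            vals = np.concatenate([rng.normal(0, 1, 19), rng.normal(0, 1, 45)])
            groups = np.array(["A"] * 19 + ["B"] * 45)
            count += gated_group_test(vals, groups).test_used == "t"
        assert count >= 85

    def test_heavy_tailed_data_routed_to_mann_whitney(self):
        rng = np.random.default_rng(3)
        count = 0
        for _ in range(100):
            vals = np.concatenate([rng.lognormal(0, 1, 45),
                                   rng.lognormal(0, 1, 45)])
            groups = np.array(["A"] * 45 + ["B"] * 45)
            count += gated_group_test(vals, groups).test_used == "mann_whitney"
        assert count >= 95

    def test_type_one_error_calibrated_under_both_nulls(self):
        rng = np.random.default_rng(4)
        for sampler in (lambda n: rng.normal(0, 1, n),
                        lambda n: rng.lognormal(0, 1, n)):
            rej = 0
            reps = 1000
            for _ in range(reps):
                vals = np.concatenate([sampler(19), sampler(45)])
                groups = np.array(["A"] * 19 + ["B"] * 45)
                rej += gated_group_test(vals, groups).p_value < 0.05
            assert 0.03 < rej / reps < 0.07

    def test_constant_variable_rejected(self):
        vals = np.ones(20)
        groups = np.array(["A"] * 10 + ["B"] * 10)
        with pytest.raises(ValueError, match="constant"):
            gated_group_test(vals, groups, variable="flat")


class TestGatedCorrelation:
    def test_perfect_linear_relation(self):
        x = np.linspace(0, 1, 30)
        r = gated_correlation(x, x)
        assert r.coefficient == pytest.approx(1.0)

    def test_near_perfect_negative_relation(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 100)
        y = -x + rng.normal(0, 1e-4, 100)
        r = gated_correlation(x, y)
        assert r.coefficient == pytest.approx(-1.0, abs=0.01)

    def test_bivariate_normal_rho_recovered_at_study_n(self):
        rng = np.random.default_rng(6)
        rho = 0.4
        ests = []
        for _ in range(1000):
            z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=43)
            ests.append(gated_correlation(z[:, 0], z[:, 1]).coefficient)
        assert abs(np.mean(ests) - rho) < 0.03


class TestPartialCorrelation:
    def test_reduces_to_plain_correlation_without_covariates(self):
        rng = np.random.default_rng(7)
        x, y = rng.normal(0, 1, 50), rng.normal(0, 1, 50)
        plain = np.corrcoef(x, y)[0, 1]
        r = partial_correlation(x, y)
        assert r.coefficient == pytest.approx(plain, abs=1e-12)

    def test_shared_covariate_explains_away_association(self):
        rng = np.random.default_rng(8)
        z = rng.normal(0, 1, 2000)
        x = z + rng.normal(0, 0.5, 2000)
        y = z + rng.normal(0, 0.5, 2000)
        r = partial_correlation(x, y, z)
        assert abs(r.coefficient) < 0.1

    def test_matches_precision_matrix_identity(self):
        # three-variable Gaussian with known precision: pcor(x,y | z)
        # equals -Omega_xy / sqrt(Omega_xx * Omega_yy)
        omega = np.array([[2.0, -0.8, -0.4],
                          [-0.8, 2.5, -0.6],
                          [-0.4, -0.6, 1.8]])
        target = -omega[0, 1] / np.sqrt(omega[0, 0] * omega[1, 1])
        rng = np.random.default_rng(9)
        x = rng.multivariate_normal(np.zeros(3), np.linalg.inv(omega), size=10_000)
        r = partial_correlation(x[:, 0], x[:, 1], x[:, 2])
        assert abs(r.coefficient - target) < 0.02

    def test_agrees_with_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(10)
        df = pd.DataFrame(rng.normal(0, 1, size=(60, 4)),
                          columns=["x", "y", "c1", "c2"])
        ours = partial_correlation(df.x, df.y, df[["c1", "c2"]])
        theirs = pg.partial_corr(df, x="x", y="y", covar=["c1", "c2"])
        assert ours.coefficient == pytest.approx(theirs["r"].iloc[0], abs=1e-10)
        assert ours.p_value == pytest.approx(theirs["p_val"].iloc[0], abs=1e-8)

    def test_collinear_covariates_rejected(self):
        rng = np.random.default_rng(11)
        x, y = rng.normal(0, 1, 30), rng.normal(0, 1, 30)
        z = rng.normal(0, 1, 30)
        with pytest.raises(ValueError, match="rank deficient"):
            partial_correlation(x, y, np.column_stack([z, 2 * z]))

    def test_spearman_variant_is_rank_invariant(self):
        rng = np.random.default_rng(12)
        x, y = rng.normal(0, 1, 80), rng.normal(0, 1, 80)
        z = rng.normal(0, 1, 80)
        a = partial_correlation(x, y, z, method="spearman")
        b = partial_correlation(np.exp(x), y, z, method="spearman")
        assert a.coefficient == pytest.approx(b.coefficient, abs=1e-12)


def bh_brute_force(p: np.ndarray, alpha: float) -> np.ndarray:
    """Reject H(i) iff i <= k*, k* = max{k : p_(k) <= k*alpha/m}."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    kstar = 0
    for k in range(1, m + 1):
        if sorted_p[k - 1] <= k * alpha / m:
            kstar = k
    reject = np.zeros(m, dtype=bool)
    reject[order[:kstar]] = True
    return reject


class TestMultiplicity:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.031])[0] == pytest.approx(0.031)

    def test_hand_computed_step_up(self):
        adj = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_matches_brute_force_rejection_sets(self):
        rng = np.random.default_rng(13)
        for _ in range(1000):
            m = int(rng.integers(1, 20))
            p = rng.uniform(0, 1, m)
            alpha = float(rng.uniform(0.01, 0.2))
            assert np.array_equal(bh_adjust(p) <= alpha, bh_brute_force(p, alpha))

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(14)
        p = rng.uniform(0, 1, 40)
        _, adj, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(bh_adjust(p), adj)

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 1.2])

    def test_bonferroni_threshold_values(self):
        assert round(bonferroni_threshold(0.05, 3), 3) == 0.017
        assert bonferroni_threshold(0.05, 1) == 0.05
        assert bonferroni_threshold(0.05, 5) == 0.01
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)


class TestAdjustedGroupTest:
    def test_independent_covariates_leave_p_close_to_unadjusted(self):
        rng = np.random.default_rng(15)
        diffs = []
        for _ in range(100):
            groups = np.array(["A"] * 30 + ["B"] * 30)
            y = rng.normal(0, 1, 60) + 0.8 * (groups == "B")
            cov = pd.DataFrame({"c": rng.normal(0, 1, 60)})
            adj = adjusted_group_test(y, groups, cov)["p_value"]
            from scipy.stats import ttest_ind

            raw = ttest_ind(y[:30], y[30:]).pvalue
            diffs.append(np.log10(adj + 1e-12) - np.log10(raw + 1e-12))
        assert abs(np.mean(diffs)) < 0.2

    def test_confounded_effect_attenuates_toward_null(self):
        rng = np.random.default_rng(16)
        adj_ps, raw_ps = [], []
        for _ in range(50):
            groups = np.array(["A"] * 30 + ["B"] * 30)
            bmi = rng.normal(23, 3, 60) + 3.0 * (groups == "B")
            y = 0.5 * bmi + rng.normal(0, 1, 60)  # marker driven by BMI only
            adj_ps.append(adjusted_group_test(y, groups,
                                              pd.DataFrame({"bmi": bmi}))["p_value"])
            adj0 = adjusted_group_test(y, groups)
            raw_ps.append(adj0["p_value"])
        assert np.median(adj_ps) > np.median(raw_ps)

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(17)
        rej = 0
        for _ in range(500):
            groups = np.array(["A"] * 19 + ["B"] * 45)
            y = rng.normal(0, 1, 64)
            cov = pd.DataFrame({"age": rng.normal(33, 10, 64),
                                "bmi": rng.normal(25, 4, 64)})
            rej += adjusted_group_test(y, groups, cov)["p_value"] < 0.05
        assert 0.03 < rej / 500 < 0.07


class TestPanssFactors:
    def test_minimum_ratings_give_minimum_sums(self):
        items = {f"P{i}": 1 for i in range(1, 8)}
        items.update({f"N{i}": 1 for i in range(1, 8)})
        items.update({f"G{i}": 1 for i in range(1, 17)})
        f = panss_factors(items)
        assert (f.negative, f.positive, f.disorganized, f.depressive) == (6, 4, 3, 4)

    def test_maximum_ratings_give_maximum_sums(self):
        items = {f"P{i}": 7 for i in range(1, 8)}
        items.update({f"N{i}": 7 for i in range(1, 8)})
        items.update({f"G{i}": 7 for i in range(1, 17)})
        f = panss_factors(items)
        assert f.negative == 42
        assert f.disorganized == 21

    def test_hand_summed_disorganized_factor(self):
        items = {f"P{i}": 1 for i in range(1, 8)}
        items.update({f"N{i}": 1 for i in range(1, 8)})
        items.update({f"G{i}": 1 for i in range(1, 17)})
        items.update({"P2": 3, "N5": 2, "G11": 4})
        assert panss_factors(items).disorganized == 9

    def test_out_of_range_item_rejected(self):
        items = {f"P{i}": 1 for i in range(1, 8)}
        items.update({f"N{i}": 1 for i in range(1, 8)})
        items.update({f"G{i}": 1 for i in range(1, 17)})
        items["N1"] = 8
        with pytest.raises(ValueError):
            panss_factors(items)

    @settings(max_examples=200, deadline=None)
    @given(st.tuples(*[st.integers(1, 7)] * 3))
    def test_disorganized_factor_bounds_hold(self, triple):
        items = {f"P{i}": 1 for i in range(1, 8)}
        items.update({f"N{i}": 1 for i in range(1, 8)})
        items.update({f"G{i}": 1 for i in range(1, 17)})
        items["P2"], items["N5"], items["G11"] = triple
        f = panss_factors(items)
        assert 3 <= f.disorganized <= 21
        assert f.disorganized == sum(triple)


class TestCompositeCognitiveScore:
    def test_hc_mean_is_exactly_zero(self):
        rng = np.random.default_rng(18)
        lns = rng.normal(20, 2, 64)
        sct = rng.normal(70, 15, 64)
        hc = np.array([True] * 19 + [False] * 45)
        score = composite_cognitive_score(lns, sct, hc)
        assert score[hc].mean() == pytest.approx(0.0, abs=1e-12)

    def test_subject_at_hc_means_scores_zero(self):
        lns = np.array([18.0, 22.0, 20.0])
        sct = np.array([70.0, 90.0, 80.0])
        hc = np.array([True, True, False])
        score = composite_cognitive_score(lns, sct, hc)
        assert score[2] == pytest.approx(0.0)

    def test_zero_variance_subtest_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            composite_cognitive_score([20, 20, 19], [70, 80, 75],
                                      [True, True, False])


class TestCohensD:
    def test_known_separation(self):
        a = np.array([0.0, 1.0, 2.0])
        b = np.array([2.0, 3.0, 4.0])
        assert cohens_d(a, b) == pytest.approx(-2.0)
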