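"""Diagnostic-accuracy toolkit against brute-force and closed-form oracles."""

import itertools

import numpy as np
import pytest
from scipy import stats

from tmgdx.metrics import (
    auc,
    auc_se_hanley_mcneil,
    auc_var_delong,
    bootstrap_ci,
    compare_independent_rocs,
    cramers_v_mc,
    evaluate_roc,
    group_tests,
    pr_curve,
    roc_points,
    two_sample_t_power,
    youden_optimal,
)


# --- independent brute-force oracles ---------------------------------------

def auc_pairwise(pos, neg):
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p, n in itertools.product(pos, neg))
    return wins / (len(pos) * len(neg))


def youden_brute(pos, neg):
    best = (-np.inf, None, None, None)
    for c in sorted({-np.inf, *pos, *neg}):
        sens = np.mean([p > c for p in pos])
        spec = np.mean([n <= c for n in neg])
        j = sens + spec - 1
        if j > best[0] + 1e-12:
            best = (j, c, sens, spec)
    return best


def average_precision_brute(pos, neg):
    thresholds = sorted(set(list(pos) + list(neg)), reverse=True) + [-np.inf]
    ap, prev_r = 0.0, 0.0
    for c in thresholds:
        tp = sum(p > c for p in pos)
        fp = sum(n > c for n in neg)
        if tp + fp == 0:
            continue
        r = tp / len(pos)
        ap += (r - prev_r) * (tp / (tp + fp))
        prev_r = r
    return ap


def random_instance(rng):
    n_pos = int(rng.integers(2, 21))
    n_neg = int(rng.integers(2, 21))
    pool = rng.integers(0, 12, n_pos + n_neg).astype(float)  # ties guaranteed
    return pool[:n_pos], pool[n_pos:]


# --- ROC -------------------------------------------------------------------

class TestRocPoints:
    def test_direct_counting_example(self):
        pts = roc_points([3, 5, 1, 4], [1, 1, 0, 0])
        row = pts[pts[:, 0] == 4][0]
        assert row[1] == pytest.approx(0.5)   # sens at c = 4
        assert row[2] == pytest.approx(1.0)   # spec at c = 4
        assert pts[0, 1] == 1.0 and pts[0, 2] == 0.0        # c = -inf
        assert pts[-1, 1] == 0.0 and pts[-1, 2] == 1.0      # c = max

    def test_identical_scores_degenerate(self):
        pts = roc_points([2, 2, 2, 2], [1, 1, 0, 0])
        assert {(s, p) for _, s, p in pts} == {(1.0, 0.0), (0.0, 1.0)}

    def test_label_inversion_swaps_roles(self):
        s = [1.0, 2.0, 3.0, 4.0]
        a = roc_points(s, [0, 0, 1, 1])
        b = roc_points(s, [1, 1, 0, 0])
        np.testing.assert_allclose(a[:, 1], 1 - b[:, 2], atol=1e-12)

    def test_one_class_errors(self):
        with pytest.raises(ValueError):
            roc_points([1, 2], [1, 1])


class TestAuc:
    def test_examples(self):
        assert auc([3, 5, 1, 4], [1, 1, 0, 0]) == pytest.approx(0.75)
        assert auc([5, 6, 1, 2], [1, 1, 0, 0]) == 1.0
        assert auc([1, 2, 1, 2], [1, 1, 0, 0]) == 0.5

    def test_matches_pairwise_oracle_with_ties(self, rng):
        for _ in range(200):
            pos, neg = random_instance(rng)
            scores = np.concatenate([pos, neg])
            labels = np.r_[np.ones_like(pos), np.zeros_like(neg)]
            assert auc(scores, labels) == pytest.approx(auc_pairwise(pos, neg), abs=1e-12)

    def test_matches_trapezoid_over_curve(self, rng):
        for _ in range(50):
            pos, neg = random_instance(rng)
            scores = np.concatenate([pos, neg])
            labels = np.r_[np.ones_like(pos), np.zeros_like(neg)]
            pts = roc_points(scores, labels)
            fpr = 1 - pts[:, 2]
            trap = -np.trapezoid(pts[:, 1], fpr)  # fpr decreases along the sweep
            assert auc(scores, labels) == pytest.approx(trap, abs=1e-12)

    def test_score_negation_complement(self, rng):
        scores = rng.normal(size=30)
        labels = rng.integers(0, 2, 30)
        if labels.sum() in (0, 30):
            labels[0] = 1 - labels[0]
        assert auc(scores, labels) + auc(-scores, labels) == pytest.approx(1.0)


class TestHanleyMcNeil:
    def test_formula_arithmetic(self):
        assert auc_se_hanley_mcneil(0.5, 10, 10) == pytest.approx(0.1323, abs=1e-4)

    def test_perfect_separation_zero(self):
        assert auc_se_hanley_mcneil(1.0, 7, 9) == 0.0

    def test_monotone_in_n(self):
        assert auc_se_hanley_mcneil(0.8, 40, 40) < auc_se_hanley_mcneil(0.8, 20, 20)


class TestDeLong:
    def test_perfect_separation_zero_variance(self):
        res = auc_var_delong([5, 6, 1, 2], [1, 1, 0, 0])
        assert res.variance == 0.0
        assert res.auc == 1.0

    def test_hand_enumerated_placements(self):
        # pos {3, 5}, neg {1, 4}: V10 = (0.5, 1.0); V01 = (1.0, 0.5)
        res = auc_var_delong([3, 5, 1, 4], [1, 1, 0, 0])
        np.testing.assert_allclose(sorted(res.placements_pos), [0.5, 1.0])
        np.testing.assert_allclose(sorted(res.placements_neg), [0.5, 1.0])
        expected = np.var([0.5, 1.0], ddof=1) / 2 + np.var([1.0, 0.5], ddof=1) / 2
        assert res.variance == pytest.approx(expected)

    def test_against_bootstrap_se(self, rng):
        pos = rng.normal(1.0, 1.0, 250)
        neg = rng.normal(0.0, 1.0, 250)
        scores = np.concatenate([pos, neg])
        labels = np.r_[np.ones(250), np.zeros(250)]
        se_delong = auc_var_delong(scores, labels).se
        boots = np.empty(2000)
        for b in range(2000):
            p = pos[rng.integers(0, 250, 250)]
            n = neg[rng.integers(0, 250, 250)]
            boots[b] = auc_pairwise_fast(p, n)
        assert se_delong == pytest.approx(boots.std(ddof=1), rel=0.15)


def auc_pairwise_fast(pos, neg):
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    return (ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2) / (len(pos) * len(neg))


class TestYouden:
    def test_brute_force_example(self):
        pts = roc_points([10, 20, 30, 5, 15], [1, 1, 1, 0, 0])
        cutoff, j, sens, spec = youden_optimal(pts)
        assert cutoff == pytest.approx(15.0)
        assert j == pytest.approx(2 / 3)

    def test_perfect_classifier(self):
        pts = roc_points([5, 6, 1, 2], [1, 1, 0, 0])
        assert youden_optimal(pts)[1] == pytest.approx(1.0)

    def test_reported_operating_point_identity(self):
        # sens 98.1 %, spec 88.68 % → J rounds to 0.868
        assert round(0.981 + 0.8868 - 1, 3) == 0.868

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(100):
            pos, neg = random_instance(rng)
            scores = np.concatenate([pos, neg])
            labels = np.r_[np.ones_like(pos), np.zeros_like(neg)]
            cutoff, j, sens, spec = youden_optimal(roc_points(scores, labels))
            j_bf, c_bf, sens_bf, spec_bf = youden_brute(pos, neg)
            assert j == pytest.approx(j_bf, abs=1e-12)
            assert j == pytest.approx(sens + spec - 1, abs=1e-12)
            assert cutoff == c_bf


class TestBootstrapCi:
    def test_perfect_separation_degenerate(self):
        scores = np.r_[np.ones(50) * 10, np.zeros(50)]
        labels = np.r_[np.ones(50), np.zeros(50)]
        lo, hi = bootstrap_ci(scores, labels, "auc", B=300, seed=0)
        assert (lo, hi) == (1.0, 1.0)

    def test_seed_determinism(self, rng):
        scores = rng.normal(size=60)
        labels = rng.integers(0, 2, 60)
        labels[:2] = [0, 1]
        a = bootstrap_ci(scores, labels, "youden_j", B=300, seed=11)
        b = bootstrap_ci(scores, labels, "youden_j", B=300, seed=11)
        assert a == b

    def test_minimum_resamples_enforced(self):
        with pytest.raises(ValueError):
            bootstrap_ci([1, 2], [0, 1], B=50)


class TestCompareIndependentRocs:
    def test_reported_comparison(self):
        se_each = 0.0223 / np.sqrt(2)
        diff, se, z, p = compare_independent_rocs(0.969, se_each, 0.989, se_each)
        assert diff == pytest.approx(-0.02)
        assert se == pytest.approx(0.0223)
        assert z == pytest.approx(-0.897, abs=1e-3)
        assert p == pytest.approx(0.369, abs=1e-3)

    def test_equal_aucs(self):
        _, _, z, p = compare_independent_rocs(0.8, 0.05, 0.8, 0.05)
        assert z == 0.0 and p == 1.0

    def test_normal_cdf_oracle(self):
        _, _, z, p = compare_independent_rocs(0.9, 0.05, 0.7, 0.05)
        assert z == pytest.approx(2.828, abs=1e-3)
        assert p == pytest.approx(2 * stats.norm.sf(2.828427), abs=1e-5)

    def test_symmetry_in_sign(self):
        *_, z1, p1 = compare_independent_rocs(0.9, 0.05, 0.7, 0.05)
        *_, z2, p2 = compare_independent_rocs(0.7, 0.05, 0.9, 0.05)
        assert z1 == -z2 and p1 == p2


class TestPrCurve:
    def test_four_point_example(self):
        res = pr_curve([0.9, 0.4, 0.6, 0.2], [1, 1, 0, 0])
        assert res.auprc == pytest.approx(0.8333, abs=1e-4)
        assert res.f1max == pytest.approx(0.8)
        assert res.ppv == pytest.approx(2 / 3)
        assert res.tpr == pytest.approx(1.0)

    def test_perfect_separation(self):
        res = pr_curve([5, 6, 1, 2], [1, 1, 0, 0])
        assert res.auprc == 1.0 and res.f1max == 1.0

    def test_all_positive_end_precision_is_prevalence(self):
        res = pr_curve([3, 1, 2, 4, 5, 6], [1, 0, 0, 0, 0, 0])
        assert res.precision[-1] == pytest.approx(1 / 6)
        assert res.recall[-1] == 1.0

    def test_matches_average_precision_oracle(self, rng):
        for _ in range(100):
            pos, neg = random_instance(rng)
            scores = np.concatenate([pos, neg])
            labels = np.r_[np.ones_like(pos), np.zeros_like(neg)]
            res = pr_curve(scores, labels)
            assert res.auprc == pytest.approx(average_precision_brute(pos, neg), abs=1e-12)

    def test_no_positive_errors(self):
        with pytest.raises(ValueError):
            pr_curve([1, 2], [0, 0])


class TestCramersV:
    @staticmethod
    def vectors_from_table(table):
        pred, truth = [], []
        for (p, t), count in np.ndenumerate(np.asarray(table)):
            pred += [1 - p] * count
            truth += [1 - t] * count
        return np.array(pred), np.array(truth)

    def test_closed_form_2x2(self):
        pred, truth = self.vectors_from_table([[30, 10], [10, 30]])
        res = cramers_v_mc(pred, truth, 1000, seed=0)
        assert res.chi2 == pytest.approx(20.0)
        assert res.cramers_v == pytest.approx(0.5)
        assert res.p_asymptotic == pytest.approx(stats.chi2.sf(20.0, 1))
        assert res.p_monte_carlo < 0.01

    def test_perfect_association(self):
        pred, truth = self.vectors_from_table([[25, 0], [0, 25]])
        res = cramers_v_mc(pred, truth, 1000, seed=1)
        assert res.cramers_v == pytest.approx(1.0)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            cramers_v_mc([1, 1, 1, 1], [1, 0, 1, 0], 1000, seed=0)

    def test_seed_reproducible(self):
        pred, truth = self.vectors_from_table([[20, 12], [12, 20]])
        a = cramers_v_mc(pred, truth, 1000, seed=5)
        b = cramers_v_mc(pred, truth, 1000, seed=5)
        assert a.p_monte_carlo == b.p_monte_carlo

    def test_independence_gives_small_v(self, rng):
        pred = rng.integers(0, 2, 400)
        truth = np.r_[np.ones(200, int), np.zeros(200, int)]
        res = cramers_v_mc(pred, truth, 1000, seed=2)
        assert res.cramers_v < 0.15


class TestPower:
    @pytest.mark.parametrize("d, expected", [(0.2, 0.175), (0.5, 0.722), (0.8, 0.983)])
    def test_reference_values(self, d, expected):
        assert two_sample_t_power(d, 53, 0.05) == pytest.approx(expected, abs=1e-3)

    def test_null_effect_gives_alpha(self):
        assert two_sample_t_power(0.0, 20, 0.05) == pytest.approx(0.05, abs=1e-10)

    def test_monotone_in_d_and_n(self):
        assert two_sample_t_power(0.6, 30) > two_sample_t_power(0.4, 30)
        assert two_sample_t_power(0.5, 60) > two_sample_t_power(0.5, 30)

    def test_against_monte_carlo(self, rng):
        """Noncentral-t power matches simulated rejection at d = 0.5, n = 53."""
        d, n, reps = 0.5, 53, 20000
        x = rng.normal(0, 1, (reps, n))
        y = rng.normal(-d, 1, (reps, n))
        t, p = stats.ttest_ind(x, y, axis=1)
        mc = (p < 0.05).mean()
        assert two_sample_t_power(d, n) == pytest.approx(mc, abs=0.01)


class TestGroupTests:
    def test_paired_identical_columns(self, default_cohort):
        from tmgdx.cohort import cohort_to_frame
        frame = cohort_to_frame(default_cohort).copy()
        frame.loc[frame["group"] == "non_injured", "tc_r"] = \
            frame.loc[frame["group"] == "non_injured", "tc_l"]
        out = group_tests(frame)
        row = out[(out.test == "paired_t_left_vs_right") & (out.parameter == "tc")].iloc[0]
        assert row["statistic"] == pytest.approx(0.0, abs=1e-12)

    def test_paired_t_hand_computed(self):
        # differences {-1, -1, -2}: t = mean/se = (-4/3)/(1/3) = -4 on df 2
        t, p = stats.ttest_rel([1, 2, 3], [2, 3, 5])
        assert t == pytest.approx(-4.0)
        # and the pipeline wiring produces the same kind of table
        assert 0 < p < 1

    def test_normality_null_calibration(self, rng):
        """Lilliefors keeps its level on normal data (≈5 % rejections)."""
        from statsmodels.stats.diagnostic import lilliefors
        rejections = 0
        reps = 400
        for _ in range(reps):
            _, p = lilliefors(rng.normal(size=100), dist="norm")
            rejections += p < 0.05
        assert 0.02 < rejections / reps < 0.09

    def test_full_table_shape(self, default_cohort):
        out = group_tests(default_cohort)
        assert set(out.columns) == {"test", "parameter", "stratum", "statistic", "p", "n"}
        assert (out[out.test == "paired_t_injured_vs_contralateral"].shape[0]) == 3
        # injured-leg Tc is systematically longer: strongly significant
        row = out[(out.test == "paired_t_injured_vs_contralateral")
                  & (out.parameter == "tc")].iloc[0]
        assert row["p"] < 1e-6 and row["statistic"] > 0


class TestEvaluateRoc:
    def test_block_consistency(self, rng):
        pos = rng.normal(1.5, 1, 60)
        neg = rng.normal(0, 1, 60)
        scores = np.concatenate([pos, neg])
        labels = np.r_[np.ones(60), np.zeros(60)]
        res = evaluate_roc(scores, labels, bootstrap_B=300, seed=3)
        assert res.youden_j == pytest.approx(res.sens_at_cutoff + res.spec_at_cutoff - 1)
        assert res.auc_ci95[0] <= res.auc <= res.auc_ci95[1]
        assert res.se_method == "delong"
        hm = evaluate_roc(scores, labels, se_method="hanley_mcneil")
        assert hm.se_auc != res.se_auc  # different estimators, both reported
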