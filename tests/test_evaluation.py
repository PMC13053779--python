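"""ROC, operating points, Kaplan-Meier and log-rank machinery."""

import itertools

import numpy as np
import numpy.testing as npt
import pytest

from oncosensi import evaluation, model
from oncosensi.evaluation import (
    km_estimate,
    log_rank,
    one_year_rfs,
    orient_scores,
    roc_auc,
    sensitivity_specificity,
)


def pairwise_auc(scores, labels):
    """Brute-force concordance oracle over all (positive, negative) pairs."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    pos, neg = s[y == 1], s[y == 0]
    total = sum(1.0 if p > n else 0.5 if p == n else 0.0
                for p, n in itertools.product(pos, neg))
    return total / (len(pos) * len(neg))


class TestROC:
    def test_cohort_auc_zscore_is_26_of_40_pairs(self, test_z, recurrence_labels):
        res = roc_auc(test_z["z_rt_auc"].to_numpy(), recurrence_labels)
        assert res.auc == pytest.approx(26 / 40)
        assert res.auc == pytest.approx(
            pairwise_auc(test_z["z_rt_auc"], recurrence_labels))

    def test_perfect_separation(self):
        assert roc_auc([1, 2, 3, 10, 11], [0, 0, 0, 1, 1]).auc == 1.0

    def test_all_tied_scores(self):
        assert roc_auc([5.0] * 6, [0, 0, 0, 1, 1, 1]).auc == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2, 3], [1, 1, 1])

    def test_reversed_scores_complement(self):
        rng = np.random.default_rng(3)
        s = rng.normal(size=30)
        y = rng.integers(0, 2, size=30)
        y[:2] = [0, 1]
        assert roc_auc(s, y).auc + roc_auc(-s, y).auc == pytest.approx(1.0)

    def test_invariant_under_monotone_transforms(self, test_z, recurrence_labels):
        s = test_z["z_growth_rate"].to_numpy()
        base = roc_auc(s, recurrence_labels).auc
        from scipy.stats import rankdata
        for transformed in (2.0 * s + 5.0, np.exp(s), rankdata(s)):
            assert roc_auc(transformed, recurrence_labels).auc == pytest.approx(base)

    def test_matches_reference_implementation_on_random_data(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(11)
        for _ in range(100):
            n = rng.integers(8, 40)
            s = np.round(rng.normal(size=n), 1)  # coarse scores force ties
            y = rng.integers(0, 2, size=n)
            if y.sum() in (0, n):
                y[0] = 1 - y[0]
            assert roc_auc(s, y).auc == pytest.approx(
                roc_auc_score(y, s), abs=1e-4)

    def test_hpv_orientation_flips_to_risk_increasing(self, test_z, recurrence_labels):
        # HPV-positive is protective: raw Z scores below 0.5, flipped above
        raw = roc_auc(test_z["z_hpv"].to_numpy(), recurrence_labels).auc
        oriented, sign = orient_scores(test_z["z_hpv"].to_numpy(), recurrence_labels)
        assert raw < 0.5 and sign == -1
        assert roc_auc(oriented, recurrence_labels).auc == pytest.approx(1 - raw)


class TestOperatingPoints:
    def test_cutoff_below_all_scores(self):
        sens, spec = sensitivity_specificity([1, 2, 3, 4], [0, 0, 1, 1], 0.0)
        assert (sens, spec) == (1.0, 0.0)

    def test_cutoff_above_all_scores(self):
        sens, spec = sensitivity_specificity([1, 2, 3, 4], [0, 0, 1, 1], 10.0)
        assert (sens, spec) == (0.0, 1.0)

    def test_separating_cutoff(self):
        assert sensitivity_specificity([1, 2, 3, 4], [0, 0, 1, 1], 2.5) == (1.0, 1.0)

    def test_roc_operating_points_consistent(self, test_z, recurrence_labels):
        res = roc_auc(test_z["z_rt_auc"].to_numpy(), recurrence_labels)
        for thr, sens, spec in res.operating_points:
            assert (sens, spec) == sensitivity_specificity(
                test_z["z_rt_auc"].to_numpy(), recurrence_labels, thr)


class TestKaplanMeier:
    def test_no_events_survival_one(self):
        km = km_estimate([100, 200, 300], [0, 0, 0])
        assert km.survival_at(1e9) == 1.0

    def test_five_subject_product_limit(self):
        # events at 131/273/316 among 5, two censored past one year:
        # (4/5)(3/4)(2/3) = 0.4
        assert one_year_rfs([131, 273, 316, 481, 446], [1, 1, 1, 0, 0]) == pytest.approx(0.4)

    def test_single_subject_step(self):
        km = km_estimate([100], [1])
        assert km.survival_at(99) == 1.0
        assert km.survival_at(100) == 0.0

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([-1, 5], [1, 0])

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(5)
        t = rng.integers(1, 100, size=40).astype(float)
        km = km_estimate(t, np.ones_like(t, dtype=int))
        for q in (10, 25, 50, 90):
            assert km.survival_at(q) == pytest.approx(np.mean(t > q))

    def test_matches_reference_implementation_on_random_data(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(23)
        for _ in range(100):
            n = rng.integers(5, 40)
            t = rng.integers(1, 500, size=n).astype(float)
            e = rng.integers(0, 2, size=n)
            km = km_estimate(t, e)
            ref = KaplanMeierFitter().fit(t, e)
            for q in (50.0, 200.0, 400.0):
                assert km.survival_at(q) == pytest.approx(
                    float(ref.predict(q)), abs=1e-4)


class TestLogRank:
    def test_identical_groups_zero_statistic(self):
        t = [100, 200, 300, 400]
        e = [1, 0, 1, 0]
        res = log_rank(t, e, t, e)
        assert res.chi_square == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_extreme_separation_tiny_p(self):
        res = log_rank([10] * 20, [1] * 20, [1000] * 20, [0] * 20)
        assert res.p_value < 0.001

    def test_hand_worked_six_subject_example(self):
        # Group A events at 6 and 10; group B event at 4, censored 8, 12.
        # Risk sets: t=4 n=6 (nA=3) dB=1; t=6 n=5 (nA=3) dA=1; t=10 n=3 (nA=2) dA=1.
        # O_A - E_A = (0-1/2) + (1-3/5) + (1-2/3) = 7/30
        # V = 1/4 + 6/25 + 2/9 = 641/900
        # chi2 = (7/30)^2 / (641/900) = 49/641
        res = log_rank([6, 10, 13], [1, 1, 0], [4, 8, 12], [1, 0, 0])
        expected = 49 / 641
        assert res.chi_square == pytest.approx(expected, abs=1e-6)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            log_rank([], [], [1, 2], [1, 1])

    def test_matches_reference_implementation_on_random_data(self):
        from lifelines.statistics import logrank_test

        rng = np.random.default_rng(31)
        for _ in range(100):
            na, nb = rng.integers(5, 25, size=2)
            ta = rng.integers(1, 300, size=na).astype(float)
            tb = rng.integers(1, 300, size=nb).astype(float)
            ea = rng.integers(0, 2, size=na)
            eb = rng.integers(0, 2, size=nb)
            if ea.sum() + eb.sum() == 0:
                ea[0] = 1
            ours = log_rank(ta, ea, tb, eb)
            ref = logrank_test(ta, tb, event_observed_A=ea, event_observed_B=eb)
            assert ours.chi_square == pytest.approx(ref.test_statistic, abs=1e-4)
            assert ours.p_value == pytest.approx(ref.p_value, abs=1e-4)


class TestCohortSurvivalSplit:
    def test_top_five_two_parameter_grouping_rfs(self, test_set, test_z,
                                                 recurrence_labels):
        # resistant = top five by the published two-parameter linear predictor:
        # one-year RFS 2/5 vs 8/9 in the remaining nine
        lp = np.asarray(model.linear_predictor(
            model.PUBLISHED_MODEL, test_z["z_growth_rate"], test_z["z_rt_auc"]))
        order = np.argsort(-lp)
        resistant = np.zeros(len(lp), dtype=bool)
        resistant[order[:5]] = True
        times = test_set["rfs_days"].to_numpy(dtype=float)
        s_res = one_year_rfs(times[resistant], recurrence_labels[resistant])
        s_sen = one_year_rfs(times[~resistant], recurrence_labels[~resistant])
        assert s_res == pytest.approx(2 / 5)
        assert s_sen == pytest.approx(8 / 9)
        res = log_rank(times[~resistant], recurrence_labels[~resistant],
                       times[resistant], recurrence_labels[resistant])
        assert res.p_value < 0.05
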