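"""Metrics: MAE, one-vs-rest AUC against a rank-sum oracle, subgroups,
reviewer-agreement arithmetic."""

import numpy as np
import pandas as pd
import pytest

from cardiov.evaluation import agreement_stats, mae, roc_auc_ovr, subgroup_eval


def rank_sum_auc(scores, positives):
    """Independent oracle: AUC = P(score_pos > score_neg) + 0.5 P(equal),
    by explicit pair enumeration (Mann-Whitney U / (n1 n2))."""
    pos = np.asarray(scores)[np.asarray(positives, bool)]
    neg = np.asarray(scores)[~np.asarray(positives, bool)]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestMae:
    def test_hand_cases(self):
        assert mae([0, 1, 2, 3], [0, 1, 2, 3]) == 0.0
        assert mae([0, 3], [3, 0]) == 3.0
        assert mae([0, 1, 2, 3], [1, 1, 2, 2]) == 0.5

    def test_order_invariance(self, rng):
        p = rng.integers(0, 4, 30)
        y = rng.integers(0, 4, 30)
        perm = rng.permutation(30)
        assert mae(p, y) == pytest.approx(mae(p[perm], y[perm]))

    def test_empty_or_mismatched_rejected(self):
        with pytest.raises(ValueError):
            mae([], [])
        with pytest.raises(ValueError):
            mae([1], [1, 2])


class TestRocAuc:
    def test_perfect_separation(self):
        y = np.array([0, 0, 1, 1, 2, 2, 3, 3])
        q = np.eye(4)[y] * 0.7 + 0.1
        aucs, macro = roc_auc_ovr(q, y)
        assert np.allclose(aucs, 1.0)
        assert macro == pytest.approx(1.0)

    def test_constant_scores_are_chance(self):
        y = np.array([0, 1, 2, 3, 0, 1, 2, 3])
        q = np.full((8, 4), 0.25)
        aucs, macro = roc_auc_ovr(q, y)
        assert np.allclose(aucs, 0.5)

    def test_six_record_hand_case_matches_oracle(self):
        y = np.array([0, 0, 1, 1, 2, 3])
        q = np.array([[.7, .1, .1, .1], [.4, .3, .2, .1], [.2, .5, .2, .1],
                      [.3, .3, .3, .1], [.1, .2, .4, .3], [.1, .1, .2, .6]])
        aucs, macro = roc_auc_ovr(q, y)
        per_class = [rank_sum_auc(q[:, c], y == c) for c in range(4)]
        assert np.allclose(aucs, per_class)
        assert macro == pytest.approx(np.mean(per_class))

    def test_random_instances_match_oracle(self, rng):
        import warnings

        for _ in range(50):
            n = int(rng.integers(5, 20))
            y = rng.integers(0, 4, n)
            q = rng.random((n, 4))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                aucs, macro = roc_auc_ovr(q, y)
            defined = []
            for c in range(4):
                if 0 < (y == c).sum() < n:
                    assert aucs[c] == pytest.approx(
                        rank_sum_auc(q[:, c], y == c))
                    defined.append(aucs[c])
                else:
                    assert np.isnan(aucs[c])
            if defined:
                assert macro == pytest.approx(np.mean(defined))

    def test_absent_class_warns_and_is_excluded(self):
        y = np.array([0, 0, 1, 1])
        q = np.random.default_rng(0).random((4, 4))
        with pytest.warns(UserWarning):
            aucs, macro = roc_auc_ovr(q, y)
        assert np.isnan(aucs[2]) and np.isnan(aucs[3])
        assert macro == pytest.approx(np.nanmean(aucs[:2]))


class TestSubgroups:
    def _toy(self, sexes, ages):
        n = len(sexes)
        rng = np.random.default_rng(1)
        pred = rng.integers(0, 4, n)
        y = rng.integers(0, 4, n)
        probs = rng.random((n, 4))
        md = pd.DataFrame({"sex": sexes, "age": ages})
        return pred, probs, y, md

    def test_all_male_set(self):
        pred, probs, y, md = self._toy(["male"] * 6, [50] * 6)
        rep = subgroup_eval(pred, probs, y, md)
        assert rep.rows["male"]["mae"] == rep.rows["full"]["mae"]
        assert rep.rows["male"]["n"] == 6
        assert rep.rows["female"]["n"] == 0

    def test_age_cut_puts_65_in_upper_group(self):
        pred, probs, y, md = self._toy(["male", "female"], [64, 65])
        rep = subgroup_eval(pred, probs, y, md)
        assert rep.rows["age<65"]["n"] == 1
        assert rep.rows["age>=65"]["n"] == 1

    def test_subgroup_sizes_partition_full(self):
        sexes = ["male", "female", "male", "female", "male"]
        ages = [30, 70, 64, 65, 80]
        pred, probs, y, md = self._toy(sexes, ages)
        rep = subgroup_eval(pred, probs, y, md)
        full_n = rep.rows["full"]["n"]
        assert rep.rows["male"]["n"] + rep.rows["female"]["n"] == full_n
        assert rep.rows["age<65"]["n"] + rep.rows["age>=65"]["n"] == full_n

    def test_missing_metadata_excluded_and_counted(self):
        pred, probs, y, md = self._toy(["male", None, "female"], [50, 60, None])
        rep = subgroup_eval(pred, probs, y, md)
        assert rep.rows["full"]["excluded_sex"] == 1
        assert rep.rows["full"]["excluded_age"] == 1
        assert rep.rows["male"]["n"] + rep.rows["female"]["n"] == 2


class TestAgreement:
    def test_reported_study_counts(self):
        # 674 wrongly predicted records re-read by an independent reviewer
        assert agreement_stats(674, 361, 259) == (53.56, 38.43, 54)

    def test_degenerate_and_arithmetic_cases(self):
        assert agreement_stats(10, 10, 0) == (100.0, 0.0, 0)
        assert agreement_stats(100, 33, 33) == (33.0, 33.0, 34)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            agreement_stats(0, 0, 0)
        with pytest.raises(ValueError):
            agreement_stats(10, 8, 8)
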