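"""Rule classifier, benchmark harness and evaluation statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from blastomorph import predict as pr
from blastomorph import synthgen


class TestRuleClassifier:
    def test_euploid_cohort_means_pass_rule1(self):
        # cohort means of the euploid class: high TE count alone decides
        assert pr.rule_classify(141, 222, 5883) == 1

    def test_noneuploid_cohort_means_rejected(self):
        assert pr.rule_classify(68, 795, 4973) == 0

    def test_boundary_semantics_exact(self):
        # variance <= 478 inclusive, ICM > 8007 exclusive, count > 94 exclusive
        assert pr.rule_classify(75, 478, 8008) == 1
        assert pr.rule_classify(75, 479, 8008) == 0
        assert pr.rule_classify(75, 478, 8007) == 0
        assert pr.rule_classify(94, 478, 8007) == 0
        assert pr.rule_classify(95, 9999, 0) == 1

    def test_vectorized(self):
        out = pr.rule_classify(
            np.array([141, 68]), np.array([222, 795]), np.array([5883, 4973])
        )
        assert out.tolist() == [1, 0]

    def test_decomposition_matches_manual_recount(self, feature_table):
        tab = feature_table.copy()
        tab["euploid"] = (tab["ploidy"] == "euploid").astype(int)
        dec = pr.rule_decomposition(tab)
        eu = tab[tab["euploid"] == 1]
        n1 = int((eu["te_count"] > 94).sum())
        n2 = int(
            (
                ~(eu["te_count"] > 94)
                & (eu["te_size_variance"] <= 478)
                & (eu["icm_area_um2"] > 8007)
            ).sum()
        )
        assert dec["euploid_via_rule1"] == n1
        assert dec["euploid_added_by_rule2"] == n2
        assert dec["euploid_total"] == len(eu)

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            pr.RuleSet(te_count_threshold=-1)


class TestSplit:
    def _table(self, n=226, frac=0.571, seed=42):
        t = synthgen.simulate_feature_table(n, euploid_fraction=frac, seed=seed)
        t["euploid"] = (t["ploidy"] == "euploid").astype(int)
        return t

    def test_cohort_sizes(self):
        train, test = pr.split_train_test(self._table(), seed=0)
        assert len(test) == 45 and len(train) == 181
        assert set(train["id"]).isdisjoint(test["id"])

    def test_stratification(self):
        tab = self._table()
        frac = tab["euploid"].mean()
        _, test = pr.split_train_test(tab, seed=1)
        assert abs(test["euploid"].sum() - frac * len(test)) <= 1.0

    def test_deterministic(self):
        tab = self._table()
        a, _ = pr.split_train_test(tab, seed=5)
        b, _ = pr.split_train_test(tab, seed=5)
        pd.testing.assert_frame_equal(a, b)


class TestRocThreshold:
    def test_perfect_separation_midpoint(self):
        thr = pr.roc_threshold([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert thr == pytest.approx(0.5)

    def test_matches_exhaustive_oracle(self):
        scores = np.array([0.1, 0.35, 0.4, 0.6, 0.9])
        labels = np.array([0, 1, 0, 1, 1])  # one inversion
        uniq = np.unique(scores)
        best = None
        for t in (uniq[:-1] + uniq[1:]) / 2:
            pred = scores > t
            sens = (pred & (labels == 1)).sum() / 3
            spec = (~pred & (labels == 0)).sum() / 2
            key = (np.hypot(1 - sens, 1 - spec), -spec)
            if best is None or key < best[0]:
                best = (key, t)
        assert pr.roc_threshold(scores, labels) == pytest.approx(best[1])

    def test_monotone_transform_invariance(self, rng):
        scores = rng.random(40)
        labels = (rng.random(40) < 0.5).astype(int)
        labels[0], labels[1] = 0, 1
        t1 = pr.roc_threshold(scores, labels)
        t2 = pr.roc_threshold(np.exp(3 * scores), labels)
        assert np.array_equal(scores > t1, np.exp(3 * scores) > t2)

    def test_constant_scores_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pr.roc_threshold([0.5, 0.5, 0.5], [0, 1, 0])


class TestClopperPearson:
    def test_zero_successes_closed_form(self):
        lo, hi = pr.clopper_pearson(0, 20)
        assert lo == 0.0
        assert hi == pytest.approx(1 - 0.025 ** (1 / 20), abs=1e-4)
        assert hi == pytest.approx(0.1684, abs=1e-3)

    def test_all_successes_symmetric(self):
        lo, hi = pr.clopper_pearson(20, 20)
        assert hi == 1.0
        assert lo == pytest.approx(0.8316, abs=1e-3)

    def test_all_correct_of_ten(self):
        lo, hi = pr.clopper_pearson(10, 10)
        assert lo == pytest.approx(0.025 ** (1 / 10), abs=1e-9)

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            pr.clopper_pearson(5, 4)


class TestEvaluate:
    def test_confusion_consistency(self, rng):
        y = (rng.random(60) < 0.5).astype(int)
        p = (rng.random(60) < 0.5).astype(int)
        ev = pr.evaluate(y, predictions=p)
        n = ev.tp + ev.tn + ev.fp + ev.fn
        assert n == 60
        assert ev.accuracy[0] == pytest.approx((ev.tp + ev.tn) / n)
        if ev.tp + ev.fp:
            assert ev.precision[0] == pytest.approx(ev.tp / (ev.tp + ev.fp))
        for metric in (ev.sensitivity, ev.specificity, ev.precision, ev.accuracy):
            if not np.isnan(metric[0]):
                assert metric[1] <= metric[0] <= metric[2]

    def test_auc_with_scores(self, rng):
        y = np.r_[np.ones(20), np.zeros(20)].astype(int)
        s = np.r_[rng.normal(1.2, 1, 20), rng.normal(0, 1, 20)]
        ev = pr.evaluate(y, scores=s, threshold=0.5)
        from sklearn.metrics import roc_auc_score

        assert ev.auc[0] == pytest.approx(roc_auc_score(y, s), abs=1e-12)
        assert ev.auc[1] <= ev.auc[0] <= ev.auc[2]


class TestDeLong:
    def test_identical_scores_p_one(self, rng):
        y = np.r_[np.ones(15), np.zeros(15)].astype(int)
        s = rng.random(30)
        out = pr.delong_test(s, s, y)
        assert out["p"] == 1.0

    def test_perfect_separation_auc(self):
        y = np.array([1, 1, 1, 0, 0])
        s = np.array([0.9, 0.8, 0.7, 0.6, 0.5])
        out = pr.delong_test(s, s, y)
        assert out["auc_a"] == pytest.approx(1.0)

    def test_variance_matches_bootstrap_oracle(self, rng):
        y = np.r_[np.ones(10), np.zeros(10)].astype(int)
        s = np.r_[rng.normal(0.8, 0.5, 10), rng.normal(0, 0.5, 10)]
        out = pr.delong_test(s, np.zeros(20), y)

        def auc(scores, labels):
            pos, neg = scores[labels == 1], scores[labels == 0]
            diff = pos[:, None] - neg[None, :]
            return np.where(diff > 0, 1.0, np.where(diff == 0, 0.5, 0.0)).mean()

        boots = []
        brng = np.random.default_rng(7)
        for _ in range(10_000):
            ip = brng.integers(0, 10, 10)
            ineg = 10 + brng.integers(0, 10, 10)
            idx = np.r_[ip, ineg]
            boots.append(auc(s[idx], y[idx]))
        boot_var = np.var(boots, ddof=1)
        assert out["var_a"] == pytest.approx(boot_var, rel=0.25)

    def test_unpaired_lengths_rejected(self):
        with pytest.raises(ValueError, match="paired"):
            pr.delong_test([0.1, 0.2], [0.1], [1, 0])


class TestMcNemar:
    def test_identical_predictions(self):
        y = np.array([1, 0, 1, 0])
        out = pr.mcnemar_test(y, y, y)
        assert out["p"] == 1.0 and out["b"] == out["c"] == 0

    def test_hand_computed_9_1(self):
        # A correct where B wrong 9 times, the reverse once
        y = np.zeros(10, dtype=int)
        pa = np.zeros(10, dtype=int)
        pb = np.ones(10, dtype=int)
        pa[0], pb[0] = 1, 0  # one discordant pair the other way
        out = pr.mcnemar_test(pa, pb, y)
        assert (out["b"], out["c"]) == (9, 1)
        assert out["p"] == pytest.approx(22 / 1024, abs=1e-6)

    def test_symmetry(self, rng):
        y = (rng.random(40) < 0.5).astype(int)
        pa = (rng.random(40) < 0.5).astype(int)
        pb = (rng.random(40) < 0.5).astype(int)
        assert pr.mcnemar_test(pa, pb, y)["p"] == pr.mcnemar_test(pb, pa, y)["p"]


def _separable_table(n=120, seed=0):
    rng = np.random.default_rng(seed)
    y = np.r_[np.ones(n // 2), np.zeros(n // 2)].astype(int)
    tab = pd.DataFrame(
        {c: rng.normal(size=n) for c in synthgen.FEATURE_COLUMNS}
    )
    tab["te_count"] = y * 4.0 + rng.normal(0, 0.3, n)  # dominant signal
    tab["euploid"] = y
    return tab


class TestTuneAndTrain:
    @pytest.mark.parametrize("model", ["LR", "DT"])
    def test_separable_reaches_perfect_validation_auc(self, model):
        scorer = pr.tune_and_train(model, _separable_table(), seed=0)
        assert scorer.cv_auc == pytest.approx(1.0, abs=1e-9)

    def test_label_shuffle_near_chance(self):
        tab = _separable_table(seed=1)
        rng = np.random.default_rng(2)
        tab["euploid"] = rng.permutation(tab["euploid"].to_numpy())
        tab["te_count"] = rng.normal(size=len(tab))
        scorer = pr.tune_and_train("LR", tab, seed=0)
        assert scorer.cv_auc == pytest.approx(0.5, abs=0.12)

    def test_deterministic_hyperparameters(self):
        a = pr.tune_and_train("DT", _separable_table(), seed=3)
        b = pr.tune_and_train("DT", _separable_table(), seed=3)
        assert a.best_params == b.best_params

    def test_unknown_model_lists_registry(self):
        with pytest.raises(ValueError, match="XGBoost"):
            pr.tune_and_train("nope", _separable_table())


class TestFeatureImportance:
    def test_planted_signal_ranks_first(self):
        tab = _separable_table(seed=4)
        scorer = pr.tune_and_train("LR", tab, seed=0)
        imp = pr.feature_importance(scorer, tab, n_repeats=10, seed=0)
        assert imp.iloc[0]["feature"] == "te_count"
        assert imp.iloc[0]["importance"] > 0.2
        assert (imp.iloc[1:]["importance"].abs() < 0.1).all()

    def test_repeat_count_stability_on_easy_case(self):
        tab = _separable_table(seed=5)
        scorer = pr.tune_and_train("LR", tab, seed=0)
        one = pr.feature_importance(scorer, tab, n_repeats=1, seed=1)
        many = pr.feature_importance(scorer, tab, n_repeats=25, seed=1)
        assert one.iloc[0]["feature"] == many.iloc[0]["feature"]
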