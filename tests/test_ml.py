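"""Hold-out split, wrapper selection, classifier evaluation and leakage guards."""

import numpy as np
import pandas as pd
import pytest
from sklearn.model_selection import StratifiedKFold

from poincarehrv import ml


def toy_table(rng, n=100, n_features=4, informative=None, n_high=30):
    cols = [f"f{i}" for i in range(n_features)]
    X = pd.DataFrame(rng.normal(size=(n, n_features)), columns=cols)
    y = np.array(["low"] * (n - n_high) + ["high"] * n_high)
    rng.shuffle(y)
    if informative is not None:
        X.loc[y == "high", informative] += 2.5
    return X, y


class TestHoldoutSplit:
    def test_stratified_proportions(self, rng):
        X, y = toy_table(rng, n=100, n_high=30)
        tr, te, ytr, yte = ml.holdout_split(X, y, ml.SplitSpec(seed=0))
        assert len(tr) == 80 and len(te) == 20
        assert (ytr == "high").sum() == 24 and (yte == "high").sum() == 6

    def test_same_seed_same_partition(self, rng):
        X, y = toy_table(rng)
        a = ml.holdout_split(X, y, ml.SplitSpec(seed=5))
        b = ml.holdout_split(X, y, ml.SplitSpec(seed=5))
        assert a[0].index.equals(b[0].index) and a[1].index.equals(b[1].index)

    def test_rounding_contract_at_199_rows(self, rng):
        X, y = toy_table(rng, n=199, n_high=61)
        tr, te, ytr, yte = ml.holdout_split(X, y)
        assert len(tr) + len(te) == 199
        assert set(tr.index).isdisjoint(te.index)
        for cls, total in (("high", 61), ("low", 138)):
            got = (ytr == cls).sum()
            assert abs(got - 0.8 * total) < 1

    def test_small_class_rejected(self, rng):
        X, y = toy_table(rng, n=20, n_high=3)
        with pytest.raises(ValueError, match=">= 5 rows"):
            ml.holdout_split(X, y)


class TestWrapperSelect:
    def test_separating_feature_found_with_perfect_cv(self, rng):
        X, y = toy_table(rng, n=60, n_high=24)
        X["f1"] = np.where(y == "high", 1.0, 0.0)  # perfect separator
        res = ml.wrapper_select(X, y, "NB", k_folds=5, features=list(X.columns))
        assert "f1" in res.best_subset
        assert res.cv_accuracy == 1.0

    def test_nine_features_evaluate_511_subsets(self, rng):
        X, y = toy_table(rng, n=60, n_features=9, n_high=24)
        res = ml.wrapper_select(X, y, "NB", k_folds=5,
                                features=list(X.columns))
        assert res.n_subsets_evaluated == 511

    def test_matches_independent_exhaustive_loop(self, rng):
        """Every subset re-scored with an independent CV loop; argmax agrees."""
        from itertools import combinations
        from sklearn.naive_bayes import GaussianNB

        X, y = toy_table(rng, n=80, n_features=4, informative="f2", n_high=32)
        res = ml.wrapper_select(X, y, "NB", k_folds=10, seed=3,
                                features=list(X.columns))
        folds = list(StratifiedKFold(10, shuffle=True, random_state=3)
                     .split(X.to_numpy(), y))
        best = -1.0
        scores = {}
        for size in range(1, 5):
            for subset in combinations(X.columns, size):
                accs = []
                for tr, te in folds:
                    clf = GaussianNB().fit(X.iloc[tr][list(subset)], y[tr])
                    accs.append((clf.predict(X.iloc[te][list(subset)]) == y[te]).mean())
                scores[subset] = float(np.mean(accs))
                best = max(best, scores[subset])
        assert res.cv_accuracy == pytest.approx(best)
        assert scores[res.best_subset] == pytest.approx(best)

    def test_ties_break_to_smaller_then_lexicographic(self, rng):
        X, y = toy_table(rng, n=60, n_features=3, n_high=24)
        X["f0"] = np.where(y == "high", 1.0, 0.0)
        X["f1"] = X["f0"]  # duplicate separator: {f0}, {f1}, {f0,f1} all tie
        res = ml.wrapper_select(X, y, "NB", k_folds=5,
                                features=["f0", "f1", "f2"])
        assert res.best_subset == ("f0",)

    def test_k_folds_larger_than_class_rejected(self, rng):
        X, y = toy_table(rng, n=30, n_high=8)
        with pytest.raises(ValueError, match="smallest class"):
            ml.wrapper_select(X, y, "NB", k_folds=10, features=list(X.columns))

    def test_greedy_agrees_on_single_strong_feature(self, rng):
        X, y = toy_table(rng, n=80, informative="f3", n_high=32)
        cfg = ml.MLConfig(wrapper="greedy")
        res = ml.wrapper_select(X, y, "NB", k_folds=5, config=cfg,
                                features=list(X.columns))
        assert "f3" in res.best_subset


class TestTrainEval:
    def test_all_negative_classifier_closed_form(self, rng, monkeypatch):
        class AllNegative:
            classes_ = np.array(["high", "low"])
            def fit(self, X, y): return self
            def predict(self, X): return np.array(["low"] * len(X))
            def predict_proba(self, X):
                return np.tile([0.0, 1.0], (len(X), 1))

        monkeypatch.setattr(ml, "make_classifier", lambda *a, **k: AllNegative())
        X, y = toy_table(rng, n=140, n_high=42)
        train, test = X.iloc[:100], X.iloc[100:]
        ytr = y[:100]
        yte = np.array(["high"] * 12 + ["low"] * 28)
        row = ml.train_eval(train, test, ytr, yte, "NB", ["f0"])
        assert row["sensitivity_pct"] == 0.0
        assert row["specificity_pct"] == 100.0
        assert row["accuracy_pct"] == 70.0

    def test_perfect_classifier_all_metrics_100(self, rng):
        X, y = toy_table(rng, n=100, n_high=40)
        X["sep"] = np.where(y == "high", 1.0, -1.0)
        tr, te, ytr, yte = ml.holdout_split(X, y)
        row = ml.train_eval(tr, te, ytr, yte, "NB", ["sep"])
        assert row["accuracy_pct"] == 100.0
        assert row["sensitivity_pct"] == 100.0
        assert row["specificity_pct"] == 100.0
        assert row["precision_pct"] == 100.0
        assert row["aucroc"] == 1.0

    def test_single_class_test_set_rejected(self, rng):
        X, y = toy_table(rng)
        with pytest.raises(ValueError, match="single class"):
            ml.train_eval(X.iloc[:80], X.iloc[80:], y[:80],
                          np.array(["low"] * 20), "NB", ["f0"])

    def test_nb_approaches_known_bayes_rate(self, rng):
        """One-feature two-Gaussian problem with 10% Bayes error."""
        d = 2 * 1.2815515655446004  # Phi(-d/2) = 0.10
        accs = []
        for seed in range(50):
            r = np.random.default_rng(seed)
            ytr = np.array(["low", "high"])[r.integers(0, 2, 2000)]
            Xtr = pd.DataFrame({"f": r.normal(0, 1, 2000) + d * (ytr == "high")})
            yte = np.array(["low", "high"])[r.integers(0, 2, 1000)]
            Xte = pd.DataFrame({"f": r.normal(0, 1, 1000) + d * (yte == "high")})
            row = ml.train_eval(Xtr, Xte, ytr, yte, "NB", ["f"])
            accs.append(row["accuracy_pct"])
        assert np.mean(accs) == pytest.approx(90.0, abs=1.0)
        assert all(abs(a - 90.0) <= 3.5 for a in accs)

    def test_random_scores_give_chance_auc(self):
        aucs = []
        for seed in range(100):
            r = np.random.default_rng(seed)
            X, y = toy_table(r, n=200, n_high=80)
            tr, te = X.iloc[:150], X.iloc[150:]
            row = ml.train_eval(tr, te, y[:150], y[150:], "NB",
                                list(X.columns), seed=seed)
            aucs.append(row["aucroc"])
        assert abs(np.mean(aucs) - 0.5) <= 0.05


class TestBoostedTrees:
    def test_matches_sklearn_adaboost(self, rng):
        from sklearn.ensemble import AdaBoostClassifier
        from sklearn.tree import DecisionTreeClassifier

        Xtr = rng.normal(size=(160, 5))
        ytr = (rng.random(160) < 0.35).astype(int)
        Xtr[ytr == 1] += 0.8
        Xte = rng.normal(size=(500, 5))
        yte = (rng.random(500) < 0.35).astype(int)
        Xte[yte == 1] += 0.8
        mine = ml._BoostedTrees(n_estimators=50, max_depth=3,
                                random_state=0).fit(Xtr, ytr)
        sk = AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_depth=3),
            n_estimators=50, random_state=0).fit(Xtr, ytr)
        agree = (mine.predict(Xte) == sk.predict(Xte)).mean()
        assert agree >= 0.95
        acc_mine = (mine.predict(Xte) == yte).mean()
        acc_sk = (sk.predict(Xte) == yte).mean()
        assert abs(acc_mine - acc_sk) <= 0.03

    def test_separable_data_perfectly_fit(self, rng):
        X = rng.normal(size=(60, 2))
        y = (X[:, 0] > 0).astype(int)
        clf = ml._BoostedTrees(n_estimators=10).fit(X, y)
        assert (clf.predict(X) == y).all()


class TestFullRun:
    def _cohort(self, rng, n=120):
        X, y = toy_table(rng, n=n, n_features=9, n_high=40)
        X.columns = list(ml.FEATURE_NAMES)
        X.loc[y == "high", "rho_y_ms"] -= 1.8
        X.loc[y == "high", "L_ms"] -= 1.2
        return X, y

    def test_metric_identities_hold(self, rng):
        X, y = self._cohort(rng)
        cfg = ml.MLConfig(wrapper="greedy", ada_rounds=10, seed=2)
        report = ml.full_run(X, y, cfg)
        for row in report["rows"]:
            tp, fp, tn, fn = row["TP"], row["FP"], row["TN"], row["FN"]
            assert row["accuracy_pct"] == pytest.approx(
                100 * (tp + tn) / (tp + fp + tn + fn))
            assert row["sensitivity_pct"] == pytest.approx(100 * tp / (tp + fn))
            assert row["specificity_pct"] == pytest.approx(100 * tn / (tn + fp))
            assert 0.0 <= row["aucroc"] <= 1.0

    def test_same_seed_identical_report(self, rng):
        X, y = self._cohort(rng)
        cfg = ml.MLConfig(wrapper="greedy", ada_rounds=10, seed=7)
        r1 = ml.full_run(X, y, cfg)
        r2 = ml.full_run(X, y, cfg)
        assert ml.format_report(r1).equals(ml.format_report(r2))

    def test_perturbing_test_rows_never_changes_selection(self, rng):
        """Leakage canary: wrapper choice depends on training rows only."""
        X, y = self._cohort(rng)
        spec = ml.SplitSpec(seed=4)
        train, test, ytr, yte = ml.holdout_split(X, y, spec)
        before = ml.wrapper_select(train, ytr, "NB", k_folds=10, seed=4)
        X2 = X.copy()
        X2.loc[test.index, :] = 1e6  # pathological test-only rows
        train2, _, ytr2, _ = ml.holdout_split(X2, y, spec)
        after = ml.wrapper_select(train2, ytr2, "NB", k_folds=10, seed=4)
        assert before == after
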