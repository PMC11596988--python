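"""Resampled classification framework: splits, SMOTE, selection, scoring."""

import numpy as np
import pandas as pd
import pytest

import quartersleep.ml as ml
from quartersleep.errors import CannotAugmentError, EmptyClassError, SplitError


def toy_table(rng, n_pos=40, n_neg=20, n_noise=4, separable=True):
    """Binary table with one informative feature and noise columns."""
    rows = []
    for label, n in ((1, n_pos), (0, n_neg)):
        for _ in range(n):
            signal = label + rng.normal(0, 0.1 if separable else 10.0)
            row = {"label": label, "signal": signal}
            for j in range(n_noise):
                row[f"noise{j}"] = rng.normal()
            rows.append(row)
    return pd.DataFrame(rows)


class TestTaskSpec:
    def test_known_tasks(self):
        assert set(ml.TASKS) == {"nt1_vs_control", "nt1_vs_nt2", "nt1_vs_ih",
                                 "nt1_vs_nt2_ih", "nt1_vs_all"}

    def test_unknown_task_raises(self):
        with pytest.raises(KeyError):
            ml.TaskSpec.from_name("nt1_vs_moon")

    def test_build_task_table_restricts_and_relabels(self):
        table = pd.DataFrame({
            "group": ["NT1"] * 3 + ["NT2"] * 2 + ["control"] * 2,
            "x": range(7),
        })
        out = ml.build_task_table(table, ml.TaskSpec.from_name("nt1_vs_control"))
        assert len(out) == 5
        assert out["label"].tolist() == [1, 1, 1, 0, 0]

    def test_nt1_vs_all_keeps_everyone(self):
        table = pd.DataFrame({"group": ["NT1", "NT2", "IH", "control"], "x": range(4)})
        out = ml.build_task_table(table, ml.TaskSpec.from_name("nt1_vs_all"))
        assert len(out) == 4 and out["label"].sum() == 1

    def test_missing_group_raises(self):
        table = pd.DataFrame({"group": ["NT1", "NT2"], "x": [0, 1]})
        with pytest.raises(EmptyClassError):
            ml.build_task_table(table, ml.TaskSpec.from_name("nt1_vs_control"))


class TestSplit:
    def test_stratified_counts(self):
        table = pd.DataFrame({"label": [1] * 70 + [0] * 30, "x": range(100)})
        train, test = ml.split_70_30(table, seed=0)
        assert len(train) == 70 and len(test) == 30
        assert abs(train["label"].mean() - 0.7) < 0.02

    def test_same_seed_same_split(self):
        table = pd.DataFrame({"label": [1] * 10 + [0] * 10, "x": range(20)})
        a, _ = ml.split_70_30(table, seed=5)
        b, _ = ml.split_70_30(table, seed=5)
        assert list(a.index) == list(b.index)

    def test_singleton_class_raises(self):
        table = pd.DataFrame({"label": [1] * 10 + [0], "x": range(11)})
        with pytest.raises(SplitError):
            ml.split_70_30(table, seed=0)


class TestSmote:
    def test_balances_to_parity(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(50, 3))
        y = np.array([1] * 40 + [0] * 10)
        Xb, yb = ml.smote_balance(X, y, k_neighbors=5, rng=1)
        assert (yb == 0).sum() == (yb == 1).sum() == 40
        assert len(Xb) == 80

    def test_balanced_input_unchanged(self):
        X = np.zeros((10, 2))
        y = np.array([0] * 5 + [1] * 5)
        Xb, yb = ml.smote_balance(X, y, rng=0)
        assert len(Xb) == 10

    def test_singleton_minority_raises(self):
        X = np.zeros((5, 2))
        y = np.array([1, 1, 1, 1, 0])
        with pytest.raises(CannotAugmentError):
            ml.smote_balance(X, y, rng=0)

    def test_synthetic_points_lie_on_minority_segments(self):
        """Convexity: on 2-feature data, each synthetic minority row is a
        convex combination of two real minority rows."""
        rng = np.random.default_rng(2)
        Xmin = rng.normal(size=(6, 2))
        Xmaj = rng.normal(size=(20, 2)) + 10
        X = np.vstack([Xmin, Xmaj])
        y = np.array([0] * 6 + [1] * 20)
        Xb, yb = ml.smote_balance(X, y, k_neighbors=3, rng=3)
        synth = Xb[len(X):]
        for s in synth:
            on_segment = False
            for i in range(len(Xmin)):
                for j in range(len(Xmin)):
                    if i == j:
                        continue
                    d = Xmin[j] - Xmin[i]
                    t = np.dot(s - Xmin[i], d) / np.dot(d, d)
                    if -1e-9 <= t <= 1 + 1e-9 and np.linalg.norm(
                            Xmin[i] + t * d - s) < 1e-9:
                        on_segment = True
            assert on_segment


class TestRemoveCorrelated:
    def test_duplicate_column_dropped(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=50)
        X = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.normal(size=50)})
        kept = ml.remove_correlated(X, threshold=0.9)
        assert "c" in kept and len(kept) == 2

    def test_orthogonal_columns_all_kept(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(size=(200, 6)),
                         columns=list("abcdef"))
        assert len(ml.remove_correlated(X, threshold=0.9)) == 6

    def test_three_duplicates_one_survivor(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=40)
        X = pd.DataFrame({"a": x, "b": x.copy(), "c": x.copy()})
        assert len(ml.remove_correlated(X, threshold=0.9)) == 1

    def test_importance_hint_protects_feature(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=40)
        X = pd.DataFrame({"weak": x, "strong": x.copy()})
        kept = ml.remove_correlated(X, threshold=0.9,
                                    importance_hint={"weak": 0.1, "strong": 0.9})
        assert kept == ["strong"]

    def test_deterministic(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.normal(size=(30, 10)),
                         columns=[f"f{i}" for i in range(10)])
        X["f1"] = X["f0"] * 2 + 0.001 * rng.normal(size=30)
        assert ml.remove_correlated(X) == ml.remove_correlated(X)


class TestFitAndScore:
    def test_separable_data_perfect_metrics(self):
        rng = np.random.default_rng(6)
        table = toy_table(rng)
        train, test = ml.split_70_30(table, seed=1)
        res = ml.fit_and_score(train, test, ["signal"] + [f"noise{j}" for j in range(4)],
                               seed=1, tune=False, compute_importance=False)
        assert res.f1 == 1.0 and res.auc_roc == 1.0

    def test_shuffled_labels_near_chance(self):
        rng = np.random.default_rng(7)
        aucs = []
        for seed in range(8):
            table = toy_table(rng, n_pos=40, n_neg=40, separable=False)
            table["label"] = rng.permutation(table["label"].to_numpy())
            train, test = ml.split_70_30(table, seed=seed)
            res = ml.fit_and_score(train, test, ["signal"] +
                                   [f"noise{j}" for j in range(4)],
                                   seed=seed, tune=False, compute_importance=False)
            aucs.append(res.auc_roc)
        assert abs(np.mean(aucs) - 0.5) < 0.15

    def test_rf_deterministic_given_seed(self):
        rng = np.random.default_rng(8)
        table = toy_table(rng)
        train, test = ml.split_70_30(table, seed=2)
        cols = ["signal"] + [f"noise{j}" for j in range(4)]
        a = ml.fit_and_score(train, test, cols, seed=3, tune=False,
                             compute_importance=False)
        b = ml.fit_and_score(train, test, cols, seed=3, tune=False,
                             compute_importance=False)
        assert (a.f1, a.auc_roc, a.auc_pr) == (b.f1, b.auc_roc, b.auc_pr)

    @pytest.mark.parametrize("mode", ["refit", "permutation"])
    def test_label_defining_feature_tops_importance(self, mode):
        rng = np.random.default_rng(9)
        table = toy_table(rng)
        train, test = ml.split_70_30(table, seed=4)
        res = ml.fit_and_score(train, test,
                               ["signal"] + [f"noise{j}" for j in range(4)],
                               seed=4, tune=False, importance_mode=mode,
                               importance_metric="auc_roc")
        top = max(res.importance, key=res.importance.get)
        assert top == "signal"
        for j in range(4):
            assert abs(res.importance[f"noise{j}"]) <= res.importance["signal"]

    @pytest.mark.parametrize("model", ["xgboost", "gp"])
    def test_alternative_backends_run(self, model):
        rng = np.random.default_rng(10)
        table = toy_table(rng)
        train, test = ml.split_70_30(table, seed=5)
        res = ml.fit_and_score(train, test,
                               ["signal"] + [f"noise{j}" for j in range(4)],
                               model=model, seed=5, tune=False,
                               compute_importance=False)
        # tree splits can land inside a tight cluster; require clear skill only
        assert res.auc_roc > 0.8


class TestRunRealizations:
    def test_reproducible_from_master_seed(self):
        rng = np.random.default_rng(11)
        table = toy_table(rng)
        table["group"] = np.where(table["label"] == 1, "NT1", "control")
        table = table.drop(columns="label")
        cols = ["signal"] + [f"noise{j}" for j in range(4)]
        out1 = ml.run_realizations(table, "nt1_vs_control", feature_sets=cols,
                                   n_realizations=4, seed=12, tune=False,
                                   compute_importance=False)
        out2 = ml.run_realizations(table, "nt1_vs_control", feature_sets=cols,
                                   n_realizations=4, seed=12, tune=False,
                                   compute_importance=False)
        assert out1[1] == out2[1]
        assert [r.f1 for r in out1[0]] == [r.f1 for r in out2[0]]

    def test_unknown_feature_column_raises(self):
        rng = np.random.default_rng(13)
        table = toy_table(rng)
        table["group"] = np.where(table["label"] == 1, "NT1", "control")
        with pytest.raises(KeyError):
            ml.run_realizations(table, "nt1_vs_control",
                                feature_sets=["not_a_column"],
                                n_realizations=1, seed=0)

    def test_summary_statistics(self):
        rng = np.random.default_rng(12)
        table = toy_table(rng)
        table["group"] = np.where(table["label"] == 1, "NT1", "control")
        table["age"] = 40.0
        results = []
        for i in range(5):
            train, test = ml.split_70_30(table, seed=100 + i)
            r = ml.fit_and_score(train, test,
                                 ["signal"] + [f"noise{j}" for j in range(4)],
                                 seed=i, tune=False, compute_importance=False)
            results.append(r)
        f1s = [r.f1 for r in results]
        assert min(f1s) <= np.mean(f1s) <= max(f1s)
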