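"""Classifiers: metric definitions against counting oracles, repeated
stratified CV behavior, and the external-validation contract."""

import numpy as np
import pandas as pd
import pytest

from tcrlearn import (FeatureTable, cross_validate, evaluate_external,
                      metrics, train)
from tcrlearn.errors import (ConfigurationError, ContractError,
                             DegenerateSampleError,
                             NonTransferableFeatureError)

from conftest import make_feature_table
from oracles import auc_rank, metrics_counting


def separable_table(n_per_class=6, gap=5.0, seed=0):
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    x = np.concatenate([rng.normal(0, 0.3, n_per_class),
                        rng.normal(gap, 0.3, n_per_class)])
    idx = [f"s{i}" for i in range(n)]
    return FeatureTable(
        data=pd.DataFrame({"x": x, "y": rng.normal(size=n)}, index=idx),
        labels=pd.Series(["neg"] * n_per_class + ["pos"] * n_per_class,
                         index=idx),
    )


class TestMetrics:
    def test_perfect_predictions(self):
        y = ["p", "p", "p", "n", "n", "n"]
        out = metrics(y, y, [1, 1, 1, 0, 0, 0], positive_class="p")
        for m in ("accuracy", "precision", "recall", "f1", "auc"):
            assert out[m] == 1.0
        np.testing.assert_array_equal(out["confusion_matrix"], [[3, 0], [0, 3]])

    def test_all_positive_predictions(self):
        y_true = ["p", "p", "n", "n"]
        out = metrics(y_true, ["p"] * 4, [0.9] * 4, positive_class="p")
        assert out["recall"] == 1.0
        assert out["accuracy"] == 0.5
        assert out["auc"] == 0.5  # constant score, mid-rank tie convention

    def test_no_positive_predictions_warns_precision_zero(self):
        with pytest.warns(UserWarning, match="precision"):
            out = metrics(["p", "n"], ["n", "n"], [0.4, 0.2],
                          positive_class="p")
        assert out["precision"] == 0.0

    def test_score_equal_to_truth_gives_auc_one(self):
        y = ["p", "n", "p", "n"]
        out = metrics(y, y, [1, 0, 1, 0], positive_class="p")
        assert out["auc"] == 1.0

    def test_matches_counting_oracle_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(4, 30))
            y_true = rng.choice(["p", "n"], size=n).tolist()
            if len(set(y_true)) < 2:
                continue
            y_pred = rng.choice(["p", "n"], size=n).tolist()
            score = rng.random(size=n)
            import warnings as _w

            with _w.catch_warnings():
                _w.simplefilter("ignore")
                got = metrics(y_true, y_pred, score, positive_class="p")
            want = metrics_counting(y_true, y_pred, "p")
            for m in ("accuracy", "precision", "recall", "f1"):
                assert got[m] == pytest.approx(want[m])
            assert got["confusion_matrix"].sum() == n
            y01 = [1 if y == "p" else 0 for y in y_true]
            assert got["auc"] == pytest.approx(auc_rank(y01, score))

    def test_class_swap_maps_to_complementary_counts(self):
        rng = np.random.default_rng(1)
        y_true = rng.choice(["p", "n"], size=20).tolist()
        y_pred = rng.choice(["p", "n"], size=20).tolist()
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore")
            as_p = metrics(y_true, y_pred, positive_class="p")
            as_n = metrics(y_true, y_pred, positive_class="n")
        want = metrics_counting(y_true, y_pred, "n")
        assert as_n["precision"] == pytest.approx(want["precision"])
        assert as_n["recall"] == pytest.approx(want["recall"])
        np.testing.assert_array_equal(as_n["confusion_matrix"],
                                      as_p["confusion_matrix"][::-1, ::-1])


class TestTrain:
    def test_separable_clusters_fit_perfectly(self):
        t = separable_table()
        model = train(t, algorithm="DT", seed=0)
        assert (model.predict(t) == t.labels.values).all()

    @pytest.mark.parametrize("algorithm", ["GNB", "LDA", "LR", "DT"])
    def test_same_seed_identical_predictions(self, algorithm):
        t = make_feature_table(n=16, seed=2)
        p1 = train(t, algorithm=algorithm, seed=3).predict(t)
        p2 = train(t, algorithm=algorithm, seed=3).predict(t)
        np.testing.assert_array_equal(p1, p2)

    def test_lda_on_identical_class_distributions_is_chance(self):
        rng = np.random.default_rng(4)
        n = 400
        idx = [f"s{i}" for i in range(n)]
        t = FeatureTable(
            data=pd.DataFrame({"x": rng.normal(size=n),
                               "y": rng.normal(size=n)}, index=idx),
            labels=pd.Series(rng.choice(["a", "b"], size=n), index=idx),
        )
        model = train(t, algorithm="LDA", seed=0)
        held = FeatureTable(
            data=pd.DataFrame({"x": rng.normal(size=n),
                               "y": rng.normal(size=n)}, index=idx),
            labels=pd.Series(rng.choice(["a", "b"], size=n), index=idx),
        )
        rep = evaluate_external(model, held)
        assert rep.means["auc"] == pytest.approx(0.5, abs=0.1)

    def test_single_class_rejected(self):
        t = make_feature_table(n=8, labels=["A"] * 8)
        with pytest.raises((DegenerateSampleError, ConfigurationError)):
            train(t)

    def test_unknown_algorithm_rejected(self):
        with pytest.raises(ConfigurationError):
            train(make_feature_table(n=8), algorithm="SVM")

    def test_positive_class_default_is_second_sorted_label(self):
        model = train(separable_table(), algorithm="LR", seed=0)
        assert model.positive_class_ == "pos"


class TestCrossValidate:
    def test_separable_data_scores_near_one(self):
        t = separable_table(n_per_class=9, gap=8.0)
        rep = cross_validate(t, algorithm="DT", k_folds=3, repeats=10, seed=0)
        for m in ("accuracy", "precision", "recall", "f1", "auc"):
            assert rep.means[m] >= 0.99

    def test_confusion_matrix_counts_all_evaluations(self):
        t = separable_table(n_per_class=6)
        rep = cross_validate(t, algorithm="GNB", k_folds=3, repeats=4, seed=1)
        assert rep.confusion_matrix.sum() == 12 * 4

    def test_label_randomized_auc_is_chance(self):
        rng = np.random.default_rng(5)
        n = 60
        idx = [f"s{i}" for i in range(n)]
        t = FeatureTable(
            data=pd.DataFrame(rng.normal(size=(n, 3)), index=idx,
                              columns=["a", "b", "c"]),
            labels=pd.Series(["x", "y"] * (n // 2), index=idx),
        )
        rep = cross_validate(t, algorithm="LR", k_folds=3, repeats=20, seed=2)
        assert 0.4 <= rep.means["auc"] <= 0.6

    def test_repeats_one_equals_manual_single_kfold(self):
        from sklearn.model_selection import StratifiedKFold

        t = separable_table(n_per_class=6, gap=3.0, seed=3)
        rep = cross_validate(t, algorithm="LR", k_folds=3, repeats=1, seed=7)
        y01 = (t.labels.values == "pos").astype(int)
        accs = []
        skf = StratifiedKFold(n_splits=3, shuffle=True, random_state=7)
        for tr_idx, te_idx in skf.split(np.arange(12), y01):
            sub_tr = FeatureTable(t.data.iloc[tr_idx], t.labels.iloc[tr_idx])
            sub_te = FeatureTable(t.data.iloc[te_idx], t.labels.iloc[te_idx])
            model = train(sub_tr, algorithm="LR", seed=7)
            accs.append((model.predict(sub_te) == sub_te.labels.values).mean())
        assert rep.means["accuracy"] == pytest.approx(np.mean(accs))

    def test_class_smaller_than_k_is_explicit(self):
        t = make_feature_table(n=6, labels=["A", "A", "B", "B", "B", "B"])
        with pytest.raises(DegenerateSampleError, match="smaller k"):
            cross_validate(t, k_folds=3, repeats=1)


class TestEvaluateExternal:
    def test_model_on_its_own_training_table(self):
        t = separable_table()
        model = train(t, algorithm="DT", seed=0)
        rep = evaluate_external(model, t)
        assert rep.confusion_matrix.sum() == 12
        assert rep.means["accuracy"] == 1.0

    def test_permuted_column_order_gives_identical_report(self):
        t = separable_table(seed=6)
        model = train(t, algorithm="LR", seed=0, normalization="standard")
        shuffled = FeatureTable(t.data[["y", "x"]], t.labels)
        r1 = evaluate_external(model, t)
        r2 = evaluate_external(model, shuffled)
        assert r1.means == r2.means

    def test_missing_motif_columns_zero_filled_with_warning(self):
        t = separable_table(seed=7)
        t2 = FeatureTable(t.data.rename(columns={"y": "motif2_VS"}), t.labels)
        model = train(t2, algorithm="LR", seed=0)
        dropped = FeatureTable(t2.data[["x"]], t2.labels)
        with pytest.warns(UserWarning, match="motif"):
            rep = evaluate_external(model, dropped)
        assert rep.confusion_matrix.sum() == 12

    def test_missing_non_motif_feature_is_contract_error(self):
        t = separable_table(seed=8)
        model = train(t, algorithm="LR", seed=0)
        dropped = FeatureTable(t.data[["y"]], t.labels)
        with pytest.raises(ContractError):
            evaluate_external(model, dropped)

    def test_tsne_features_are_not_transferable(self):
        t = separable_table(seed=9)
        renamed = FeatureTable(
            t.data.rename(columns={"x": "TSNE1", "y": "TSNE2"}), t.labels)
        model = train(renamed, algorithm="LR", seed=0)
        with pytest.raises(NonTransferableFeatureError):
            evaluate_external(model, renamed)

    def test_cross_cohort_transfer_at_large_effect(self):
        train_t = separable_table(n_per_class=8, gap=6.0, seed=10)
        test_t = separable_table(n_per_class=8, gap=6.0, seed=11)
        model = train(train_t, algorithm="DT", seed=0)
        rep = evaluate_external(model, test_t)
        assert rep.means["accuracy"] >= 0.9
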