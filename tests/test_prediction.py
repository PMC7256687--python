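"""Sample assembly, grouped folds, greedy FSS, SVM, nested CV, evaluation."""

import numpy as np
import pandas as pd
import pytest

from neurodecline.prediction import (
    CVConfig,
    assemble,
    evaluate,
    feature_columns,
    greedy_fss,
    grouped_folds,
    nested_cv,
    train_svm,
)
from conftest import make_sample_table


class TestAssemble:
    def test_mri_columns_replicated_per_segment(self):
        eeg = pd.DataFrame({
            "participant_id": ["A", "A", "A", "B", "B", "B"],
            "pdc1": np.arange(6, dtype=float),
        })
        mri = pd.DataFrame({"vol:1": [0.4, 0.6]}, index=["A", "B"])
        labels = pd.Series([0, 1], index=["A", "B"])
        table = assemble(eeg_features=eeg, mri_features=mri, labels=labels)
        assert len(table) == 6
        assert (table.loc[table["participant_id"] == "A", "vol:1"] == 0.4).all()
        assert (table.loc[table["participant_id"] == "B", "vol:1"] == 0.6).all()

    def test_mri_only_design_is_per_participant(self):
        mri = pd.DataFrame({"vol:1": [0.4, 0.6, 0.5]}, index=["A", "B", "C"])
        labels = pd.Series([0, 1, 0], index=["A", "B", "C"])
        table = assemble(mri_features=mri, labels=labels)
        assert len(table) == 3

    def test_empty_modality_set_errors(self):
        with pytest.raises(ValueError, match="modality"):
            assemble(labels=pd.Series([0, 1], index=["A", "B"]))

    def test_unlabeled_participant_dropped(self):
        mri = pd.DataFrame({"vol:1": [0.4, 0.6]}, index=["A", "B"])
        labels = pd.Series([1], index=["A"])
        table = assemble(mri_features=mri, labels=labels)
        assert list(table["participant_id"]) == ["A"]


class TestGroupedFolds:
    def test_no_participant_split_across_folds(self):
        labels = pd.Series([0, 1] * 5, index=[f"P{i}" for i in range(10)])
        folds = grouped_folds(labels, 5, seed=0)
        assert sorted(folds) == sorted(labels.index)
        sizes = pd.Series(folds).value_counts()
        assert (sizes == 2).all()

    def test_stratification_balances_classes(self):
        labels = pd.Series([0] * 10 + [1] * 10, index=[f"P{i}" for i in range(20)])
        folds = grouped_folds(labels, 5, seed=1)
        df = pd.DataFrame({"fold": pd.Series(folds), "label": labels})
        per_fold = df.groupby("fold")["label"].sum()
        assert (per_fold == 2).all()

    def test_determinism_and_seed_sensitivity(self):
        labels = pd.Series([0, 1] * 8, index=[f"P{i}" for i in range(16)])
        assert grouped_folds(labels, 4, seed=5) == grouped_folds(labels, 4, seed=5)
        assert grouped_folds(labels, 4, seed=5) != grouped_folds(labels, 4, seed=6)

    def test_too_few_participants_errors(self):
        labels = pd.Series([0, 1], index=["A", "B"])
        with pytest.raises(ValueError):
            grouped_folds(labels, 5, seed=0)


class TestSVM:
    def test_separable_data_fit_perfectly(self, rng):
        x = np.vstack([rng.normal(-3, 0.5, (20, 2)), rng.normal(3, 0.5, (20, 2))])
        y = np.array([0] * 20 + [1] * 20)
        model = train_svm(x, y)
        assert (model.predict(x) == y).all()

    def test_single_class_errors(self, rng):
        with pytest.raises(ValueError, match="single class"):
            train_svm(rng.normal(size=(10, 2)), np.zeros(10))

    def test_non_support_vector_removal_preserves_decision(self, rng):
        x = np.vstack([rng.normal(-3, 0.5, (30, 2)), rng.normal(3, 0.5, (30, 2))])
        y = np.array([0] * 30 + [1] * 30)
        model = train_svm(x, y)
        margins = np.abs(model.decision_function(x))
        far = int(np.argmax(margins))  # most distant point: not a support vector
        keep = np.arange(len(y)) != far
        model2 = train_svm(x[keep], y[keep])
        probe = rng.normal(0, 3, (50, 2))
        d1 = model.decision_function(probe)
        d2 = model2.decision_function(probe)
        assert np.allclose(d1, d2, atol=0.05)

    def test_label_permutation_near_chance(self, rng):
        # cross-validated balanced accuracy under the permutation null
        from sklearn.metrics import balanced_accuracy_score
        from sklearn.model_selection import cross_val_predict

        accs = []
        for rep in range(50):
            x = rng.normal(size=(60, 5))
            y = rng.permutation([0] * 30 + [1] * 30)
            model = train_svm(x[:40], y[:40])
            accs.append(balanced_accuracy_score(y[40:], model.predict(x[40:])))
        assert abs(np.mean(accs) - 0.5) < 0.1


class TestGreedyFSS:
    def test_cap_respected(self):
        table, _ = make_sample_table(n_participants=12, n_features=15, seed=1)
        subset = greedy_fss(table, cap=4, inner_k=3, seed=0)
        assert len(subset) <= 4

    def test_perfect_feature_found_first(self):
        hits = 0
        for seed in range(20):
            table, labels = make_sample_table(
                n_participants=12, n_segments=3, n_features=40,
                n_informative=1, effect=8.0, seed=seed,
            )
            subset = greedy_fss(table, cap=3, inner_k=3, seed=seed)
            hits += subset[0] == "f0"
        assert hits >= 19  # >= 95% of trials

    def test_pure_noise_stops_early_near_chance(self):
        table, _ = make_sample_table(
            n_participants=12, n_features=10, n_informative=0, seed=2
        )
        subset = greedy_fss(table, cap=10, inner_k=3, seed=0)
        assert len(subset) < 10


class TestNestedCV:
    def test_selection_frequency_bounded_by_middle_folds(self):
        table, _ = make_sample_table(n_participants=15, n_features=10, seed=3)
        res = nested_cv(table, CVConfig(feature_cap=3, seed=0))
        assert res.selection_frequency.max() <= 5
        assert len(res.selected_subsets) == 5

    def test_train_test_participants_disjoint(self):
        table, _ = make_sample_table(n_participants=15, n_features=10, seed=3)
        res = nested_cv(table, CVConfig(feature_cap=3, seed=0))
        assert not set(res.train_participants) & set(res.test_participants)
        test_rows = set(
            res.test_predictions["participant_id"]
        )
        assert test_rows <= set(res.test_participants)

    def test_planted_features_recovered_with_high_accuracy(self):
        table, _ = make_sample_table(
            n_participants=20, n_segments=5, n_features=25,
            n_informative=3, effect=3.0, seed=4,
        )
        res = nested_cv(table, CVConfig(feature_cap=5, seed=1))
        top = res.selection_frequency.sort_values(ascending=False)
        assert top.index[0] in {"f0", "f1", "f2"}
        rep = evaluate(res)
        assert rep["participant_level"]["balanced_accuracy"] > 90.0

    def test_noise_features_do_not_inflate_accuracy(self):
        # adding pure-noise columns must not raise held-out accuracy much
        accs = {}
        for extra in (0, 30):
            vals = []
            for seed in range(5):
                table, _ = make_sample_table(
                    n_participants=16, n_segments=3,
                    n_features=10 + extra, n_informative=2,
                    effect=2.0, seed=seed,
                )
                res = nested_cv(table, CVConfig(feature_cap=4, seed=seed))
                vals.append(evaluate(res)["participant_level"]["balanced_accuracy"])
            accs[extra] = np.mean(vals)
        assert accs[30] <= accs[0] + 5.0


class TestEvaluate:
    def _result_from_predictions(self, rows):
        from neurodecline.prediction import CVResult

        preds = pd.DataFrame(rows, columns=["participant_id", "label", "prediction"])
        return CVResult(
            config=CVConfig(), feature_names=[], selected_subsets=[],
            selection_frequency=pd.Series(dtype=int), final_features=[],
            test_predictions=preds,
        )

    def test_all_correct_gives_100s(self):
        rows = [("A", 1, 1), ("B", 0, 0)]
        rep = evaluate(self._result_from_predictions(rows))
        part = rep["participant_level"]
        assert part["accuracy"] == part["sensitivity"] == part["specificity"] == 100.0
        assert rep["reportable"]

    def test_confusion_arithmetic(self):
        rows = (
            [(f"TP{i}", 1, 1) for i in range(9)]
            + [("FN0", 1, 0)]
            + [(f"TN{i}", 0, 0) for i in range(8)]
            + [(f"FP{i}", 0, 1) for i in range(2)]
        )
        rep = evaluate(self._result_from_predictions(rows))
        part = rep["participant_level"]
        assert part["sensitivity"] == pytest.approx(90.0)
        assert part["specificity"] == pytest.approx(80.0)

    def test_below_70_benchmark_not_reportable(self):
        # sens 72%, spec 68% -> flagged as a statistical artifact
        rows = (
            [(f"TP{i}", 1, 1) for i in range(18)]
            + [(f"FN{i}", 1, 0) for i in range(7)]
            + [(f"TN{i}", 0, 0) for i in range(17)]
            + [(f"FP{i}", 0, 1) for i in range(8)]
        )
        rep = evaluate(self._result_from_predictions(rows))
        part = rep["participant_level"]
        assert part["sensitivity"] == pytest.approx(72.0)
        assert part["specificity"] == pytest.approx(68.0)
        assert not rep["reportable"]

    def test_majority_vote_tie_goes_positive(self):
        rows = [("A", 1, 1), ("A", 1, 0)]
        rep = evaluate(self._result_from_predictions(rows))
        assert rep["participant_level"]["tp"] == 1


def test_feature_columns_excludes_metadata():
    df = pd.DataFrame({
        "participant_id": ["A"], "label": [1], "condition": ["rest"],
        "session": [1], "f0": [0.1],
    })
    assert feature_columns(df) == ["f0"]
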