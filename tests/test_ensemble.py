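"""Splitting, training, voting and evaluation of the six-member ensemble."""

import numpy as np
import pytest

from peakvote import (
    CLASSIFIER_KEYS,
    SimSpec,
    VoteRecord,
    diagnostics,
    evaluate_predictions,
    simulate_dataset,
    stratified_split,
    train_ensemble,
)
from peakvote._domain import feature_matrix
from peakvote.ensemble import PCA_ROUTED
from conftest import SMALL_GRIDS


class TestStratifiedSplit:
    def test_proportions_preserved_within_rounding(self, small_dataset):
        examples, _ = small_dataset
        train, test = stratified_split(examples, test_fraction=0.25, seed=3)
        n_test_pep = sum(e.annotation == "peptide" for e in test)
        assert len(train) + len(test) == len(examples)
        assert n_test_pep == round(0.25 * 60)

    def test_paper_style_explicit_counts(self, small_dataset):
        examples, _ = small_dataset
        train, test = stratified_split(examples, seed=0, test_counts={"peptide": 25, "noise": 20})
        assert sum(e.annotation == "peptide" for e in test) == 25
        assert sum(e.annotation == "noise" for e in test) == 20

    def test_same_seed_same_membership(self, small_dataset):
        examples, _ = small_dataset
        a = stratified_split(examples, 0.3, seed=5)
        b = stratified_split(examples, 0.3, seed=5)
        assert [e.source_id for e in a[1]] == [e.source_id for e in b[1]]

    @pytest.mark.parametrize("fraction", [0.0, 1.0, -0.2])
    def test_fraction_out_of_range_errors(self, small_dataset, fraction):
        with pytest.raises(ValueError):
            stratified_split(small_dataset[0], fraction, seed=0)

    def test_single_class_errors(self, small_dataset):
        peptides = [e for e in small_dataset[0] if e.annotation == "peptide"]
        with pytest.raises(ValueError):
            stratified_split(peptides, 0.3, seed=0)


class TestEvaluatePredictions:
    @pytest.mark.parametrize(
        "tp, fp, fn, tn, precision",
        [(151, 7, 10, 151, 95.6), (140, 2, 21, 156, 98.6), (160, 87, 1, 71, 64.8)],
    )
    def test_precision_percentages(self, tp, fp, fn, tn, precision):
        pred = np.array([True] * (tp + fp) + [False] * (fn + tn))
        truth = np.array(
            [True] * tp + [False] * fp + [True] * fn + [False] * tn
        )
        cc = evaluate_predictions(pred, truth)
        assert (cc.tp, cc.fp, cc.fn, cc.tn) == (tp, fp, fn, tn)
        assert cc.precision_pct == precision

    def test_undefined_precision_is_none_not_zero(self):
        cc = evaluate_predictions([False, False], ["peptide", "noise"])
        assert cc.precision_pct is None
        assert cc.tp + cc.fp == 0

    def test_accuracy_percentage(self):
        cc = evaluate_predictions(
            ["peptide", "noise", "peptide"], ["peptide", "noise", "noise"]
        )
        assert cc.accuracy_pct == pytest.approx(66.7)

    def test_misaligned_inputs_error(self):
        with pytest.raises(ValueError):
            evaluate_predictions([True], [True, False])


class TestVoteRecord:
    def test_agreement_takes_only_seven_values(self):
        seen = set()
        for k in range(7):
            votes = {c: i < k for i, c in enumerate(CLASSIFIER_KEYS)}
            rec = VoteRecord(votes=votes)
            seen.add(round(rec.agreement, 2))
            assert rec.unanimous_peptide == (k == 6)
        assert seen == {0.0, 0.17, 0.33, 0.5, 0.67, 0.83, 1.0}

    def test_incomplete_votes_rejected(self):
        with pytest.raises(ValueError):
            VoteRecord(votes={"svm": True})


class TestTrainEnsemble:
    def test_contains_six_members_and_no_gnb_tuning_record(self, small_model):
        assert set(small_model.classifiers) == set(CLASSIFIER_KEYS)
        assert "gnb" not in small_model.hyperparameters
        assert set(small_model.hyperparameters) == set(CLASSIFIER_KEYS) - {"gnb"}

    def test_routing_map_is_total(self, small_model):
        routing = small_model.routing
        assert set(routing) == set(CLASSIFIER_KEYS)
        assert {k for k, v in routing.items() if v == "pca"} == set(PCA_ROUTED)

    def test_separable_data_reaches_high_cv_accuracy(self, small_model):
        assert all(acc >= 0.9 for acc in small_model.cv_accuracy.values())

    def test_single_class_train_set_errors(self, small_dataset):
        peptides = [e for e in small_dataset[0] if e.annotation == "peptide"]
        with pytest.raises(ValueError):
            train_ensemble(peptides, seed=0, grids=SMALL_GRIDS)

    def test_empty_grid_for_tuned_member_errors(self, small_dataset):
        grids = dict(SMALL_GRIDS)
        grids["svm"] = []
        with pytest.raises(ValueError, match="svm"):
            train_ensemble(small_dataset[0], seed=0, grids=grids)

    def test_full_determinism_under_fixed_seed(self, small_dataset):
        examples, _ = small_dataset
        X, _ = feature_matrix(examples)
        grids = {k: v + [] for k, v in SMALL_GRIDS.items()}
        grids["svm"] = [{"C": 0.1}, {"C": 1.0}]
        m1 = train_ensemble(examples, seed=21, grids=grids)
        m2 = train_ensemble(examples, seed=21, grids=grids)
        assert m1.hyperparameters == m2.hyperparameters
        v1 = m1.predict_votes_batch(X)
        v2 = m2.predict_votes_batch(X)
        assert [v.votes for v in v1] == [v.votes for v in v2]


class TestUnanimousRule:
    def test_unanimous_positive_set_is_subset_of_every_member(self, small_model, small_dataset):
        examples, _ = simulate_dataset(SimSpec(n_peptide=80, n_noise=80, seed=13))
        X, y = feature_matrix(examples)
        votes = small_model.predict_votes_batch(X)
        unanimous = np.array([v.unanimous_peptide for v in votes])
        for key in CLASSIFIER_KEYS:
            member = np.array([v.votes[key] for v in votes])
            assert np.all(unanimous <= member)  # subset
            assert (
                evaluate_predictions(unanimous, y).fp
                <= evaluate_predictions(member, y).fp
            )

    def test_precision_for_recall_trade_on_separable_data(self, small_model):
        examples, _ = simulate_dataset(
            SimSpec(n_peptide=100, n_noise=100, seed=29, separation=2.0)
        )
        X, y = feature_matrix(examples)
        votes = small_model.predict_votes_batch(X)
        unanimous = np.array([v.unanimous_peptide for v in votes])
        cc = evaluate_predictions(unanimous, y)
        assert cc.precision_pct is None or cc.precision_pct >= 95.0
        assert cc.fp <= min(
            evaluate_predictions([v.votes[k] for v in votes], y).fp
            for k in CLASSIFIER_KEYS
        )


class TestDiagnostics:
    def test_permutation_null_centers_on_half(self, small_dataset):
        examples, _ = small_dataset
        out = diagnostics(examples, seed=2, n_permutations=25, classifiers=["gnb"])
        perm = out["permutation"]["gnb"]["permuted_accuracies"]
        se = np.sqrt(0.25 / len(examples))
        assert abs(perm.mean() - 0.5) <= 3 * se
        assert out["permutation"]["gnb"]["observed_accuracy"] > 0.8

    def test_learning_curve_scores_tabulated(self, small_dataset):
        out = diagnostics(
            small_dataset[0], seed=2, n_permutations=1,
            curve_sizes=[30, 60, 90], classifiers=["knn"],
        )
        lc = out["learning_curve"]
        assert list(lc["train_size"]) == [30, 60, 90]
        assert lc["cv_accuracy"].iloc[-1] > 0.8

    def test_zero_permutations_error(self, small_dataset):
        with pytest.raises(ValueError):
            diagnostics(small_dataset[0], n_permutations=0)

    def test_oversized_curve_errors(self, small_dataset):
        with pytest.raises(ValueError):
            diagnostics(
                small_dataset[0], n_permutations=1,
                curve_sizes=[10_000], classifiers=["knn"],
            )
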