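"""Feature selection, the six classifier families, and complete LOOCV."""

import numpy as np
import pandas as pd
import pytest
from itertools import combinations
from sklearn.svm import SVC

from lungsig import (
    CvSpec,
    classifier_overlap_venn,
    fit_predict,
    greedy_pairs_select,
    loocv_class_prediction,
    svm_rfe_select,
    tscore_rank,
)
from oracles import greedy_pairs_oracle, pooled_t_oracle, venn_oracle


def labelled_matrix(values, n_case):
    n = values.shape[1]
    cols = [f"a{j}" for j in range(n)]
    matrix = pd.DataFrame(values, columns=cols,
                          index=[f"f{i}" for i in range(values.shape[0])])
    labels = pd.Series(["case"] * n_case + ["control"] * (n - n_case), index=cols)
    return matrix, labels


@pytest.fixture
def separable():
    rng = np.random.default_rng(0)
    values = rng.normal(8, 1, (10, 12))
    values[0, :6] += 5.0
    values[1, :6] += 4.0
    return labelled_matrix(values, 6)


class TestTscoreRank:
    def test_informative_feature_ranks_first(self, separable):
        matrix, labels = separable
        assert tscore_rank(matrix, labels)[0] == "f0"

    def test_label_swap_leaves_ranking_unchanged(self, separable):
        matrix, labels = separable
        swapped = labels.map({"case": "control", "control": "case"})
        assert tscore_rank(matrix, labels) == tscore_rank(matrix, swapped)

    def test_order_matches_brute_force_t(self):
        rng = np.random.default_rng(1)
        matrix, labels = labelled_matrix(rng.normal(0, 1, (5, 8)), 4)
        case = matrix.iloc[:, :4].to_numpy()
        ctrl = matrix.iloc[:, 4:].to_numpy()
        expected = sorted(
            range(5),
            key=lambda g: (-abs(pooled_t_oracle(case[g], ctrl[g])), g),
        )
        assert tscore_rank(matrix, labels) == [f"f{g}" for g in expected]


class TestGreedyPairs:
    def test_jointly_separating_pair_beats_marginal_ranking(self):
        """Two features that separate only in combination are picked as the
        first pair (verified against the exhaustive-pair oracle)."""
        rng = np.random.default_rng(2)
        n = 20
        half = n // 2
        values = rng.normal(0, 0.3, (6, n))
        # f0/f1: shared anti-correlated noise, so the pair separates far
        # better than either alone; f2 is a mediocre marginal feature
        u = rng.normal(0, 2, n)
        values[0] = u + rng.normal(0, 0.05, n)
        values[1] = -u + rng.normal(0, 0.05, n)
        values[0, :half] += 1.5
        values[1, :half] += 1.5
        values[2, :half] += 0.3
        matrix, labels = labelled_matrix(values, half)
        chosen = greedy_pairs_select(matrix, labels, 2)
        oracle = greedy_pairs_oracle(
            matrix.to_numpy(), (labels == "case").to_numpy().astype(int), 2
        )
        assert chosen == [f"f{g}" for g in oracle]
        assert set(chosen[:2]) == {"f0", "f1"}

    def test_matches_oracle_on_random_instances(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            values = rng.normal(0, 1, (9, 10))
            values[:3, :5] += rng.normal(0, 1, (3, 1))
            matrix, labels = labelled_matrix(values, 5)
            mine = greedy_pairs_select(matrix, labels, 3)
            oracle = greedy_pairs_oracle(
                values, (labels == "case").to_numpy().astype(int), 3
            )
            assert mine == [f"f{g}" for g in oracle]

    def test_zero_pairs_gives_empty_list(self, separable):
        matrix, labels = separable
        assert greedy_pairs_select(matrix, labels, 0) == []

    def test_identical_copies_still_distinct_features(self):
        rng = np.random.default_rng(3)
        row = rng.normal(0, 1, 10)
        values = np.tile(row, (6, 1)) + rng.normal(0, 1e-9, (6, 10))
        matrix, labels = labelled_matrix(values, 5)
        chosen = greedy_pairs_select(matrix, labels, 3)
        assert len(chosen) == len(set(chosen)) == 6

    def test_capacity_exceeded_rejected(self, separable):
        matrix, labels = separable
        with pytest.raises(ValueError, match="pairs"):
            greedy_pairs_select(matrix, labels, 6)


class TestSvmRfe:
    def test_informative_pair_survives_to_target(self):
        rng = np.random.default_rng(4)
        values = rng.normal(0, 1, (10, 16))
        values[3, :8] += 4.0
        values[7, :8] -= 4.0
        matrix, labels = labelled_matrix(values, 8)
        kept = svm_rfe_select(matrix, labels, target_size=2)
        assert set(kept) == {"f3", "f7"}
        # cross-check: the kept pair is the best 2-subset by training accuracy
        y = (labels == "case").to_numpy(int)
        best, best_acc = None, -1
        for pair in combinations(range(10), 2):
            clf = SVC(kernel="linear", C=1.0)
            x = values[list(pair)].T
            acc = clf.fit(x, y).score(x, y)
            if acc > best_acc:
                best, best_acc = pair, acc
        assert best_acc == pytest.approx(
            SVC(kernel="linear", C=1.0)
            .fit(matrix.loc[kept].to_numpy().T, y)
            .score(matrix.loc[kept].to_numpy().T, y)
        )

    def test_target_equal_to_feature_count_is_identity(self, separable):
        matrix, labels = separable
        assert svm_rfe_select(matrix, labels, target_size=10) == list(matrix.index)

    def test_deterministic_given_fixed_input(self, separable):
        matrix, labels = separable
        assert svm_rfe_select(matrix, labels, 4) == svm_rfe_select(matrix, labels, 4)

    def test_non_binary_labels_rejected(self, separable):
        matrix, labels = separable
        labels = labels.copy()
        labels.iloc[0] = "other"
        with pytest.raises(ValueError, match="binary"):
            svm_rfe_select(matrix, labels, 4)


class TestFitPredict:
    def build(self):
        # hand-sized training set: 2 features, 4 arrays
        train = pd.DataFrame(
            {"a0": [2.0, 1.0], "a1": [3.0, 2.0], "b0": [0.0, 0.0], "b1": [1.0, 1.0]},
            index=["f0", "f1"],
        )
        labels = pd.Series(["case", "case", "control", "control"], index=train.columns)
        return train, labels

    def test_ccp_matches_hand_computed_compound_score(self):
        train, labels = self.build()
        # hand: means (2.5, 1.5) vs (0.5, 0.5); pooled var = 0.5 each
        # t_g = diff / sqrt(0.5 * (1/2 + 1/2)) = (2.0, 1.0) / 0.7071
        t0 = 2.0 / np.sqrt(0.5)
        t1 = 1.0 / np.sqrt(0.5)
        test = pd.Series([2.0, 1.5], index=train.index)
        expected_score = t0 * 2.0 + t1 * 1.5
        pred, score = fit_predict(train, labels, test, "CCP")
        assert score == pytest.approx(expected_score)
        assert pred == "case"

    def test_ccp_tie_at_threshold_predicts_control(self):
        train = pd.DataFrame({"a0": [1.0], "a1": [1.2], "b0": [0.0], "b1": [-0.2]},
                             index=["f0"])
        labels = pd.Series(["case", "case", "control", "control"], index=train.columns)
        midpoint = pd.Series([0.5], index=train.index)
        pred, _ = fit_predict(train, labels, midpoint, "CCP")
        assert pred == "control"

    def test_dlda_matches_hand_computed_discriminant(self):
        train, labels = self.build()
        test = pd.Series([0.4, 0.6], index=train.index)
        s2 = np.array([0.5, 0.5])
        d_case = ((0.4 - 2.5) ** 2 + (0.6 - 1.5) ** 2) / 0.5
        d_ctrl = ((0.4 - 0.5) ** 2 + (0.6 - 0.5) ** 2) / 0.5
        pred, score = fit_predict(train, labels, test, "DLDA")
        assert pred == ("case" if d_case < d_ctrl else "control")
        assert score == pytest.approx(d_ctrl - d_case)

    def test_nc_predicts_class_of_matching_centroid(self):
        train, labels = self.build()
        centroid = train[["a0", "a1"]].mean(axis=1)
        pred, _ = fit_predict(train, labels, centroid, "NC")
        assert pred == "case"

    def test_nn_majority_vote(self):
        train, labels = self.build()
        test = pd.Series([0.1, 0.1], index=train.index)
        pred, frac = fit_predict(train, labels, test, "NN", k=3)
        assert pred == "control" and frac == pytest.approx(1 / 3)

    def test_nn_k_must_be_below_train_size(self):
        train, labels = self.build()
        with pytest.raises(ValueError, match="k"):
            fit_predict(train, labels, train["a0"], "NN", k=5)

    def test_bccp_posterior_against_closed_form(self):
        train, labels = self.build()
        test = pd.Series([2.0, 1.5], index=train.index)
        t = np.array([2.0, 1.0]) / np.sqrt(0.5)
        c_case = t @ train[["a0", "a1"]].to_numpy()
        c_ctrl = t @ train[["b0", "b1"]].to_numpy()
        c = t @ test.to_numpy()
        var = (c_case.var(ddof=1) + c_ctrl.var(ddof=1)) / 2
        ll_case = -0.5 * (c - c_case.mean()) ** 2 / var + np.log(0.5)
        ll_ctrl = -0.5 * (c - c_ctrl.mean()) ** 2 / var + np.log(0.5)
        expected = 1 / (1 + np.exp(ll_ctrl - ll_case))
        pred, post = fit_predict(train, labels, test, "BCCP")
        assert post == pytest.approx(expected)
        assert pred == ("case" if expected > 0.5 else "control")

    def test_svm_agrees_with_sklearn_decision(self):
        train, labels = self.build()
        test = pd.Series([2.0, 2.0], index=train.index)
        clf = SVC(kernel="linear", C=1.0)
        clf.fit(train.to_numpy().T, (labels == "case").to_numpy(int))
        expected = float(clf.decision_function(test.to_numpy()[None, :])[0])
        pred, score = fit_predict(train, labels, test, "SVM")
        assert score == pytest.approx(expected)
        assert pred == ("case" if expected > 0 else "control")

    def test_unknown_model_rejected(self):
        train, labels = self.build()
        with pytest.raises(ValueError, match="unknown model"):
            fit_predict(train, labels, train["a0"], "LOGISTIC")


class TestLoocv:
    def test_perfectly_separated_classes_reach_full_accuracy(self):
        rng = np.random.default_rng(5)
        values = rng.normal(0, 0.2, (12, 10))
        values[0, :5] += 8.0
        matrix, labels = labelled_matrix(values, 5)
        spec = CvSpec(feature_selection="greedy_pairs", selected_size=2, model="DLDA")
        perf = loocv_class_prediction(matrix, labels, spec)
        assert perf.correct_rate == 1.0
        assert perf.sensitivity == 1.0 and perf.specificity == 1.0

    def test_matches_brute_force_fold_by_fold_oracle(self):
        rng = np.random.default_rng(6)
        values = rng.normal(0, 1, (10, 8))
        values[2, :4] += 2.0
        matrix, labels = labelled_matrix(values, 4)
        spec = CvSpec(feature_selection="greedy_pairs", selected_size=2, model="NC")
        perf = loocv_class_prediction(matrix, labels, spec)
        for array_id in matrix.columns:
            train = matrix.drop(columns=[array_id])
            tl = labels.drop(index=array_id)
            feats = greedy_pairs_select(train, tl, 2)
            assert perf.fold_features[array_id] == feats
            pred, _ = fit_predict(
                train.loc[feats], tl, matrix.loc[feats, array_id], "NC"
            )
            assert perf.predictions[array_id] == pred

    def test_metrics_identity_holds_exactly(self):
        rng = np.random.default_rng(7)
        values = rng.normal(0, 1, (10, 14))
        values[0, :8] += 1.0
        matrix, labels = labelled_matrix(values, 8)
        spec = CvSpec(feature_selection="rfe", selected_size=4, model="SVM")
        perf = loocv_class_prediction(matrix, labels, spec)
        p, n = 8, 6
        assert perf.correct_rate * (p + n) == pytest.approx(
            perf.sensitivity * p + perf.specificity * n
        )

    def test_permuted_labels_hover_at_chance(self):
        """With random balanced labels, cross-validated accuracy stays near
        50% (binomial fluctuation band) for most seeds."""
        hits = 0
        for seed in range(8):
            rng = np.random.default_rng(100 + seed)
            values = rng.normal(0, 1, (30, 20))
            matrix, labels = labelled_matrix(values, 10)
            spec = CvSpec(feature_selection="greedy_pairs", selected_size=3,
                          model="DLDA")
            perf = loocv_class_prediction(matrix, labels, spec)
            hits += 0.35 <= perf.correct_rate <= 0.65
        assert hits >= 6

    def test_held_out_array_cannot_leak_into_selection(self):
        rng = np.random.default_rng(8)
        values = rng.normal(0, 1, (15, 10))
        values[1, :5] += 1.5
        matrix, labels = labelled_matrix(values, 5)
        spec = CvSpec(feature_selection="greedy_pairs", selected_size=3, model="CCP")
        baseline = loocv_class_prediction(matrix, labels, spec)
        spiked = matrix.copy()
        spiked["a0"] = spiked["a0"] + 50.0
        perturbed = loocv_class_prediction(spiked, labels, spec)
        assert baseline.fold_features["a0"] == perturbed.fold_features["a0"]

    def test_odd_k_enforced_for_nn(self):
        with pytest.raises(ValueError, match="odd"):
            CvSpec(model="NN", k=2).validate()


class TestVenn:
    def test_disjoint_panels_have_empty_intersections(self):
        panels = {n: [f"{n}{i}" for i in range(4)] for n in "ABCD"}
        regions = classifier_overlap_venn(panels)
        assert all(v == 0 for k, v in regions.items() if "&" in k)
        assert all(regions[n] == 4 for n in "ABCD")

    def test_identical_panels_fill_only_the_four_way_region(self):
        panels = {n: ["x", "y"] for n in "ABCD"}
        regions = classifier_overlap_venn(panels)
        assert regions["A&B&C&D"] == 2
        assert sum(v for k, v in regions.items() if k != "A&B&C&D") == 0

    def test_random_panels_match_enumeration_oracle(self):
        rng = np.random.default_rng(9)
        universe = [f"Ag{i}" for i in range(5000)]
        panels = {
            h: list(rng.choice(universe, 100, replace=False))
            for h in ("SCLC", "SqLC", "LCLC", "AdCa")
        }
        regions = classifier_overlap_venn(panels)
        expected = venn_oracle({k: set(v) for k, v in panels.items()})
        assert len(regions) == 15
        assert regions == expected
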