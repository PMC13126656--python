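"""Cosine similarity, force layout, similarity-summary LOOCV, ROC."""

import numpy as np
import pandas as pd
import pytest

from conftest import auc_pair_counting
from pamvasc import similarity_classifier as sc
from pamvasc import synthetic_data as sd
from pamvasc.rf_preprocessing import ValidationError

NB, EE = "normal_benign", "ec_ein"


def _sim_from(S, labels):
    return sc.SimilarityMatrix(
        S=np.asarray(S, dtype=float),
        ids=[str(i) for i in range(len(labels))],
        labels=np.asarray(labels),
    )


class TestCosineSimilarity:
    def test_identical_rows_similarity_one(self):
        df = pd.DataFrame({"a": [1.0, 1.0], "b": [2.0, 2.0], "label": [NB, EE]})
        sim = sc.cosine_similarity(df)
        assert sim.S[0, 1] == pytest.approx(1.0)

    def test_orthogonal_rows_similarity_zero(self):
        df = pd.DataFrame(
            {"a": [1.0, 0.0], "b": [0.0, 1.0], "c": [0.0, 0.0], "label": [NB, EE]}
        )
        assert sc.cosine_similarity(df).S[0, 1] == pytest.approx(0.0, abs=1e-15)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.random((10, 5)), columns=list("abcde"))
        df["label"] = [NB] * 5 + [EE] * 5
        sim = sc.cosine_similarity(df)
        x = df[list("abcde")].to_numpy()
        for i in range(10):
            for j in range(10):
                ref = np.dot(x[i], x[j]) / (np.linalg.norm(x[i]) * np.linalg.norm(x[j]))
                assert sim.S[i, j] == pytest.approx(ref, abs=1e-12)

    def test_row_scale_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.random((6, 4))
        df1 = pd.DataFrame(x, columns=list("abcd"))
        df1["label"] = [NB] * 3 + [EE] * 3
        df2 = df1.copy()
        df2.loc[:, list("abcd")] = x * rng.uniform(0.1, 10.0, size=(6, 1))
        np.testing.assert_allclose(
            sc.cosine_similarity(df1).S, sc.cosine_similarity(df2).S, atol=1e-12
        )

    def test_symmetric_unit_diagonal(self, separated_table):
        sim = sc.cosine_similarity(separated_table, list(sd.SELECTED_FEATURES))
        np.testing.assert_array_equal(sim.S, sim.S.T)
        np.testing.assert_array_equal(np.diag(sim.S), 1.0)

    def test_zero_norm_row_rejected(self):
        df = pd.DataFrame({"a": [1.0, 0.0], "b": [1.0, 0.0], "label": [NB, EE]})
        with pytest.raises(ValidationError, match="zero-norm"):
            sc.cosine_similarity(df)

    def test_missing_rows_dropped_with_warning(self):
        df = pd.DataFrame(
            {"a": [1.0, 2.0, np.nan], "b": [1.0, 1.0, 1.0], "label": [NB, EE, EE]}
        )
        with pytest.warns(UserWarning, match="dropping"):
            sim = sc.cosine_similarity(df)
        assert len(sim) == 2


class TestForceLayout:
    def test_two_node_distance_decreases_with_similarity(self):
        dists = []
        for w in (0.2, 0.5, 0.9):
            sim = _sim_from([[1.0, w], [w, 1.0]], [NB, EE])
            emb = sc.force_layout(sim, seed=3)
            dists.append(np.linalg.norm(emb.coords[0] - emb.coords[1]))
        assert dists[0] > dists[1] > dists[2]

    def test_block_structure_separates(self):
        labels = [NB] * 10 + [EE] * 10
        same = np.equal.outer(np.array(labels), np.array(labels))
        S = np.where(same, 0.9, 0.1)
        np.fill_diagonal(S, 1.0)
        sim = _sim_from(S, labels)
        emb = sc.force_layout(sim, seed=0)
        d = np.linalg.norm(emb.coords[:, None] - emb.coords[None, :], axis=2)
        iu = np.triu_indices(20, 1)
        assert d[iu][same[iu]].mean() < d[iu][~same[iu]].mean()

    def test_deterministic_given_seed(self, separated_table):
        sim = sc.cosine_similarity(separated_table, list(sd.SELECTED_FEATURES))
        e1 = sc.force_layout(sim, seed=42)
        e2 = sc.force_layout(sim, seed=42)
        np.testing.assert_array_equal(e1.coords, e2.coords)

    def test_single_node_rejected(self):
        sim = _sim_from([[1.0]], [NB])
        with pytest.raises(ValidationError):
            sc.force_layout(sim)


class TestBoundary2D:
    def test_separable_toy(self):
        coords = np.array(
            [[-2, 0], [-2, 1], [-3, 0], [-3, 1], [2, 0], [2, 1], [3, 0], [3, 1]],
            dtype=float,
        )
        emb = sc.Embedding2D(coords=coords, seed=0, n_iter=0, final_energy=0.0)
        labels = np.array([NB] * 4 + [EE] * 4)
        res = sc.boundary_2d(emb, labels)
        assert res.n_correct_side == 8

    def test_shuffled_labels_near_chance(self):
        rng = np.random.default_rng(0)
        coords = rng.standard_normal((20, 2))
        emb = sc.Embedding2D(coords=coords, seed=0, n_iter=0, final_energy=0.0)
        base = np.array([NB] * 10 + [EE] * 10)
        fracs = []
        for _ in range(100):
            labels = rng.permutation(base)
            fracs.append(sc.boundary_2d(emb, labels).n_correct_side / 20)
        assert 0.45 <= np.mean(fracs) <= 0.75  # slightly above 1/2: in-sample fit

    def test_separated_dataset_end_to_end(self, separated_table):
        sim = sc.cosine_similarity(separated_table, list(sd.SELECTED_FEATURES))
        emb = sc.force_layout(sim, seed=42)
        res = sc.boundary_2d(emb, sim.labels)
        assert res.n_correct_side >= 38  # >= 95% of 40


class TestSimilaritySummary:
    def test_constant_similarities(self):
        sims = np.full(6, 0.7)
        labels = np.array([NB, NB, NB, EE, EE, EE])
        vec = sc.similarity_summary(sims, labels)
        np.testing.assert_allclose(vec, [0.7, 0.0, 0.7, 0.0], atol=1e-12)

    def test_hand_computed_five_sample_case(self):
        labels = np.array([NB, NB, EE, EE, EE])
        sims = np.array([0.9, 0.7, 0.4, 0.5, 0.6])
        vec = sc.similarity_summary(sims, labels)
        assert vec[0] == pytest.approx(0.8)
        assert vec[1] == pytest.approx(np.std([0.9, 0.7], ddof=1))
        assert vec[2] == pytest.approx(0.5)
        assert vec[3] == pytest.approx(np.std([0.4, 0.5, 0.6], ddof=1))

    def test_self_exclusion(self):
        labels = np.array([NB, NB, NB, EE, EE])
        sims = np.array([1.0, 0.5, 0.7, 0.3, 0.4])
        vec = sc.similarity_summary(sims, labels, exclude_index=0)
        assert vec[0] == pytest.approx(0.6)  # mean of 0.5, 0.7 — self dropped

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        labels = np.array([NB] * 4 + [EE] * 4)
        sims = rng.random(8)
        perm = rng.permutation(8)
        v1 = sc.similarity_summary(sims, labels)
        v2 = sc.similarity_summary(sims[perm], labels[perm])
        np.testing.assert_allclose(v1, v2)

    def test_tiny_cluster_rejected(self):
        labels = np.array([NB, EE, EE])
        with pytest.raises(ValidationError, match="fewer than 2"):
            sc.similarity_summary(np.ones(3), labels)


class TestLOOCV:
    def test_strong_separation_perfect_metrics(self, separated_table):
        sim = sc.cosine_similarity(separated_table, list(sd.SELECTED_FEATURES))
        cv = sc.loocv(sim)
        assert cv.auc == 1.0
        assert cv.confusion["sensitivity"] == 1.0
        assert cv.confusion["specificity"] == 1.0
        assert sum(cv.confusion[k] for k in ("tp", "fn", "tn", "fp")) == 40

    def test_fold_is_pure_function_of_training_data(self, separated_table):
        """Leakage audit: deleting the held-out row/column and re-running the
        fold computation reproduces the recorded outputs exactly."""
        sim = sc.cosine_similarity(separated_table, list(sd.SELECTED_FEATURES))
        cv = sc.loocv(sim)
        n = len(sim)
        for i in range(n):
            train = np.arange(n) != i
            S_train = sim.S[np.ix_(train, train)]
            assert S_train.shape == (n - 1, n - 1)
            prob, coef, intercept = sc.fold_probability(
                S_train, sim.labels[train], sim.S[i, train]
            )
            assert prob == cv.probabilities[i]
            np.testing.assert_array_equal(coef, cv.fold_coefs[i])

    def test_fold_coefficient_signs_consistent(self, separated_table):
        """Similarity to the disease cluster should push toward disease,
        similarity to the normal cluster away, in >= 90% of folds."""
        sim = sc.cosine_similarity(separated_table, list(sd.SELECTED_FEATURES))
        cv = sc.loocv(sim)
        good = (cv.fold_coefs[:, 2] > 0) & (cv.fold_coefs[:, 0] < 0)
        assert good.mean() >= 0.9

    def test_degenerate_single_class_rejected(self):
        S = np.eye(6)
        sim = _sim_from(S, [EE] * 6)
        with pytest.raises(ValidationError):
            sc.loocv(sim)


class TestROC:
    def test_perfectly_ordered(self):
        probs = np.array([0.9, 0.8, 0.2, 0.1])
        labels = np.array([EE, EE, NB, NB])
        assert sc.roc_auc(probs, labels) == 1.0

    def test_all_ties(self):
        probs = np.full(6, 0.5)
        labels = np.array([EE] * 3 + [NB] * 3)
        assert sc.roc_auc(probs, labels) == 0.5

    def test_worked_example_pair_counting(self):
        probs = np.array([0.9, 0.8, 0.4, 0.3])
        labels = np.array([EE, NB, EE, NB])
        assert sc.roc_auc(probs, labels) == 0.75
        assert auc_pair_counting(probs, labels == EE) == 0.75

    def test_matches_pair_counting_oracle_random(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = rng.integers(6, 50)
            probs = np.round(rng.random(n), 2)  # rounding makes ties likely
            labels = np.where(rng.random(n) < 0.5, EE, NB)
            if len(set(labels)) < 2:
                continue
            assert sc.roc_auc(probs, labels) == pytest.approx(
                auc_pair_counting(probs, labels == EE), abs=1e-12
            )

    def test_confusion_counts(self):
        probs = np.array([0.9, 0.6, 0.4, 0.2])
        labels = np.array([EE, NB, EE, NB])
        c = sc.confusion_at(probs, labels, threshold=0.5)
        assert (c["tp"], c["fn"], c["tn"], c["fp"]) == (1, 1, 1, 1)
        assert c["accuracy"] == 0.5
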