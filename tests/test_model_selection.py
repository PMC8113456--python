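"""Kennard-Stone, MLM splitting, venetian-blinds CV and PLS-DA."""

import itertools

import numpy as np
import pytest

import ftirchem as fc
from ftirchem.errors import DataError, DegenerateDataError


def _maximin_oracle(X, n_select):
    """Brute-force Kennard-Stone: same maximin rule, enumerated directly."""
    X = np.atleast_2d(np.asarray(X, float))
    n = X.shape[0]
    d = np.linalg.norm(X[:, None] - X[None, :], axis=-1)
    best = min(
        ((i, j) for i, j in itertools.combinations(range(n), 2)),
        key=lambda p: (-d[p], p),
    )
    sel = list(best)
    while len(sel) < n_select:
        rest = [i for i in range(n) if i not in sel]
        sel.append(min(rest, key=lambda i: (-min(d[i, j] for j in sel), i)))
    return sel


class TestKennardStone:
    def test_documented_1d_cases(self):
        X = np.array([[0.0], [2.0], [3.0], [10.0]])
        assert fc.kennard_stone(X, 3).tolist() == [0, 3, 2]  # points {0, 10, 3}
        assert fc.kennard_stone(np.array([[0.0], [1.0], [10.0]]), 2).tolist() == [0, 2]

    def test_select_all(self):
        X = np.random.default_rng(0).normal(size=(6, 3))
        assert sorted(fc.kennard_stone(X, 6).tolist()) == list(range(6))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        X = rng.normal(size=(n, 2))
        k = int(rng.integers(2, n + 1))
        assert fc.kennard_stone(X, k).tolist() == _maximin_oracle(X, k)

    def test_duplicate_rows_resolved_by_tie_rule(self):
        X = np.array([[0.0], [0.0], [5.0], [5.0]])
        sel = fc.kennard_stone(X, 2)
        assert sel.tolist() == [0, 2]


class TestMlmSplit:
    def test_counts_with_balanced_classes(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 4))
        labels = ["A"] * 10 + ["B"] * 10
        s = fc.mlm_split(X, labels, train_frac=0.6, mutation_frac=0.1, seed=0)
        assert len(s.train_ids) == 12 and len(s.test_ids) == 8
        assert s.per_class_counts["A"] == {"train": 6, "test": 4}
        assert s.per_class_counts["B"] == {"train": 6, "test": 4}

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 5))
        labels = ["A"] * 14 + ["B"] * 16
        a = fc.mlm_split(X, labels, seed=9)
        b = fc.mlm_split(X, labels, seed=9)
        assert a.train_ids == b.train_ids and a.test_ids == b.test_ids
        c = fc.mlm_split(X, labels, seed=10)
        assert c.train_ids != a.train_ids or c.test_ids != a.test_ids

    def test_zero_mutation_equals_pure_kennard_stone(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(18, 3))
        labels = np.array(["A"] * 8 + ["B"] * 10)
        s = fc.mlm_split(X, labels, train_frac=0.5, mutation_frac=0.0, seed=4)
        expected = []
        for cls in ("A", "B"):
            idx = np.where(labels == cls)[0]
            n_train = int(np.floor(0.5 * idx.size + 0.5))
            expected.extend(idx[fc.kennard_stone(X[idx], n_train)])
        assert sorted(s.train_ids) == sorted(expected)

    def test_partitions_are_disjoint_and_cover(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(25, 3))
        labels = ["A"] * 11 + ["B"] * 14
        s = fc.mlm_split(X, labels, seed=0)
        assert set(s.train_ids).isdisjoint(s.test_ids)
        assert len(s.train_ids) + len(s.test_ids) == 25

    def test_singleton_class_rejected(self):
        X = np.random.default_rng(5).normal(size=(5, 2))
        with pytest.raises(DataError):
            fc.mlm_split(X, ["A"] * 4 + ["B"], seed=0)


class TestVenetianBlinds:
    def test_fold_assignment_definition(self):
        from ftirchem.model_selection import venetian_blinds_folds

        folds = venetian_blinds_folds(10, 5)
        for f in range(5):
            assert np.where(folds == f)[0].tolist() == [f, f + 5]

    def test_perfectly_separable_data_reaches_full_accuracy_early(self):
        rng = np.random.default_rng(6)
        n = 30
        labels = np.array(["A"] * 15 + ["B"] * 15)
        X = rng.normal(size=(n, 20)) * 0.05
        X[labels == "B", 0] += 10.0
        cv = fc.venetian_blinds_cv(X, labels, k=5, max_lv=8)
        assert cv.accuracy_per_lv[cv.chosen_n_lv - 1] == 1.0
        assert cv.chosen_n_lv <= 2

    def test_two_informative_directions_select_two_or_three_lvs(self):
        # class depends on t1 + t2, but the two latent directions live in
        # column blocks of very different scale, so the first component
        # captures mostly t1 and a second is genuinely needed
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 60
            t1 = rng.normal(size=n)
            t2 = rng.normal(size=n)
            p1 = rng.normal(size=20)
            p2 = rng.normal(size=20)
            X = np.hstack([np.outer(t1, p1) * 5.0, np.outer(t2, p2) * 0.4])
            X += 0.05 * rng.normal(size=X.shape)
            labels = np.where(t1 + t2 > 0, "A", "B")
            cv = fc.venetian_blinds_cv(X, labels, k=10, max_lv=10)
            hits += cv.chosen_n_lv in (2, 3)
        assert hits >= 16

    def test_ties_resolve_to_fewest_lvs(self):
        rng = np.random.default_rng(8)
        labels = np.array(["A", "B"] * 10)
        X = rng.normal(size=(20, 6)) * 0.01
        X[labels == "B", 1] += 5.0
        cv = fc.venetian_blinds_cv(X, labels, k=4, max_lv=5)
        first_max = int(np.argmax(cv.accuracy_per_lv)) + 1
        assert cv.chosen_n_lv == first_max


class TestPlsda:
    def test_separable_training_accuracy(self):
        rng = np.random.default_rng(9)
        labels = ["DR"] * 12 + ["AD"] * 12
        X = rng.normal(size=(24, 10))
        X[12:, 3] += 10.0
        model = fc.train_plsda(X, labels, n_lv=2, positive_label="AD")
        _, pred = fc.predict_plsda(model, X)
        assert list(pred) == labels

    def test_record_requested_lv_count(self):
        rng = np.random.default_rng(10)
        labels = ["DR"] * 20 + ["AD"] * 20
        X = rng.normal(size=(40, 30))
        X[20:, 5] += 2.0
        model = fc.train_plsda(X, labels, n_lv=5, positive_label="AD")
        assert model.pls.n_lv == 5

    def test_identical_labels_rejected(self):
        X = np.random.default_rng(11).normal(size=(8, 4))
        with pytest.raises((DataError, DegenerateDataError)):
            fc.train_plsda(X, ["AD"] * 8, n_lv=1)

    def test_three_classes_rejected(self):
        X = np.random.default_rng(12).normal(size=(9, 4))
        with pytest.raises(DataError, match="one-vs-one|two-class"):
            fc.train_plsda(X, ["A", "B", "C"] * 3, n_lv=1)

    def test_threshold_tie_goes_to_reference(self):
        rng = np.random.default_rng(13)
        labels = ["DR"] * 10 + ["AD"] * 10
        X = rng.normal(size=(20, 5))
        X[10:, 0] += 4.0
        model = fc.train_plsda(X, labels, n_lv=1, positive_label="AD")
        # craft a row whose score is exactly the threshold
        direction = model.pls.coef
        x = model.pls.x_mean + (model.threshold - model.pls.y_mean) * direction / (
            direction @ direction
        )
        score, pred = fc.predict_plsda(model, x[None, :])
        assert score[0] == pytest.approx(model.threshold, abs=1e-12)
        assert pred[0] == "DR"

    def test_scores_invariant_to_constant_column(self):
        rng = np.random.default_rng(14)
        labels = ["DR"] * 15 + ["AD"] * 15
        X = rng.normal(size=(30, 8))
        X[15:, 2] += 3.0
        m1 = fc.train_plsda(X, labels, n_lv=3, positive_label="AD")
        X_aug = np.column_stack([X, np.full(30, 7.0)])
        m2 = fc.train_plsda(X_aug, labels, n_lv=3, positive_label="AD")
        s1, _ = fc.predict_plsda(m1, X)
        s2, _ = fc.predict_plsda(m2, X_aug)
        np.testing.assert_allclose(s1, s2, atol=1e-10)
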