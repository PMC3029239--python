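"""Tuple sampling, the margin ranking loss, SGD updates, and multitask steps."""

import io

import numpy as np
import pytest

from conftest import (
    away_from_kinks,
    fd_grad,
    random_sparse_features,
    ranking_loss_oracle,
)
from protembed.embedding import EmbeddingModel
from protembed.io import PairwiseHit
from protembed.training import (
    AuxiliaryLabel,
    CentroidSet,
    TrainConfig,
    TrainingTuple,
    auxiliary_positive_index,
    auxiliary_ranking_tuples,
    build_positive_index,
    class_task_step,
    read_labels,
    sample_tuple,
    sgd_step,
    train,
    tuple_margin_loss,
)


class TestPositiveIndex:
    def test_strict_threshold(self):
        hits = [
            PairwiseHit("a", "b", 0.1),   # exactly at threshold: not positive
            PairwiseHit("a", "c", 0.099),
            PairwiseHit("a", "a", 0.0),   # self hit never positive
        ]
        idx = build_positive_index(hits, ["a", "b", "c"], threshold=0.1)
        assert list(idx.keys()) == [0]
        assert list(idx[0]) == [2]

    def test_no_signal_raises(self):
        with pytest.raises(ValueError, match="no training signal"):
            sample_tuple({}, 5, np.random.default_rng(0))


class TestSampleTuple:
    def test_forced_choice(self):
        idx = build_positive_index([PairwiseHit("a", "b", 0.01)], ["a", "b", "c"])
        rng = np.random.default_rng(0)
        for _ in range(20):
            t = sample_tuple(idx, 3, rng)
            assert (t.q, t.pos) == (0, 1)
            assert t.neg == 2  # only non-degenerate choice

    def test_positive_frequencies_uniform(self):
        hits = [PairwiseHit("q", t, 0.01) for t in ("a", "b", "c")]
        idx = build_positive_index(hits, ["q", "a", "b", "c"])
        rng = np.random.default_rng(1)
        draws = np.array([sample_tuple(idx, 4, rng).pos for _ in range(10_000)])
        counts = np.bincount(draws, minlength=4)[1:]
        # binomial 3-sigma band around 1/3
        sigma = np.sqrt(10_000 * (1 / 3) * (2 / 3))
        assert np.all(np.abs(counts - 10_000 / 3) < 3 * sigma)

    def test_negative_never_degenerate(self):
        idx = build_positive_index([PairwiseHit("a", "b", 0.01)], ["a", "b", "c", "d"])
        rng = np.random.default_rng(2)
        negs = {sample_tuple(idx, 4, rng).neg for _ in range(200)}
        assert negs == {2, 3}


class TestRankingLoss:
    def _setup(self, seed=0, n=10, d=4):
        rng = np.random.default_rng(seed)
        features = random_sparse_features(rng, n)
        model = EmbeddingModel(rng.standard_normal((d, n)), features.ids)
        return rng, features, model

    def test_satisfied_constraint_zero(self):
        # identical q and pos, distant neg: hinge satisfied for small margin
        rng, features, model = self._setup()
        F = features.matrix.toarray()
        dists = np.abs(model.W @ (F[0] - F[2])).sum()
        t = TrainingTuple(0, 0, 2)
        assert tuple_margin_loss(model, t, features, margin=dists / 2) == 0.0

    def test_hinge_at_equality(self):
        rng, features, model = self._setup()
        t = TrainingTuple(0, 1, 1)  # pos == neg -> equal distances
        assert tuple_margin_loss(model, t, features, margin=1.0) == pytest.approx(1.0)

    def test_two_path_computation(self):
        rng, features, model = self._setup(seed=3)
        for _ in range(20):
            t = TrainingTuple(*rng.integers(0, features.n, size=3))
            got = tuple_margin_loss(model, t, features, margin=1.0)
            assert got == pytest.approx(
                ranking_loss_oracle(model.W, features, t, 1.0), abs=1e-12
            )


class TestSgdStep:
    def test_zero_loss_is_noop(self):
        rng = np.random.default_rng(4)
        features = random_sparse_features(rng, 8)
        model = EmbeddingModel(rng.standard_normal((3, 8)), features.ids)
        # find a satisfied tuple
        for _ in range(200):
            t = TrainingTuple(*rng.integers(0, 8, size=3))
            if tuple_margin_loss(model, t, features, margin=0.01) == 0.0:
                break
        else:
            pytest.fail("no satisfied tuple found")
        before = model.W.copy()
        sgd_step(model, t, features, lr=0.5, margin=0.01)
        assert np.array_equal(model.W, before)  # bitwise unchanged

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(5)
        checked = 0
        while checked < 10:
            n, d = int(rng.integers(5, 21)), int(rng.integers(2, 6))
            features = random_sparse_features(rng, n)
            W0 = rng.standard_normal((d, n))
            t = TrainingTuple(*rng.integers(0, n, size=3))
            if len({t.q, t.pos, t.neg}) < 3 or not away_from_kinks(W0, features, t, 1.0):
                continue
            model = EmbeddingModel(W0.copy(), features.ids)
            sgd_step(model, t, features, lr=1.0, margin=1.0)
            analytic = W0 - model.W
            W = W0.copy()
            numerical = fd_grad(
                lambda: ranking_loss_oracle(W, features, t, 1.0), W
            )
            # relative error, with an absolute floor for near-zero gradients
            denom = max(np.linalg.norm(numerical), 1.0)
            assert np.linalg.norm(analytic - numerical) / denom < 1e-4
            checked += 1

    def test_descent_property(self):
        rng = np.random.default_rng(6)
        features = random_sparse_features(rng, 10)
        model = EmbeddingModel(rng.standard_normal((4, 10)), features.ids)
        for _ in range(200):
            t = TrainingTuple(*rng.integers(0, 10, size=3))
            if t.q != t.pos and tuple_margin_loss(model, t, features, 1.0) > 0.1:
                break
        before = tuple_margin_loss(model, t, features, 1.0)
        sgd_step(model, t, features, lr=1e-3, margin=1.0)
        assert tuple_margin_loss(model, t, features, 1.0) < before


def _two_hot_loss(W, cols, f_x, own, oth, margin):
    """Independent centroid hinge: margin + D(phi, own centroid) - D(phi, other)."""
    phi = W @ f_x
    cy = sum(cols[j] for j in own)
    cy2 = sum(cols[j] for j in oth)
    return max(0.0, margin + np.abs(phi - cy).sum() - np.abs(phi - cy2).sum())


class TestClassTaskStep:
    def _instance(self, seed):
        rng = np.random.default_rng(seed)
        n, d = int(rng.integers(5, 21)), int(rng.integers(2, 6))
        features = random_sparse_features(rng, n)
        model = EmbeddingModel(rng.standard_normal((d, n)), features.ids)
        la = AuxiliaryLabel("p0", "f0", "f0.0", "f0.0.0")
        lb = AuxiliaryLabel("p1", "f1", "f1.0", "f1.0.0")
        cents = CentroidSet(d, rng)
        for lab in (la, lb):
            cents.column(lab.fold)
            cents.column(lab.superfamily)
        return rng, features, model, la, lb, cents

    def test_same_category_pair_is_noop(self):
        rng, features, model, la, _, cents = self._instance(7)
        W0 = model.W.copy()
        C0 = [c.copy() for c in cents._cols]
        loss = class_task_step(model, 0, la, 1, la, features, cents, lr=0.5, margin=1.0)
        assert loss == 1.0  # sits at the margin
        assert np.array_equal(model.W, W0)
        assert all(np.array_equal(a, b) for a, b in zip(cents._cols, C0))

    def test_gradient_matches_finite_differences(self):
        checked, seed = 0, 0
        while checked < 5:
            seed += 1
            rng, features, model, la, lb, cents = self._instance(100 + seed)
            F = features.matrix.toarray()
            own = sorted({cents.index[la.fold], cents.index[la.superfamily]})
            oth = sorted({cents.index[lb.fold], cents.index[lb.superfamily]})
            phi = model.W @ F[0]
            cy = sum(cents._cols[j] for j in own)
            cy2 = sum(cents._cols[j] for j in oth)
            loss = 1.0 + np.abs(phi - cy).sum() - np.abs(phi - cy2).sum()
            if loss < 1e-3 or np.abs(phi - cy).min() < 1e-3 or np.abs(phi - cy2).min() < 1e-3:
                continue
            W0 = model.W.copy()
            C0 = np.column_stack(cents._cols)
            class_task_step(model, 0, la, 1, lb, features, cents, lr=1.0, margin=1.0)
            ana_W = W0 - model.W
            ana_C = C0 - np.column_stack(cents._cols)
            W = W0.copy()
            Cm = C0.copy()
            cols = lambda: [Cm[:, j] for j in range(Cm.shape[1])]
            num_W = fd_grad(lambda: _two_hot_loss(W, cols(), F[0], own, oth, 1.0), W)
            num_C = fd_grad(lambda: _two_hot_loss(W0, cols(), F[0], own, oth, 1.0), Cm)
            for ana, num in ((ana_W, num_W), (ana_C, num_C)):
                denom = max(np.linalg.norm(num), 1.0)
                assert np.linalg.norm(ana - num) / denom < 1e-4
            checked += 1

    def test_classes_separate_after_training(self):
        # two well-separated synthetic classes (block features): 200 seeded
        # steps leave members closer to their own class centroid than to the
        # other class's centroid
        import scipy.sparse as sp

        from protembed.io import SparseFeatureMatrix

        rng = np.random.default_rng(11)
        n, d = 12, 4
        block = np.zeros((n, n))
        block[:6, :6] = rng.random((6, 6))
        block[6:, 6:] = rng.random((6, 6))
        features = SparseFeatureMatrix(
            sp.csr_matrix(block), [f"p{i}" for i in range(n)], 100.0, False
        )
        model = EmbeddingModel(rng.standard_normal((d, n)), features.ids)
        labels = [
            AuxiliaryLabel(f"p{i}", f"f{i // 6}", f"f{i // 6}.0", f"f{i // 6}.0.0")
            for i in range(n)
        ]
        cents = CentroidSet(d, rng)
        for lab in labels:
            cents.column(lab.fold)
            cents.column(lab.superfamily)
        for _ in range(200):
            i, j = rng.integers(n, size=2)
            class_task_step(model, int(i), labels[i], int(j), labels[j],
                            features, cents, lr=0.05, margin=1.0)
        F = features.matrix.toarray()
        pts = F @ model.W.T
        C = np.column_stack(cents._cols)
        centroid_of = [
            C[:, cents.index[lab.fold]] + C[:, cents.index[lab.superfamily]]
            for lab in labels
        ]
        own = np.mean([np.abs(pts[i] - centroid_of[i]).sum() for i in range(n)])
        other = np.mean(
            [np.abs(pts[i] - centroid_of[(i + 6) % n]).sum() for i in range(n)]
        )
        assert own < other


class TestAuxiliaryRanking:
    def test_struct_cutoff_strict(self):
        from protembed.training import StructuralPair

        pairs = [StructuralPair("a", "b", 2.5), StructuralPair("a", "c", 1.0),
                 StructuralPair("b", "c", 2.0)]  # exactly 2.0: excluded
        idx = auxiliary_positive_index(["a", "b", "c"], struct_pairs=pairs, cutoff=2.0)
        assert {k: list(v) for k, v in idx.items()} == {0: [1], 1: [0]}

    def test_label_mode_symmetric(self):
        labels = [AuxiliaryLabel("a", "f0", "f0.0", "f0.0.0"),
                  AuxiliaryLabel("b", "f0", "f0.0", "f0.0.1"),
                  AuxiliaryLabel("c", "f1", "f1.0", "f1.0.0")]
        idx = auxiliary_positive_index(["a", "b", "c"], labels=labels)
        assert {k: list(v) for k, v in idx.items()} == {0: [1], 1: [0]}
        rng = np.random.default_rng(0)
        gen = auxiliary_ranking_tuples(["a", "b", "c"], rng, labels=labels)
        tuples = [next(gen) for _ in range(100)]
        assert {(0, 1), (1, 0)} <= {(t.q, t.pos) for t in tuples}

    def test_no_qualifying_pairs(self):
        from protembed.training import StructuralPair

        with pytest.raises(ValueError, match="no qualifying"):
            auxiliary_positive_index(
                ["a", "b"], struct_pairs=[StructuralPair("a", "b", 1.0)], cutoff=2.0
            )


class TestTrain:
    def _features_hits(self, seed=0, n=12):
        rng = np.random.default_rng(seed)
        features = random_sparse_features(rng, n)
        hits = [PairwiseHit(f"p{i}", f"p{(i + 1) % n}", 0.01) for i in range(n)]
        return features, hits

    def test_epochs_zero_returns_initialization(self):
        features, hits = self._features_hits()
        cfg = TrainConfig(d=3, epochs=0, tuples_per_epoch=10, seed=42)
        model, log = train(features, hits, cfg)
        expected = np.random.default_rng(42).standard_normal((3, features.n))
        assert np.array_equal(model.W, expected)
        assert len(log) == 0

    def test_same_seed_bitwise_identical(self):
        features, hits = self._features_hits()
        cfg = TrainConfig(d=3, epochs=3, tuples_per_epoch=50, seed=7)
        m1, log1 = train(features, hits, cfg)
        m2, log2 = train(features, hits, cfg)
        assert m1.W.tobytes() == m2.W.tobytes()
        assert log1.equals(log2)

    def test_loss_decreases_smoothed(self, trained):
        # epoch losses on the benchmark fixture: after window-5 smoothing the
        # trace never rises by more than 5%
        loss = trained.training_log["mean_loss"].to_numpy()
        smooth = np.convolve(loss, np.ones(5) / 5, mode="valid")
        assert np.all(np.diff(smooth) <= 0.05 * smooth[:-1])
        assert smooth[-1] < smooth[0]

    def test_labels_file_dotted_derivation(self):
        text = "id\tfamily\nd1\td.15.6.1\n"
        labs = read_labels(io.StringIO(text))
        assert labs[0] == AuxiliaryLabel("d1", "d.15", "d.15.6", "d.15.6.1")

    def test_config_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(lr=0.0)
        with pytest.raises(ValueError):
            TrainConfig(aux_mode="bogus")
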