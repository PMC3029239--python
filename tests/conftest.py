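"""Shared fixtures: the default synthetic benchmark and one trained model.

Expensive objects (the trained embedding, the null calibration) are
session-scoped so evaluation, calibration and acceptance tests reuse them.
"""

from __future__ import annotations

import numpy as np
import pytest

from protembed import calibration as cal
from protembed.evaluation import label_targets, roc_n
from protembed.fixtures import SyntheticTeacher, generate_fixture, holdout_split
from protembed.model import ProtEmbed


@pytest.fixture(scope="session")
def fixture():
    return generate_fixture()


@pytest.fixture(scope="session")
def split(fixture):
    return holdout_split(fixture, 20, seed=1)


@pytest.fixture(scope="session")
def teacher(fixture):
    return SyntheticTeacher(fixture)


@pytest.fixture(scope="session")
def labels_map(fixture):
    return {l.id: l for l in fixture.labels}


@pytest.fixture(scope="session")
def model_obj(fixture, split):
    train_ids, _ = split
    return ProtEmbed.from_fixture(fixture, train_ids)


@pytest.fixture(scope="session")
def trained(model_obj):
    """The reference fit: d=10, lr=0.05, margin=1, 30 epochs x 2000 tuples."""
    return model_obj.fit(d=10, lr=0.05, margin=1.0, epochs=30,
                         tuples_per_epoch=2000, seed=1)


@pytest.fixture(scope="session")
def untrained(model_obj):
    """The random initialization (epochs=0) with the same seed."""
    return model_obj.fit(d=10, lr=0.05, margin=1.0, epochs=0,
                         tuples_per_epoch=2000, seed=1)


@pytest.fixture(scope="session")
def null_model(fixture):
    return cal.fit_markov(fixture.sequences, seed=0)


@pytest.fixture(scope="session")
def calibrated(trained, null_model, teacher):
    lo = min(s.length for s in teacher.fixture.sequences)
    hi = max(s.length for s in teacher.fixture.sequences)
    trained.calibrate(
        null_model,
        lambda decoys: teacher.score_queries(decoys, trained.embedding.ids),
        (lo, hi),
        n_decoys_per_bin=1000,
        tail_fraction=0.25,
        seed=3,
    )
    return trained


def random_sparse_features(rng, n, density=0.5):
    """A random n x n sparse feature matrix with weights in (0, 1]."""
    import scipy.sparse as sp

    from protembed.io import SparseFeatureMatrix

    dense = np.where(rng.random((n, n)) < density, rng.random((n, n)), 0.0)
    dense[dense > 0] = np.maximum(dense[dense > 0], 0.05)
    return SparseFeatureMatrix(sp.csr_matrix(dense), [f"p{i}" for i in range(n)],
                               sigma=100.0, normalized=False)


def ranking_loss_oracle(W, features, t, margin):
    """Independent dense computation of the tuple hinge (1-norm distances)."""
    F = features.matrix.toarray()
    phi = lambda i: W @ F[i]
    d_pos = np.abs(phi(t.q) - phi(t.pos)).sum()
    d_neg = np.abs(phi(t.q) - phi(t.neg)).sum()
    return max(0.0, margin - d_neg + d_pos)


def fd_grad(loss_fn, X, h=1e-6):
    """Central finite-difference gradient of loss_fn at matrix X."""
    g = np.zeros_like(X)
    it = np.nditer(X, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        orig = X[idx]
        X[idx] = orig + h
        up = loss_fn()
        X[idx] = orig - h
        down = loss_fn()
        X[idx] = orig
        g[idx] = (up - down) / (2 * h)
    return g


def away_from_kinks(W, features, t, margin, min_gap=1e-3):
    """True when the hinge is active and no 1-norm component is near its
    sign discontinuity, so the loss is differentiable at W."""
    F = features.matrix.toarray()
    z_pos = W @ (F[t.q] - F[t.pos])
    z_neg = W @ (F[t.q] - F[t.neg])
    loss = margin - np.abs(z_neg).sum() + np.abs(z_pos).sum()
    return (
        loss > min_gap
        and np.abs(z_pos).min() > min_gap
        and np.abs(z_neg).min() > min_gap
    )


def heldout_roc1_scores(results, fixture, teacher, test_ids, labels_map,
                        exclude_family=False):
    """Per-query held-out ROC1 of a fitted embedding (None scores dropped)."""
    train_ids = results.embedding.ids
    scores = []
    for qid in test_ids:
        hits = teacher.score_queries([qid], train_ids)
        qf = results.query_features(hits, qid)
        ranking = results.rank(qf, qid)
        classes = label_targets(
            labels_map[qid], [labels_map[t] for t in ranking.target_ids],
            exclude_family=exclude_family,
        )
        score = roc_n(classes, n_cap=1)
        if score is not None:
            scores.append(score.value)
    return np.array(scores)
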