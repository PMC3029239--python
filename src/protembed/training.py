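"""Learning the embedding by stochastic gradient descent on a margin ranking loss.

The teacher's all-vs-all search supplies a noisy training signal: for a
query q, any target with E-value strictly below a threshold (default 0.1)
is taken as a positive p+, while p- is drawn uniformly from the whole
database and is with high probability unrelated.  Each tuple (q, p+, p-)
incurs the hinge

    loss = max(0, margin - D(q, p-) + D(q, p+))

with D the p-norm distance between embedded points, and a violated tuple
triggers a subgradient step on the projection W (for p = 1 the subgradient
is the componentwise sign).  Structural side information enters as a
multitask objective: either a class-centroid task over fold/superfamily
categories (updating W and a centroid matrix C), or extra ranking tuples
whose positives are same-superfamily pairs or structure-alignment pairs
scoring strictly above a cutoff (default 2.0).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .embedding import EmbeddingModel
from .io import PairwiseHit, SparseFeatureMatrix

__all__ = [
    "TrainingTuple",
    "AuxiliaryLabel",
    "StructuralPair",
    "TrainConfig",
    "read_labels",
    "read_structural_scores",
    "build_positive_index",
    "sample_tuple",
    "tuple_margin_loss",
    "sgd_step",
    "class_task_step",
    "auxiliary_positive_index",
    "auxiliary_ranking_tuples",
    "train",
]


@dataclass(frozen=True)
class TrainingTuple:
    """Indices (query, positive, negative) driving one SGD step."""

    q: int
    pos: int
    neg: int


@dataclass(frozen=True)
class AuxiliaryLabel:
    """Structural category labels for one protein (SCOP-style hierarchy)."""

    id: str
    fold: str
    superfamily: str
    family: str

    @classmethod
    def from_family(cls, pid: str, family: str) -> "AuxiliaryLabel":
        """Derive fold and superfamily from a dotted family id,
        e.g. 'd.15.6.1' -> fold 'd.15', superfamily 'd.15.6'."""
        parts = family.split(".")
        if len(parts) < 3:
            raise ValueError(f"family id {family!r} has no dotted hierarchy")
        return cls(
            id=pid,
            fold=".".join(parts[:2]),
            superfamily=".".join(parts[:3]),
            family=family,
        )


@dataclass(frozen=True)
class StructuralPair:
    """A pairwise structure-alignment similarity score; (a,b) == (b,a)."""

    id_a: str
    id_b: str
    score: float


@dataclass
class TrainConfig:
    """Hyperparameters of one training run.

    Defaults follow the cross-validated values for a PSI-BLAST-style
    teacher (d=250, lr=0.05, 150 epochs of 20,000 tuples); an HMM-HMM
    style teacher works better with d=100, lr=0.02.  The margin is 1 by
    the usual margin-ranking convention (the loss scale is coupled to lr).
    """

    d: int = 250
    lr: float = 0.05
    margin: float = 1.0
    p: float = 1.0
    epochs: int = 150
    tuples_per_epoch: int = 20_000
    pos_evalue_threshold: float = 0.1
    struct_cutoff: float = 2.0
    seed: int = 0
    aux_mode: str = "none"  # none | class | rank_scop | rank_struct
    aux_mix: int = 1  # auxiliary draws per main draw when aux_mode != none

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")
        if self.margin <= 0:
            raise ValueError("margin must be positive")
        if self.epochs < 0:
            raise ValueError("epochs must be non-negative")
        if self.aux_mode not in ("none", "class", "rank_scop", "rank_struct"):
            raise ValueError(f"unknown aux_mode {self.aux_mode!r}")

    def to_dict(self) -> dict:
        return asdict(self)


def read_labels(source) -> list[AuxiliaryLabel]:
    """Read a labels TSV: either (id, fold, superfamily, family) or
    (id, family) with the hierarchy derived from the dotted family id."""
    df = pd.read_csv(source, sep="\t", dtype=str, comment="#")
    cols = [c.lower() for c in df.columns]
    df.columns = cols
    if {"id", "fold", "superfamily", "family"} <= set(cols):
        return [
            AuxiliaryLabel(r["id"], r["fold"], r["superfamily"], r["family"])
            for _, r in df.iterrows()
        ]
    if {"id", "family"} <= set(cols):
        return [AuxiliaryLabel.from_family(r["id"], r["family"]) for _, r in df.iterrows()]
    raise ValueError("labels file needs columns (id, fold, superfamily, family) or (id, family)")


def read_structural_scores(source) -> list[StructuralPair]:
    """Read structure-alignment scores from a 3-column TSV (id_a, id_b, score)."""
    df = pd.read_csv(
        source, sep="\t", header=None, names=["id_a", "id_b", "score"], comment="#",
        dtype={"id_a": str, "id_b": str, "score": float},
    )
    return [StructuralPair(r.id_a, r.id_b, float(r.score)) for r in df.itertuples()]


def build_positive_index(
    hits: Iterable[PairwiseHit],
    ids: Sequence[str],
    threshold: float = 0.1,
) -> dict[int, np.ndarray]:
    """Map each query index to the array of its positive target indices.

    A target is positive when the teacher E-value is *strictly* below the
    threshold and the target is not the query itself.  Queries with no
    positives are absent from the map.
    """
    index = {pid: i for i, pid in enumerate(ids)}
    pos: dict[int, set[int]] = {}
    for h in hits:
        if h.evalue < threshold:
            qi, ti = index[h.query_id], index[h.target_id]
            if qi != ti:
                pos.setdefault(qi, set()).add(ti)
    return {q: np.array(sorted(s), dtype=np.int64) for q, s in sorted(pos.items())}


def sample_tuple(
    pos_index: dict[int, np.ndarray],
    n_db: int,
    rng: np.random.Generator,
    queries: np.ndarray | None = None,
) -> TrainingTuple:
    """Draw one training tuple: q uniform over queries with positives, p+
    uniform over q's positives, p- uniform over the whole database
    (resampled in the degenerate cases p- == q or p- == p+)."""
    if not pos_index:
        raise ValueError("no training signal: no query has a positive")
    if queries is None:
        queries = np.fromiter(pos_index.keys(), dtype=np.int64)
    q = int(queries[rng.integers(len(queries))])
    positives = pos_index[q]
    pos = int(positives[rng.integers(len(positives))])
    while True:
        neg = int(rng.integers(n_db))
        if neg != q and neg != pos:
            return TrainingTuple(q, pos, neg)


class _SparseRows:
    """CSR row accessor giving (column indices, values) per protein."""

    def __init__(self, features: SparseFeatureMatrix):
        m = features.matrix
        self.indptr = m.indptr
        self.indices = m.indices
        self.data = m.data

    def row(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        a, b = self.indptr[i], self.indptr[i + 1]
        return self.indices[a:b], self.data[a:b]


def _phi(W: np.ndarray, idx: np.ndarray, val: np.ndarray) -> np.ndarray:
    if len(idx) == 0:
        return np.zeros(W.shape[0])
    return W[:, idx] @ val


def _dist_grad(z: np.ndarray, p: float) -> tuple[float, np.ndarray]:
    """p-norm of z and the (sub)gradient of the norm w.r.t. z."""
    if p == 1.0:
        return float(np.abs(z).sum()), np.sign(z)
    D = float(np.linalg.norm(z, ord=p))
    if D == 0.0:
        return 0.0, np.zeros_like(z)
    return D, np.sign(z) * np.abs(z) ** (p - 1.0) / D ** (p - 1.0)


def tuple_margin_loss(
    model: EmbeddingModel,
    t: TrainingTuple,
    features: SparseFeatureMatrix,
    margin: float = 1.0,
    p: float = 1.0,
) -> float:
    """Hinge loss of one tuple: max(0, margin - D(q, neg) + D(q, pos))."""
    rows = _SparseRows(features)
    W = model.W
    phi_q = _phi(W, *rows.row(t.q))
    phi_p = _phi(W, *rows.row(t.pos))
    phi_n = _phi(W, *rows.row(t.neg))
    d_pos, _ = _dist_grad(phi_q - phi_p, p)
    d_neg, _ = _dist_grad(phi_q - phi_n, p)
    return max(0.0, margin - d_neg + d_pos)


def sgd_step(
    model: EmbeddingModel,
    t: TrainingTuple,
    features: SparseFeatureMatrix,
    lr: float,
    margin: float = 1.0,
    p: float = 1.0,
    _rows: _SparseRows | None = None,
) -> float:
    """One in-place subgradient step on W for a tuple; returns the pre-step loss.

    If the margin constraint already holds (loss = 0) the model is untouched.
    The update exploits sparsity: only the feature-support columns of W move.
    """
    rows = _rows if _rows is not None else _SparseRows(features)
    W = model.W
    iq, vq = rows.row(t.q)
    ip, vp = rows.row(t.pos)
    iN, vN = rows.row(t.neg)
    phi_q = _phi(W, iq, vq)
    phi_p = _phi(W, ip, vp)
    phi_n = _phi(W, iN, vN)
    d_pos, g_pos = _dist_grad(phi_q - phi_p, p)
    d_neg, g_neg = _dist_grad(phi_q - phi_n, p)
    loss = margin - d_neg + d_pos
    if loss <= 0.0:
        return 0.0
    # dL/dW = g_pos (f_q - f_pos)^T - g_neg (f_q - f_neg)^T
    if len(iq):
        W[:, iq] -= lr * np.outer(g_pos - g_neg, vq)
    if len(ip):
        W[:, ip] += lr * np.outer(g_pos, vp)
    if len(iN):
        W[:, iN] -= lr * np.outer(g_neg, vN)
    return float(loss)


class CentroidSet:
    """Lazily allocated class-centroid columns, one per category label."""

    def __init__(self, d: int, rng: np.random.Generator):
        self.d = d
        self._rng = rng
        self.index: dict[str, int] = {}
        self._cols: list[np.ndarray] = []

    def column(self, label: str) -> int:
        if label not in self.index:
            self.index[label] = len(self._cols)
            self._cols.append(self._rng.standard_normal(self.d))
        return self.index[label]

    @property
    def C(self) -> np.ndarray | None:
        if not self._cols:
            return None
        return np.column_stack(self._cols)

    def set_matrix(self, C: np.ndarray) -> None:
        self._cols = [C[:, j].copy() for j in range(C.shape[1])]


def class_task_step(
    model: EmbeddingModel,
    x: int,
    x_label: AuxiliaryLabel,
    x2: int,
    x2_label: AuxiliaryLabel,
    features: SparseFeatureMatrix,
    centroids: CentroidSet,
    lr: float,
    margin: float = 1.0,
    p: float = 1.0,
    _rows: _SparseRows | None = None,
) -> float:
    """One multitask step on the class-centroid hinge, updating W and C.

    The category of a labeled protein is encoded as a 2-hot bit vector over
    fold and superfamily columns of C, so its centroid is the sum of those
    two columns.  The hinge pushes phi(x) toward its own centroid and away
    from the centroid of the other example's categories:

        loss = max(0, margin + D(phi(x), C y(x)) - D(phi(x), C y(x')))

    When both examples share fold and superfamily the two distance terms
    coincide and the step is a no-op (the loss sits at the margin but its
    subgradient cancels exactly).  Returns the pre-step loss.
    """
    cols_own = sorted({centroids.column(x_label.fold), centroids.column(x_label.superfamily)})
    cols_oth = sorted({centroids.column(x2_label.fold), centroids.column(x2_label.superfamily)})
    rows = _rows if _rows is not None else _SparseRows(features)
    ix, vx = rows.row(x)
    phi = _phi(model.W, ix, vx)
    C = centroids._cols
    cy = sum(C[j] for j in cols_own)
    cy2 = sum(C[j] for j in cols_oth)
    d_own, g_own = _dist_grad(phi - cy, p)
    d_oth, g_oth = _dist_grad(phi - cy2, p)
    loss = margin + d_own - d_oth
    if cols_own == cols_oth or loss <= 0.0:
        return float(max(0.0, loss)) if cols_own != cols_oth else float(margin)
    if len(ix):
        model.W[:, ix] -= lr * np.outer(g_own - g_oth, vx)
    for j in cols_own:
        C[j] += lr * g_own
    for j in cols_oth:
        C[j] -= lr * g_oth
    return float(loss)


def auxiliary_positive_index(
    ids: Sequence[str],
    labels: Sequence[AuxiliaryLabel] | None = None,
    struct_pairs: Sequence[StructuralPair] | None = None,
    cutoff: float = 2.0,
) -> dict[int, np.ndarray]:
    """Positive index for the auxiliary ranking task.

    Label mode: positives are same-superfamily pairs.  Structure mode:
    positives are pairs scoring *strictly* above the cutoff, treated
    symmetrically.  Exactly one of `labels` / `struct_pairs` must be given.
    """
    if (labels is None) == (struct_pairs is None):
        raise ValueError("give exactly one of labels or struct_pairs")
    index = {pid: i for i, pid in enumerate(ids)}
    pos: dict[int, set[int]] = {}
    if labels is not None:
        by_sf: dict[str, list[int]] = {}
        for lab in labels:
            if lab.id in index:
                by_sf.setdefault(lab.superfamily, []).append(index[lab.id])
        for members in by_sf.values():
            for a in members:
                for b in members:
                    if a != b:
                        pos.setdefault(a, set()).add(b)
    else:
        for pair in struct_pairs:
            if pair.score > cutoff and pair.id_a in index and pair.id_b in index:
                a, b = index[pair.id_a], index[pair.id_b]
                if a != b:
                    pos.setdefault(a, set()).add(b)
                    pos.setdefault(b, set()).add(a)
    result = {q: np.array(sorted(s), dtype=np.int64) for q, s in sorted(pos.items())}
    if not result:
        raise ValueError("no qualifying auxiliary pairs")
    return result


def auxiliary_ranking_tuples(
    ids: Sequence[str],
    rng: np.random.Generator,
    labels: Sequence[AuxiliaryLabel] | None = None,
    struct_pairs: Sequence[StructuralPair] | None = None,
    cutoff: float = 2.0,
) -> Iterator[TrainingTuple]:
    """Endless stream of auxiliary ranking tuples (see auxiliary_positive_index)."""
    pos_index = auxiliary_positive_index(ids, labels, struct_pairs, cutoff)
    queries = np.fromiter(pos_index.keys(), dtype=np.int64)
    while True:
        yield sample_tuple(pos_index, len(ids), rng, queries)


def train(
    features: SparseFeatureMatrix,
    hits: Iterable[PairwiseHit],
    config: TrainConfig,
    labels: Sequence[AuxiliaryLabel] | None = None,
    struct_pairs: Sequence[StructuralPair] | None = None,
) -> tuple[EmbeddingModel, pd.DataFrame]:
    """Train the embedding; returns the model and a per-epoch training log.

    W (and any centroid columns) are initialized i.i.d. N(0, 1) from
    config.seed, so identical (seed, config, inputs) give bit-identical
    models.  With an auxiliary mode, main and auxiliary draws are
    interleaved `aux_mix` auxiliary steps per main step; an epoch is
    config.tuples_per_epoch main-task tuples either way.  The log columns
    are (epoch, mean_loss, violations[, mean_aux_loss]).
    """
    rng = np.random.default_rng(config.seed)
    n = features.n
    W = rng.standard_normal((config.d, n))
    model = EmbeddingModel(W, features.ids, config.to_dict())
    rows = _SparseRows(features)

    pos_index = build_positive_index(hits, features.ids, config.pos_evalue_threshold)
    if not pos_index:
        raise ValueError("no training signal: no pair is below the positive threshold")
    queries = np.fromiter(pos_index.keys(), dtype=np.int64)

    aux = config.aux_mode
    centroids: CentroidSet | None = None
    aux_pos_index = None
    aux_queries = None
    labeled_idx = None
    label_by_idx: dict[int, AuxiliaryLabel] = {}
    if aux == "class":
        if not labels:
            raise ValueError("aux_mode 'class' needs labels")
        centroids = CentroidSet(config.d, rng)
        id_index = {pid: i for i, pid in enumerate(features.ids)}
        for lab in sorted(labels, key=lambda l: l.id):
            if lab.id in id_index:
                label_by_idx[id_index[lab.id]] = lab
                # deterministic pre-allocation in sorted label order
                centroids.column(lab.fold)
                centroids.column(lab.superfamily)
        labeled_idx = np.array(sorted(label_by_idx), dtype=np.int64)
        if len(labeled_idx) < 2:
            raise ValueError("aux_mode 'class' needs at least two labeled proteins")
    elif aux == "rank_scop":
        aux_pos_index = auxiliary_positive_index(features.ids, labels=labels)
        aux_queries = np.fromiter(aux_pos_index.keys(), dtype=np.int64)
    elif aux == "rank_struct":
        aux_pos_index = auxiliary_positive_index(
            features.ids, struct_pairs=struct_pairs, cutoff=config.struct_cutoff
        )
        aux_queries = np.fromiter(aux_pos_index.keys(), dtype=np.int64)

    log_rows = []
    for epoch in range(config.epochs):
        total = 0.0
        violations = 0
        aux_total = 0.0
        aux_steps = 0
        for _ in range(config.tuples_per_epoch):
            t = sample_tuple(pos_index, n, rng, queries)
            loss = sgd_step(
                model, t, features, config.lr, config.margin, config.p, _rows=rows
            )
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}; lower the learning rate"
                )
            total += loss
            violations += loss > 0.0
            if aux == "none":
                continue
            for _k in range(config.aux_mix):
                if aux == "class":
                    i, j = labeled_idx[rng.integers(len(labeled_idx), size=2)]
                    aux_loss = class_task_step(
                        model, int(i), label_by_idx[int(i)], int(j), label_by_idx[int(j)],
                        features, centroids, config.lr, config.margin, config.p, _rows=rows,
                    )
                else:
                    ta = sample_tuple(aux_pos_index, n, rng, aux_queries)
                    aux_loss = sgd_step(
                        model, ta, features, config.lr, config.margin, config.p, _rows=rows
                    )
                aux_total += aux_loss
                aux_steps += 1
        row = {
            "epoch": epoch,
            "mean_loss": total / max(config.tuples_per_epoch, 1),
            "violations": violations,
        }
        if aux_steps:
            row["mean_aux_loss"] = aux_total / aux_steps
        log_rows.append(row)

    if centroids is not None and centroids.C is not None:
        model.C = centroids.C
        model.centroid_index = dict(centroids.index)
    log = pd.DataFrame(log_rows, columns=["epoch", "mean_loss", "violations"]
                       + (["mean_aux_loss"] if aux == "class" or aux.startswith("rank") else []))
    return model, log
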