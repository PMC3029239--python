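"""The learned linear embedding, distances in embedding space, and retrieval.

A protein's sparse n-dimensional similarity profile f(x) is projected to a
d-dimensional point phi(x) = W f(x).  Retrieval is an explicit linear scan:
database points are ranked by ascending p-norm distance to the embedded
query (default p = 1, whose subgradient is the componentwise sign used by
the training update).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp

__all__ = ["EmbeddingModel", "EmbeddedPoint", "RankedResult", "embed", "distance", "rank_database"]


@dataclass(frozen=True)
class EmbeddedPoint:
    """A point in the d-dimensional embedding space."""

    coords: np.ndarray
    source_id: str | None = None

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=np.float64)
        if not np.all(np.isfinite(coords)):
            raise ValueError("embedded point has non-finite coordinates")
        object.__setattr__(self, "coords", coords)


@dataclass
class RankedResult:
    """A database ranking for one query, ascending by embedding distance.

    ``entries`` is a list of (target_id, distance, rank) with rank starting
    at 1; optional significance columns are parallel lists.
    """

    query_id: str
    entries: list[tuple[str, float, int]]
    pvalues: list[float] | None = None
    qvalues: list[float] | None = None

    @property
    def target_ids(self) -> list[str]:
        return [t for t, _, _ in self.entries]

    @property
    def distances(self) -> np.ndarray:
        return np.array([d for _, d, _ in self.entries])

    def to_tsv(self, dest) -> None:
        close = False
        if isinstance(dest, (str, bytes)) or hasattr(dest, "__fspath__"):
            dest = open(dest, "w")
            close = True
        try:
            cols = ["rank", "target_id", "distance"]
            if self.pvalues is not None:
                cols.append("p_value")
            if self.qvalues is not None:
                cols.append("q_value")
            dest.write("\t".join(cols) + "\n")
            for k, (t, d, r) in enumerate(self.entries):
                row = [str(r), t, f"{d:.8g}"]
                if self.pvalues is not None:
                    row.append(f"{self.pvalues[k]:.6g}")
                if self.qvalues is not None:
                    row.append(f"{self.qvalues[k]:.6g}")
                dest.write("\t".join(row) + "\n")
        finally:
            if close:
                dest.close()


class EmbeddingModel:
    """The learned projection W (and optional class centroids C).

    Parameters
    ----------
    W : (d, n) array
        Linear map from the n-dimensional teacher-similarity feature space
        to the d-dimensional embedding space.
    ids : sequence of str
        The n database identifiers defining the feature-space axes.
    config : dict
        Training hyperparameters and provenance (sigma, d, lr, margin,
        p-norm order, epochs, tuples per epoch, seed, ...).
    C : (d, n_classes) array, optional
        Class-centroid columns learned by the auxiliary classification task.
    centroid_index : dict, optional
        Maps category label -> column of C.
    """

    def __init__(
        self,
        W: np.ndarray,
        ids: Sequence[str],
        config: dict | None = None,
        C: np.ndarray | None = None,
        centroid_index: dict[str, int] | None = None,
    ):
        W = np.asarray(W, dtype=np.float64)
        if W.ndim != 2:
            raise ValueError("W must be a 2-D matrix")
        if W.shape[1] != len(ids):
            raise ValueError(
                f"W has {W.shape[1]} columns but {len(ids)} ids were given"
            )
        if W.shape[0] < 1:
            raise ValueError("embedding dimension must be at least 1")
        self.W = W
        self.ids = list(ids)
        self.config = dict(config or {})
        self.C = None if C is None else np.asarray(C, dtype=np.float64)
        self.centroid_index = dict(centroid_index or {})
        if self.C is not None and self.C.shape[0] != W.shape[0]:
            raise ValueError("C must have the same number of rows as W")

    @property
    def d(self) -> int:
        return self.W.shape[0]

    @property
    def n(self) -> int:
        return self.W.shape[1]

    @property
    def p(self) -> float:
        return float(self.config.get("p", 1.0))

    def save(self, path) -> None:
        payload = {
            "W": self.W,
            "ids": np.frombuffer(json.dumps(self.ids).encode(), dtype=np.uint8),
            "config": np.frombuffer(json.dumps(self.config).encode(), dtype=np.uint8),
        }
        if self.C is not None:
            payload["C"] = self.C
            payload["centroid_index"] = np.frombuffer(
                json.dumps(self.centroid_index).encode(), dtype=np.uint8
            )
        np.savez(path, **payload)

    @classmethod
    def load(cls, path) -> "EmbeddingModel":
        with np.load(path) as z:
            config = json.loads(bytes(z["config"]).decode())
            ids = json.loads(bytes(z["ids"]).decode())
            C = z["C"] if "C" in z.files else None
            cindex = (
                json.loads(bytes(z["centroid_index"]).decode())
                if "centroid_index" in z.files
                else None
            )
            return cls(z["W"], ids, config, C, cindex)


def embed(model: EmbeddingModel, feature_vector, source_id: str | None = None) -> EmbeddedPoint:
    """Project a feature vector into the embedding space: phi(x) = W f(x).

    Accepts a dense 1-D array or a sparse 1-row matrix; the sparse path
    costs O(nnz * d).
    """
    if sp.issparse(feature_vector):
        fv = feature_vector.tocsr()
        if fv.shape != (1, model.n):
            raise ValueError(
                f"feature vector has shape {fv.shape}, expected (1, {model.n})"
            )
        if fv.nnz == 0:
            coords = np.zeros(model.d)
        else:
            coords = model.W[:, fv.indices] @ fv.data
    else:
        fv = np.asarray(feature_vector, dtype=np.float64).ravel()
        if fv.shape[0] != model.n:
            raise ValueError(
                f"feature vector has length {fv.shape[0]}, expected {model.n}"
            )
        coords = model.W @ fv
    return EmbeddedPoint(coords, source_id)


def embed_all(model: EmbeddingModel, features) -> np.ndarray:
    """Project every row of a (m, n) sparse/dense feature matrix: returns (m, d)."""
    m = features.matrix if hasattr(features, "matrix") else features
    if sp.issparse(m):
        return np.asarray(m @ model.W.T)
    return np.asarray(m) @ model.W.T


def distance(a, b, p: float = 1.0) -> float:
    """p-norm distance between two embedded points (p >= 1)."""
    ca = a.coords if isinstance(a, EmbeddedPoint) else np.asarray(a, dtype=np.float64)
    cb = b.coords if isinstance(b, EmbeddedPoint) else np.asarray(b, dtype=np.float64)
    if ca.shape != cb.shape:
        raise ValueError(f"dimension mismatch: {ca.shape} vs {cb.shape}")
    if p < 1:
        raise ValueError(f"p must be >= 1, got {p}")
    return float(np.linalg.norm(ca - cb, ord=p))


def rank_database(
    query_point: EmbeddedPoint,
    db_points: np.ndarray,
    db_ids: Sequence[str],
    p: float = 1.0,
    query_id: str = "query",
) -> RankedResult:
    """Rank database points by ascending p-norm distance to the query.

    Ties are broken by ascending lexicographic target id so rankings are
    run-to-run identical.  An empty database yields an empty result.
    """
    db_points = np.asarray(db_points, dtype=np.float64)
    db_ids = list(db_ids)
    if db_points.shape[0] != len(db_ids):
        raise ValueError("db_points row count must equal number of db_ids")
    if len(db_ids) == 0:
        return RankedResult(query_id, [])
    if db_points.shape[1] != query_point.coords.shape[0]:
        raise ValueError("query and database dimensions differ")
    diffs = db_points - query_point.coords[None, :]
    if p == 1.0:
        dists = np.abs(diffs).sum(axis=1)
    elif p == 2.0:
        dists = np.sqrt((diffs**2).sum(axis=1))
    else:
        dists = (np.abs(diffs) ** p).sum(axis=1) ** (1.0 / p)
    order = sorted(range(len(db_ids)), key=lambda i: (dists[i], db_ids[i]))
    entries = [(db_ids[i], float(dists[i]), r + 1) for r, i in enumerate(order)]
    return RankedResult(query_id, entries)
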