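"""2D neighborhood maps of a query and its significant hits.

Classical (Torgerson) multidimensional scaling projects the pairwise
distances among the query and its hits into the plane; distances can be
measured either in the initial teacher-similarity feature space (the
state before any training) or in the learned embedding space, which is
how the effect of training on a single query is visualized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .embedding import EmbeddingModel, RankedResult

__all__ = ["NeighborhoodMap", "mds_project", "pairwise_pnorm", "neighborhood"]


def mds_project(distance_matrix: np.ndarray, n_components: int = 2) -> np.ndarray:
    """Classical MDS: double-center the squared distances and take the top
    eigendirections.

    Deterministic up to axis sign, which is fixed by making the largest-
    magnitude coordinate of each axis positive.  Exact for distances that
    are realizable in the plane; otherwise a least-squares projection.
    """
    D = np.asarray(distance_matrix, dtype=np.float64)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.diagonal(D) != 0) and not np.allclose(np.diagonal(D), 0, atol=1e-12):
        raise ValueError("distance matrix must have a zero diagonal")
    m = D.shape[0]
    J = np.eye(m) - np.full((m, m), 1.0 / m)
    B = -0.5 * J @ (D**2) @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1][:n_components]
    coords = np.zeros((m, n_components))
    for k, idx in enumerate(order):
        lam = evals[idx]
        if lam > 1e-12:
            axis = evecs[:, idx] * np.sqrt(lam)
            if axis[np.argmax(np.abs(axis))] < 0:
                axis = -axis
            coords[:, k] = axis
    return coords


def pairwise_pnorm(points: np.ndarray, p: float = 1.0) -> np.ndarray:
    """Symmetric matrix of p-norm distances between rows of `points`."""
    pts = np.asarray(points, dtype=np.float64)
    diffs = pts[:, None, :] - pts[None, :, :]
    if p == 1.0:
        return np.abs(diffs).sum(axis=2)
    return (np.abs(diffs) ** p).sum(axis=2) ** (1.0 / p)


@dataclass
class NeighborhoodMap:
    """2D map of a query and its included hits.

    `classes` carries a display label per point (e.g. same-family /
    same-superfamily / other); the query appears exactly once.
    """

    query_id: str
    ids: list[str]
    coords: np.ndarray
    classes: list[str]
    space: str
    q_threshold: float | None

    def to_tsv(self, dest) -> None:
        close = False
        if not hasattr(dest, "write"):
            dest = open(dest, "w")
            close = True
        try:
            dest.write("id\tx\ty\tclass\tis_query\n")
            for pid, (x, y), cls in zip(self.ids, self.coords, self.classes):
                dest.write(
                    f"{pid}\t{x:.8g}\t{y:.8g}\t{cls}\t{int(pid == self.query_id)}\n"
                )
        finally:
            if close:
                dest.close()

    def plot(self, path=None, ax=None):
        """Optional rendered scatter (cosmetics only; the TSV is canonical)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 6))
        palette = {}
        for pid, (x, y), cls in zip(self.ids, self.coords, self.classes):
            color = palette.setdefault(cls, f"C{len(palette) % 10}")
            if pid == self.query_id:
                ax.scatter([x], [y], c="black", s=90, marker="o", zorder=3, label="query")
            else:
                ax.scatter([x], [y], c=color, s=30, label=cls if cls not in palette or True else None)
        handles, labels = ax.get_legend_handles_labels()
        seen = {}
        for h, l in zip(handles, labels):
            seen.setdefault(l, h)
        ax.legend(seen.values(), seen.keys(), fontsize=8)
        ax.set_title(f"{self.query_id} ({self.space} space)")
        if path is not None:
            ax.figure.savefig(path, dpi=120)
        return ax


def neighborhood(
    model: EmbeddingModel,
    result: RankedResult,
    query_features,
    db_features,
    q_threshold: float | None = 0.01,
    space: str = "embedded",
    max_rank: int = 25,
    classes: dict[str, str] | None = None,
) -> NeighborhoodMap:
    """Build the MDS neighborhood map for one ranked query.

    Included points: the query plus every target with q-value at or below
    `q_threshold`; when the ranking carries no q-values (no calibration),
    the top `max_rank` targets are used instead.  Distances are computed
    in the requested space — `embedded` (learned projection) or `initial`
    (raw feature vectors) — then projected by classical MDS.  A threshold
    that admits nothing yields a singleton map of the query alone.
    """
    if space not in ("embedded", "initial"):
        raise ValueError("space must be 'embedded' or 'initial'")
    if q_threshold is not None and result.qvalues is not None:
        keep = [
            t for (t, _, _), q in zip(result.entries, result.qvalues) if q <= q_threshold
        ]
    else:
        keep = [t for t, _, _ in result.entries[:max_rank]]
    keep = [t for t in keep if t != result.query_id]
    ids = [result.query_id] + keep

    db_matrix = db_features.matrix if hasattr(db_features, "matrix") else db_features
    db_index = {pid: i for i, pid in enumerate(
        db_features.ids if hasattr(db_features, "ids") else model.ids
    )}
    qf = query_features
    if sp.issparse(qf):
        qf = np.asarray(qf.todense()).ravel()
    rows = [np.asarray(qf, dtype=np.float64).ravel()]
    for t in keep:
        r = db_matrix[db_index[t]]
        rows.append(np.asarray(r.todense()).ravel() if sp.issparse(r) else np.asarray(r).ravel())
    X = np.vstack(rows)
    if space == "embedded":
        X = X @ model.W.T
    D = pairwise_pnorm(X, model.p)
    coords = mds_project(D)
    cls = [
        "query" if pid == result.query_id else (classes or {}).get(pid, "hit")
        for pid in ids
    ]
    return NeighborhoodMap(result.query_id, ids, coords, cls, space, q_threshold)
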