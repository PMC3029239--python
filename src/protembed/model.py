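"""Model-object front end: build from data, fit, inspect, search.

`ProtEmbed` holds the training data (feature matrix, teacher hits,
optional structural side information); its `fit()` runs the stochastic
margin-ranking training and returns a `ProtEmbedResults` carrying the
learned projection, the per-epoch loss trace, precomputed database
coordinates, and methods for retrieval, calibration, evaluation and
visualization.

Typical use::

    fixture = generate_fixture()
    feats = build_feature_matrix(fixture.hits, fixture.ids)
    mod = ProtEmbed(feats, fixture.hits, labels=fixture.labels)
    res = mod.fit(d=10, epochs=30, tuples_per_epoch=2000, seed=1)
    print(res.summary())
    ranking = res.rank(query_features, query_id="q1")
"""

from __future__ import annotations

from dataclasses import replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import calibration as _cal
from . import training as _tr
from .embedding import EmbeddingModel, RankedResult, embed, embed_all, rank_database
from .io import PairwiseHit, SparseFeatureMatrix, build_feature_matrix
from .training import AuxiliaryLabel, StructuralPair, TrainConfig
from .viz import NeighborhoodMap, neighborhood

__all__ = ["ProtEmbed", "ProtEmbedResults"]


class ProtEmbed:
    """Semantic embedding model for remote homology detection.

    Parameters
    ----------
    features : SparseFeatureMatrix
        Database-by-database transformed teacher similarities.
    hits : iterable of PairwiseHit
        The teacher's all-vs-all E-values (training signal).
    labels : sequence of AuxiliaryLabel, optional
        Structural category labels for the class / label-ranking
        auxiliary tasks.
    struct_pairs : sequence of StructuralPair, optional
        Pairwise structure-alignment scores for the structure-ranking
        auxiliary task.
    """

    def __init__(
        self,
        features: SparseFeatureMatrix,
        hits: Iterable[PairwiseHit],
        labels: Sequence[AuxiliaryLabel] | None = None,
        struct_pairs: Sequence[StructuralPair] | None = None,
    ):
        self.features = features
        self.hits = list(hits)
        self.labels = list(labels) if labels is not None else None
        self.struct_pairs = list(struct_pairs) if struct_pairs is not None else None

    @classmethod
    def from_fixture(cls, fixture, ids: Sequence[str] | None = None,
                     sigma: float = 100.0, normalize: bool = True) -> "ProtEmbed":
        """Build the model from a synthetic fixture, optionally restricted
        to a subset of ids (e.g. a training split)."""
        ids = list(ids) if ids is not None else fixture.ids
        idset = set(ids)
        hits = [h for h in fixture.hits if h.query_id in idset and h.target_id in idset]
        feats = build_feature_matrix(hits, ids, sigma=sigma, normalize=normalize)
        labels = [l for l in fixture.labels if l.id in idset]
        pairs = [p for p in fixture.struct_pairs if p.id_a in idset and p.id_b in idset]
        return cls(feats, hits, labels=labels, struct_pairs=pairs)

    def fit(self, config: TrainConfig | None = None, **overrides) -> "ProtEmbedResults":
        """Train the embedding; keyword overrides patch the config
        (e.g. ``fit(d=10, epochs=30, seed=1)``)."""
        cfg = config or TrainConfig()
        if overrides:
            cfg = replace(cfg, **overrides)
        model, log = _tr.train(
            self.features, self.hits, cfg,
            labels=self.labels, struct_pairs=self.struct_pairs,
        )
        model.config["sigma"] = self.features.sigma
        model.config["normalized"] = self.features.normalized
        return ProtEmbedResults(self, model, log, cfg)


class ProtEmbedResults:
    """Fitted embedding: learned projection, diagnostics, and retrieval."""

    def __init__(self, model_obj: ProtEmbed, embedding: EmbeddingModel,
                 training_log: pd.DataFrame, config: TrainConfig):
        self.model = model_obj
        self.embedding = embedding
        self.training_log = training_log
        self.config = config
        self.db_points = embed_all(embedding, model_obj.features)
        self.calibration: _cal.NullCalibration | None = None

    @property
    def params(self) -> np.ndarray:
        """The learned projection matrix W (d x n)."""
        return self.embedding.W

    @property
    def centroids(self) -> np.ndarray | None:
        return self.embedding.C

    def query_features(self, query_hits: Sequence[PairwiseHit], query_id: str):
        """Feature vector of an unseen query from its teacher scores
        against the training database (axes never change)."""
        feats = build_feature_matrix(
            [h for h in query_hits if h.query_id == query_id
             and h.target_id in set(self.embedding.ids)],
            ids=[query_id],
            sigma=self.model.features.sigma,
            normalize=self.model.features.normalized,
            column_ids=self.embedding.ids,
        )
        return feats.row(0)

    def rank(self, query_features, query_id: str = "query",
             query_length: int | None = None) -> RankedResult:
        """Rank the database by ascending embedding distance to the query;
        adds p- and q-values when a calibration is attached and the query
        length is given."""
        point = embed(self.embedding, query_features, source_id=query_id)
        result = rank_database(
            point, self.db_points, self.embedding.ids,
            p=self.embedding.p, query_id=query_id,
        )
        if self.calibration is not None and query_length is not None and result.entries:
            dists = result.distances
            pvals = np.asarray(self.calibration.pvalue(dists, query_length))
            pi0 = _cal.estimate_pi0(pvals)
            qvals = _cal.qvalues(pvals, pi0)
            result.pvalues = [float(x) for x in pvals]
            result.qvalues = [float(x) for x in qvals]
        return result

    def calibrate(self, null_model: _cal.MarkovNullModel, teacher,
                  length_range: tuple[int, int], n_decoys_per_bin: int = 1000,
                  tail_fraction: float = 0.25, seed: int = 0) -> _cal.NullCalibration:
        """Fit and attach the length-binned decoy null calibration."""
        self.calibration = _cal.calibrate(
            self.embedding, null_model, teacher, self.db_points,
            length_range, n_decoys_per_bin, tail_fraction, seed,
        )
        return self.calibration

    def neighborhood(self, result: RankedResult, query_features,
                     q_threshold: float | None = 0.01, space: str = "embedded",
                     classes: dict[str, str] | None = None,
                     max_rank: int = 25) -> NeighborhoodMap:
        """MDS neighborhood map of a ranked query (see viz.neighborhood)."""
        return neighborhood(
            self.embedding, result, query_features, self.model.features,
            q_threshold=q_threshold, space=space, classes=classes, max_rank=max_rank,
        )

    def summary(self) -> str:
        """Plain-text fit summary in the style of statsmodels results."""
        cfg = self.config
        log = self.training_log
        lines = [
            "Protein Semantic Embedding Results",
            "=" * 50,
            f"{'database size (n)':<30}{self.embedding.n}",
            f"{'embedding dimension (d)':<30}{self.embedding.d}",
            f"{'feature sigma':<30}{self.model.features.sigma:g}",
            f"{'row-normalized features':<30}{self.model.features.normalized}",
            f"{'distance norm (p)':<30}{cfg.p:g}",
            f"{'learning rate':<30}{cfg.lr:g}",
            f"{'margin':<30}{cfg.margin:g}",
            f"{'epochs x tuples/epoch':<30}{cfg.epochs} x {cfg.tuples_per_epoch}",
            f"{'positive E-value threshold':<30}{cfg.pos_evalue_threshold:g}",
            f"{'auxiliary task':<30}{cfg.aux_mode}",
            f"{'seed':<30}{cfg.seed}",
        ]
        if len(log):
            first, last = log.iloc[0], log.iloc[-1]
            lines += [
                "-" * 50,
                f"{'initial mean tuple loss':<30}{first['mean_loss']:.4f}",
                f"{'final mean tuple loss':<30}{last['mean_loss']:.4f}",
                f"{'final violating tuples':<30}{int(last['violations'])}"
                f" / {cfg.tuples_per_epoch}",
            ]
        if self.embedding.C is not None:
            lines.append(f"{'class centroids learned':<30}{self.embedding.C.shape[1]}")
        if self.calibration is not None:
            lines.append(f"{'calibration length bins':<30}{len(self.calibration.bins)}")
        lines.append("=" * 50)
        return "\n".join(lines)

    def save(self, path) -> None:
        self.embedding.save(path)
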