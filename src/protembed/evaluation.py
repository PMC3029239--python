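"""ROC-based evaluation of homology rankings and paired method comparison.

Targets are labeled from structural categories: a target in the query's
superfamily is a positive (homolog), a target in a different fold is a
negative (non-homolog), and a target in the same fold but a different
superfamily is ignored, its homology being uncertain.  An optional
family-exclusion mode additionally ignores same-family targets, so that
only remote relationships contribute.  Rankings are scored by ROC-n — the
area under the ROC curve truncated at the n-th false positive, normalized
so perfect retrieval is 1.0 — and methods are compared across queries with
the Wilcoxon signed-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.stats as st

from .training import AuxiliaryLabel

__all__ = [
    "POSITIVE",
    "NEGATIVE",
    "IGNORE",
    "LabeledRanking",
    "RocScore",
    "label_targets",
    "roc_n",
    "pooled_roc",
    "wilcoxon_signed_rank",
]

POSITIVE = "positive"
NEGATIVE = "negative"
IGNORE = "ignore"


@dataclass
class LabeledRanking:
    """An ordered target list with homology classes relative to one query."""

    query_id: str
    target_ids: list[str]
    classes: list[str]

    def __post_init__(self):
        if len(self.target_ids) != len(self.classes):
            raise ValueError("target_ids and classes must align")

    def without_ignores(self) -> list[str]:
        return [c for c in self.classes if c != IGNORE]


@dataclass(frozen=True)
class RocScore:
    """Normalized truncated-ROC score: 1.0 is perfect, 0.0 means the first
    n_cap negatives all precede every positive."""

    value: float
    n_cap: int
    n_pos: int
    n_neg: int


def label_targets(
    query_label: AuxiliaryLabel,
    target_labels: Sequence[AuxiliaryLabel],
    exclude_family: bool = False,
) -> list[str]:
    """Assign positive / negative / ignore to each target.

    positive: same superfamily as the query; negative: different fold;
    ignore: same fold but different superfamily.  With `exclude_family`,
    same-family targets are also ignored, leaving only remote homologs
    as positives.
    """
    classes = []
    for t in target_labels:
        if t.superfamily == query_label.superfamily:
            if exclude_family and t.family == query_label.family:
                classes.append(IGNORE)
            else:
                classes.append(POSITIVE)
        elif t.fold == query_label.fold:
            classes.append(IGNORE)
        else:
            classes.append(NEGATIVE)
    return classes


def roc_n(labeled: LabeledRanking | Sequence[str], n_cap: int = 50) -> RocScore | None:
    """Area under the ROC curve truncated at the n_cap-th false positive,
    normalized by (n_cap x #positives).

    Accepts a LabeledRanking or a bare class sequence.  Ignored targets are
    removed first.  Positives that the ranking never retrieves ahead of the
    cap do not contribute.  Negatives beyond the end of the list count as
    ranked after every positive.  Returns None when the ranking has no
    positives (undefined score, excluded from means).
    """
    classes = labeled.without_ignores() if isinstance(labeled, LabeledRanking) else [
        c for c in labeled if c != IGNORE
    ]
    n_pos = sum(c == POSITIVE for c in classes)
    n_neg = sum(c == NEGATIVE for c in classes)
    if n_pos == 0:
        return None
    area = 0
    seen_pos = 0
    seen_neg = 0
    for c in classes:
        if c == POSITIVE:
            seen_pos += 1
        else:
            seen_neg += 1
            area += seen_pos
            if seen_neg == n_cap:
                break
    if seen_neg < n_cap:
        # remaining (hypothetical) negatives rank after all positives
        area += (n_cap - seen_neg) * n_pos
    return RocScore(area / (n_cap * n_pos), n_cap, n_pos, n_neg)


def pooled_roc(
    scored_rankings: Sequence[tuple[np.ndarray, Sequence[str]]],
) -> tuple[np.ndarray, np.ndarray, float]:
    """Pool scores from many queries into a single ROC curve.

    Each element is (scores, classes) for one query, scores ascending =
    better (distances or p-values).  All scores are merged into one global
    ranking; returns (false-positive fraction, true-positive fraction,
    AUC).  Ignored targets are dropped.
    """
    all_scores, all_pos = [], []
    for scores, classes in scored_rankings:
        scores = np.asarray(scores, dtype=np.float64)
        for s, c in zip(scores, classes):
            if c == IGNORE:
                continue
            all_scores.append(s)
            all_pos.append(c == POSITIVE)
    if not all_scores:
        return np.array([0.0]), np.array([0.0]), float("nan")
    scores = np.asarray(all_scores)
    is_pos = np.asarray(all_pos)
    order = np.argsort(scores, kind="stable")
    is_pos = is_pos[order]
    P = int(is_pos.sum())
    N = int(len(is_pos) - P)
    tp = np.concatenate([[0], np.cumsum(is_pos)])
    fp = np.concatenate([[0], np.cumsum(~is_pos)])
    tpf = tp / P if P else np.zeros_like(tp, dtype=float)
    fpf = fp / N if N else np.zeros_like(fp, dtype=float)
    auc = float(np.trapezoid(tpf, fpf)) if P and N else float("nan")
    return fpf, tpf, auc


def wilcoxon_signed_rank(
    scores_a: Sequence[float], scores_b: Sequence[float]
) -> tuple[float, float, int]:
    """Two-sided Wilcoxon signed-rank test on paired per-query scores.

    Zero differences are dropped.  The exact null distribution is used for
    fewer than 15 non-zero differences without ties; otherwise the normal
    approximation with tie correction.  Returns (statistic, p-value,
    direction) where direction is the sign of the median difference
    (+1 if a tends larger).  All-zero differences give p = 1.
    """
    a = np.asarray(scores_a, dtype=np.float64)
    b = np.asarray(scores_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("paired score vectors must have equal length")
    diffs = a - b
    nz = diffs[diffs != 0.0]
    if nz.size == 0:
        return 0.0, 1.0, 0
    has_ties = np.unique(np.abs(nz)).size < nz.size
    method = "exact" if (nz.size < 15 and not has_ties) else "approx"
    stat, p = st.wilcoxon(a, b, zero_method="wilcox", method=method)
    direction = int(np.sign(np.median(nz)))
    return float(stat), float(p), direction


def evaluation_report(per_query: dict[str, dict[str, float | int | None]]) -> str:
    """Render a per-query TSV block (query_id, roc1, roc50, n_pos, n_neg)
    plus summary means; queries with undefined ROC are counted, not averaged."""
    lines = ["query_id\troc1\troc50\tn_pos\tn_neg"]
    roc1s, roc50s, undefined = [], [], 0
    for qid, row in per_query.items():
        r1, r50 = row.get("roc1"), row.get("roc50")
        if r1 is None:
            undefined += 1
        else:
            roc1s.append(r1)
        if r50 is not None:
            roc50s.append(r50)
        lines.append(
            f"{qid}\t{'NA' if r1 is None else f'{r1:.4f}'}\t"
            f"{'NA' if r50 is None else f'{r50:.4f}'}\t"
            f"{row.get('n_pos', 0)}\t{row.get('n_neg', 0)}"
        )
    lines.append("# mean_roc1\t%.4f" % (np.mean(roc1s) if roc1s else float("nan")))
    lines.append("# mean_roc50\t%.4f" % (np.mean(roc50s) if roc50s else float("nan")))
    lines.append(f"# queries_without_positives\t{undefined}")
    return "\n".join(lines) + "\n"
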