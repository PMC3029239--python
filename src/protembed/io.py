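"""Sequence and teacher-score ingestion, and the sparse feature representation.

Every database protein is represented by the vector of its transformed
teacher similarities against the whole database: feature j of protein i is
``exp(-E(i, j) / sigma)`` where ``E(i, j)`` is the E-value the teacher search
program assigned to target j for query i.  Pairs the teacher did not report
are exactly zero, so the representation is sparse.  With row normalization
the matrix is row-stochastic and can be read as the transition matrix of a
random walk on the protein similarity network.
"""

from __future__ import annotations

import io as _io
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

__all__ = [
    "SequenceRecord",
    "PairwiseHit",
    "SparseFeatureMatrix",
    "read_fasta",
    "write_fasta",
    "filter_sequences",
    "read_hits",
    "write_hits",
    "transfer",
    "build_feature_matrix",
]

#: weights below this are treated as exactly zero in sparse storage
WEIGHT_FLOOR = 1e-12

#: filter bounds for database construction
MIN_SEQ_LEN = 6
MAX_SEQ_LEN = 10_000


@dataclass(frozen=True)
class SequenceRecord:
    """A protein domain sequence."""

    id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PairwiseHit:
    """One teacher search hit: E-value of `target_id` for query `query_id`."""

    query_id: str
    target_id: str
    evalue: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(
                f"negative E-value {self.evalue} for ({self.query_id}, {self.target_id})"
            )


def read_fasta(source) -> list[SequenceRecord]:
    """Read FASTA from a path or text stream into SequenceRecords.

    Duplicate identifiers and empty sequences are rejected.  No length
    filtering is applied here; see :func:`filter_sequences`.
    """
    if isinstance(source, (str, Path)):
        handle = open(source)
        close = True
    else:
        handle, close = source, False
    try:
        records: list[SequenceRecord] = []
        seen: set[str] = set()
        for rec in SeqIO.parse(handle, "fasta"):
            if not rec.id:
                raise ValueError("malformed FASTA: record with empty header")
            if rec.id in seen:
                raise ValueError(f"duplicate id {rec.id}")
            seq = str(rec.seq).upper()
            if not seq:
                raise ValueError(f"empty sequence for record {rec.id}")
            seen.add(rec.id)
            records.append(SequenceRecord(id=rec.id, sequence=seq))
        return records
    finally:
        if close:
            handle.close()


def write_fasta(records: Iterable[SequenceRecord], dest) -> None:
    """Write SequenceRecords as FASTA to a path or text stream."""
    bio = [
        _BioSeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    if isinstance(dest, (str, Path)):
        with open(dest, "w") as handle:
            SeqIO.write(bio, handle, "fasta-2line")
    else:
        SeqIO.write(bio, dest, "fasta-2line")


def filter_sequences(
    records: Iterable[SequenceRecord],
    min_len: int = MIN_SEQ_LEN,
    max_len: int = MAX_SEQ_LEN,
) -> list[SequenceRecord]:
    """Drop sequences shorter than `min_len`, longer than `max_len`, or
    composed entirely of the ambiguity code "X".  Order is preserved; a
    sequence of exactly `min_len` or `max_len` residues is kept.
    """
    out = []
    for r in records:
        if r.length < min_len or r.length > max_len:
            continue
        if set(r.sequence) == {"X"}:
            continue
        out.append(r)
    return out


def read_hits(source) -> list[PairwiseHit]:
    """Read teacher pairwise scores from TSV.

    Two dialects are accepted: the canonical 3-column form
    (query_id, target_id, evalue) and 12-column BLAST tabular output
    (-outfmt 6), from which columns 1, 2 and 11 are used.  Lines starting
    with '#' are ignored.
    """
    if isinstance(source, (str, Path)):
        handle = open(source)
        close = True
    else:
        handle, close = source, False
    try:
        hits = []
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 3:
                q, t, e = parts
            elif len(parts) == 12:
                q, t, e = parts[0], parts[1], parts[10]
            else:
                raise ValueError(
                    f"line {lineno}: expected 3 or 12 tab-separated columns, got {len(parts)}"
                )
            hits.append(PairwiseHit(q, t, float(e)))
        return hits
    finally:
        if close:
            handle.close()


def write_hits(hits: Iterable[PairwiseHit], dest) -> None:
    """Write hits in the canonical 3-column TSV dialect."""
    if isinstance(dest, (str, Path)):
        handle = open(dest, "w")
        close = True
    else:
        handle, close = dest, False
    try:
        for h in hits:
            handle.write(f"{h.query_id}\t{h.target_id}\t{h.evalue:.6g}\n")
    finally:
        if close:
            handle.close()


def transfer(evalue: float, sigma: float) -> float:
    """Exponential transfer exp(-E/sigma) mapping an E-value to a weight in [0, 1].

    Undetectable similarities (the teacher's large sentinel E-values) map to
    weights below the storage floor and are treated as exactly zero.
    """
    if evalue < 0:
        raise ValueError(f"E-value must be non-negative, got {evalue}")
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    w = math.exp(-evalue / sigma)
    return w if w >= WEIGHT_FLOOR else 0.0


class SparseFeatureMatrix:
    """Database-by-database matrix of transformed teacher similarities.

    Row i is the feature vector of protein ``ids[i]``; column axes are the
    same ``ids``.  Stored as CSR with no explicit zeros.
    """

    def __init__(
        self,
        matrix: sp.csr_matrix,
        ids: Sequence[str],
        sigma: float,
        normalized: bool,
    ):
        matrix = sp.csr_matrix(matrix)
        matrix.eliminate_zeros()
        if matrix.shape[0] != len(ids):
            raise ValueError("matrix row count must equal number of ids")
        self.matrix = matrix
        self.ids = list(ids)
        self.sigma = float(sigma)
        self.normalized = bool(normalized)
        self._index = {pid: i for i, pid in enumerate(self.ids)}

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def n_cols(self) -> int:
        return self.matrix.shape[1]

    def index_of(self, pid: str) -> int:
        try:
            return self._index[pid]
        except KeyError:
            raise KeyError(f"unknown id {pid!r}") from None

    def row(self, i: int) -> sp.csr_matrix:
        return self.matrix.getrow(i)

    def density(self) -> float:
        return self.matrix.nnz / (self.matrix.shape[0] * self.matrix.shape[1])

    def save(self, path) -> None:
        m = self.matrix
        np.savez(
            path,
            data=m.data,
            indices=m.indices,
            indptr=m.indptr,
            shape=np.asarray(m.shape),
            meta=np.frombuffer(
                json.dumps(
                    {"ids": self.ids, "sigma": self.sigma, "normalized": self.normalized}
                ).encode(),
                dtype=np.uint8,
            ),
        )

    @classmethod
    def load(cls, path) -> "SparseFeatureMatrix":
        with np.load(path) as z:
            meta = json.loads(bytes(z["meta"]).decode())
            m = sp.csr_matrix(
                (z["data"], z["indices"], z["indptr"]), shape=tuple(z["shape"])
            )
        return cls(m, meta["ids"], meta["sigma"], meta["normalized"])


def build_feature_matrix(
    hits: Iterable[PairwiseHit],
    ids: Sequence[str],
    sigma: float = 100.0,
    normalize: bool = True,
    column_ids: Sequence[str] | None = None,
) -> SparseFeatureMatrix:
    """Build the transformed similarity matrix over the given database ids.

    Entry (i, j) is ``transfer(E(i, j), sigma)``.  Duplicate (query, target)
    hits keep the smallest E-value (the strongest evidence reported by an
    iterated search).  With ``normalize=True`` every nonempty row is divided
    by its sum, giving the row-stochastic connectivity matrix.

    ``column_ids`` lets query feature vectors for sequences outside the
    database be expressed against the database axes: rows are then ``ids``
    (the queries) and columns ``column_ids`` (the database).
    """
    ids = list(ids)
    col_ids = list(column_ids) if column_ids is not None else ids
    row_index = {pid: i for i, pid in enumerate(ids)}
    col_index = {pid: j for j, pid in enumerate(col_ids)}

    best: dict[tuple[int, int], float] = {}
    for h in hits:
        try:
            i = row_index[h.query_id]
        except KeyError:
            raise KeyError(f"unknown query id {h.query_id!r}") from None
        try:
            j = col_index[h.target_id]
        except KeyError:
            raise KeyError(f"unknown target id {h.target_id!r}") from None
        key = (i, j)
        if key not in best or h.evalue < best[key]:
            best[key] = h.evalue

    rows, cols, vals = [], [], []
    for (i, j), e in best.items():
        w = transfer(e, sigma)
        if w > 0.0:
            rows.append(i)
            cols.append(j)
            vals.append(w)
    m = sp.csr_matrix(
        (vals, (rows, cols)), shape=(len(ids), len(col_ids)), dtype=np.float64
    )
    if normalize:
        row_sums = np.asarray(m.sum(axis=1)).ravel()
        scale = np.ones_like(row_sums)
        nonempty = row_sums > 0
        scale[nonempty] = 1.0 / row_sums[nonempty]
        m = sp.diags(scale) @ m
    return SparseFeatureMatrix(m, ids, sigma, normalize)
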