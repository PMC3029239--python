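"""A self-contained synthetic benchmark with the statistical structure the
embedding method assumes.

The generator emulates a structural classification hierarchy (folds >
superfamilies > families > members) and a pairwise-search teacher.  Each
superfamily descends from a random ancestral sequence; family ancestors are
substitution-mutated copies, and members are mutated copies of their family
ancestor.  Teacher E-values are sampled from tiered log-normal
distributions — tight for same-family pairs, looser within a superfamily,
mostly undetected across folds — so the transformed feature matrix is
sparse and carries a learnable homology signal.  Structural similarity
scores are high within superfamilies and low across folds.  Everything is
driven by a single seed, so outputs are byte-identical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .calibration import AMINO_ACIDS
from .io import PairwiseHit, SequenceRecord, write_fasta, write_hits
from .training import AuxiliaryLabel, StructuralPair

__all__ = ["FixtureConfig", "Fixture", "SyntheticTeacher", "generate_fixture", "holdout_split"]

SAME_FAMILY = "family"
SAME_SUPERFAMILY = "superfamily"
SAME_FOLD = "fold"
UNRELATED = "unrelated"


@dataclass
class FixtureConfig:
    """Shape and noise parameters of the synthetic benchmark.

    Defaults give 4 folds x 2 superfamilies x 2 families x 6 members =
    96 sequences.  Mutation rates are per-residue substitution
    probabilities applied when deriving family ancestors from the
    superfamily ancestor and members from the family ancestor.  The
    teacher model is tiered: log10 E-value means rise (weaker evidence)
    and detection probabilities fall with evolutionary distance, with
    cross-fold pairs almost never reported — the source of sparsity.
    """

    n_folds: int = 4
    superfamilies_per_fold: int = 2
    families_per_superfamily: int = 2
    members_per_family: int = 6
    seq_length_range: tuple[int, int] = (60, 120)
    superfamily_mutation: float = 0.40
    family_mutation: float = 0.15
    # teacher noise: mean/sd of log10 E and detection probability per tier
    log_e_family: tuple[float, float] = (-8.0, 2.0)
    log_e_superfamily: tuple[float, float] = (-3.0, 1.5)
    log_e_fold: tuple[float, float] = (0.5, 1.0)
    log_e_unrelated: tuple[float, float] = (1.5, 1.0)
    detect_family: float = 0.95
    detect_superfamily: float = 0.90
    detect_fold: float = 0.30
    detect_unrelated: float = 0.02
    self_evalue: float = 1e-10
    # structural scores (MAMMOTH-like): mean/sd per tier, floored at 0
    struct_superfamily: tuple[float, float] = (4.0, 1.0)
    struct_fold: tuple[float, float] = (1.0, 0.5)
    struct_unrelated: tuple[float, float] = (0.2, 0.3)
    seed: int = 0

    def __post_init__(self):
        for name in ("n_folds", "superfamilies_per_fold", "families_per_superfamily",
                     "members_per_family"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be at least 1")
        if self.log_e_family[0] >= self.log_e_unrelated[0]:
            raise ValueError("related pairs must have lower mean log E than unrelated")


@dataclass
class Fixture:
    """The generated benchmark: sequences, labels, teacher hits, structural
    scores, and the relationship truth table."""

    config: FixtureConfig
    sequences: list[SequenceRecord]
    labels: list[AuxiliaryLabel]
    hits: list[PairwiseHit]
    struct_pairs: list[StructuralPair]

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.sequences]

    def label_of(self, pid: str) -> AuxiliaryLabel:
        return self._label_index[pid]

    def __post_init__(self):
        self._label_index = {l.id: l for l in self.labels}

    def relationship(self, a: str, b: str) -> str:
        la, lb = self._label_index[a], self._label_index[b]
        if la.family == lb.family:
            return SAME_FAMILY
        if la.superfamily == lb.superfamily:
            return SAME_SUPERFAMILY
        if la.fold == lb.fold:
            return SAME_FOLD
        return UNRELATED

    def write(self, directory) -> None:
        """Emit FASTA, hits TSV, labels TSV, structural TSV, a truth TSV and
        the generating config (JSON)."""
        import json

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        cfg = asdict(self.config)
        with open(directory / "fixture_config.json", "w") as fh:
            json.dump(cfg, fh, indent=1, sort_keys=True)
        write_fasta(self.sequences, directory / "sequences.fasta")
        write_hits(self.hits, directory / "teacher_hits.tsv")
        with open(directory / "labels.tsv", "w") as fh:
            fh.write("id\tfold\tsuperfamily\tfamily\n")
            for lab in self.labels:
                fh.write(f"{lab.id}\t{lab.fold}\t{lab.superfamily}\t{lab.family}\n")
        with open(directory / "structural_scores.tsv", "w") as fh:
            for p in self.struct_pairs:
                fh.write(f"{p.id_a}\t{p.id_b}\t{p.score:.4f}\n")
        with open(directory / "truth.tsv", "w") as fh:
            fh.write("id_a\tid_b\trelationship\n")
            ids = self.ids
            for i, a in enumerate(ids):
                for b in ids[i + 1:]:
                    fh.write(f"{a}\t{b}\t{self.relationship(a, b)}\n")


def read_fixture(directory) -> Fixture:
    """Reload a fixture written by :meth:`Fixture.write`."""
    import json

    from .io import read_fasta, read_hits
    from .training import read_labels, read_structural_scores

    directory = Path(directory)
    with open(directory / "fixture_config.json") as fh:
        raw = json.load(fh)
    for key in ("seq_length_range", "log_e_family", "log_e_superfamily", "log_e_fold",
                "log_e_unrelated", "struct_superfamily", "struct_fold", "struct_unrelated"):
        raw[key] = tuple(raw[key])
    cfg = FixtureConfig(**raw)
    return Fixture(
        cfg,
        sequences=read_fasta(directory / "sequences.fasta"),
        labels=read_labels(directory / "labels.tsv"),
        hits=read_hits(directory / "teacher_hits.tsv"),
        struct_pairs=read_structural_scores(directory / "structural_scores.tsv"),
    )


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitution-only mutation: each residue replaced (uniformly over the
    19 alternatives) with probability `rate`."""
    chars = list(seq)
    hit = rng.random(len(chars)) < rate
    for i in np.flatnonzero(hit):
        alternatives = AMINO_ACIDS.replace(chars[i], "")
        chars[i] = alternatives[rng.integers(len(alternatives))]
    return "".join(chars)


class SyntheticTeacher:
    """Simulates the pairwise-search teacher on fixture (or decoy) sequences.

    Any sequence whose id is not in the fixture truth table — e.g. a Markov
    decoy — is treated as unrelated to everything.  Scoring is seeded and
    repeatable: the same query list always yields the same hits.
    """

    def __init__(self, fixture: Fixture, seed: int | None = None):
        self.fixture = fixture
        cfg = fixture.config
        self.seed = cfg.seed if seed is None else seed
        self._tier_params = {
            SAME_FAMILY: (cfg.log_e_family, cfg.detect_family),
            SAME_SUPERFAMILY: (cfg.log_e_superfamily, cfg.detect_superfamily),
            SAME_FOLD: (cfg.log_e_fold, cfg.detect_fold),
            UNRELATED: (cfg.log_e_unrelated, cfg.detect_unrelated),
        }

    def _tier(self, qid: str, tid: str) -> str:
        known = self.fixture._label_index
        if qid in known and tid in known:
            return self.fixture.relationship(qid, tid)
        return UNRELATED

    def score_queries(
        self,
        queries: Sequence[SequenceRecord | str],
        db_ids: Sequence[str] | None = None,
    ) -> list[PairwiseHit]:
        """Teacher hits of each query against the database (default: all
        fixture sequences)."""
        db_ids = list(db_ids) if db_ids is not None else self.fixture.ids
        hits: list[PairwiseHit] = []
        cfg = self.fixture.config
        for rec in queries:
            qid = rec if isinstance(rec, str) else rec.id
            for tid in db_ids:
                if tid == qid:
                    hits.append(PairwiseHit(qid, tid, cfg.self_evalue))
                    continue
                (mu, sd), detect = self._tier_params[self._tier(qid, tid)]
                # E(q, t) is a pure function of (seed, q, t): scoring against
                # any database subset reproduces the same values
                u, z = _pair_randoms(self.seed, qid, tid)
                if u < detect:
                    hits.append(PairwiseHit(qid, tid, 10.0 ** (mu + sd * z)))
        return hits

    def __call__(self, queries: Sequence[SequenceRecord]) -> list[PairwiseHit]:
        return self.score_queries(queries)


def _stable_hash(s: str) -> int:
    h = 1469598103934665603
    for ch in s.encode():
        h = ((h ^ ch) * 1099511628211) % (2**64)
    return h


def _unit(h: int) -> float:
    return ((h >> 11) + 0.5) / 2**53


def _pair_randoms(seed: int, qid: str, tid: str) -> tuple[float, float]:
    """A uniform and a standard normal, both pure functions of (seed, q, t)."""
    u_detect = _unit(_stable_hash(f"{seed}\x00{qid}\x00{tid}\x00detect"))
    u1 = _unit(_stable_hash(f"{seed}\x00{qid}\x00{tid}\x00z1"))
    u2 = _unit(_stable_hash(f"{seed}\x00{qid}\x00{tid}\x00z2"))
    z = float(np.sqrt(-2.0 * np.log(u1)) * np.cos(2.0 * np.pi * u2))
    return u_detect, z


def generate_fixture(config: FixtureConfig | None = None) -> Fixture:
    """Generate the synthetic benchmark from its config (fully seeded)."""
    cfg = config or FixtureConfig()
    rng = np.random.default_rng(cfg.seed)
    aa = np.array(list(AMINO_ACIDS))
    sequences: list[SequenceRecord] = []
    labels: list[AuxiliaryLabel] = []
    lo, hi = cfg.seq_length_range
    for f in range(cfg.n_folds):
        fold_id = f"f{f}"
        for s in range(cfg.superfamilies_per_fold):
            sf_id = f"{fold_id}.{s}"
            length = int(rng.integers(lo, hi + 1))
            sf_ancestor = "".join(aa[rng.integers(20, size=length)])
            for fam in range(cfg.families_per_superfamily):
                fam_id = f"{sf_id}.{fam}"
                fam_ancestor = _mutate(sf_ancestor, cfg.superfamily_mutation, rng)
                for m in range(cfg.members_per_family):
                    pid = f"p_{f}_{s}_{fam}_{m}"
                    seq = _mutate(fam_ancestor, cfg.family_mutation, rng)
                    sequences.append(SequenceRecord(pid, seq))
                    labels.append(AuxiliaryLabel(pid, fold_id, sf_id, fam_id))

    fixture = Fixture(cfg, sequences, labels, hits=[], struct_pairs=[])
    teacher = SyntheticTeacher(fixture)
    fixture.hits = teacher.score_queries(sequences)

    struct_params = {
        SAME_FAMILY: cfg.struct_superfamily,
        SAME_SUPERFAMILY: cfg.struct_superfamily,
        SAME_FOLD: cfg.struct_fold,
        UNRELATED: cfg.struct_unrelated,
    }
    srng = np.random.default_rng(cfg.seed + 1)
    ids = fixture.ids
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            mu, sd = struct_params[fixture.relationship(a, b)]
            score = max(0.0, mu + sd * srng.standard_normal())
            fixture.struct_pairs.append(StructuralPair(a, b, float(score)))
    return fixture


def holdout_split(
    fixture: Fixture, n_test_queries: int, seed: int = 0
) -> tuple[list[str], list[str]]:
    """Split fixture ids into (train, test) with test queries excluded from
    training entirely.

    Test queries are drawn at random but constrained so that every test
    query keeps at least one same-superfamily target in the training set
    (otherwise its retrieval problem has no answer).
    """
    ids = fixture.ids
    if n_test_queries >= len(ids):
        raise ValueError("cannot hold out the whole database")
    rng = np.random.default_rng(seed)
    sf_size: dict[str, int] = {}
    for pid in ids:
        sf = fixture.label_of(pid).superfamily
        sf_size[sf] = sf_size.get(sf, 0) + 1
    sf_held: dict[str, int] = {sf: 0 for sf in sf_size}
    test: list[str] = []
    for k in rng.permutation(len(ids)):
        if len(test) == n_test_queries:
            break
        cand = ids[k]
        sf = fixture.label_of(cand).superfamily
        # a superfamily must keep >=1 member in train to answer its test queries
        if sf_size[sf] - sf_held[sf] - 1 >= 1:
            test.append(cand)
            sf_held[sf] += 1
    if len(test) < n_test_queries:
        raise ValueError("stratified holdout impossible with this config")
    test_set = set(test)
    train = [i for i in ids if i not in test_set]
    return train, test
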