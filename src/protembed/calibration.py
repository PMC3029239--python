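"""Statistical calibration of embedding distances.

Retrieval scores are distances in a single embedding space, so they are
comparable across queries; to attach significance we build an empirical
null.  Decoy sequences are generated from a third-order Markov chain fitted
to the database, embedded via their (sparse) teacher scores, and each
decoy's score is its distance to the nearest database point.  Decoy scores
are binned by query length; within a bin, the left (significant) tail of
the null is modelled by a two-parameter Weibull fitted by maximum
likelihood, and the remainder by the interpolated empirical distribution,
giving a continuous null CDF.  p-values are then corrected to q-values by
the Benjamini-Hochberg step-up including the Storey pi0 multiplicative
factor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import scipy.stats as st

from .embedding import EmbeddingModel, embed
from .io import SequenceRecord, build_feature_matrix

__all__ = [
    "AMINO_ACIDS",
    "MarkovNullModel",
    "WeibullFit",
    "NullCalibration",
    "fit_markov",
    "generate_decoys",
    "decoy_scores",
    "fit_weibull_left_tail",
    "pvalue",
    "estimate_pi0",
    "qvalues",
    "calibrate",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

# ambiguity codes resolved to a uniform choice among their standard expansions
_AMBIGUITY = {"B": "DN", "Z": "EQ", "J": "IL", "U": "C", "O": "K", "X": AMINO_ACIDS}


class MarkovNullModel:
    """Order-k Markov chain over the 20 standard amino acids.

    Holds additive-pseudocount transition probabilities P(a | k-mer context)
    and an initial distribution over k-mers.
    """

    def __init__(self, order: int, transitions: np.ndarray, initial: np.ndarray):
        if transitions.shape != (20,) * (order + 1):
            raise ValueError("transition table shape does not match order")
        self.order = order
        self.transitions = transitions  # [c1..ck, next] conditional probabilities
        self.initial = initial  # flat distribution over 20**order initial k-mers
        if not np.allclose(transitions.sum(axis=-1), 1.0, atol=1e-9):
            raise ValueError("conditional distributions must sum to 1")

    def sample(self, length: int, rng: np.random.Generator) -> str:
        if length < self.order + 1:
            raise ValueError(f"length must be at least order+1 = {self.order + 1}")
        start = rng.choice(len(self.initial), p=self.initial)
        context = []
        for _ in range(self.order):
            context.append(start % 20)
            start //= 20
        context.reverse()
        out = list(context)
        for _ in range(length - self.order):
            probs = self.transitions[tuple(out[-self.order:])]
            out.append(int(rng.choice(20, p=probs)))
        return "".join(AMINO_ACIDS[i] for i in out)


def _encode(seq: str, rng: np.random.Generator) -> list[int]:
    """Map a sequence to alphabet indices, resolving ambiguity codes uniformly."""
    out = []
    for ch in seq.upper():
        if ch in _AA_INDEX:
            out.append(_AA_INDEX[ch])
        elif ch in _AMBIGUITY:
            choices = _AMBIGUITY[ch]
            out.append(_AA_INDEX[choices[rng.integers(len(choices))]])
        # other characters (gaps, '*') are skipped
    return out


def fit_markov(
    sequences: Iterable[SequenceRecord | str],
    order: int = 3,
    pseudocount: float = 1.0,
    seed: int = 0,
) -> MarkovNullModel:
    """Fit the Markov null by counting (order+1)-mers with a pseudocount.

    The initial distribution is the empirical distribution of leading
    order-mers (also pseudocounted).  `seed` only drives the uniform
    resolution of ambiguity codes.
    """
    rng = np.random.default_rng(seed)
    counts = np.full((20,) * (order + 1), pseudocount, dtype=np.float64)
    init_counts = np.full(20**order, pseudocount, dtype=np.float64)
    n_seqs = 0
    for rec in sequences:
        seq = rec.sequence if isinstance(rec, SequenceRecord) else rec
        idx = _encode(seq, rng)
        if len(idx) < order + 1:
            continue
        n_seqs += 1
        flat = 0
        for i in range(order):
            flat = flat * 20 + idx[i]
        init_counts[flat] += 1
        arr = np.asarray(idx)
        windows = np.lib.stride_tricks.sliding_window_view(arr, order + 1)
        flat_ctx = np.zeros(len(windows), dtype=np.int64)
        for i in range(order + 1):
            flat_ctx = flat_ctx * 20 + windows[:, i]
        np.add.at(counts.reshape(-1), flat_ctx, 1.0)
    if n_seqs == 0:
        raise ValueError("no usable training sequences for the Markov null")
    transitions = counts / counts.sum(axis=-1, keepdims=True)
    initial = init_counts / init_counts.sum()
    return MarkovNullModel(order, transitions, initial)


def generate_decoys(
    null_model: MarkovNullModel,
    length: int,
    n: int,
    seed: int = 0,
    prefix: str = "decoy",
) -> list[SequenceRecord]:
    """Sample n decoy sequences of exactly `length` residues from the chain."""
    rng = np.random.default_rng(seed)
    return [
        SequenceRecord(id=f"{prefix}_{length}_{i}", sequence=null_model.sample(length, rng))
        for i in range(n)
    ]


def decoy_scores(
    model: EmbeddingModel,
    decoys: Sequence[SequenceRecord],
    teacher: Callable[[Sequence[SequenceRecord]], Iterable],
    db_points: np.ndarray,
    sigma: float | None = None,
    normalize: bool = True,
) -> np.ndarray:
    """Null score of each decoy: distance to its nearest database point.

    `teacher` maps the decoy records to pairwise hits against the model's
    database ids (in tests, the synthetic teacher).  Decoys the teacher
    reports nothing for embed to the origin and still receive a score.
    """
    hits = list(teacher(decoys))
    feats = build_feature_matrix(
        hits,
        ids=[d.id for d in decoys],
        sigma=model.config.get("sigma", 100.0) if sigma is None else sigma,
        normalize=normalize,
        column_ids=model.ids,
    )
    p = model.p
    scores = np.empty(len(decoys))
    for i in range(len(decoys)):
        point = embed(model, feats.row(i))
        diffs = db_points - point.coords[None, :]
        if p == 1.0:
            d = np.abs(diffs).sum(axis=1)
        else:
            d = np.linalg.norm(diffs, ord=p, axis=1)
        scores[i] = d.min()
    return scores


def split_atoms(samples: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split samples into a continuous part and point masses (atoms).

    A value repeated more than max(2, 1%) times is an atom — in this null,
    the score shared by every decoy with an empty similarity profile.
    Returns (sorted continuous values, atom values, atom counts).
    """
    samples = np.asarray(samples, dtype=np.float64)
    values, counts = np.unique(samples, return_counts=True)
    threshold = max(2, int(0.01 * samples.size))
    keep = counts <= threshold
    continuous = np.repeat(values[keep], counts[keep])
    return continuous, values[~keep], counts[~keep]


@dataclass(frozen=True)
class WeibullFit:
    """Two-parameter Weibull (location fixed at 0) fitted to a left tail."""

    shape: float
    scale: float
    tail_fraction: float
    tail_cutoff: float  # empirical tail_fraction-quantile of the samples

    def cdf(self, x) -> np.ndarray:
        return st.weibull_min.cdf(x, self.shape, loc=0.0, scale=self.scale)


def fit_weibull_left_tail(samples: np.ndarray, tail_fraction: float = 0.25) -> WeibullFit:
    """Fit a Weibull by MLE to the lowest `tail_fraction` of the samples.

    Small scores are the significant ones, so the left tail is the region
    where the parametric form matters.  The null is in general a mixture:
    decoys with an empty similarity profile all collapse to one score, a
    point mass the parametric form cannot describe.  Exactly repeated
    values (multiplicity above 1% of the tail) are therefore excluded from
    the MLE — the calibration handles them empirically — and the Weibull
    models the continuous component.  Requires at least 200 samples and a
    non-degenerate continuous tail.
    """
    samples = np.asarray(samples, dtype=np.float64)
    if samples.size < 200:
        raise ValueError(f"need at least 200 null samples, got {samples.size}")
    if not 0.0 < tail_fraction <= 1.0:
        raise ValueError("tail_fraction must be in (0, 1]")
    if np.ptp(samples) == 0.0:
        raise ValueError("degenerate null samples (all equal)")
    srt, _, _ = split_atoms(samples)
    if srt.size < 20:
        raise ValueError("left tail too small or degenerate for a Weibull fit")
    cutoff = float(np.quantile(srt, tail_fraction))
    tail = srt[srt <= cutoff]
    if tail.size < 20 or np.ptp(tail) == 0.0:
        raise ValueError("left tail too small or degenerate for a Weibull fit")
    # distances are non-negative; guard exact zeros for the log-likelihood
    tail = np.maximum(tail, 1e-12)
    shape, loc, scale = st.weibull_min.fit(tail, floc=0.0)
    if shape <= 0 or scale <= 0:
        raise RuntimeError("Weibull fit returned non-positive parameters")
    return WeibullFit(float(shape), float(scale), float(tail_fraction), cutoff)


class NullCalibration:
    """Length-binned decoy score samples with Weibull left-tail fits.

    Bin edges default to a geometric ladder (x1.5 from 25 residues) over
    the query-length range.  Per bin, the null CDF is the Weibull CDF
    rescaled to hit `tail_fraction` at the empirical tail cutoff, and the
    interpolated empirical CDF above it — continuous, 0 at distance 0,
    1 in the limit.
    """

    def __init__(
        self,
        bins: list[tuple[int, int]],
        samples: list[np.ndarray],
        fits: list[WeibullFit],
        seed: int,
        n_decoys_per_bin: int,
    ):
        if not (len(bins) == len(samples) == len(fits)):
            raise ValueError("bins, samples and fits must align")
        self.bins = bins
        self.samples = [np.sort(np.asarray(s, dtype=np.float64)) for s in samples]
        self.fits = fits
        self.seed = seed
        self.n_decoys_per_bin = n_decoys_per_bin
        # per-bin mixture decomposition (recomputed, not serialized)
        self._continuous = []
        self._atom_values = []
        self._atom_masses = []
        for s in self.samples:
            cont, av, ac = split_atoms(s)
            self._continuous.append(cont)
            self._atom_values.append(av)
            self._atom_masses.append(ac / s.size)

    def bin_for_length(self, length: int) -> int:
        for k, (lo, hi) in enumerate(self.bins):
            if lo <= length <= hi:
                return k
        # nearest bin by midpoint when the length falls outside every bin
        mids = np.array([(lo + hi) / 2 for lo, hi in self.bins])
        return int(np.argmin(np.abs(mids - length)))

    def pvalue(
        self,
        distance,
        query_length: int,
        rng: np.random.Generator | None = None,
    ) -> np.ndarray | float:
        """P(null score <= distance) for a query of the given length.

        The null is a mixture: decoys the teacher reports nothing for embed
        to the origin, so their score is a point mass (atom), while decoys
        with hits produce a continuous component whose left tail is the
        fitted Weibull.  The CDF is evaluated additively:

            p(x) = (atom mass strictly below x)
                 + (continuous fraction) * F_cont(x)

        with F_cont the scaled Weibull below the tail cutoff and the
        interpolated empirical CDF of the continuous samples above it.
        At an atom the CDF jumps; a seeded `rng` applies the randomized
        probability integral transform across the jump (making null
        p-values exactly uniform); without an rng the conservative upper
        edge of the jump is returned.
        """
        k = self.bin_for_length(query_length)
        fit = self.fits[k]
        cont = self._continuous[k]
        atom_v, atom_m = self._atom_values[k], self._atom_masses[k]
        cont_frac = 1.0 - atom_m.sum()
        x = np.asarray(distance, dtype=np.float64)
        scalar = x.ndim == 0
        x = np.atleast_1d(x)

        # continuous component CDF
        mc = cont.size
        grid = np.arange(1, mc + 1) / (mc + 1.0)
        f_cont = np.interp(x, cont, grid, left=0.0, right=1.0)
        below = x <= fit.tail_cutoff
        tail_mass = fit.cdf(fit.tail_cutoff)
        scale = fit.tail_fraction / tail_mass if tail_mass > 0 else 1.0
        f_cont[below] = fit.cdf(x[below]) * scale

        # atom mass strictly below x (upper edge at ties added next)
        atom_below = np.zeros_like(x)
        tie_mass = np.zeros_like(x)
        for v, mass in zip(atom_v, atom_m):
            atom_below += mass * (x > v)
            tie_mass += mass * (x == v)
        p = atom_below + cont_frac * f_cont
        tied = tie_mass > 0
        if np.any(tied):
            u = rng.random(int(tied.sum())) if rng is not None else np.ones(int(tied.sum()))
            p[tied] += u * tie_mass[tied]
        p = np.clip(p, 0.0, 1.0)
        return float(p[0]) if scalar else p

    def save(self, path) -> None:
        meta = {
            "bins": self.bins,
            "seed": self.seed,
            "n_decoys_per_bin": self.n_decoys_per_bin,
            "fits": [
                [f.shape, f.scale, f.tail_fraction, f.tail_cutoff] for f in self.fits
            ],
        }
        payload = {f"samples_{k}": s for k, s in enumerate(self.samples)}
        payload["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
        np.savez(path, **payload)

    @classmethod
    def load(cls, path) -> "NullCalibration":
        with np.load(path) as z:
            meta = json.loads(bytes(z["meta"]).decode())
            samples = [z[f"samples_{k}"] for k in range(len(meta["bins"]))]
        fits = [WeibullFit(*f) for f in meta["fits"]]
        bins = [tuple(b) for b in meta["bins"]]
        return cls(bins, samples, fits, meta["seed"], meta["n_decoys_per_bin"])


def geometric_length_bins(
    min_len: int, max_len: int, start: int = 25, factor: float = 1.5
) -> list[tuple[int, int]]:
    """Geometric length-bin edges covering [min_len, max_len]."""
    edges = [start]
    while edges[-1] < max_len:
        edges.append(int(np.ceil(edges[-1] * factor)))
    bins = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        if hi >= min_len:
            bins.append((lo, hi - 1))
    if not bins:
        bins = [(min_len, max_len)]
    bins[-1] = (bins[-1][0], max(bins[-1][1], max_len))
    if bins[0][0] > min_len:
        bins[0] = (min_len, bins[0][1])
    return bins


def calibrate(
    model: EmbeddingModel,
    null_model: MarkovNullModel,
    teacher,
    db_points: np.ndarray,
    length_range: tuple[int, int],
    n_decoys_per_bin: int = 1000,
    tail_fraction: float = 0.25,
    seed: int = 0,
    bins: list[tuple[int, int]] | None = None,
) -> NullCalibration:
    """Build the length-binned null calibration for a trained model.

    For each length bin, decoys of the bin's midpoint length are sampled
    from the Markov chain, scored against the database, and fitted.
    """
    if bins is None:
        bins = geometric_length_bins(*length_range)
    all_samples, fits = [], []
    for k, (lo, hi) in enumerate(bins):
        length = max((lo + hi) // 2, null_model.order + 1)
        decoys = generate_decoys(
            null_model, length, n_decoys_per_bin, seed=seed + 7919 * k, prefix=f"decoy{k}"
        )
        scores = decoy_scores(model, decoys, teacher, db_points)
        all_samples.append(scores)
        fits.append(fit_weibull_left_tail(scores, tail_fraction))
    return NullCalibration(bins, all_samples, fits, seed, n_decoys_per_bin)


def pvalue(distance, calibration: NullCalibration, query_length: int):
    """P(null score <= distance) for a query of the given length."""
    return calibration.pvalue(distance, query_length)


def estimate_pi0(pvalues: np.ndarray, lam: float = 0.5) -> float:
    """Storey estimate of the null proportion: #{p > lam} / ((1 - lam) m),
    clamped to (1/m, 1]."""
    p = np.asarray(pvalues, dtype=np.float64)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    m = p.size
    pi0 = np.count_nonzero(p > lam) / ((1.0 - lam) * m)
    return float(min(1.0, max(pi0, 1.0 / m)))


def qvalues(pvalues: np.ndarray, pi0: float = 1.0) -> np.ndarray:
    """pi0-adjusted Benjamini-Hochberg q-values.

    q_i = min over j with p_j >= p_i of (pi0 * m * p_j / rank_j), clamped
    to at most 1; monotone in p and invariant to input order.
    """
    p = np.asarray(pvalues, dtype=np.float64)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return np.array([])
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    raw = pi0 * m * ranked / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(raw[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q
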