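# Methods

This note documents the model implemented by `protembed`, its
assumptions, the parameters that matter, what the synthetic benchmark
does and does not emulate, and the numerical choices made where the
design was genuinely open.

## Feature representation

A protein domain `x` is represented relative to a fixed database
`x_1..x_n` by the transformed E-values of a pairwise search program (the
*teacher*):

    f(x)_j = exp(-E(x, x_j) / sigma)

- `sigma` (default 100, dimensionless like the E-value): the width of the
  exponential transfer. Larger sigma keeps weakly similar pairs in the
  profile; the default makes E-values of a few hundred effectively zero.
  sigma is recorded in model provenance because embeddings built with
  different sigma are not comparable.
- Weights below 1e-12 are stored as exact zeros, which implements the
  teacher's "no detectable similarity" sentinel deterministically and
  keeps the matrix sparse (most protein pairs are unrelated).
- By default each nonempty row is normalized to sum to 1, making the
  matrix row-stochastic — the transition matrix of a random walk on the
  protein similarity network. The raw exponential is available via
  `normalize=False`; both are defensible, the stochastic form is the
  package default.
- Duplicate (query, target) hits keep the minimum E-value, matching how
  iterated searches report their strongest evidence.
- Database construction filters sequences shorter than 6 residues, longer
  than 10,000, or consisting entirely of the ambiguity code "X".

Queries never seen in training are represented by their teacher scores
against the *training* ids, so the feature dimension n never changes.

## Embedding and retrieval

`phi(x) = W f(x)` with `W` a dense `d x n` matrix. Retrieval is an
explicit linear scan: all database points are precomputed and ranked by
ascending `||phi(q) - phi(x)||_p`.

- `p` defaults to 1. The training update applies the componentwise sign
  function, which is exactly the subgradient of the 1-norm; other p >= 1
  are supported with the generalized gradient, but the sign form is the
  reference path.
- Ties in distance are broken by ascending lexicographic target id, so
  rankings — and therefore ROC scores — are run-to-run identical.

## Training

Tuples `(q, p+, p-)` are sampled online: `q` uniform over proteins with
at least one positive, `p+` uniform over targets with teacher E-value
*strictly* below 0.1, `p-` uniform over the database. Degenerate draws
(`p- = q` or `p- = p+`) are rejected and resampled; a zero-distance
negative makes the hinge trivially maximal and carries no signal. No
attempt is made to filter accidental true homologs from the negatives —
they are rare and act as label noise the hinge tolerates.

The loss per tuple is `max(0, margin - D(q,p-) + D(q,p+))`; a violated
tuple moves only the feature-support columns of W (cost proportional to
the nonzeros times d). `W` is initialized i.i.d. N(0, 1) from the config
seed; identical (seed, config, inputs) give bit-identical models.

Defaults: `margin = 1` (the conventional margin-ranking normalization —
the loss scale is coupled to the learning rate, so only their ratio
matters), `lr = 0.05`, `d = 250`, 150 epochs of 20,000 tuples for a
profile-search teacher; `lr = 0.02`, `d = 100` suit a more sensitive
HMM-HMM teacher. The tests and the acceptance script use `d = 10` and
30 epochs x 2,000 tuples, which saturate the 96-sequence benchmark; the
full-scale defaults are intended for real databases.

### Structural auxiliary tasks

Three multitask modes share the embedding:

- `class`: a centroid matrix `C` holds one learned column per fold and
  per superfamily. A labeled example's category is a 2-hot bit vector
  `y(x)` (its fold and superfamily columns), and the hinge
  `max(0, margin + D(phi(x), C y(x)) - D(phi(x), C y(x')))` pushes each
  protein toward its own centroid and away from the centroid of a second
  randomly drawn labeled example, updating both W and C. When the two
  examples share fold and superfamily the two distance terms coincide and
  the subgradients cancel exactly — the step is a no-op.
- `rank_scop`: extra ranking tuples whose positives are same-superfamily
  pairs.
- `rank_struct`: extra ranking tuples whose positives are pairs whose
  structure-alignment score is *strictly* above a cutoff (default 2.0,
  the conventional significance threshold of that score scale). The
  boundary case is excluded; scores exactly at the cutoff are treated as
  not similar.

The multitask objective is the sum of the main and auxiliary losses;
per-tuple SGD on a sum is equivalent in expectation to interleaving
draws, so the implementation alternates one auxiliary step per main step
(`aux_mix` controls the ratio). An epoch is always counted in main-task
tuples.

## Score calibration

Decoy sequences are sampled from a third-order Markov chain fitted to the
database (additive pseudocount 1; initial state from the empirical
distribution of leading 3-mers; ambiguity codes resolved uniformly over
their standard expansions so the alphabet stays at 20). Each decoy is
scored like a query — teacher scores, feature vector, embedding — and its
null score is the distance to its nearest database point, the quantity a
retrieval threshold actually acts on (`kth`-nearest is a config away).

Null scores are collected per query-length bin (geometric edges, factor
1.5 from 25 residues, 1000 decoys per bin) because longer queries collect
more teacher hits and embed differently.

The null is a *mixture*: decoys for which the teacher reports nothing
embed exactly to the origin, so one score value carries a point mass
(about 20% under the benchmark defaults), while the rest form a
continuous distribution whose left (significant) tail is well described
by a two-parameter Weibull. The p-value is therefore computed additively:

    p(x) = (atom mass strictly below x) + (continuous fraction) * F_cont(x)

where `F_cont` is the Weibull CDF (maximum-likelihood fit to the lowest
`tail_fraction`, default 25%, of the continuous component; location fixed
at 0) below the tail cutoff, and the interpolated empirical CDF of the
continuous samples above it. The parametric tail is what gives meaningful
p-values far beyond empirical resolution. At an atom the CDF jumps;
callers may pass a seeded generator to apply the randomized probability
integral transform across the jump, which makes null p-values exactly
uniform — the package's own uniformity test does this. Without a
generator the conservative upper edge is returned.

Multiple testing: Storey's pi0 with the single-lambda estimator
(lambda = 0.5, clamped to (1/m, 1]) — the simplest variant, chosen over
spline smoothing for transparency — then q-values by the
Benjamini-Hochberg step-up including the pi0 multiplicative factor. The
default reporting threshold is q <= 0.01.

## Evaluation

Targets are labeled relative to a query's structural categories: same
superfamily = positive, different fold = negative, same fold but
different superfamily = ignored (homology uncertain). The optional
family-exclusion mode also ignores same-family targets, so only remote
homologs count. ROC-n is the area under the ROC curve truncated at the
n-th false positive, normalized by (n x #positives); queries with no
positives have undefined scores and are excluded from means, with the
count reported. Paired method comparisons use the Wilcoxon signed-rank
test (exact null below 15 non-zero differences without ties, normal
approximation with tie correction otherwise).

Pooled ROC curves merge the scores of all queries into one ranking —
meaningful precisely because distances live in a single embedding space
and are comparable across queries.

## The synthetic benchmark

`fixtures.generate_fixture` builds a hierarchy of 4 folds x 2
superfamilies x 2 families x 6 members (96 sequences, lengths 60-120):
one random ancestral sequence per superfamily, family ancestors obtained
by substituting 40% of residues, members by substituting 15%. Mutations
are substitution-only — the teacher is simulated, so alignment realism
(indels, position-specific rates) adds nothing the method would see.

The simulated teacher draws log10 E-values from tiered normals
(family: mean -8, sd 2, detected with probability 0.95; superfamily:
-3, 1.5, 0.90; same fold: 0.5, 1.0, 0.30; unrelated: 1.5, 1.0, 0.02;
self-hits at 1e-10). Every E(q, t) is a pure function of (seed, q, t),
so scoring any subset of targets reproduces the same values — the
property that lets held-out queries and decoys be scored consistently.
Under these defaults ~87% of within-superfamily ordered pairs score
below the 0.1 positive threshold, ~2% of cross-fold pairs are reported
at all, and the feature matrix is ~83% zeros. Structural scores are
normal per tier (within superfamily: 4.0 +/- 1.0, mostly above the 2.0
cutoff; within fold: 1.0 +/- 0.5; unrelated: 0.2 +/- 0.3, floored at 0).

What passing tests on this benchmark show: the optimization recovers
planted neighborhood structure from noisy, sparse, tiered similarity
scores; the calibration is self-consistent against its own null; the
auxiliary tasks do not hurt. What they cannot show: performance on real
databases, where similarity tiers overlap far more, detection is
length- and composition-dependent, and the hierarchy is deeper and
heavily unbalanced. The benchmark's holdout keeps at least one
same-superfamily member in training for every test query, so every
retrieval problem posed has an answer.

## Numerical choices and degenerate inputs

- Sparse updates touch only feature-support columns; overlapping
  supports accumulate sequentially within a step.
- The 1-norm subgradient at exactly zero coordinates is taken as 0
  (numpy's sign convention); gradient tests exclude these
  measure-zero neighborhoods.
- Non-finite training loss aborts with a diagnostic rather than
  continuing from a diverged state (remedy: lower the learning rate).
- Weibull fitting requires >= 200 null samples and a non-degenerate
  continuous tail of >= 20 points; all-equal samples are an error.
- Classical (Torgerson) MDS is used for neighborhood maps: double-center
  the squared distances, take the top-2 eigendirections, fix each axis
  sign by its largest-magnitude coordinate. It is deterministic — the
  reason it was preferred over stress-minimizing variants — and exact
  for planar Euclidean configurations; for 1-norm embedding distances it
  is a least-squares approximation. The coordinates TSV is the canonical
  output; rendered images are cosmetic.
- Queries whose length falls outside every calibration bin use the
  nearest bin by midpoint.

## Known limitations

- The embedding is defined on single-domain sequences; multidomain
  queries violate the transitivity the metric space assumes and are out
  of scope.
- The teacher is consumed from files; running search programs is not
  part of the package.
- Negatives are never screened against the teacher, so a small fraction
  of training tuples are mislabeled by construction.
- The q-value pipeline estimates pi0 per query from its own p-values;
  for very small databases that estimate is coarse.
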