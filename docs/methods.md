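# Methods

## Problem setting

Given binary substructure fingerprints for compounds (D bits; presence or
absence of predefined chemical substructures, e.g. the 881 PubChem keys) and
binary domain fingerprints for proteins (D' bits; e.g. 4,137 PFAM domains),
the task is to classify compound-protein pairs as interacting or not and to
say *why*: which substructure-domain co-occurrences drive the prediction.

Each pair (C, P) is represented by the tensor product of the two
fingerprints, a D*D'-dimensional binary vector whose active entries are the
pairs (substructure of C, domain of P). A linear classifier over this space
is interpretable — each weight speaks about one substructure-domain
association — but the space is large (3,644,697 features for the dimensions
above) and the number of pairs is the product of the compound and protein
counts, so the direct route does not scale. The package's core is a sketching
pipeline that compresses pair fingerprints before classification while
keeping both accuracy and interpretability.

## Compact fingerprints

A pair's feature set S ⊆ {0, ..., DD'−1} is sketched by minwise hashing:
for ℓ seeded random permutations π_k of the universe, the k-th coordinate is
t_k = min π_k(S). Two sets agree on a coordinate with probability equal to
their Jaccard similarity J, so the expected Hamming distance between two
signatures is ℓ(1−J).

Raw minhash values cost a machine word each; an additional hashing stage
maps every value through a random hash h into [0, N) with N ≪ M. Identical
values still always collide, distinct ones collide with probability 1/N,
giving the per-coordinate collision law

    P(collision) = 1 − ((N−1)/N)(1−J),

monotone in J and saturating to J as N grows; N = 2^8 is already within
~4·10⁻³ of the limit for any J, which is why small bin counts lose nothing.
Each hashed value is one-hot expanded into an N-bit block and the ℓ blocks
are concatenated: an ℓN-bit vector with exactly ℓ ones, the compact
fingerprint. Inner products of compact fingerprints form a positive
semidefinite Gram matrix and track Jaccard similarity, so a linear model on
compact fingerprints behaves like a (nonlinear) Jaccard-kernel classifier
while training at linear-model cost.

### Hash realizations and seeding

Permutations are explicit seeded uniform permutations of [0, M) (exact
theory) for M up to 2^24; for larger universes an injective affine map
x ↦ (a_k x + b_k) mod p (p the smallest prime ≥ M, a_k ≠ 0) stands in,
flagged as `universal_hash` mode. Tests and desk-scale runs use explicit
mode.

The additional hash h is a seeded 64-bit bit-mixing hash (the splitmix64
finalizer) reduced mod N. A fixed 2-universal affine map was tried first
and rejected: affine maps are pairwise-uniform over their seed draw, but a
*single fixed* draw shares its linear structure across all ℓ coordinates —
minhash values concentrate near zero with repetitive differences — and the
realized collision rate deviates from the law above by several binomial
standard errors. The mixer behaves like an independent uniform random
function per input and restores the law empirically.

Everything derives from one master seed: permutation k is seeded from
(master_seed, k), h from (master_seed, ℓ). A family is therefore fully
reconstructible from its five defining fields (ℓ, M, N, master_seed, mode),
which is what makes model serialization and weight recovery possible
without storing any M-sized table. Empty feature sets (a compound or
protein with no active bit) have no defined minhash; encoding raises a
typed error naming the pair, with an explicit opt-in to drop such pairs —
a silent sentinel bin would bias collision statistics.

## Classification

The classifier is a linear score f(x) = wᵀx (optionally plus a bias,
default off: compact rows have constant sum ℓ, which largely absorbs an
intercept) trained by minimizing

    R(w) + C Σ_i max(1 − y_i f(x_i), 0)

with R(w) = ‖w‖₁ (L1, sparsity-inducing) or ½‖w‖₂² (L2). The squared L2
form and the placement of C on the loss follow the convention of
liblinear-style solvers; C sweeps such as 10⁻⁵...10⁵ are interpreted in
that convention. Applied to compact fingerprints these are MH-L1SVM /
MH-L2SVM; applied to raw tensor features, the direct L1SVM / L2SVM.

L2+hinge is trained with scikit-learn's `LinearSVC` (liblinear dual
coordinate descent; deterministic given its seed). L1+hinge is solved as
an exact linear program (w = u − v, one slack per example) with SciPy's
HiGHS backend — at desk scale this yields the true optimum, and exact
zeros in the L1 path. Both routes are cross-checked against a shipped
solver-independent subgradient reference (`reference_subgradient`, pilot
step-size selection plus a long diminishing-step run) and against a
term-by-term objective evaluator. Non-convergence within the iteration
budget is reported on the model (`converged=False`), never silently.

## Weight recovery

A weight on compact coordinate k·N + b speaks for every tensor feature
whose k-th minhash image hashes to bin b. Inverting the chain (h is
one-to-many, π_k is a bijection) and averaging over blocks gives

    recovered[i] = (1/ℓ) Σ_k w[k·N + h(π_k(i))].

The averaging divides by ℓ — each block contributes exactly one weight per
tensor feature, making the estimator's scale independent of ℓ; dividing by
h-preimage multiplicities instead would entangle the estimate with the
(irrelevant) bin occupancy. The forward composition above equals the
literal inverse-mapping procedure (enumerate h⁻¹ of each bin, pull back
through π_k⁻¹), which is kept in the test suite as an explicit oracle; no
inverse tables are ever stored. By default recovery enumerates only tensor
features observed in a reference dataset's pair sets; full [0, DD')
enumeration is available but wasteful. Ranked output decomposes each index
as (substructure, domain) with ties broken by ascending index.

Recovery fidelity (correlation with direct-mode weights) grows with ℓ;
at ℓ = 10 individual top features are noisy while the planted set is
already enriched at the top of the ranking, and at ℓ = 30 the enrichment
is strong (see the rank-sum tests).

## Evaluation protocols

Pair-wise 5-fold CV splits labeled pairs at random (optionally stratified
by label) — the "fill in missing interactions among known entities"
scenario. Block-wise 5-fold CV splits compounds and proteins separately;
test fold i is compound fold i × protein fold i, training uses only pairs
with both entities outside fold i, and straddling pairs are used in
neither — the cold-start scenario. The diagonal pairing is the default;
the full grid of fold combinations is available through
`FoldAssignment.train_test_indices(protein_fold=...)`. Fold sizes differ
by at most one element, remainders going to the lowest-numbered folds.

Negatives are drawn uniformly without replacement from non-positive grid
cells at a chosen positive:negative ratio (unlabeled pairs are treated as
negatives, the standard assumption for gold standards that list only
interactions). AUC is the Mann-Whitney statistic with midrank ties,
identical to the trapezoidal ROC area. The hyper-parameter C is chosen as
the grid value with the best mean test-fold AUC, reproducing the printed
protocol; users wanting unbiased estimates should nest the selection in an
inner split.

## Synthetic data

The generator emulates the statistical shape of screening data within the
classifier's own hypothesis class: i.i.d. Bernoulli fingerprint bits,
a planted sparse weight vector over tensor features (random signs, fixed
magnitude), pair scores summing planted weights over active tensor
features, and labels from thresholding those scores. Defaults: 100
compounds × 80 proteins, D = 50, D' = 40, bit densities 0.15 / 0.12, 40
planted features (2% of the 2,000-feature universe), effect magnitude 1,
label noise 0.02, positive fraction 0.2. The densities are chosen so a
typical entity carries a handful of active bits, as curated fingerprints
do, and — importantly — so that the labeling threshold falls strictly
inside the informative part of the score distribution: with much sparser
bits most pairs carry no planted feature at all and the positive class
becomes partly arbitrary, destroying the learnable signal.

Two non-obvious rules:

* the pre-noise positive count is n(target − noise)/(1 − 2·noise), so the
  *expected* positive fraction after symmetric label flipping equals the
  target (requires noise < target);
* entities drawing no bits are redrawn; score ties at the threshold are
  broken by a seeded jitter, so generation is fully deterministic given
  the seed.

The generator does not model substructure co-occurrence structure, domain
grammar, or entity-degree heterogeneity; passing tests show the method
behaves as its theory predicts under its own assumptions, not that it
will reach any particular accuracy on real screening data.

## Problem sizes and numerical choices

Desk-scale study conditions used throughout the tests: the default
generator config above with balanced (1:1) negative subsampling
(~3,200 pairs); compact fingerprints at ℓ = 10·⌈log₂ M⌉ = 110 with N
capped at M for accuracy comparisons (ℓ = 10 is the operating point for
hundreds of thousands of training pairs, and undersketches at a few
thousand); ℓ = 10, N = 2⁸ — the saturation bin count — with C = 1 for the
L1-vs-L2 sparsity comparison; C grids spanning 10⁻³...10 (the best value
sat at 10⁻²...1 throughout, so the tails of the printed 10⁻⁵...10⁵ sweep
are omitted from routine runs). Stochastic laws are asserted within three
binomial standard errors at ℓ = 5,000 coordinates; solver agreement is
asserted at 10⁻¹² (exact identities), 0.5–2% (objective vs reference), or
rank-level (recovery enrichment, rank-sum p < 0.01). All randomness flows
from explicit integer seeds; reruns are bit-identical.

## Known limitations

* Explicit permutations hold an (ℓ, M) table in memory; beyond M ≈ 2²⁴
  the affine `universal_hash` approximation must be used, which slightly
  perturbs the exact minhash theory (it is injective but not a uniform
  random permutation).
* The L1 linear program scales to thousands of examples and features, not
  to millions; at full screening scale an L1-capable stochastic solver
  would be needed.
* C selection by test-fold AUC reproduces the published protocol but is
  optimistically biased; nest the selection for honest estimates.
* Blockwise folds can produce single-class test blocks on small or
  imbalanced data; such folds score NaN and are excluded from the mean.
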