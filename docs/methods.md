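# Methods

## The model and the constructions

`splitrank` scores candidate phylogenetic splits from site-pattern data
using the rank properties of two matrix constructions.

For taxa `X` with `|X| = t` and a `k`-state alphabet (DNA: `k = 4`,
states ordered A, C, G, T), a sequence alignment reduces to a table of
site-pattern weights — counts summing to the sequence length `L`, or
exact probabilities summing to 1 computed on a model tree.  For a split
`A|B` of `X`:

* The **flattening** `Flat_{A|B}` is the `k^|A| × k^|B|` matrix whose
  `(I, J)` entry is the weight of the pattern interleaving sub-pattern
  `I` on `A` with `J` on `B`.  On exact probabilities from a tree with
  invertible (generic) edge matrices, its rank is `k` when `A|B` is
  displayed by the tree and `k^p` otherwise, where `p` is the split's
  parsimony score (minimum state changes for the two-state character
  assigning one state per side).
* The **subflattening** `Subflat_{A|B}` is the
  `(|A|(k−1)+1) × (|B|(k−1)+1)` submatrix of the flattening after the
  pattern tensor has been conjugated axis-wise by a Hadamard-type matrix
  `H` (first row all ones, other rows summing to zero).  The conjugation
  sends every row-stochastic matrix `M` to `H M H⁻¹ = [[1, v], [0, z]]`,
  which concentrates all substitution information in the rows/columns
  whose index tuples have at most one non-trivial transformed
  coordinate.  Its generic rank is `k` for displayed splits and
  `(k−1)p + 1` otherwise.

Closeness to rank `k` is measured by the **split score**

    SplitScore(F) = sqrt(1 − Σ_{i≤k} σ_i² / ‖F‖²),

with `σ_i` the largest singular values and `‖F‖` the Frobenius norm — by
the Eckart–Young theorem, the normalised distance from `F` to the
nearest rank-`k` matrix.  Displayed splits score ~0 at exact
probabilities; the score is invariant to positive rescaling, so counts
need not be normalised.

## Conventions

* **Taxon order** is the lexicographic order of labels; it fixes the
  pattern-tuple layout and all matrix indexing, so matrices are
  bit-comparable across runs.  Flattening row indices encode the
  sub-pattern on the sorted `A` side in base `k`, first taxon most
  significant.  Subflattening row `r = (k−1)a + j` applies row `j` of
  `H` to the `a`-th taxon of `A`; row 0 is the all-trivial component,
  so entry `(0, 0)` is the total weight.
* **Edge matrices are row-stochastic** with entry `(parent, child)`.
  Growing a pendant edge therefore transforms a flattening as
  `(⊗ left)ᵀ F (⊗ right)`; in the transposed, distribution-acting
  convention this is the familiar `(⊗ left) F (⊗ right)ᵀ` rule.  Both
  are implemented by `apply_pendant_action` in the package convention.
* **Branch lengths** are expected substitutions per site under the
  unit-rate normalisation; `jc_matrix(d, k)` has off-diagonal entries
  `(1/k)(1 − exp(−k d/(k−1)))`.  Any sub-model of the general Markov
  model is supported by assigning explicit matrices per edge.  The root
  distribution defaults to uniform.
* **`H` for `k = 4`** is the Kronecker square of `[[1, 1], [1, −1]]`.
  The submatrix-selection rule ("at most one non-trivial transformed
  coordinate") reproduces the 3×3 binary worked example and the
  `(3|A|+1) × (3|B|+1)` DNA dimensions; equivalent alternative
  selections exist in the literature, and any user-supplied transform
  with the required row structure is accepted.

## Numerical choices

* **Sparse flattenings.** Flattenings are stored sparsely (one nonzero
  per distinct pattern; a 16-taxon flattening has `4^16 ≈ 4.2` billion
  nominal entries but at most `L` nonzeros).  When even a CSR
  row-pointer array would be large, the matrix stays in coordinate
  form.  Singular values are computed after *compacting* to the nonzero
  rows and columns — deleting zero rows/columns preserves singular
  values exactly — so a score on a `4^10 × 4^10` flattening costs one
  dense SVD of at most an `L × L` block.  A truncated iterative SVD
  (`scipy.sparse.linalg.svds`) is used only if the compact block itself
  is large.  Subflattenings are never sparse and always use dense SVD.
* **Subflattening fast path.** Each entry is a weighted sum over
  observed patterns of at most two non-trivial `H` coefficients, so
  construction is `O(#patterns × output size)` and never touches the
  `k^t` tensor.  Per-state coefficient columns of `H` are memoised in a
  process-wide cache keyed by `(k, H, state)` and reused across splits
  and datasets; the memoised and unmemoised paths agree bit-for-bit.  A
  dense reference (`subflattening_oracle`) that transforms the full
  flattening and extracts the submatrix exists for testing only.
* **Rank tolerance.** `numerical_rank` counts singular values above a
  relative tolerance, default `1e-8`.  At exact probabilities the
  "zero" singular values sit at ~1e−16 relative, so the classification
  is robust; but products of many strongly-mixing edge matrices can
  push genuinely nonzero singular values toward the tolerance, which is
  why the generic-rank test fixtures use diagonally dominant random
  matrices (substitution probability below 1/2 per branch — the
  biologically ordinary regime).
* **Score floor and ties.** The score is a square root of a
  cancellation-prone difference; its floating-point floor is
  ~sqrt(machine epsilon) ≈ 1.5e−8.  Quartet decisions flag ties at an
  absolute score difference of 1e−6, safely above that floor and far
  below any phylogenetically meaningful score difference.
* **Degenerate inputs.** All-zero matrices have no defined score
  (error) and rank 0.  Scoring every flattening of more than 16 taxa is
  refused with guidance (the subflattening path and explicit split
  lists remain available).  Star trees (zero internal edge) are valid
  inputs everywhere; the greedy assembler returns a flagged partial
  result when fewer than `t − 3` compatible splits exist.

## Combinatorial machinery

Split parsimony uses a unit-cost Sankoff dynamic programme over an
arbitrary rooting — exact for any node degree (polytomies included) and
independent of root placement.  Shared edges between the two induced
subtrees are counted by testing, per edge, whether both endpoints'
components contain taxa of both sides.  Tree automorphisms are
enumerated as graph self-isomorphisms (networkx `GraphMatcher`); on a
tree each automorphism restricts to a unique leaf permutation, and
orbits of the action on splits follow directly.  This one mechanism is
exact at every size the package handles, which is why it replaced a
two-regime (brute-force / canonical-form) plan.

The greedy tree assembler scans splits in ascending score order and
keeps each split compatible with those already kept, stopping at
`t − 3` non-trivial splits.  It deliberately reproduces the naive
algorithm whose biases the experiments quantify — comparing scores
across split sizes is statistically dubious (scores are biased upward
for balanced splits), and the assembler warns accordingly.

## The simulation experiments

All experiments simulate under Jukes–Cantor and are pure functions of
(configuration, seed); per-replicate streams derive from the master
seed by the counter scheme `default_rng([seed, stream, replicate])`, so
any replicate reproduces in isolation.

* **Six-taxon score distributions.** The balanced six-taxon caterpillar
  (cherries (0,1) and (4,5); non-trivial displayed splits 01|2345,
  012|345, 0123|45; all lengths equal, default 0.1 or 0.8) has
  automorphism group of order 8 and exactly 9 orbits of non-trivial
  splits, so scores are computed for the 9 orbit representatives over
  multinomial draws (defaults: 1000 replicates at 1000 and 10000 bp).
* **Shared-edges regression.** 20 replicates of the same topology with
  every edge length drawn uniformly (defaults 0.1–1; a second regime
  0.5–1), exact probabilities, subflattening scores.  Linear models on
  all subsets of {shared edges, parsimony, split size} are compared by
  adjusted R².  The pool is the 25 non-trivial splits: trivial splits
  are displayed by every tree and score ~0 regardless of branch
  lengths, so including them would inflate the fit with rows that carry
  no information about falseness (an `include_trivial` switch exists).
* **Split balance.** One 500-bp alignment simulated site-wise down a
  20-taxon tree (default: a balanced 20-leaf topology, lengths 0.05 —
  the experiment accepts any 20-taxon tree), 190 splits sampled per
  size 2–10 (190 = C(20,2), the size of the smallest class), scored
  with both methods; reported as per-size means and the relative
  increase from size 2 to size 10.
* **Long-branch attraction.** Four quartet presets (all-short,
  opposite-long, cherry-long, all-long; short/long = 0.05/0.5, second
  regime 0.1/1.0; internal edge always short) over sequence lengths
  100–1000 bp in steps of 100, 100 replicates each, scoring the
  fraction recovering the generating split.  The star-tree variant
  (internal length zero, long pendants on opposite leaves) measures
  pure bias: an unbiased method picks the long-pair split 1/3 of the
  time.
* **Sliding window.** Windows of 10000 bp advancing 1000 bp along a
  4-taxon alignment, each window scored for its best quartet split per
  method; designed for scans such as detecting chromosomal inversions
  in the *Anopheles gambiae* species complex alignment.

## What the generator emulates — and what it does not

Simulated data are i.i.d. sites from a single tree under homogeneous
Jukes–Cantor (or user-assigned general Markov matrices), matching the
theory's assumptions exactly.  Real alignments violate several of them:
rate variation across sites, substitution-process heterogeneity across
lineages, gene-tree discordance under the coalescent, alignment error
and missing data.  Passing tests therefore certify the constructions
and their relative biases under the stated model, not performance on
real data; the theory is expected (but not here verified) to degrade
gracefully under the coalescent.

## Problem sizes in the shipped test suite

Unit tests run the experiments at reduced replicate counts; the
acceptance suite runs the worked examples exactly, the rank theorems on
50 random 4–6-taxon trees, the fast-path/oracle comparison on 200
random quartet datasets, the regression at its full design (20
replicates per regime), and the balance and star-tree bias checks at
full design (190 splits per size at 500 bp; 100 star replicates at
1000 bp).  These sizes keep the whole suite under a minute on one CPU
while preserving every qualitative conclusion.

## Known limitations

* Adjusted R² of the shared-edges regression varies by a few
  percentage points across seeds (20 random trees is a small design);
  the 0.5–1 regime typically lands in the low-to-mid 80s.
* The greedy assembler inherits the split-balance bias it warns about;
  quartet-amalgamation strategies would avoid it but are out of scope.
* Squangle-based quartet scoring, Eriksson's bottom-up SVD tree builder
  and SAQ scoring are not implemented; coalescent simulation, rate
  heterogeneity and amino-acid alphabets are out of scope.
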