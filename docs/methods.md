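# Methods

## Problem

Collections of phylogenetic trees on a common taxon set — bootstrap
replicates, Bayesian posterior samples, gene-tree sets — are usually
summarised by consensus methods, which can hide large, strongly supported
subtrees: one unstable ("rogue") taxon is enough to collapse every node it
wanders across. An alternative summary is the *frequent agreement subtree*
(FAST): a tree `S` is present in an input tree `T` when `T` restricted to
the leaves of `S` equals `S`, and `S` is a FAST at cutoff `γ ∈ (0, 1]` when
it is present in at least a fraction `γ` of the `m` input trees. The object
of interest is the *maximum* FAST (MFAST), the FAST with the most taxa.
Exact MFAST search is intractable beyond toy sizes (the leaf-subset lattice
is exponential, and maximum-agreement-subtree computation is already
NP-hard for many variants), so this package implements a three-phase
seed-and-extend heuristic that scales to hundreds of taxa and trees,
together with the tooling needed to validate it: a planted-subtree
generator, an exhaustive small-instance oracle, and a closed-form model of
seed-capture probability.

## The heuristic

**Phase 1 — seed generation.** For each cell of a grid of seed sizes `k`
and contraction counts `c`, every clade (node-rooted subtree) with exactly
`k + c` leaves in every input tree is expanded into all `C(k+c, c)` ways of
contracting `c` of its taxa. The resulting `k`-taxon subtrees are
deduplicated by canonical form; each survivor's frequency is counted over
all `m` trees, and those below `γ` are dropped. Seeds are kept sorted by
decreasing frequency (ties: canonical string), each carrying a bitset of
supporting tree indices. The inclusive threshold (`freq ≥ γ`) follows the
FAST definition. The same topology found in several grid cells is kept
once; its frequency does not depend on the discovering cell.

**Phase 2 — seed combination.** Two subtrees both present in a *reference
tree* `T` combine into the restriction of `T` to the union of their leaf
sets. Distinct reference trees can induce distinct combined topologies, so
candidate references (trees supporting both operands) are scanned in
ascending index order; after a topology is formed, every tree containing it
is *marked* and never used as a reference for this pair again — any such
tree would reproduce the same topology — and the scan stops once fewer
unmarked candidates remain than the quorum `⌈γm⌉`, because supports of
distinct alternatives on one leaf set are disjoint, so no topology found
later could still be frequent. The acceptance cutoff starts at `γ` and
ratchets to the best accepted frequency; among equally frequent
alternatives the first in reference order is kept. Because combining can
only shrink frequency (`freq(A ⊕ B) ≤ min(freq A, freq B)`; both operands
are present in the combination), attempts whose support-bitset intersection
is already below the quorum are skipped outright.

Growth proceeds from a starting seed, repeatedly choosing the next seed by
one of two strategies: *in-order* (highest remaining frequency) or
*minimum overlap* (fewest taxa shared with the current subtree, frequency
as tie-break, canonical string last) — the latter grows faster since the
combined size is `|L1| + |L2| − |L1 ∩ L2|`, and is the default. Every seed
is tried as a starting point; the largest result wins, with later starts
beating earlier ones on equal size. Two time-cutoff controls are provided:
`sample_fraction` draws a uniform random subsample of starting seeds, and
`max_starts` truncates the start loop after the first N (most frequent)
seeds. Truncation is the deterministic form of the cutoff and is what the
desk-scale replications use: frequent-seed lists are sorted, and seeds of a
genuinely shared subtree concentrate in the high-frequency prefix, so a
prefix is a far more reliable start pool than a uniform sample of equal
size. The full seed list always remains available for growth regardless of
how starts are limited.

**Phase 3 — post-processing to maximality.** Seeds can miss taxa entirely
(no small clade captures them) and combination can reject seeds carrying
extra conflicting taxa, so the phase-2 result need not be maximal. Each
absent taxon is offered as a one-leaf tree through the same
reference-marking search (candidate references = supporters of the current
subtree; cutoff resets to `γ` per taxon). Taxa are swept in lexicographic
order, accepted placements take effect immediately, and full sweeps repeat
until one adds nothing; a single pass does not guarantee maximality, the
fixpoint does, and the suite certifies it by re-testing every absent taxon
on the final result. The best `top_k` phase-2 candidates are all
post-processed and the largest final subtree is reported, which guards
against a start that grows into a large but badly placed candidate.

The result is a *maximal* FAST — no single taxon can be added without
dropping below `γ` — and is reported as "a possible MFAST": global
optimality is not claimed, and the test suite checks it only against the
exhaustive oracle on small instances.

## Synthetic data

`generate_dataset` plants a known answer: a uniform random rooted binary
tree on `n′` of the `n` taxa is embedded in `round(m·f)` *bearing* trees
("round" is round-half-up); the remaining `n − n′` taxa are inserted one at
a time, each with probability `ε` onto a uniformly chosen edge *inside* the
minimal clade spanning the embedded taxa (scattering its taxa apart — the
noise that hurts seed generation) and otherwise onto a uniform edge outside
it, including the root edge. Background trees are unconstrained uniform
random trees, re-drawn (capped at 1000 attempts) if they contain the
embedded subtree by chance, so the realized frequency is exactly
`round(m·f)/m`. Random topologies come from sequential uniform-edge
attachment: a tree with `q` leaves has `2q − 1` attachment edges (counting
the root edge) and `R(q+1) = R(q)·(2q−1)`, so induction gives every
labelled topology equal probability; the suite checks the `n = 3` case
against the exact 1/3 split.

What the generator does *not* emulate: real bootstrap trees are correlated
(they come from one data matrix), their shared subtrees are nested rather
than a single planted clade, and their shapes are not uniform. Passing the
planted-recovery tests therefore demonstrates that the search machinery
finds a signal that is present at frequency `f` against unstructured noise;
it does not by itself calibrate performance on empirical bootstrap sets.

## Seed-capture probability model

Under the idealisation that input trees are independent uniform topologies,
the model multiplies: `R(n) = (2n−3)!/(2^(n−2)(n−2)!)` topologies on `n`
leaves (with `R(1) = R(2) = 1` so the boundary `k + c = n` is defined);
`NU(k, c)` clade shapes of size `k + c` containing a fixed `k`-subtree,
computed by the recursion `NU(k, 0) = 1`, `NU(k,c) = NU(k,c−1)·2·(k+c−2)`;
`P(n,k,c) = NU(k,c)·R(n−(k+c)+1)/R(n)` for one tree;
`P(n,k,c,m) = 1−(1−P(n,k,c))^m` over a collection; and
`P(n,k,c,m,h) = 1−(1−P(n,k,c,m))^(h−k+1)` over the `NS(h,k) ≥ h−k+1`
distinct `k`-subtrees of an `h`-taxon target. Small-`n` evaluation is exact
rational arithmetic; large `n` goes through log-gamma (stable at
`n = 1000`), and the two agree to 10+ significant digits where both run.

Three caveats, kept deliberately rather than silently "fixed":

* `NU`'s recursion counts attachments of each added leaf to `2(k+c−2)`
  edges, which excludes the clade-root edge; direct enumeration of 3-leaf
  clades containing a fixed cherry gives 3 where the recursion gives
  `NU(2,1) = 2`.
* For `c = 0` the model is an exact event probability (a fixed clade
  topology inside a uniform tree) and the suite validates it against
  Monte-Carlo draws from the generator; for `c > 0` it is not exact (at
  `n = 5, k = 3, c = 2` the formula gives 24/105 where the true probability
  is 1/3), so Monte-Carlo validation is pinned at `c = 0`.
* The composed model cannot make the success probability approach 1 at
  target sizes around 20% of the tree: the ratio `R(n−(k+c)+1)/R(n)` decays
  like `(2n)^−(k+c−1)`, so at `k + c = 8`, `n` in the hundreds and
  `m ≤ 1000` the composed probability is ~1e−12. The qualitative
  monotonicities (in `m`, in `h`, and in `c` at fixed `k + c`) all hold and
  are tested; the near-certainty claim is asserted in the acceptance suite
  and fails there by design, as a faithful record of what these formulas
  produce.

## Numerical and implementation choices

* **Canonical form.** Children ordered by smallest descendant leaf label;
  the canonical newick string doubles as the dedup key and equality test.
  Presence is restriction + canonical comparison, never contraction-order
  search.
* **Exact rational thresholds.** Frequencies are `Fraction`s and the quorum
  is `⌈γm⌉` computed in rational arithmetic, so a binary-float cutoff like
  0.7 never rounds the required support count up by one.
* **Fast induced topologies.** Each collection lazily builds, per tree, the
  dense matrix of pairwise leaf LCA depths plus the depth-first leaf order
  (`m·n²` int16 entries, built once in O(n²) per tree; skipped above 2·10⁸
  entries). A rooted triplet `((a,b),c)` is present in a tree iff
  `D[a,b] > D[a,c]`, which turns phase-1 frequency counting into vectorised
  comparisons — a seed of size ≤ 8 is the conjunction of its rooted
  triplets, evaluated with `np.minimum.reduceat` over chunked columns. The
  restriction of a tree to `s` leaves is rebuilt from the index in O(s²)
  worst case (sort leaves by depth-first position, then the induced tree is
  the cartesian tree of adjacent-pair LCA depths, whose range minima are
  unique in binary trees), independent of `n`; a pure recursive O(n)
  restriction is the reference implementation and the fallback, and the
  suite asserts the two agree on random subsets.
* **Support bitsets.** Seed and candidate supports are Python integers used
  as bitmasks; intersection pruning, quorum checks and marking are popcount
  and bitwise operations.
* **Determinism.** All randomness (generator, start subsampling, the
  optional randomized sweep orders) flows from explicit integer seeds; the
  same inputs and seed give byte-identical reports. Ties are broken by
  canonical string everywhere the algorithm is otherwise indifferent.
* **Degenerate inputs.** Single-leaf trees parse and serialise; duplicate
  labels, non-binary nodes (without the resolve flag), differing leaf sets
  across a collection, empty restriction sets and out-of-range clade sizes
  all raise typed errors naming the offending line or taxon.

## Replication problem sizes and defaults

The desk-scale replications use: planted datasets with `n = 100`,
`m = 100`, `n′ = 15`, `f = 0.8`, `γ = 0.7` at 20% and 60% noise (10
datasets each), the full seed grid `k ∈ {3,4,5}`, `c ∈ {0..5}`, the
minimum-overlap strategy with `max_starts = 60` and `top_k = 10`; and one
larger run at `n = 500`, `m = 50`, `n′ = 75` with `k = 3`, `c ≤ 1`,
`max_starts = 10`. The 60%-noise protocol keeps the full grid because
high noise scatters the planted taxa out of small clades — exactly the
regime where larger `k + c` earns its cost — while 20%-noise recovery
also succeeds with `k = 3`, `c ≤ 2`. Library defaults mirror the grid
(`γ = 0.7`, `k ∈ {3,4,5}`, `c ∈ {0..5}`, minoverlap, all seeds as starts).

## Known limitations

* Rooted, bifurcating trees only; multifurcating input is either rejected
  or resolved arbitrarily (label-ordered), and unrooted semantics are out
  of scope.
* All trees must share one taxon set; there is no partial-overlap
  frequency semantics.
* The heuristic offers no approximation guarantee; phase 2 is greedy and
  phase 3 is a local (single-taxon) optimum certified maximal, not maximum.
* The probability model inherits the printed-formula caveats above and
  assumes uniform, independent tree topologies, which real tree sets are
  not.
* The exhaustive oracle is capped at 14 taxa by design.
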