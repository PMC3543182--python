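# mfast — mining maximum frequent agreement subtrees

Collections of phylogenetic trees over one taxon set — bootstrap
replicates, Bayesian posterior samples, gene trees — are usually condensed
into a consensus tree. Consensus support values collapse quickly when even
a single unstable taxon wanders between replicates, hiding subtrees that
are in fact shared almost everywhere. `mfast` looks for those subtrees
directly: given `m` rooted bifurcating trees `T = {T_1, …, T_m}` on `n`
taxa and a frequency cutoff `γ ∈ (0, 1]`, it searches for a largest tree
`S` such that

```
freq(S, T) = |{ i : T_i restricted to leaves(S) equals S }| / m  ≥  γ,
```

a *maximum frequent agreement subtree* (MFAST). At `γ = 1` this is the
classical maximum agreement subtree; smaller `γ` tolerates a minority of
disagreeing trees. Exact search is hopeless beyond toy sizes, so `mfast`
uses a three-phase heuristic that handles hundreds of taxa and trees:

1. **Seeds** — every way of contracting `c` taxa from a `(k+c)`-leaf clade
   of an input tree yields a `k`-leaf candidate; deduplicate, count
   frequencies, keep those ≥ `γ` (defaults `k ∈ {3,4,5}`, `c ∈ {0..5}`).
2. **Combination** — grow a subtree by repeatedly merging it with seeds,
   using input trees that contain both parts as topology references,
   keeping the most frequent alternative that stays ≥ `γ` (minimum-overlap
   seed order by default).
3. **Post-processing** — add absent taxa one at a time wherever a
   placement stays ≥ `γ`, sweeping to a fixpoint; the result is maximal.

The package also ships the supporting cast used to validate the heuristic:
a synthetic-data generator that plants a known subtree in a controlled
fraction of trees with tunable noise, an exhaustive oracle for instances up
to 14 taxa, and a closed-form model of the probability that phase 1
captures part of a hidden subtree.

## Worked example

Plant a 10-taxon subtree in 80% of 20 trees of 40 taxa, with 30% of the
remaining taxa inserted inside the planted clade as noise, then mine at
`γ = 0.7`:

```
$ mfast synth --n 40 --m 20 --f 0.8 --nprime 10 --epsilon 0.3 \
              --rng-seed 11 --out-prefix demo
$ mfast find --trees demo.trees.nwk --gamma 0.7 --k 3,4,5 --c 0,1,2,3 \
             --max-starts 20 --top-k 3 --rng-seed 0
{
  "mfast_newick": "(((t12,t31),((((t13,t36),(t33,t39)),((t29,t30),t40)),t21)),t24);",
  "size": 11,
  "frequency": 0.75,
  "support_indices": [0, 1, 2, 4, 6, 7, 8, 10, 11, 13, 14, 16, 17, 18, 19],
  "phase2_newick": "((((t13,t36),(t33,t39)),((t29,t30),t40)),t24);",
  "phase2_size": 8,
  "n_seeds": 148,
  ...
}
```

Reading the report: 148 frequent seeds survived phase 1; phase 2 assembled
8 of them into a subtree present in ≥ 70% of trees; phase 3 grew it to 11
taxa, present in 15 of the 20 trees (frequency 0.75). The planted truth
(`demo.truth.nwk`) was
`((t12,t31),((((t13,t36),(t33,t39)),((t29,t30),t40)),t21));` — all 10
planted taxa are inside the reported subtree, plus `t24`, a noise taxon
that happened to land in the same place often enough to clear the cutoff.

The same machinery is available as a library:

```python
from mfast import SynthParams, generate_dataset, find_mfast

ts, truth = generate_dataset(SynthParams(n=40, m=20, f=0.8, n_prime=10,
                                         epsilon=0.3, rng_seed=11))
report = find_mfast(ts, gamma=0.7, k_values=[3, 4, 5], c_values=[0, 1, 2, 3],
                    max_starts=20, top_k=3)
best = report.best
print(best.size, float(best.freq), truth.leaves <= best.tree.leaves)
```

Other entry points: `mfast oracle` (exhaustive ground truth, ≤ 14 taxa),
`mfast prob` (seed-capture probability grids as CSV), and the module-level
API (`parse_newick_collection`, `pooled_frequent_seeds`,
`minoverlap_combine`, `grow_to_maximal`, `brute_force_mfast`, …).

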