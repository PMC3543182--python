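"""Exhaustive ground truth for small instances.

``brute_force_mfast`` certifies the true maximum frequent agreement subtree
size by scanning taxon subsets in decreasing size.  For a fixed leaf set X
any agreement subtree on X must equal some input tree's restriction to X, so
the best achievable frequency for X is the modal restricted topology's share
— this replaces enumeration of all subtree shapes and keeps the cost at
O(2^n * m) instead of super-exponential.  Guarded at n <= 14.

``naive_best_combination`` is the unoptimised reference-tree search (no
marking, no early exit); the optimised phase-2 search must agree with it,
which the test suite checks on random instances.
"""

from __future__ import annotations

from collections import Counter
from fractions import Fraction
from itertools import combinations

from .combine import FastCandidate
from .seed_gen import Seed, gamma_count
from .tree_core import PhyloTree, TreeSet, _restrict_node, frequency


def brute_force_mfast(
    ts: TreeSet, gamma: float, max_n: int = 14
) -> tuple[int, list[PhyloTree]]:
    """Exact MFAST size and all witness topologies of that size."""
    if ts.n > max_n:
        raise ValueError(
            f"n = {ts.n} exceeds the brute-force guard ({max_n}); "
            "use the three-phase heuristic instead"
        )
    need = gamma_count(gamma, ts.m)
    taxa = sorted(ts.taxa)
    for size in range(ts.n, 1, -1):
        witnesses: list[PhyloTree] = []
        for subset in combinations(taxa, size):
            keep = frozenset(subset)
            counts = Counter(
                _restrict_node(t.node, keep)[0] for t in ts.trees
            )
            for topo, cnt in counts.items():
                if cnt >= need:
                    witnesses.append(PhyloTree(topo, _canonical=True))
        if witnesses:
            return size, witnesses
    # any 2-taxon subtree has the unique rooted topology, frequency 1
    return 1, [PhyloTree(t) for t in taxa[:1]]


def naive_best_combination(
    current: FastCandidate,
    addition: PhyloTree | Seed,
    ts: TreeSet,
    gamma: float,
    floor_freq=None,
) -> FastCandidate | None:
    """Try *every* shared reference tree, no marking or early exit."""
    if isinstance(addition, Seed):
        add_tree = addition.tree
        add_support = addition.support
    else:
        add_tree = addition
        _, add_support = frequency(addition, ts)
    cur_support = current.support
    refs = sorted(cur_support & add_support)
    union = current.tree.leaves | add_tree.leaves
    floor = Fraction(gamma) if floor_freq is None else Fraction(floor_freq)

    best: FastCandidate | None = None
    cutoff = floor
    for ref in refs:
        topo = _restrict_node(ts.trees[ref].node, union)[0]
        combined = PhyloTree(topo, _canonical=True)
        freq, support = frequency(combined, ts)
        if freq >= cutoff and (best is None or freq > best.freq):
            mask = 0
            for i in support:
                mask |= 1 << i
            best = FastCandidate(combined, freq, mask)
            cutoff = freq
    return best
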