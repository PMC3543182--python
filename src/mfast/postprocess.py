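"""Phase 3 — growing a frequent agreement subtree to maximality.

Every taxon absent from the current subtree is treated as a one-leaf tree and
offered to the same reference-marking search used in phase 2: each supporting
tree of the current subtree proposes a placement (its restriction to the
enlarged leaf set), placements are grouped into alternatives, and the best
alternative reaching the cutoff gamma is accepted.  Taxa are swept in
lexicographic order and full sweeps repeat until nothing can be added, at
which point the result is maximal: no single-taxon extension is frequent.
"""

from __future__ import annotations

from fractions import Fraction

from .combine import FastCandidate, _best_combo
from .seed_gen import gamma_count
from .tree_core import PhyloTree, TreeSet


def add_taxon(
    current: FastCandidate,
    taxon: str,
    ts: TreeSet,
    gamma: float,
    audit: list | None = None,
) -> FastCandidate | None:
    """Best frequent placement of one new taxon, or None.

    The acceptance cutoff resets to gamma for each taxon and then ratchets to
    the accepted placement's frequency while alternatives are scanned.
    """
    if taxon in current.tree.leaves:
        raise ValueError(f"taxon {taxon!r} is already in the subtree")
    if taxon not in ts.taxa:
        raise KeyError(f"taxon {taxon!r} is not in the collection's taxon set")
    leaf = PhyloTree(taxon, _canonical=True)
    all_trees_mask = (1 << ts.m) - 1  # every tree contains every taxon
    need = gamma_count(gamma, ts.m)
    return _best_combo(
        current, leaf, all_trees_mask, ts, need, Fraction(gamma), audit
    )


def grow_to_maximal(
    start: FastCandidate,
    ts: TreeSet,
    gamma: float,
    audit: list | None = None,
) -> FastCandidate:
    """Sweep absent taxa (lexicographic) until a full sweep adds nothing."""
    if start.freq < Fraction(gamma):
        raise ValueError("starting subtree is below the frequency cutoff")
    cur = start
    while True:
        added = False
        for taxon in sorted(ts.taxa - cur.tree.leaves):
            res = add_taxon(cur, taxon, ts, gamma, audit)
            if res is not None:
                cur = res
                added = True
        if not added:
            return cur
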