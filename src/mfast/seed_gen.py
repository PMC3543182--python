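"""Phase 1 — seed generation.

A *seed* is a small subtree (k taxa) obtained from a clade of k + c taxa of
some input tree by c contractions.  Every clade of the right size in every
tree is expanded into all C(k+c, c) contraction outcomes; outcomes are
deduplicated by canonical form, their frequencies over the collection are
counted, and everything below the frequency cutoff gamma is discarded.  The
surviving seeds — each carrying its exact frequency and the bitset of
supporting tree indices — are the building blocks of phase 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations

import numpy as np

from .tree_core import (
    PhyloTree,
    TreeSet,
    canonical_form,
    enumerate_clades,
    is_present,
    restrict,
)


def gamma_count(gamma: float, m: int) -> int:
    """Smallest support count whose frequency is >= gamma (exact ceil(gamma*m)).

    Computed in exact rational arithmetic so binary-float cutoffs such as 0.7
    never round the threshold up by a spurious ulp.
    """
    return math.ceil(Fraction(gamma) * m)


@dataclass(frozen=True)
class SeedParams:
    """One cell of the seed-extraction grid plus the frequency cutoff."""

    k: int
    c: int
    gamma: float

    def __post_init__(self):
        if self.k < 2:
            raise ValueError("seed size k must be >= 2")
        if self.c < 0:
            raise ValueError("contraction count c must be >= 0")
        if not 0 < self.gamma <= 1:
            raise ValueError("gamma must be in (0, 1]")


@dataclass
class Seed:
    """A frequent subtree with its frequency and supporting-tree bitset."""

    tree: PhyloTree
    freq: Fraction
    support_mask: int
    k: int = 0
    c: int = 0

    @property
    def support(self) -> frozenset[int]:
        return frozenset(_bit_indices(self.support_mask))

    @property
    def size(self) -> int:
        return self.tree.size

    @property
    def canonical(self) -> str:
        return canonical_form(self.tree)


def _bit_indices(mask: int):
    while mask:
        low = mask & -mask
        yield low.bit_length() - 1
        mask ^= low


def potential_seeds(ts: TreeSet, k: int, c: int) -> list[PhyloTree]:
    """All deduplicated k-taxon contraction outcomes of (k+c)-taxon clades."""
    if k + c > ts.n:
        raise ValueError(f"k + c = {k + c} exceeds tree size n = {ts.n}")
    seen: dict = {}
    for tree in ts.trees:
        for clade in enumerate_clades(tree, k + c):
            leaves = sorted(clade.leaves)
            for dropped in combinations(leaves, c):
                sub = restrict(clade, clade.leaves.difference(dropped))
                seen.setdefault(sub.node, sub)
    return list(seen.values())


def _triplet_of(tree: PhyloTree) -> tuple[str, str, str]:
    """Decompose a 3-leaf tree into (cherry a, cherry b, outgroup c)."""
    left, right = tree.node
    if isinstance(left, str):
        out, cherry = left, right
    else:
        out, cherry = right, left
    return cherry[0], cherry[1], out


_VECTOR_SIZE_MAX = 8  # triplet decomposition up to C(8,3) = 56 columns/seed
_CHUNK_COLUMNS = 250_000


def _pair_depths(node, depth: int, out: dict) -> list[str]:
    if isinstance(node, str):
        return [node]
    left = _pair_depths(node[0], depth + 1, out)
    right = _pair_depths(node[1], depth + 1, out)
    for a in left:
        for b in right:
            key = (a, b) if a <= b else (b, a)
            out[key] = depth
    return left + right


def _seed_triplets(tree: PhyloTree) -> list[tuple[str, str, str]]:
    """All rooted triplets displayed by a small tree.

    A binary leaf-labelled tree is determined by its triplet set, and
    restriction commutes with triplet extraction, so a subtree is present in
    an input tree iff every one of its triplets is.  The cherry of each
    triplet is the pair with the strictly deepest LCA, read off a one-pass
    pairwise-depth table.
    """
    depths: dict = {}
    _pair_depths(tree.node, 0, depths)

    def d(a, b):
        return depths[(a, b)] if a <= b else depths[(b, a)]

    out = []
    for a, b, c in combinations(sorted(tree.leaves), 3):
        dab, dac, dbc = d(a, b), d(a, c), d(b, c)
        if dab > dac and dab > dbc:
            out.append((a, b, c))
        elif dac > dab and dac > dbc:
            out.append((a, c, b))
        else:
            out.append((b, c, a))
    return out


def _mask_from_column(col: np.ndarray) -> int:
    mask = 0
    for i in np.flatnonzero(col):
        mask |= 1 << int(i)
    return mask


def _frequencies(
    ts: TreeSet, pots: list[PhyloTree]
) -> list[tuple[PhyloTree, int, int]]:
    """(tree, support_count, support_mask) per potential seed.

    Seeds of modest size are counted through the vectorised LCA-depth index
    when it is available: each seed becomes the conjunction of its rooted
    triplets, evaluated in chunked fancy-indexing passes.  Oversized seeds or
    oversized collections fall back to per-tree presence tests.
    """
    out: list[tuple[PhyloTree, int, int]] = []
    idx = ts.triplet_index()
    if idx is not None:
        vec = [p for p in pots if 3 <= p.size <= _VECTOR_SIZE_MAX]
        generic = [p for p in pots if not 3 <= p.size <= _VECTOR_SIZE_MAX]
    else:
        vec = []
        generic = pots

    pos = 0
    while pos < len(vec):
        # grow a chunk of seeds whose total triplet count stays bounded
        chunk: list[PhyloTree] = []
        trips: list[tuple[str, str, str]] = []
        starts: list[int] = []
        while pos < len(vec) and len(trips) < _CHUNK_COLUMNS:
            p = vec[pos]
            starts.append(len(trips))
            trips.extend(_seed_triplets(p))
            chunk.append(p)
            pos += 1
        pres = idx.presence_matrix(trips)  # (m, n_triplets)
        seed_pres = np.minimum.reduceat(pres, np.array(starts), axis=1)
        counts = seed_pres.sum(axis=0)
        for j, p in enumerate(chunk):
            out.append((p, int(counts[j]), _mask_from_column(seed_pres[:, j])))

    for p in generic:
        if p.size == 2:
            # the unique rooted topology on two leaves is present everywhere
            out.append((p, ts.m, (1 << ts.m) - 1))
            continue
        mask = 0
        count = 0
        for i, tree in enumerate(ts.trees):
            if is_present(p, tree):
                mask |= 1 << i
                count += 1
        out.append((p, count, mask))
    return out


def _collect_potentials(
    ts: TreeSet, cells: list[tuple[int, int]]
) -> dict:
    """Potential seeds across a (k, c) grid, deduplicated globally.

    Returns canonical node -> (PhyloTree, k, c) with the first discovering
    cell recorded; frequencies are identical whichever cell found the seed.
    """
    seen: dict = {}
    for k, c in cells:
        if k + c > ts.n:
            raise ValueError(f"k + c = {k + c} exceeds tree size n = {ts.n}")
        for tree in ts.trees:
            for clade in enumerate_clades(tree, k + c):
                leaves = sorted(clade.leaves)
                for dropped in combinations(leaves, c):
                    sub = restrict(clade, clade.leaves.difference(dropped))
                    if sub.node not in seen:
                        seen[sub.node] = (sub, k, c)
    return seen


def _filter_sort(
    ts: TreeSet, seen: dict, gamma: float
) -> list[Seed]:
    need = gamma_count(gamma, ts.m)
    pots = [entry[0] for entry in seen.values()]
    seeds = []
    for tree, count, mask in _frequencies(ts, pots):
        if count >= need:
            _, k, c = seen[tree.node]
            seeds.append(Seed(tree, Fraction(count, ts.m), mask, k=k, c=c))
    seeds.sort(key=lambda s: (-s.freq, s.canonical))
    return seeds


def frequent_seeds(ts: TreeSet, params: SeedParams) -> list[Seed]:
    """Seeds of one (k, c) cell with frequency >= gamma, sorted by
    decreasing frequency (ties broken by canonical string)."""
    seen = _collect_potentials(ts, [(params.k, params.c)])
    return _filter_sort(ts, seen, params.gamma)


def pooled_frequent_seeds(
    ts: TreeSet,
    k_values,
    c_values,
    gamma: float,
) -> list[Seed]:
    """Union of frequent seeds over the full (k, c) grid, deduplicated."""
    cells = [(k, c) for k in k_values for c in c_values]
    if not cells:
        raise ValueError("empty (k, c) grid")
    for k, c in cells:
        SeedParams(k, c, gamma)  # validate
    seen = _collect_potentials(ts, cells)
    return _filter_sort(ts, seen, gamma)


def write_seed_tsv(seeds: list[Seed], path) -> None:
    """Dump a seed list as TSV: canonical_newick, k, c, frequency, support_count."""
    with open(path, "w") as fh:
        fh.write("canonical_newick\tk\tc\tfrequency\tsupport_count\n")
        for s in seeds:
            fh.write(
                f"{s.canonical}\t{s.k}\t{s.c}\t{float(s.freq):.6g}\t"
                f"{s.support_mask.bit_count()}\n"
            )
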