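"""Rooted, bifurcating, leaf-labelled trees and the primitives built on them.

Two container types underpin the whole package: :class:`PhyloTree`, a rooted
binary tree whose leaves carry unique taxon labels, and :class:`TreeSet`, an
ordered collection of such trees over one shared taxon universe.  All
topology-level operations — contraction of a leaf, restriction to a leaf
subset, the induced-subtree ("present in") test, frequency of a subtree in a
collection, and clade enumeration — live here.

A tree is stored internally as a nested pair structure in *canonical order*:
every internal node is a 2-tuple whose children are sorted by their smallest
descendant leaf label, and every leaf is its label string.  Two trees are
topology-identical as rooted leaf-labelled trees exactly when their canonical
structures (equivalently, their canonical newick strings) are equal, which
makes structural equality, hashing and deduplication cheap.

Newick text is read through dendropy; branch lengths, internal-node labels and
quoted labels are accepted and discarded, keeping only topology and leaf
names.  Multifurcating input is rejected unless ``resolve_polytomies=True``
is passed, in which case polytomies are expanded into a deterministic
(label-ordered, left-combed) binary structure.
"""

from __future__ import annotations

import sys
from fractions import Fraction
from typing import Iterable, Iterator, Union

import dendropy
import numpy as np

# Nested-tuple recursion depth tracks tree depth, which can approach the leaf
# count for comb-like trees; raise the interpreter limit once so trees with a
# few thousand taxa are safe.
if sys.getrecursionlimit() < 50_000:
    sys.setrecursionlimit(50_000)

#: A node of the nested representation: a leaf label, or a pair of nodes.
Node = Union[str, tuple]


class NewickParseError(ValueError):
    """Malformed newick input (unbalanced parentheses, duplicate label, ...)."""


class TreeStructureError(ValueError):
    """The tree violates the rooted-binary structural contract."""


class TaxonSetError(ValueError):
    """Trees in one collection do not share an identical leaf-label set."""


def _canon(node: Node) -> tuple[Node, str]:
    """Return ``(canonical_node, min_label)`` for an arbitrary nested node."""
    if isinstance(node, str):
        return node, node
    left, lm = _canon(node[0])
    right, rm = _canon(node[1])
    if lm <= rm:
        return (left, right), lm
    return (right, left), rm


def _collect_labels(node: Node, out: list) -> None:
    if isinstance(node, str):
        out.append(node)
    else:
        _collect_labels(node[0], out)
        _collect_labels(node[1], out)


def _restrict_node(node: Node, keep) -> tuple[Node, str] | None:
    """Restriction of a canonical node to ``keep``; returns (node, min label).

    Degree-2 nodes produced by pruning are suppressed on the way up, and
    children are re-ordered so the result is again canonical.  Returns None
    when no leaf of ``keep`` occurs below ``node``.
    """
    if isinstance(node, str):
        return (node, node) if node in keep else None
    left = _restrict_node(node[0], keep)
    right = _restrict_node(node[1], keep)
    if left is None:
        return right
    if right is None:
        return left
    ln, lm = left
    rn, rm = right
    if lm <= rm:
        return (ln, rn), lm
    return (rn, ln), rm


def _to_newick(node: Node, out: list) -> None:
    if isinstance(node, str):
        out.append(node)
    else:
        out.append("(")
        _to_newick(node[0], out)
        out.append(",")
        _to_newick(node[1], out)
        out.append(")")


class PhyloTree:
    """A rooted bifurcating phylogenetic tree with uniquely labelled leaves.

    Parameters
    ----------
    node
        Nested pair structure (leaf = label string, internal = 2-tuple).
        It is canonicalized on construction unless ``_canonical=True``.
    """

    __slots__ = ("node", "leaves")

    def __init__(self, node: Node, _canonical: bool = False):
        if not _canonical:
            node, _ = _canon(node)
        labels: list[str] = []
        _collect_labels(node, labels)
        leaves = frozenset(labels)
        if len(leaves) != len(labels):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise NewickParseError(f"duplicate leaf label(s): {', '.join(dupes)}")
        self.node = node
        self.leaves = leaves

    # -- basic protocol ---------------------------------------------------

    @property
    def size(self) -> int:
        """Number of taxa (tree size is counted in leaves throughout)."""
        return len(self.leaves)

    def __eq__(self, other) -> bool:
        return isinstance(other, PhyloTree) and self.node == other.node

    def __hash__(self) -> int:
        return hash(self.node)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        s = self.newick()
        if len(s) > 60:
            s = s[:57] + "..."
        return f"PhyloTree({s!r}, size={self.size})"

    # -- serialisation ----------------------------------------------------

    @classmethod
    def from_newick(cls, text: str, *, resolve_polytomies: bool = False) -> "PhyloTree":
        return parse_newick(text, resolve_polytomies=resolve_polytomies)

    def newick(self) -> str:
        """Canonical newick string (no branch lengths), ending in ';'."""
        out: list = []
        _to_newick(self.node, out)
        out.append(";")
        return "".join(out)


def write_newick(tree: PhyloTree) -> str:
    """Serialize ``tree`` as a canonical newick string."""
    return tree.newick()


def canonical_form(tree: PhyloTree) -> str:
    """Deterministic string equal between two trees iff they are topology-identical.

    Children are ordered by smallest descendant leaf label, so the canonical
    form doubles as the package-wide deduplication key.
    """
    return tree.newick()


def _from_dendropy(nd, resolve_polytomies: bool):
    children = nd.child_nodes()
    if not children:
        label = nd.taxon.label if nd.taxon is not None else nd.label
        if label is None or label == "":
            raise NewickParseError("leaf without a label")
        return str(label)
    if len(children) == 1:
        # unary node (e.g. redundant parentheses) - suppress silently
        return _from_dendropy(children[0], resolve_polytomies)
    subs = [_from_dendropy(ch, resolve_polytomies) for ch in children]
    if len(subs) == 2:
        return (subs[0], subs[1])
    if not resolve_polytomies:
        raise TreeStructureError(
            f"multifurcating node with {len(subs)} children "
            "(pass resolve_polytomies=True to expand deterministically)"
        )
    # deterministic binary expansion: order children by smallest descendant
    # label and fold into a left comb
    keyed = sorted((_canon(s) for s in subs), key=lambda p: p[1])
    node = keyed[0][0]
    for sub, _ in keyed[1:]:
        node = (node, sub)
    return node


def parse_newick(
    text: str, *, resolve_polytomies: bool = False, _line: int | None = None
) -> PhyloTree:
    """Parse a single newick tree (topology only).

    Branch lengths, internal labels and quoted labels are parsed and
    discarded.  Raises :class:`NewickParseError` for malformed input and
    :class:`TreeStructureError` for non-binary nodes (unless resolved).
    """
    where = f"line {_line}: " if _line is not None else ""
    text = text.strip()
    if not text.endswith(";"):
        raise NewickParseError(f"{where}newick tree must end in ';'")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
            rooting="force-rooted",
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickParseError(f"{where}malformed newick: {exc}") from None
    try:
        node = _from_dendropy(dtree.seed_node, resolve_polytomies)
        return PhyloTree(node)
    except (NewickParseError, TreeStructureError) as exc:
        raise type(exc)(f"{where}{exc}") from None


def contract(tree: PhyloTree, taxon: str) -> PhyloTree:
    """Remove one leaf and suppress the degree-2 node it leaves behind."""
    if taxon not in tree.leaves:
        raise KeyError(f"taxon {taxon!r} not in tree")
    if tree.size < 2:
        raise ValueError("cannot contract the last leaf of a tree")
    return restrict(tree, tree.leaves - {taxon})


def restrict(tree: PhyloTree, keep: Iterable[str]) -> PhyloTree:
    """Subtree induced by the leaf subset ``keep``.

    Equals the result of contracting every other taxon in any order.
    """
    keep = frozenset(keep)
    if not keep:
        raise ValueError("cannot restrict to an empty leaf set")
    extra = keep - tree.leaves
    if extra:
        raise KeyError(f"taxa not in tree: {sorted(extra)}")
    if keep == tree.leaves:
        return tree
    node, _ = _restrict_node(tree.node, keep)
    return PhyloTree(node, _canonical=True)


def is_present(sub: PhyloTree, tree: PhyloTree) -> bool:
    """True iff ``sub`` is obtainable from ``tree`` by contractions.

    Implemented as restriction to ``sub``'s leaves plus canonical comparison.
    """
    if not sub.leaves <= tree.leaves:
        return False
    if sub.leaves == tree.leaves:
        return sub.node == tree.node
    restricted = _restrict_node(tree.node, sub.leaves)
    return restricted is not None and restricted[0] == sub.node


def frequency(sub: PhyloTree, ts: "TreeSet") -> tuple[Fraction, frozenset[int]]:
    """Fraction m'/m of trees in which ``sub`` is present, plus the index set."""
    support = frozenset(i for i, t in enumerate(ts.trees) if is_present(sub, t))
    return Fraction(len(support), ts.m), support


def _clades(node: Node, size: int, out: list) -> int:
    if isinstance(node, str):
        if size == 1:
            out.append(node)
        return 1
    count = _clades(node[0], size, out) + _clades(node[1], size, out)
    if count == size:
        out.append(node)
    return count


def enumerate_clades(tree: PhyloTree, size: int) -> list[PhyloTree]:
    """All clades (subtrees rooted at a node) with exactly ``size`` leaves.

    The whole tree counts as a clade when ``size`` equals the tree size.
    """
    if not 1 <= size <= tree.size:
        raise ValueError(f"clade size {size} out of range [1, {tree.size}]")
    nodes: list[Node] = []
    _clades(tree.node, size, nodes)
    return [PhyloTree(n, _canonical=True) for n in nodes]


class _TripletIndex:
    """Vectorised presence tests for 3-taxon subtrees over a whole TreeSet.

    For every tree i a dense matrix ``D[i, a, b]`` holds the depth of the
    lowest common ancestor of leaves a and b.  In a binary tree the rooted
    triplet ``((a,b),c)`` is present iff ``D[a,b] > D[a,c]`` (the cherry is
    the unique pair with the strictly deepest LCA), which turns phase-1
    frequency counting into a couple of fancy-indexing operations.
    """

    # memory guard: m * n^2 int16 entries
    MAX_ENTRIES = 200_000_000

    def __init__(self, ts: "TreeSet"):
        self.taxa = sorted(ts.taxa)
        self.ids = {t: i for i, t in enumerate(self.taxa)}
        n, m = len(self.taxa), ts.m
        self.D = np.zeros((m, n, n), dtype=np.int16)
        self.leaf_order = np.zeros((m, n), dtype=np.int32)
        for i, tree in enumerate(ts.trees):
            dfs_leaves = self._fill(self.D[i], tree.node, 0)
            self.leaf_order[i][dfs_leaves] = np.arange(n)

    def _fill(self, D: np.ndarray, node: Node, depth: int) -> list[int]:
        if isinstance(node, str):
            return [self.ids[node]]
        left = self._fill(D, node[0], depth + 1)
        right = self._fill(D, node[1], depth + 1)
        D[np.ix_(left, right)] = depth
        D[np.ix_(right, left)] = depth
        return left + right

    def induced_node(self, i: int, labels) -> Node:
        """Canonical induced topology of tree ``i`` on a leaf subset.

        Leaves are sorted by their depth-first position in tree i; the
        induced tree is then the (binary) cartesian tree of the adjacent-pair
        LCA depths, built in O(s^2) worst case for s leaves — independent of
        the full tree size.  Equals the canonical restriction node.
        """
        order = self.leaf_order[i]
        ids = sorted((self.ids[lab] for lab in labels), key=order.__getitem__)
        if len(ids) == 1:
            return self.taxa[ids[0]]
        D = self.D[i]
        depths = [int(D[ids[j], ids[j + 1]]) for j in range(len(ids) - 1)]
        labs = [self.taxa[t] for t in ids]
        return _cartesian_build(labs, depths, 0, len(labs) - 1)[0]

    def presence_matrix(self, triplets: list[tuple[str, str, str]]) -> np.ndarray:
        """Boolean (m, len(triplets)) matrix; triplet = (cherry a, cherry b, out c)."""
        a = np.array([self.ids[t[0]] for t in triplets])
        b = np.array([self.ids[t[1]] for t in triplets])
        c = np.array([self.ids[t[2]] for t in triplets])
        return self.D[:, a, b] > self.D[:, a, c]


def _cartesian_build(labs, depths, lo, hi):
    """Subtree over leaves lo..hi; the unique minimum adjacent-LCA depth in
    the range is the root junction.  Returns (canonical node, min label)."""
    if lo == hi:
        return labs[lo], labs[lo]
    p = lo
    mn = depths[lo]
    for q in range(lo + 1, hi):
        if depths[q] < mn:
            mn = depths[q]
            p = q
    ln, lm = _cartesian_build(labs, depths, lo, p)
    rn, rm = _cartesian_build(labs, depths, p + 1, hi)
    if lm <= rm:
        return (ln, rn), lm
    return (rn, ln), rm


class TreeSet:
    """An ordered collection of trees over one shared taxon universe."""

    def __init__(self, trees: Iterable[PhyloTree]):
        self.trees: list[PhyloTree] = list(trees)
        if not self.trees:
            raise TaxonSetError("a TreeSet needs at least one tree")
        taxa = self.trees[0].leaves
        for i, t in enumerate(self.trees[1:], start=2):
            if t.leaves != taxa:
                missing = sorted(taxa - t.leaves)[:3]
                extra = sorted(t.leaves - taxa)[:3]
                raise TaxonSetError(
                    f"tree {i} has a different leaf set than tree 1 "
                    f"(e.g. missing {missing}, extra {extra})"
                )
        self.taxa: frozenset[str] = taxa
        self._tripidx: _TripletIndex | None = None
        self._tripidx_tried = False

    @property
    def m(self) -> int:
        return len(self.trees)

    @property
    def n(self) -> int:
        return len(self.taxa)

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self) -> Iterator[PhyloTree]:
        return iter(self.trees)

    def __getitem__(self, i: int) -> PhyloTree:
        return self.trees[i]

    @classmethod
    def from_newick(cls, text: str, *, resolve_polytomies: bool = False) -> "TreeSet":
        return parse_newick_collection(text, resolve_polytomies=resolve_polytomies)

    def to_newick(self) -> str:
        return "".join(t.newick() + "\n" for t in self.trees)

    def triplet_index(self) -> _TripletIndex | None:
        """Shared LCA-depth index, or None when it would not fit in memory."""
        if not self._tripidx_tried:
            self._tripidx_tried = True
            if self.m * self.n * self.n <= _TripletIndex.MAX_ENTRIES:
                self._tripidx = _TripletIndex(self)
        return self._tripidx


def parse_newick_collection(
    text: str, *, resolve_polytomies: bool = False
) -> TreeSet:
    """Parse a multi-line newick string (one tree per non-empty line)."""
    trees = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        trees.append(
            parse_newick(line, resolve_polytomies=resolve_polytomies, _line=lineno)
        )
    return TreeSet(trees)
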