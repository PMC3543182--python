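"""Synthetic tree collections with a known embedded agreement subtree.

The generator emulates bootstrap-style tree collections in which a common
subtree is shared by a controlled fraction of the trees:

1. draw a random rooted binary tree on n' of the n taxa — the embedded
   subtree (the planted "true" answer);
2. build round(m*f) *bearing* trees by inserting the remaining n - n' taxa
   one at a time: with probability epsilon on a uniformly random edge
   *inside* the minimal clade spanning the embedded taxa (noise that
   scatters the embedded taxa apart), otherwise on a uniform edge outside
   that clade;
3. build the remaining trees as unconstrained random trees over all n taxa,
   re-drawn if they happen to contain the embedded subtree, so the realized
   frequency of the embedded subtree is exactly round(m*f)/m.

Random topologies use sequential uniform-edge attachment (every edge,
including the edge above the root, is equally likely), which draws uniformly
from the R(n) rooted binary leaf-labelled topologies.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .tree_core import PhyloTree, TreeSet, is_present


@dataclass(frozen=True)
class SynthParams:
    """Generator parameters: n taxa per tree, m trees, embedded-subtree
    frequency f, embedded size n_prime, noise fraction epsilon."""

    n: int
    m: int
    f: float
    n_prime: int
    epsilon: float
    rng_seed: int = 0

    def __post_init__(self):
        if not 2 <= self.n_prime <= self.n:
            raise ValueError("need 2 <= n_prime <= n")
        if not 0 <= self.f <= 1:
            raise ValueError("f must be in [0, 1]")
        if not 0 <= self.epsilon <= 1:
            raise ValueError("epsilon must be in [0, 1]")
        if self.m < 1:
            raise ValueError("m must be >= 1")


class _MNode:
    __slots__ = ("parent", "left", "right", "label")

    def __init__(self, label=None):
        self.parent = None
        self.left = None
        self.right = None
        self.label = label


def _attach(node: "_MNode", label: str, root: "_MNode"):
    """Subdivide the edge above ``node`` (the root edge when node is the
    root) and hang a new leaf there.  Returns (new_internal, new_leaf, root)."""
    internal = _MNode()
    leaf = _MNode(label)
    parent = node.parent
    internal.left = node
    internal.right = leaf
    node.parent = internal
    leaf.parent = internal
    if parent is None:
        root = internal
    elif parent.left is node:
        parent.left = internal
        internal.parent = parent
    else:
        parent.right = internal
        internal.parent = parent
    return internal, leaf, root


def _to_node(mnode: "_MNode"):
    if mnode.label is not None:
        return mnode.label
    return (_to_node(mnode.left), _to_node(mnode.right))


def _build_random(labels: list[str], rng: random.Random):
    """Mutable random tree by uniform-edge attachment; returns (root, nodes)."""
    root = _MNode(labels[0])
    nodes = [root]
    for label in labels[1:]:
        target = nodes[rng.randrange(len(nodes))]
        internal, leaf, root = _attach(target, label, root)
        nodes.append(internal)
        nodes.append(leaf)
    return root, nodes


def random_tree(labels, rng: random.Random) -> PhyloTree:
    """Uniform random rooted binary topology on the given labels."""
    labels = list(labels)
    if len(labels) < 2:
        raise ValueError("need at least 2 labels")
    root, _ = _build_random(labels, rng)
    return PhyloTree(_to_node(root))


def _bearing_tree(
    embedded: PhyloTree,
    extra_labels: list[str],
    epsilon: float,
    rng: random.Random,
) -> PhyloTree:
    """One tree that contains the embedded subtree by construction."""

    def clone(node):
        if isinstance(node, str):
            return _MNode(node)
        mn = _MNode()
        mn.left = clone(node[0])
        mn.right = clone(node[1])
        mn.left.parent = mn
        mn.right.parent = mn
        return mn

    root = clone(embedded.node)
    clade_root = root  # minimal clade spanning the embedded taxa

    def subtree_nodes(mn):
        out = []
        stack = [mn]
        while stack:
            x = stack.pop()
            out.append(x)
            if x.label is None:
                stack.append(x.left)
                stack.append(x.right)
        return out

    # inside = nodes strictly below the embedded clade root (each node stands
    # for the edge above it); outside = everything else incl. the root edge
    inside = [x for x in subtree_nodes(clade_root) if x is not clade_root]
    outside = [clade_root]

    order = list(extra_labels)
    rng.shuffle(order)
    for label in order:
        go_inside = rng.random() < epsilon
        pool = inside if go_inside else outside
        target = pool[rng.randrange(len(pool))]
        internal, leaf, root = _attach(target, label, root)
        # leaf insertion never changes the restriction to the embedded taxa,
        # and the clade root node object persists, so only the edge pools
        # need updating
        pool.append(internal)
        pool.append(leaf)
    return PhyloTree(_to_node(root))


def generate_dataset(params: SynthParams) -> tuple[TreeSet, PhyloTree]:
    """Generate (collection, embedded subtree) for the given parameters."""
    rng = random.Random(params.rng_seed)
    width = len(str(params.n))
    labels = [f"t{i:0{width}d}" for i in range(1, params.n + 1)]
    embedded_labels = rng.sample(labels, params.n_prime)
    embedded = random_tree(embedded_labels, rng)
    extra = [x for x in labels if x not in set(embedded_labels)]

    n_bearing = int(params.m * params.f + 0.5)  # round half up
    trees = [
        _bearing_tree(embedded, extra, params.epsilon, rng)
        for _ in range(n_bearing)
    ]
    for _ in range(params.m - n_bearing):
        shuffled = list(labels)
        rng.shuffle(shuffled)
        for _attempt in range(1000):
            t = random_tree(shuffled, rng)
            if not is_present(embedded, t):
                break
        else:
            raise RuntimeError(
                "could not draw a background tree avoiding the embedded "
                "subtree; parameters leave too little freedom"
            )
        trees.append(t)
    rng.shuffle(trees)
    return TreeSet(trees), embedded
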