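"""Shared fixtures: small worked-example trees and random-instance helpers.

The four-taxon caterpillar and the three-tree collection mirror the worked
examples used throughout the package documentation: the caterpillar
(((a1,a2),a3),a4) has clades {a1,a2}, {a1,a2,a3} and itself; the three-tree
collection is built so that, at seed size 3 with one contraction, exactly
nine distinct potential seeds exist — one present in all three trees, one in
two, and seven in a single tree each.
"""

from __future__ import annotations

import random

import pytest

from mfast import (
    SynthParams,
    TreeSet,
    generate_dataset,
    parse_newick,
    parse_newick_collection,
    random_tree,
)

CATERPILLAR4 = "(((a1,a2),a3),a4);"

# Three 4-taxon trees whose nine distinct 3-taxon restrictions have
# frequencies 1.0, 2/3 and (seven times) 1/3.
THREE_TREES = """\
((a1,a2),(a3,a4));
(((a1,a2),a3),a4);
(((a1,a4),a2),a3);
"""


@pytest.fixture
def caterpillar4():
    return parse_newick(CATERPILLAR4)


@pytest.fixture
def three_trees() -> TreeSet:
    return parse_newick_collection(THREE_TREES)


@pytest.fixture
def identical_trees() -> TreeSet:
    line = "(((a,b),(c,d)),((e,f),g));\n"
    return parse_newick_collection(line * 3)


def random_treeset(n: int, m: int, seed: int) -> TreeSet:
    """m independent uniform random trees on n shared labels."""
    rng = random.Random(seed)
    labels = [f"x{i}" for i in range(n)]
    trees = []
    for _ in range(m):
        order = list(labels)
        rng.shuffle(order)
        trees.append(random_tree(order, rng))
    return TreeSet(trees)


def embedded_instance(
    seed: int,
    n: int = 9,
    m: int = 5,
    n_prime: int = 5,
    f: float = 1.0,
    epsilon: float = 0.2,
):
    params = SynthParams(
        n=n, m=m, f=f, n_prime=n_prime, epsilon=epsilon, rng_seed=seed
    )
    return generate_dataset(params)
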