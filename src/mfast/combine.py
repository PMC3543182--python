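"""Phase 2 — growing a frequent agreement subtree by combining seeds.

Two subtrees A and B that are both present in some input tree T (the
*reference tree*) combine into ``restrict(T, leaves(A) | leaves(B))``,
written A (+)_T B.  Different reference trees may induce different combined
topologies; every alternative that could still be frequent is tried, but a
tree that contains an already-constructed alternative is *marked* and never
used as a reference again (it would reproduce the same topology), and the
search stops as soon as fewer unmarked candidates remain than the gamma
quorum — no topology discovered later could reach the cutoff.

Two seed-ordering strategies are provided, mirroring the two behaviours of
the underlying heuristic: in-order combination (try seeds by decreasing
frequency) and minimum-overlap combination (try the unconsidered seed
sharing the fewest taxa with the current subtree, frequency as tie-break).
"""

from __future__ import annotations

import heapq
import random
from dataclasses import dataclass
from fractions import Fraction

from .seed_gen import Seed, gamma_count
from .tree_core import (
    PhyloTree,
    TreeSet,
    _restrict_node,
    canonical_form,
    frequency,
    is_present,
)


@dataclass
class FastCandidate:
    """A frequent agreement subtree under construction."""

    tree: PhyloTree
    freq: Fraction
    support_mask: int

    @property
    def support(self) -> frozenset[int]:
        out = set()
        mask = self.support_mask
        while mask:
            low = mask & -mask
            out.add(low.bit_length() - 1)
            mask ^= low
        return frozenset(out)

    @property
    def size(self) -> int:
        return self.tree.size


@dataclass
class CombineConfig:
    """Knobs for the phase-2 search.

    ``sample_fraction`` (and the optional hard cap ``max_starts``) subsample
    the *starting* seeds only — the entire seed list is still available while
    growing — which is the seed-sampling form of a maximum time cutoff.
    """

    gamma: float
    strategy: str = "minoverlap"
    sample_fraction: float = 1.0
    max_starts: int | None = None
    rng_seed: int = 0
    top_k: int = 1
    audit: list | None = None  # collects (freq_a, freq_b, freq_combined)

    def __post_init__(self):
        if not 0 < self.sample_fraction <= 1:
            raise ValueError("sample_fraction must be in (0, 1]")
        if self.strategy not in ("inorder", "minoverlap"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if not 0 < self.gamma <= 1:
            raise ValueError("gamma must be in (0, 1]")


def overlap(a: PhyloTree, b: PhyloTree) -> int:
    """Number of taxa common to both subtrees."""
    return len(a.leaves & b.leaves)


def combine_on_reference(a: PhyloTree, b: PhyloTree, ref: PhyloTree) -> PhyloTree:
    """A (+)_ref B: the restriction of ``ref`` to the union of leaf sets."""
    if not is_present(a, ref):
        raise ValueError("first operand is not present in the reference tree")
    if not is_present(b, ref):
        raise ValueError("second operand is not present in the reference tree")
    node, _ = _restrict_node(ref.node, a.leaves | b.leaves)
    return PhyloTree(node, _canonical=True)


def _best_combo(
    current: FastCandidate,
    add_tree: PhyloTree,
    add_mask: int,
    ts: TreeSet,
    need: int,
    floor: Fraction,
    audit: list | None = None,
) -> FastCandidate | None:
    """Core reference-marking search shared by phase 2 and phase 3.

    Iterates candidate reference trees (indices supporting both operands) in
    ascending order, restricting each tree to the union leaf set at most once
    per call; returns the highest-frequency combined topology whose frequency
    reaches the running cutoff, or None.
    """
    inter = current.support_mask & add_mask
    if inter.bit_count() < need:
        return None
    union = current.tree.leaves | add_tree.leaves
    if union == current.tree.leaves:
        # the addition carries no new taxa: every reference in the current
        # support restricts back to the current topology
        return current if current.freq >= floor else None

    m = ts.m
    trees = ts.trees
    idx = ts.triplet_index()
    if idx is not None:
        union_list = sorted(union)

        def _topo_of(i: int):
            return idx.induced_node(i, union_list)

    else:

        def _topo_of(i: int):
            return _restrict_node(trees[i].node, union)[0]

    restr: dict[int, object] = {}  # tree index -> restricted canonical node
    unmarked = inter
    best: FastCandidate | None = None
    cutoff = floor
    add_freq = Fraction(add_mask.bit_count(), m) if audit is not None else None

    while unmarked and unmarked.bit_count() >= need:
        ref = (unmarked & -unmarked).bit_length() - 1
        topo = restr.get(ref)
        if topo is None:
            topo = _topo_of(ref)
            restr[ref] = topo
        # supporters of a topology first seen at an unmarked reference are
        # themselves unmarked (a tree restricts to a unique topology on this
        # leaf set, so supports of distinct alternatives are disjoint)
        support = 0
        scan = unmarked
        while scan:
            low = scan & -scan
            i = low.bit_length() - 1
            scan ^= low
            ti = restr.get(i)
            if ti is None:
                ti = _topo_of(i)
                restr[i] = ti
            if ti == topo:
                support |= low
        freq = Fraction(support.bit_count(), m)
        if audit is not None:
            audit.append((current.freq, add_freq, freq))
        if freq >= cutoff and (best is None or freq > best.freq):
            best = FastCandidate(PhyloTree(topo, _canonical=True), freq, support)
            cutoff = freq
        unmarked &= ~support
    return best


def best_frequent_combination(
    current: FastCandidate,
    addition: PhyloTree | Seed,
    ts: TreeSet,
    gamma: float,
    floor_freq: float | Fraction | None = None,
    audit: list | None = None,
) -> FastCandidate | None:
    """Best frequent combination of ``current`` with one more subtree.

    ``floor_freq`` is the initial acceptance cutoff (defaults to gamma); it
    ratchets up to each accepted topology's frequency, and among equally
    frequent alternatives the first in reference order is kept.
    """
    if isinstance(addition, Seed):
        add_tree, add_mask = addition.tree, addition.support_mask
    else:
        add_tree = addition
        _, support = frequency(addition, ts)
        add_mask = 0
        for i in support:
            add_mask |= 1 << i
    floor = Fraction(gamma) if floor_freq is None else Fraction(floor_freq)
    if floor < Fraction(gamma):
        raise ValueError("floor_freq must be >= gamma")
    need = gamma_count(gamma, ts.m)
    return _best_combo(current, add_tree, add_mask, ts, need, floor, audit)


def _sample_starts(p: int, cfg: CombineConfig) -> list[int]:
    """Starting-seed indices into the frequency-sorted seed list.

    ``sample_fraction`` draws a uniform random subsample (the randomized
    time cutoff); ``max_starts`` then truncates the outer loop, keeping the
    earliest (most frequent) starts, which is the deterministic form of the
    same cutoff.
    """
    if cfg.sample_fraction < 1.0:
        n_sampled = max(1, round(cfg.sample_fraction * p))
        rng = random.Random(cfg.rng_seed)
        starts = sorted(rng.sample(range(p), n_sampled))
    else:
        starts = list(range(p))
    if cfg.max_starts is not None:
        starts = starts[: cfg.max_starts]
    return starts


def _grow_from_start(
    start_index: int,
    seeds: list[Seed],
    ts: TreeSet,
    cfg: CombineConfig,
    need: int,
    taxon2seeds: dict,
) -> FastCandidate:
    p = len(seeds)
    gamma_floor = Fraction(cfg.gamma)
    s0 = seeds[start_index]
    cur = FastCandidate(s0.tree, s0.freq, s0.support_mask)
    considered = bytearray(p)
    considered[start_index] = 1

    if cfg.strategy == "inorder":
        # seeds are pre-sorted by decreasing frequency
        for j in range(p):
            if considered[j]:
                continue
            considered[j] = 1
            res = _best_combo(
                cur, seeds[j].tree, seeds[j].support_mask, ts, need,
                gamma_floor, cfg.audit,
            )
            if res is not None:
                cur = res
        return cur

    # minimum-overlap: maintain |leaves(seed_j) & leaves(cur)| incrementally
    # and select through a lazy heap (stale overlap entries are re-pushed)
    cur_leaves = set(cur.tree.leaves)
    ov = [len(s.tree.leaves & cur_leaves) for s in seeds]
    neg_freqs = [-s.freq for s in seeds]
    canons = [s.canonical for s in seeds]
    heap = [
        (ov[j], neg_freqs[j], canons[j], j)
        for j in range(p)
        if not considered[j]
    ]
    heapq.heapify(heap)
    while heap:
        ov_seen, nf, canon, j = heapq.heappop(heap)
        if considered[j]:
            continue
        if ov[j] != ov_seen:
            heapq.heappush(heap, (ov[j], nf, canon, j))
            continue
        considered[j] = 1
        res = _best_combo(
            cur, seeds[j].tree, seeds[j].support_mask, ts, need,
            gamma_floor, cfg.audit,
        )
        if res is not None and res.tree.leaves != cur.tree.leaves:
            new_taxa = res.tree.leaves - cur.tree.leaves
            cur = res
            cur_leaves |= new_taxa
            for t in new_taxa:
                for jj in taxon2seeds.get(t, ()):
                    ov[jj] += 1
        elif res is not None:
            cur = res
    return cur


def combine_candidates(
    seeds: list[Seed], ts: TreeSet, cfg: CombineConfig
) -> list[FastCandidate]:
    """Run the configured strategy from every sampled starting seed.

    Returns the per-start results ranked by (size desc, frequency desc,
    canonical form), deduplicated, truncated to ``cfg.top_k``.  Later starts
    beat earlier ones on equal size, matching the incumbent rule of the
    in-order algorithm.
    """
    if not seeds:
        raise ValueError(
            "no frequent seeds; lower gamma or raise the contraction count c"
        )
    seeds = sorted(seeds, key=lambda s: (-s.freq, s.canonical))
    need = gamma_count(cfg.gamma, ts.m)
    taxon2seeds: dict[str, list[int]] = {}
    if cfg.strategy == "minoverlap":
        for j, s in enumerate(seeds):
            for t in s.tree.leaves:
                taxon2seeds.setdefault(t, []).append(j)

    results: list[FastCandidate] = []
    incumbent: FastCandidate | None = None
    for si in _sample_starts(len(seeds), cfg):
        cand = _grow_from_start(si, seeds, ts, cfg, need, taxon2seeds)
        if incumbent is None or cand.size >= incumbent.size:
            incumbent = cand
        results.append(cand)

    seen = set()
    ranked = []
    for cand in sorted(
        results, key=lambda c: (-c.size, -c.freq, canonical_form(c.tree))
    ):
        key = cand.tree.node
        if key not in seen:
            seen.add(key)
            ranked.append(cand)
    # the incumbent (last among the largest) leads, then the remaining ranked
    ranked.remove(next(c for c in ranked if c.tree.node == incumbent.tree.node))
    return [incumbent] + ranked[: max(0, cfg.top_k - 1)]


def inorder_combine(
    seeds: list[Seed], ts: TreeSet, cfg: CombineConfig | None = None, **kw
) -> FastCandidate:
    """In-order combination: grow each start by combining with the most
    frequent unconsidered seed; keep the largest result over all starts."""
    cfg = _with_strategy(cfg, "inorder", kw)
    return combine_candidates(seeds, ts, cfg)[0]


def minoverlap_combine(
    seeds: list[Seed], ts: TreeSet, cfg: CombineConfig | None = None, **kw
) -> FastCandidate:
    """Minimum-overlap combination: prefer the unconsidered seed sharing the
    fewest taxa with the current subtree (frequency breaks ties)."""
    cfg = _with_strategy(cfg, "minoverlap", kw)
    return combine_candidates(seeds, ts, cfg)[0]


def _with_strategy(cfg: CombineConfig | None, strategy: str, kw) -> CombineConfig:
    if cfg is None:
        if "gamma" not in kw:
            raise TypeError("either a CombineConfig or gamma= is required")
        cfg = CombineConfig(strategy=strategy, **kw)
    else:
        cfg = CombineConfig(
            gamma=cfg.gamma,
            strategy=strategy,
            sample_fraction=cfg.sample_fraction,
            max_starts=cfg.max_starts,
            rng_seed=cfg.rng_seed,
            top_k=cfg.top_k,
            audit=cfg.audit,
        )
    return cfg
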