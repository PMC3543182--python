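"""Phase 2: reference-guided combination, marking optimization, strategies."""

from __future__ import annotations

import random
from fractions import Fraction

import pytest

from mfast import (
    CombineConfig,
    FastCandidate,
    Seed,
    SeedParams,
    TreeSet,
    best_frequent_combination,
    brute_force_mfast,
    combine_on_reference,
    frequent_seeds,
    inorder_combine,
    is_present,
    minoverlap_combine,
    overlap,
    parse_newick,
    parse_newick_collection,
    pooled_frequent_seeds,
    restrict,
)
from mfast.oracle import naive_best_combination
from conftest import embedded_instance, random_treeset

REF8 = "((((a1,a3),a4),(a2,a5)),((a6,a7),a8));"


def _candidate(tree, ts) -> FastCandidate:
    from mfast import frequency

    freq, support = frequency(tree, ts)
    mask = 0
    for i in support:
        mask |= 1 << i
    return FastCandidate(tree, freq, mask)


class TestCombineOnReference:
    def test_size_is_union_of_leaf_sets(self):
        ref = parse_newick(REF8)
        s1 = restrict(ref, {"a1", "a3", "a4"})
        s2 = restrict(ref, {"a1", "a2", "a5", "a7"})
        assert overlap(s1, s2) == 1
        combined = combine_on_reference(s1, s2, ref)
        assert combined.leaves == {"a1", "a2", "a3", "a4", "a5", "a7"}
        assert combined.size == 3 + 4 - 1
        assert is_present(s1, combined) and is_present(s2, combined)

    def test_self_combination_is_identity(self):
        ref = parse_newick(REF8)
        s = restrict(ref, {"a1", "a4", "a8"})
        assert combine_on_reference(s, s, ref) == s

    def test_disjoint_operands_equal_hand_restriction(self):
        ref = parse_newick("(((a,b),c),((d,e),f));")
        a = parse_newick("(a,b);")
        b = parse_newick("(d,e);")
        assert combine_on_reference(a, b, ref) == parse_newick(
            "((a,b),(d,e));"
        )

    def test_absent_operand_reported(self):
        ref = parse_newick(REF8)
        bad = parse_newick("((a1,a2),a3);")  # conflicts with ref
        good = restrict(ref, {"a6", "a7"})
        with pytest.raises(ValueError, match="first operand"):
            combine_on_reference(bad, good, ref)
        with pytest.raises(ValueError, match="second operand"):
            combine_on_reference(good, bad, ref)


class TestOverlap:
    def test_identical_and_disjoint(self):
        t = parse_newick("((a,b),c);")
        u = parse_newick("((d,e),f);")
        assert overlap(t, t) == t.size
        assert overlap(t, u) == 0


class TestBestFrequentCombination:
    def test_identical_trees_accept_immediately(self, identical_trees):
        cur = _candidate(parse_newick("(a,b);"), identical_trees)
        addition = parse_newick("(c,d);")
        res = best_frequent_combination(cur, addition, identical_trees, 1.0)
        assert res is not None and res.freq == 1
        assert res.tree.leaves == {"a", "b", "c", "d"}

    def test_majority_topology_wins(self):
        # the combined leaf set {a,b,c,d} resolves 6:4 across the collection;
        # interleave the minority first so reference order cannot decide
        minority = "(((a,b),c),d);"
        majority = "((a,b),(c,d));"
        lines = [minority, majority] * 4 + [majority, majority]
        ts = parse_newick_collection("\n".join(lines) + "\n")
        cur = _candidate(parse_newick("(a,b);"), ts)
        res = best_frequent_combination(
            cur, parse_newick("(c,d);"), ts, gamma=0.5
        )
        assert res.tree == parse_newick(majority)
        assert res.freq == Fraction(6, 10)

    def test_no_shared_support_returns_none(self):
        ts = parse_newick_collection(
            "((a,b),(c,d));\n((a,c),(b,d));\n"
        )
        cur = FastCandidate(parse_newick("(a,b);"), Fraction(1, 2), 0b01)
        addition = Seed(parse_newick("(b,d);"), Fraction(1, 2), 0b10)
        assert (
            best_frequent_combination(cur, addition, ts, 0.5) is None
        )

    @pytest.mark.parametrize("seed", range(12))
    def test_marking_matches_naive_search(self, seed):
        # the marking + early-exit optimization must return the same
        # topology/frequency as trying every reference tree exhaustively
        rng = random.Random(seed)
        ts = random_treeset(n=8, m=6, seed=seed + 50)
        gamma = rng.choice([0.3, 0.5])
        seeds = frequent_seeds(ts, SeedParams(3, 1, gamma))
        if len(seeds) < 2:
            pytest.skip("instance produced too few frequent seeds")
        for _ in range(6):
            a, b = rng.sample(seeds, 2)
            cur = FastCandidate(a.tree, a.freq, a.support_mask)
            fast = best_frequent_combination(cur, b, ts, gamma)
            naive = naive_best_combination(cur, b, ts, gamma)
            if fast is None:
                assert naive is None
            else:
                assert naive is not None
                assert (fast.tree, fast.freq) == (naive.tree, naive.freq)


class TestStrategies:
    def test_single_seed_returned_unchanged(self, identical_trees):
        seeds = frequent_seeds(identical_trees, SeedParams(3, 0, 1.0))[:1]
        res = inorder_combine(seeds, identical_trees, gamma=1.0)
        assert res.tree == seeds[0].tree

    def test_identical_trees_grow_to_oracle_size(self, identical_trees):
        seeds = pooled_frequent_seeds(identical_trees, [2, 3], [0, 1], 1.0)
        best_size, _ = brute_force_mfast(identical_trees, 1.0)
        for strat in (inorder_combine, minoverlap_combine):
            res = strat(seeds, identical_trees, gamma=1.0)
            assert res.freq == 1
            assert res.size == best_size  # the whole tree

    def test_empty_seed_list_rejected(self, identical_trees):
        with pytest.raises(ValueError, match="no frequent seeds"):
            inorder_combine([], identical_trees, gamma=1.0)

    def test_proposition1_on_every_combination(self):
        # combining can never increase frequency beyond either operand
        audit: list = []
        ts, _ = embedded_instance(seed=7, n=12, m=6, n_prime=6)
        seeds = pooled_frequent_seeds(ts, [3], [0, 1], 0.8)
        cfg = CombineConfig(gamma=0.8, audit=audit)
        minoverlap_combine(seeds, ts, cfg)
        assert audit
        for freq_a, freq_b, freq_comb in audit:
            assert freq_comb <= min(freq_a, freq_b)

    def test_result_present_in_every_support_tree(self):
        ts, _ = embedded_instance(seed=3, n=10, m=5, n_prime=5)
        seeds = pooled_frequent_seeds(ts, [3], [0, 1], 0.8)
        res = minoverlap_combine(seeds, ts, gamma=0.8)
        assert res.freq >= Fraction(4, 5)
        for i in res.support:
            assert is_present(res.tree, ts[i])

    def test_embedded_subtree_mostly_recovered(self):
        # a planted 8-taxon subtree shared by all trees: phase 2 alone should
        # pick up most of it
        ts, embedded = embedded_instance(
            seed=11, n=30, m=10, n_prime=8, f=1.0, epsilon=0.0
        )
        seeds = pooled_frequent_seeds(ts, [3, 4, 5], [0, 1, 2, 3, 4, 5], 0.8)
        cfg = CombineConfig(gamma=0.8, max_starts=20)
        res = minoverlap_combine(seeds, ts, cfg)
        assert len(res.tree.leaves & embedded.leaves) >= 6

    def test_minoverlap_no_smaller_than_inorder_usually(self):
        # the size advantage of minimum-overlap is a tendency, not a law:
        # require it in a majority of trials
        wins = 0
        for seed in range(10):
            ts, _ = embedded_instance(
                seed=seed, n=14, m=8, n_prime=7, f=1.0, epsilon=0.3
            )
            seeds = pooled_frequent_seeds(ts, [3], [0, 1], 0.75)
            a = minoverlap_combine(seeds, ts, gamma=0.75)
            b = inorder_combine(seeds, ts, gamma=0.75)
            if a.size >= b.size:
                wins += 1
        assert wins > 5

    def test_deterministic_given_seed(self):
        ts, _ = embedded_instance(seed=5, n=12, m=6, n_prime=6)
        seeds = pooled_frequent_seeds(ts, [3], [0, 1], 0.8)
        cfg = CombineConfig(gamma=0.8, sample_fraction=0.5, rng_seed=9)
        r1 = minoverlap_combine(seeds, ts, cfg)
        r2 = minoverlap_combine(seeds, ts, cfg)
        assert r1.tree == r2.tree and r1.freq == r2.freq


def _hand_seed(newick: str, ts: TreeSet) -> Seed:
    cand = _candidate(parse_newick(newick), ts)
    return Seed(cand.tree, cand.freq, cand.support_mask)


class TestSelectionOrder:
    """The min-overlap selection rule, observed through the audit trail
    (each audit entry records the attempted addition's frequency)."""

    def _attempt_order(self, seeds, ts, gamma):
        from mfast.combine import _grow_from_start
        from mfast.seed_gen import gamma_count

        audit: list = []
        cfg = CombineConfig(gamma=gamma, strategy="minoverlap", audit=audit)
        t2s: dict = {}
        for j, s in enumerate(seeds):
            for t in s.tree.leaves:
                t2s.setdefault(t, []).append(j)
        _grow_from_start(
            0, seeds, ts, cfg, gamma_count(gamma, ts.m), t2s
        )
        return [entry[1] for entry in audit]  # addition frequencies in order

    def test_smaller_overlap_attempted_first(self):
        # the overlap-0 seed has the *lower* frequency, so a frequency-first
        # rule would try the other one; min-overlap must pick it anyway
        lines = ["(((a,b),c),((d,e),f));"] * 3 + ["(((a,b),c),((d,f),e));"]
        ts = parse_newick_collection("\n".join(lines) + "\n")
        seeds = [
            _hand_seed("((a,b),c);", ts),  # start, freq 1
            _hand_seed("((a,b),d);", ts),  # overlap 2, freq 1
            _hand_seed("((d,e),f);", ts),  # overlap 0, freq 3/4
        ]
        order = self._attempt_order(seeds, ts, 0.5)
        assert order[0] == Fraction(3, 4)

    def test_frequency_breaks_overlap_ties(self):
        lines = ["((p,q),((u,v),(w,x)));"] * 3 + ["((p,q),(((u,v),w),x));"]
        ts = parse_newick_collection("\n".join(lines) + "\n")
        seeds = [
            _hand_seed("(p,q);", ts),      # start, freq 1
            _hand_seed("((w,x),u);", ts),  # overlap 0, freq 3/4
            _hand_seed("((u,v),w);", ts),  # overlap 0, freq 1 -> tried first
        ]
        order = self._attempt_order(seeds, ts, 0.5)
        assert order[0] == Fraction(1)
        assert Fraction(3, 4) in order
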