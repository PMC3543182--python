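"""Closed-form model of the chance that seed generation captures part of a
hidden agreement subtree.

Under the idealisation that input trees are uniform random rooted binary
topologies, the model composes four quantities:

* ``R(n) = (2n-3)! / (2^(n-2) (n-2)!)`` — the number of rooted bifurcating
  leaf-labelled topologies on n taxa (R(1) and R(2) are defined as 1, which
  keeps the boundary case k + c = n meaningful);
* ``NU(k, c)`` — a recursive count of (k+c)-taxon clade topologies that
  contain a fixed k-taxon subtree, ``NU(k, 0) = 1`` and
  ``NU(k, c) = NU(k, c-1) * 2 * (k + c - 2)``;
* ``P(n, k, c) = NU(k, c) * R(n - (k+c) + 1) / R(n)`` — the chance one
  random n-taxon tree yields a given k-taxon subtree from a (k+c)-clade;
* geometric amplification over m trees and over the h - k + 1 (a lower
  bound) k-taxon subtrees of an h-taxon target:
  ``P(n,k,c,m) = 1 - (1 - P(n,k,c))^m`` and
  ``P(n,k,c,m,h) = 1 - (1 - P(n,k,c,m))^(h-k+1)``.

Exact big-integer/rational evaluation is used for small n; large n goes
through log-gamma so nothing overflows at n = 1000.  For c = 0 the model is
an exact event probability (a fixed clade topology in a uniform tree) and is
validated against Monte-Carlo draws from the generator; for c > 0 it is the
model as stated, not an exact combinatorial identity — see the methods note.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import pandas as pd

_EXACT_N_MAX = 300  # exact rationals stay cheap well beyond the validated range


@dataclass(frozen=True)
class ProbParams:
    n: int
    k: int
    c: int
    m: int
    h: int

    def __post_init__(self):
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.c < 0:
            raise ValueError("c must be >= 0")
        if self.k + self.c > self.n:
            raise ValueError("k + c must not exceed n")
        if self.h < self.k:
            raise ValueError("h must be >= k")
        if self.m < 1:
            raise ValueError("m must be >= 1")

    def success_probability(self) -> float:
        return p_success(self.n, self.k, self.c, self.m, self.h)


def count_rooted_trees(n: int) -> int:
    """Exact R(n); satisfies R(n+1) = R(n) * (2n - 1), R(1) = R(2) = 1."""
    if n < 1:
        raise ValueError("n must be >= 1")
    r = 1
    for q in range(2, n):
        r *= 2 * q - 1
    return r


def log_count_rooted_trees(n: int) -> float:
    """log R(n) via log-gamma, stable up to very large n."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if n <= 2:
        return 0.0
    return math.lgamma(2 * n - 2) - (n - 2) * math.log(2.0) - math.lgamma(n - 1)


def count_containing_clades(k: int, c: int) -> int:
    """NU(k, c): clade topologies of size k+c containing a fixed k-subtree."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if c < 0:
        raise ValueError("c must be >= 0")
    nu = 1
    for j in range(1, c + 1):
        nu *= 2 * (k + j - 2)
    return nu


def _check_nkc(n: int, k: int, c: int) -> None:
    if k < 2 or c < 0:
        raise ValueError("need k >= 2 and c >= 0")
    if k + c > n:
        raise ValueError("k + c must not exceed n")


def p_seed_in_tree_exact(n: int, k: int, c: int) -> Fraction:
    """Exact rational P(n, k, c) (big integers; intended for moderate n)."""
    _check_nkc(n, k, c)
    return Fraction(
        count_containing_clades(k, c) * count_rooted_trees(n - (k + c) + 1),
        count_rooted_trees(n),
    )


def p_seed_in_tree(n: int, k: int, c: int) -> float:
    """P(n, k, c): probability one random n-taxon tree yields the seed."""
    _check_nkc(n, k, c)
    if n <= _EXACT_N_MAX:
        return float(p_seed_in_tree_exact(n, k, c))
    logp = (
        math.log(count_containing_clades(k, c))
        + log_count_rooted_trees(n - (k + c) + 1)
        - log_count_rooted_trees(n)
    )
    return math.exp(logp)


def _one_minus_pow(p: float, exponent: float) -> float:
    """1 - (1 - p)^exponent, accurate for tiny p."""
    if p >= 1.0:
        return 1.0
    if p <= 0.0:
        return 0.0
    return -math.expm1(exponent * math.log1p(-p))


def p_seed_in_any_tree(n: int, k: int, c: int, m: int) -> float:
    """P(n, k, c, m) = 1 - (1 - P(n,k,c))^m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return _one_minus_pow(p_seed_in_tree(n, k, c), m)


def p_success(n: int, k: int, c: int, m: int, h: int) -> float:
    """P(n, k, c, m, h) with the NS(h, k) >= h - k + 1 lower bound."""
    if h < k:
        raise ValueError("h must be >= k")
    return _one_minus_pow(p_seed_in_any_tree(n, k, c, m), h - k + 1)


def probability_grid(n: int, k_c_pairs, m_values, h_values) -> pd.DataFrame:
    """Success-probability surface over (k, c) x m x h, as a tidy DataFrame."""
    rows = []
    for k, c in k_c_pairs:
        for m in m_values:
            for h in h_values:
                rows.append(
                    {
                        "n": n,
                        "k": k,
                        "c": c,
                        "m": m,
                        "h": h,
                        "probability": p_success(n, k, c, m, h),
                    }
                )
    return pd.DataFrame(rows)
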