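"""End-to-end orchestration of the three phases.

``find_mfast`` runs seed generation over a (k, c) grid, the configured
combination strategy from sampled starting seeds, and taxon-at-a-time
post-processing of the best phase-2 candidates, returning a report that
carries both the final maximal subtree and the phase-2 intermediate (their
before/after sizes are the quantities the synthetic experiments track).
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from fractions import Fraction

from .combine import CombineConfig, combine_candidates
from .postprocess import grow_to_maximal
from .seed_gen import pooled_frequent_seeds
from .tree_core import PhyloTree, TreeSet, canonical_form, frequency

logger = logging.getLogger("mfast")

DEFAULT_K = (3, 4, 5)
DEFAULT_C = (0, 1, 2, 3, 4, 5)


@dataclass
class MfastResult:
    """One maximal frequent agreement subtree with its provenance."""

    tree: PhyloTree
    freq: Fraction
    support: frozenset[int]
    phase2_tree: PhyloTree
    phase2_freq: Fraction

    @property
    def size(self) -> int:
        return self.tree.size

    @property
    def phase2_size(self) -> int:
        return self.phase2_tree.size


@dataclass
class MfastReport:
    results: list[MfastResult]
    n_seeds: int
    params: dict
    timings: dict = field(default_factory=dict)

    @property
    def best(self) -> MfastResult:
        return self.results[0]

    def to_dict(self) -> dict:
        best = self.best
        return {
            "mfast_newick": best.tree.newick(),
            "size": best.size,
            "frequency": float(best.freq),
            "support_indices": sorted(best.support),
            "phase2_newick": best.phase2_tree.newick(),
            "phase2_size": best.phase2_size,
            "n_seeds": self.n_seeds,
            "params": self.params,
            "timings": {k: round(v, 3) for k, v in self.timings.items()},
            "alternatives": [
                {
                    "mfast_newick": r.tree.newick(),
                    "size": r.size,
                    "frequency": float(r.freq),
                }
                for r in self.results[1:]
            ],
        }


def run_mfast(trees_path, **kwargs) -> MfastReport:
    """File-level entry point: read a newick collection, run phases 1-3."""
    from pathlib import Path

    from .tree_core import parse_newick_collection

    resolve = kwargs.pop("resolve_polytomies", False)
    ts = parse_newick_collection(
        Path(trees_path).read_text(), resolve_polytomies=resolve
    )
    return find_mfast(ts, **kwargs)


def find_mfast(
    ts: TreeSet,
    gamma: float = 0.7,
    k_values=DEFAULT_K,
    c_values=DEFAULT_C,
    strategy: str = "minoverlap",
    sample_fraction: float = 1.0,
    max_starts: int | None = None,
    rng_seed: int = 0,
    top_k: int = 1,
    audit: list | None = None,
) -> MfastReport:
    """Run phases 1-3 on a tree collection and report the best maximal FAST."""
    params = {
        "gamma": gamma,
        "k_values": list(k_values),
        "c_values": list(c_values),
        "strategy": strategy,
        "sample_fraction": sample_fraction,
        "max_starts": max_starts,
        "rng_seed": rng_seed,
        "top_k": top_k,
        "m": ts.m,
        "n": ts.n,
    }
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    seeds = pooled_frequent_seeds(ts, k_values, c_values, gamma)
    timings["phase1_s"] = time.perf_counter() - t0
    logger.info("phase 1: %d frequent seeds (gamma=%s)", len(seeds), gamma)
    if not seeds:
        raise ValueError(
            "no frequent seeds; lower gamma or raise the contraction count c"
        )

    cfg = CombineConfig(
        gamma=gamma,
        strategy=strategy,
        sample_fraction=sample_fraction,
        max_starts=max_starts,
        rng_seed=rng_seed,
        top_k=top_k,
        audit=audit,
    )
    t0 = time.perf_counter()
    candidates = combine_candidates(seeds, ts, cfg)
    timings["phase2_s"] = time.perf_counter() - t0
    logger.info(
        "phase 2: best candidate size %d (freq %.3f) from %d kept",
        candidates[0].size, float(candidates[0].freq), len(candidates),
    )

    t0 = time.perf_counter()
    results = []
    for cand in candidates:
        final = grow_to_maximal(cand, ts, gamma, audit)
        results.append(
            MfastResult(
                tree=final.tree,
                freq=final.freq,
                support=final.support,
                phase2_tree=cand.tree,
                phase2_freq=cand.freq,
            )
        )
    timings["phase3_s"] = time.perf_counter() - t0
    results.sort(
        key=lambda r: (-r.size, -r.freq, canonical_form(r.tree))
    )
    logger.info("phase 3: final size %d", results[0].size)

    # re-verify the reported frequency independently
    check_freq, check_support = frequency(results[0].tree, ts)
    assert check_freq == results[0].freq and check_support == results[0].support

    return MfastReport(results=results, n_seeds=len(seeds), params=params,
                       timings=timings)
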