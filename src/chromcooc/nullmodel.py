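"""Degree-class-preserving randomization of the binding map.

The null model rewires each TF-region link to a region of similar
interaction degree, keeping the factor's out-degree exact. Degree classes:
a link to a region of degree d <= 5 may only move to a region of exactly
degree d; for 6 <= d <= 10 to a region with degree within +/- 2 of d; and
for d > 10 to any region of degree > 10 (capped in practice by the
network's degree filter). The original region is always a legal target
("possibly the same" region), so every class is non-empty.

Within one replicate a factor never binds the same region twice; surplus
links that cannot be placed distinctly keep their original regions (with a
warning). Replicates are seeded independently of ordering, so ensembles are
reproducible and streamable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .network import BindingMap, InteractionNetwork

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DegreeClassRule:
    """Degree-class boundaries for link reassignment."""

    exact_max: int = 5
    window_lo: int = 6
    window_hi: int = 10
    window_halfwidth: int = 2

    def __post_init__(self) -> None:
        if not (self.exact_max < self.window_lo <= self.window_hi):
            raise ValueError("require exact_max < window_lo <= window_hi")


DEFAULT_RULE = DegreeClassRule()


def candidate_degrees(d: int, rule: DegreeClassRule = DEFAULT_RULE,
                      max_degree: int | None = None) -> set[int]:
    """Degrees a link to a degree-``d`` region may be reassigned to.

    For d > window_hi the class is open-ended; ``max_degree`` (typically
    the network's maximum degree) bounds the returned set.
    """
    if d < 0:
        raise ValueError("degree must be >= 0")
    if d <= rule.exact_max:
        return {d}
    if d <= rule.window_hi:
        lo = max(0, d - rule.window_halfwidth)
        return set(range(lo, d + rule.window_halfwidth + 1))
    hi = max_degree if max_degree is not None else d
    return set(range(rule.window_hi + 1, max(hi, d) + 1))


class _Randomizer:
    """Precomputed sampling state for repeated randomization of one
    (network, binding) pair.

    Exact classes (d <= exact_max) and the open top class (d > window_hi)
    have mutually disjoint candidate pools, so their links are drawn
    without replacement in single vectorized calls. Window-class links
    (window_lo <= d <= window_hi) have pools overlapping the others and
    are placed link by link with collision checks; they are rare in
    realistic degree distributions.
    """

    def __init__(self, network: InteractionNetwork, binding: BindingMap,
                 rule: DegreeClassRule = DEFAULT_RULE):
        binding.check_consistent(network)
        self.rule = rule
        self.factors = list(binding.factors)
        self.region_ids = np.array(network.region_ids, dtype=np.int64)
        index = {rid: i for i, rid in enumerate(self.region_ids)}
        self.degree = np.array(
            [network.regions[rid].degree for rid in self.region_ids], dtype=np.int64
        )
        self.n_regions = len(self.region_ids)
        max_deg = int(self.degree.max(initial=0))

        # candidate pools, as index arrays into region_ids
        self.pool_exact: dict[int, np.ndarray] = {}
        for d in range(0, min(rule.exact_max, max_deg) + 1):
            self.pool_exact[d] = np.flatnonzero(self.degree == d)
        self.pool_top = np.flatnonzero(self.degree > rule.window_hi)
        self.pool_window: dict[int, np.ndarray] = {}
        for d in range(rule.window_lo, rule.window_hi + 1):
            lo = max(0, d - rule.window_halfwidth)
            hi = d + rule.window_halfwidth
            self.pool_window[d] = np.flatnonzero(
                (self.degree >= lo) & (self.degree <= hi)
            )

        # per-factor link structure: counts per exact degree, top count,
        # and the (degree, original index) list of window links
        self.links: dict[str, dict] = {}
        for f in self.factors:
            idx = np.array(sorted(index[rid] for rid in binding.bound[f]),
                           dtype=np.int64)
            degs = self.degree[idx] if idx.size else np.array([], dtype=np.int64)
            exact_counts = {
                d: int(np.sum(degs == d)) for d in np.unique(degs)
                if d <= rule.exact_max
            }
            top_count = int(np.sum(degs > rule.window_hi))
            wmask = (degs >= rule.window_lo) & (degs <= rule.window_hi)
            window_links = [(int(d), int(i)) for d, i in zip(degs[wmask], idx[wmask])]
            self.links[f] = {
                "exact": exact_counts,
                "top": top_count,
                "window": window_links,
                "n": int(idx.size),
            }

    def sample_indices(self, rng: np.random.Generator) -> dict[str, np.ndarray]:
        """One replicate: factor -> array of bound region indices."""
        out: dict[str, np.ndarray] = {}
        used = np.zeros(self.n_regions, dtype=bool)
        for f in self.factors:
            info = self.links[f]
            chosen: list[np.ndarray] = []
            used[:] = False
            for d, k in info["exact"].items():
                pool = self.pool_exact[d]
                pick = pool[rng.permutation(pool.size)[:k]]
                chosen.append(pick)
                used[pick] = True
            if info["top"]:
                pick = self.pool_top[rng.permutation(self.pool_top.size)[: info["top"]]]
                chosen.append(pick)
                used[pick] = True
            for d, orig in info["window"]:
                pool = self.pool_window[d]
                pick = -1
                for _ in range(100):
                    cand = int(pool[rng.integers(pool.size)])
                    if not used[cand]:
                        pick = cand
                        break
                if pick < 0:
                    unused = pool[~used[pool]]
                    if unused.size:
                        pick = int(unused[rng.integers(unused.size)])
                    elif not used[orig]:
                        pick = orig
                        logger.warning(
                            "factor %s: window pool (d=%d) exhausted; link kept "
                            "at its original region", f, d,
                        )
                    else:
                        free = np.flatnonzero(~used)
                        pick = int(free[rng.integers(free.size)])
                        logger.warning(
                            "factor %s: window pool (d=%d) exhausted and original "
                            "region taken; link placed outside its class", f, d,
                        )
                chosen.append(np.array([pick], dtype=np.int64))
                used[pick] = True
            idx = (np.concatenate(chosen) if chosen
                   else np.array([], dtype=np.int64))
            assert idx.size == info["n"]
            out[f] = idx
        return out

    def to_binding_map(self, indices: dict[str, np.ndarray]) -> BindingMap:
        bm = BindingMap(list(self.factors))
        for f, idx in indices.items():
            bm.bound[f] = set(self.region_ids[idx].tolist())
        return bm


def replicate_rng(master_seed: int, replicate_index: int) -> np.random.Generator:
    """Generator for one replicate, independent of replicate ordering."""
    ss = np.random.SeedSequence(entropy=master_seed,
                                spawn_key=(replicate_index,))
    return np.random.default_rng(ss)


def randomize_bindings(
    network: InteractionNetwork,
    binding: BindingMap,
    rule: DegreeClassRule = DEFAULT_RULE,
    seed: int = 0,
) -> BindingMap:
    """One degree-class-preserving randomization of ``binding``."""
    rnd = _Randomizer(network, binding, rule)
    return rnd.to_binding_map(rnd.sample_indices(replicate_rng(seed, 0)))


@dataclass
class RandomizationEnsemble:
    """A streamable ensemble of randomized binding maps."""

    network: InteractionNetwork
    binding: BindingMap
    replicate_count: int
    rule: DegreeClassRule
    seed: int

    def __post_init__(self) -> None:
        if self.replicate_count < 1:
            raise ValueError("replicate_count must be >= 1")
        self._randomizer = _Randomizer(self.network, self.binding, self.rule)

    @property
    def factors(self) -> list[str]:
        return list(self._randomizer.factors)

    def iter_indices(self) -> Iterator[dict[str, np.ndarray]]:
        """Stream replicates as factor -> region-index arrays (fast path)."""
        rnd = self._randomizer
        for i in range(self.replicate_count):
            yield rnd.sample_indices(replicate_rng(self.seed, i))

    def __iter__(self) -> Iterator[BindingMap]:
        rnd = self._randomizer
        for idx in self.iter_indices():
            yield rnd.to_binding_map(idx)

    def iter_matrices(self) -> Iterator[np.ndarray]:
        """Stream replicates as boolean (factors x regions) matrices."""
        rnd = self._randomizer
        mat = np.zeros((len(rnd.factors), rnd.n_regions), dtype=bool)
        for idx in self.iter_indices():
            mat[:] = False
            for fi, f in enumerate(rnd.factors):
                mat[fi, idx[f]] = True
            yield mat


def generate_ensemble(
    network: InteractionNetwork,
    binding: BindingMap,
    R: int = 1000,
    rule: DegreeClassRule = DEFAULT_RULE,
    seed: int = 0,
) -> RandomizationEnsemble:
    """Ensemble of ``R`` independent randomized binding maps."""
    if R < 1:
        raise ValueError("R must be >= 1")
    return RandomizationEnsemble(network, binding, R, rule, seed)
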