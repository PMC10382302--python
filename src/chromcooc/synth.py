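"""Synthetic interaction networks, bindings, motifs and sequences with
planted attraction/repulsion structure.

The generator emulates the study conditions end to end: a region-region
contact graph with a realistic degree law, a bipartite binding map in
which same-group factor pairs co-bind across edges more often than chance
and cross-group pairs less often, and region sequences with consensus
motif matches planted preferentially in spatially isolated regions. All
generators are deterministic under their seed, and the emitted regions
are laid out so that the construction filters (anchor merging, the
short-range filter, degree/length caps) are no-ops on them.

Planted pair dependence is generated through latent compartment-like
clusters: the contact graph is partitioned into small connected clusters,
a fraction of clusters is assigned to each factor group, and a group's
factors bind regions of matching clusters with odds boosted by
attract_boost, regions of opposing clusters with odds damped by
repel_damp, and all other regions at a compensating baseline. Each
factor's bound set is then thinned (or topped up) to an exact
Binomial(n_regions, base_bind_prob) draw, so marginal binding rates match
the design value up to sampling error while the planted dependence -- and
hence the observed/null co-occurrence enrichment -- is preserved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .intervals import GenomicInterval
from .network import BindingMap, InteractionNetwork, Region

logger = logging.getLogger(__name__)

RELATION_ATTRACT = "attract"
RELATION_REPEL = "repel"
RELATION_NULL = "null"


@dataclass
class SynthConfig:
    """Study-condition parameters for the synthetic generator."""

    n_regions: int = 2000
    degree_law: tuple = ("poisson", 3.0)  # ("poisson", lam) | ("fixed", k) | ("empirical", seq)
    n_factors: int = 20
    group_of: dict[str, int] | None = None  # factor -> 1/2 (0 = ungrouped)
    n_ungrouped: int = 2  # default split: two null factors, remainder halved
    attract_boost: float = 8.0
    repel_damp: float = 0.125
    base_bind_prob: float = 0.05
    seed: int = 0
    chrom: str = "chrS"
    region_length: tuple[int, int] = (500, 2000)
    region_gap: tuple[int, int] = (2100, 8000)
    typed_fraction: float = 0.1  # region clusters assigned to each group
    cluster_cap: int = 20
    max_degree: int = 20

    factors: list[str] = field(init=False)

    def __post_init__(self) -> None:
        if self.n_regions < 2:
            raise ValueError("need at least 2 regions")
        if not (0 <= self.base_bind_prob <= 1):
            raise ValueError("base_bind_prob must be a probability")
        if self.attract_boost < 1 or not (0 < self.repel_damp <= 1):
            raise ValueError("require attract_boost >= 1 and 0 < repel_damp <= 1")
        self.factors = [f"TF{i:02d}" for i in range(self.n_factors)]
        if self.group_of is None:
            grouped = self.n_factors - self.n_ungrouped
            half = grouped // 2
            self.group_of = {}
            for i, f in enumerate(self.factors):
                if i < half:
                    self.group_of[f] = 1
                elif i < grouped:
                    self.group_of[f] = 2
                else:
                    self.group_of[f] = 0


def _degree_sequence(config: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    kind = config.degree_law[0]
    n = config.n_regions
    if kind == "poisson":
        d = rng.poisson(float(config.degree_law[1]), size=n)
        d = np.minimum(d, config.max_degree)
    elif kind == "fixed":
        d = np.full(n, int(config.degree_law[1]))
    elif kind == "empirical":
        seq = np.asarray(config.degree_law[1], dtype=np.int64)
        if seq.size != n:
            raise ValueError("empirical degree list length != n_regions")
        d = seq.copy()
    else:
        raise ValueError(f"unknown degree law {kind!r}")
    if np.any(d < 0) or np.any(d > config.max_degree):
        raise ValueError("degree sequence outside [0, max_degree]")
    if d.sum() % 2:  # make the stub count even
        i = int(np.flatnonzero(d > 0)[0]) if np.any(d > 0) else 0
        d[i] += -1 if d[i] > 0 else 1
    if d.sum() == 0 and kind != "fixed":
        raise ValueError("degenerate degree sequence (no edges)")
    return d


def _pair_stubs(degrees: np.ndarray, rng: np.random.Generator,
                max_rounds: int = 200) -> set[tuple[int, int]]:
    """Configuration-model pairing preserving the degree sequence exactly.

    Stubs are shuffled and paired; self-loops and duplicate edges are
    repaired by random edge swaps (which keep every degree fixed). Raises
    if the sequence cannot be realised as a simple graph.
    """
    stubs = np.repeat(np.arange(degrees.size), degrees)
    rng.shuffle(stubs)
    pairs = [(int(stubs[i]), int(stubs[i + 1])) for i in range(0, stubs.size - 1, 2)]

    for _ in range(max_rounds):
        seen: set[tuple[int, int]] = set()
        conflicts = []
        for k, (u, v) in enumerate(pairs):
            key = (u, v) if u < v else (v, u)
            if u == v or key in seen:
                conflicts.append(k)
            else:
                seen.add(key)
        if not conflicts:
            return seen
        for k in conflicts:  # swap one endpoint with a random other pair
            j = int(rng.integers(len(pairs)))
            u, v = pairs[k]
            x, y = pairs[j]
            pairs[k], pairs[j] = (u, y), (x, v)
    raise ValueError("could not realise the degree sequence as a simple graph")


def simulate_network(config: SynthConfig) -> InteractionNetwork:
    """Region-region interaction network on a synthetic genome.

    Region lengths stay below the 30 kbp cap and inter-region gaps above
    2 kbp, so running the emitted anchors through the network-construction
    filters reproduces the same graph.
    """
    rng = np.random.default_rng(np.random.SeedSequence(
        entropy=config.seed, spawn_key=(0,)))
    degrees = _degree_sequence(config, rng)
    edges = _pair_stubs(degrees, rng) if degrees.sum() else set()

    lo_len, hi_len = config.region_length
    lo_gap, hi_gap = config.region_gap
    lengths = rng.integers(lo_len, hi_len + 1, size=config.n_regions)
    gaps = rng.integers(lo_gap, hi_gap + 1, size=config.n_regions)
    starts = np.cumsum(gaps) + np.concatenate([[0], np.cumsum(lengths[:-1])])
    regions = {
        i: Region(i, GenomicInterval(config.chrom, int(starts[i]),
                                     int(starts[i] + lengths[i])))
        for i in range(config.n_regions)
    }
    return InteractionNetwork(regions, edges)


def _cluster_partition(network: InteractionNetwork, cap: int,
                       rng: np.random.Generator) -> list[list[int]]:
    """Partition connected regions into clusters of at most ``cap`` nodes
    by randomized breadth-first growth (degree-0 regions are left out)."""
    adj = network.adjacency_lists()
    order = np.array(network.region_ids)
    rng.shuffle(order)
    assigned: set[int] = set()
    clusters: list[list[int]] = []
    for seed_rid in order:
        rid = int(seed_rid)
        if rid in assigned or not adj[rid]:
            continue
        cluster = [rid]
        assigned.add(rid)
        frontier = [rid]
        while frontier and len(cluster) < cap:
            nxt = []
            for u in frontier:
                nbs = sorted(nb for nb in adj[u] if nb not in assigned)
                for nb in nbs:
                    if len(cluster) >= cap:
                        break
                    assigned.add(nb)
                    cluster.append(nb)
                    nxt.append(nb)
            frontier = nxt
        clusters.append(cluster)
    return clusters


def planted_truth(config: SynthConfig) -> pd.DataFrame:
    """Truth table of planted pair relations (rows for i <= j).

    Within-group pairs (homotypic included) are tilted towards co-binding,
    cross-group pairs away from it; pairs involving ungrouped factors are
    untouched nulls.
    """
    planted = (config.attract_boost != 1.0 or config.repel_damp != 1.0)
    rows = []
    for i, fi in enumerate(config.factors):
        for fj in config.factors[i:]:
            gi, gj = config.group_of.get(fi, 0), config.group_of.get(fj, 0)
            if not planted or gi == 0 or gj == 0:
                rel = RELATION_NULL
            elif gi == gj:
                rel = RELATION_ATTRACT
            else:
                rel = RELATION_REPEL
            rows.append((fi, fj, rel))
    return pd.DataFrame(rows, columns=["factor_i", "factor_j", "relation"])


def simulate_bindings(
    network: InteractionNetwork, config: SynthConfig
) -> tuple[BindingMap, pd.DataFrame]:
    """Binding map with planted attraction/repulsion, plus its truth table.

    Mechanism: connected regions are partitioned into small clusters
    (randomized BFS, size cap ``cluster_cap``); each cluster is assigned
    to group 1 or group 2 with probability ``typed_fraction`` each, or
    stays neutral. A group-g factor binds regions of group-g clusters
    with probability base_bind_prob * attract_boost (clipped below 1),
    regions of the opposing group's clusters with probability
    base_bind_prob * repel_damp, and all remaining regions at a
    compensating baseline chosen so its expected marginal equals
    base_bind_prob. Ungrouped factors bind uniformly. Finally every
    factor's bound set is resampled to an exact Binomial(n_regions,
    base_bind_prob) size (uniform thinning or top-up), which pins the
    marginals while preserving the planted dependence structure up to
    uniform dilution.

    With attract_boost = repel_damp = 1 every factor is an independent
    uniform binder (the null condition).
    """
    rng = np.random.default_rng(np.random.SeedSequence(
        entropy=config.seed, spawn_key=(1,)))
    F, p = config.n_factors, config.base_bind_prob
    region_ids = network.region_ids
    R = len(region_ids)
    groups = np.array([config.group_of.get(f, 0) for f in config.factors])
    planted = (config.attract_boost != 1.0 or config.repel_damp != 1.0)

    if not planted or p in (0.0, 1.0) or not np.any(groups > 0):
        B = rng.random((F, R)) < p
    else:
        f_typed = config.typed_fraction
        # binding probability boosted on matching compartments; the damped
        # probability is set so that cross-group CO-binding odds on a
        # compartment contact (p_hi * p_lo vs the p^2 baseline) are
        # multiplied by repel_damp
        p_hi = min(0.9, p * config.attract_boost)
        p_lo = p * config.repel_damp / config.attract_boost
        idx = {rid: i for i, rid in enumerate(region_ids)}
        clusters = _cluster_partition(network, config.cluster_cap, rng)
        # assign shuffled clusters to each group until it covers its target
        # fraction of regions, so typed coverage is stable across seeds
        region_type = np.zeros(R, dtype=np.int64)
        order = list(rng.permutation(len(clusters)))
        target = f_typed * R
        covered = {1: 0, 2: 0}
        t = 1
        for ci in order:
            if covered[1] >= target and covered[2] >= target:
                break
            if covered[t] >= target:
                t = 3 - t
            cluster = clusters[int(ci)]
            for rid in cluster:
                region_type[idx[rid]] = t
            covered[t] += len(cluster)
            t = 3 - t
        # halo masks: regions adjacent to a cluster of type t. A factor of
        # the opposing group is damped there too; without the halo,
        # boundary contacts between opposing clusters would leak
        # cross-group co-binding into the planted repulsion.
        adj_lists = network.adjacency_lists()
        near_type = {1: np.zeros(R, dtype=bool), 2: np.zeros(R, dtype=bool)}
        for rid in region_ids:
            r = idx[rid]
            for nb in adj_lists[rid]:
                t = region_type[idx[nb]]
                if t:
                    near_type[t][r] = True
        prob = np.full((F, R), p)
        for fi in range(F):
            g = groups[fi]
            if g == 0:
                continue
            opposing = (region_type == (3 - g)) | near_type[3 - g]
            boosted = (region_type == g) & ~opposing
            n_boost = int(boosted.sum())
            n_opp = int(opposing.sum())
            n_base = R - n_boost - n_opp
            # baseline on remaining regions chosen so E[marginal] = p
            p0 = (p * R - n_boost * p_hi - n_opp * p_lo) / max(1, n_base)
            p0 = min(1.0, max(0.0, p0))
            prob[fi, :] = p0
            prob[fi, boosted] = p_hi
            prob[fi, opposing] = p_lo
        B = rng.random((F, R)) < prob
        # exact-marginal resampling: thin uniformly, or top up with draws
        # following the factor's own binding-probability profile
        for fi in range(F):
            target = int(rng.binomial(R, p))
            bound = np.flatnonzero(B[fi])
            unbound = np.flatnonzero(~B[fi])
            if bound.size > target:
                drop = rng.choice(bound, size=bound.size - target, replace=False)
                B[fi, drop] = False
            elif bound.size < target and unbound.size:
                k = min(target - bound.size, unbound.size)
                w = prob[fi, unbound]
                w = w / w.sum() if w.sum() > 0 else None
                add = rng.choice(unbound, size=k, replace=False, p=w)
                B[fi, add] = True

    bm = BindingMap(list(config.factors))
    for fi, f in enumerate(config.factors):
        bm.bound[f] = {region_ids[r] for r in np.flatnonzero(B[fi])}
    return bm, planted_truth(config)


# ---------------------------------------------------------------------------
# Motif dataset
# ---------------------------------------------------------------------------

@dataclass
class SimulatedMotifData:
    genome: dict[str, str]
    network: InteractionNetwork
    peaks: pd.DataFrame  # factor, chrom, start, end
    pwm: "PWM"
    planted: pd.Series   # region id -> bool (consensus planted)

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for chrom, seq in self.genome.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i:i + 70] + "\n")


def default_motif(rng: np.random.Generator, length: int = 10,
                  dominant: float = 0.85, name: str = "SYNTH_MOTIF") -> "PWM":
    """A moderately informative random PWM (one dominant base/position)."""
    from .motif import PWM

    mat = np.full((length, 4), (1 - dominant) / 3)
    cons = rng.integers(0, 4, size=length)
    mat[np.arange(length), cons] = dominant
    return PWM.from_array(name, mat)


def simulate_motif_dataset(
    n_isolated: int = 120,
    n_interacting: int = 120,
    region_length: int = 400,
    p_iso: float = 0.6,
    p_int: float = 0.2,
    pwm: "PWM | None" = None,
    seed: int = 0,
    chrom: str = "chrS",
) -> SimulatedMotifData:
    """Sequences and peaks with consensus matches planted preferentially in
    isolated regions.

    Interacting regions are paired into degree-1 contact edges; isolated
    regions have degree 0. Background sequence is i.i.d. uniform; with
    probability ``p_iso`` (isolated) or ``p_int`` (interacting) a region
    receives one exact-consensus insertion at a random offset. One peak
    per region (the region itself) is emitted for the motif's factor.
    """
    if n_interacting % 2:
        raise ValueError("n_interacting must be even (regions are paired)")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(2,)))
    if pwm is None:
        pwm = default_motif(rng)
    n = n_isolated + n_interacting
    gap = 2500
    lengths = np.full(n, region_length)
    starts = np.arange(n) * (region_length + gap) + gap
    regions = {
        i: Region(i, GenomicInterval(chrom, int(starts[i]),
                                     int(starts[i] + lengths[i])))
        for i in range(n)
    }
    interacting = list(range(n_isolated, n))
    edges = [(interacting[k], interacting[k + 1])
             for k in range(0, len(interacting), 2)]
    network = InteractionNetwork(regions, edges)

    genome_len = int(starts[-1] + region_length + gap)
    codes = rng.integers(0, 4, size=genome_len)
    consensus = pwm.consensus
    cons_codes = np.array([("ACGT").index(b) for b in consensus])
    planted = {}
    for i in range(n):
        p_plant = p_iso if i < n_isolated else p_int
        plant = bool(rng.random() < p_plant)
        planted[i] = plant
        if plant:
            off = int(rng.integers(0, region_length - len(consensus) + 1))
            s = int(starts[i]) + off
            codes[s:s + len(consensus)] = cons_codes
    genome = {chrom: "".join("ACGT"[c] for c in codes)}
    peaks = pd.DataFrame(
        [(pwm.name, chrom, int(starts[i]), int(starts[i] + region_length))
         for i in range(n)],
        columns=["factor", "chrom", "start", "end"],
    )
    return SimulatedMotifData(genome, network, peaks, pwm,
                              pd.Series(planted, name="planted"))


# ---------------------------------------------------------------------------
# Fixture emission in pipeline file formats
# ---------------------------------------------------------------------------

def write_interaction_tsv(network: InteractionNetwork, path) -> None:
    """Emit edges as a 6-column anchor-pair TSV the pipeline can re-read."""
    with open(path, "w") as fh:
        fh.write("# chrom1\tstart1\tend1\tchrom2\tstart2\tend2\n")
        for u, v in sorted(network.edges):
            a = network.regions[u].interval
            b = network.regions[v].interval
            fh.write(f"{a.chrom}\t{a.start}\t{a.end}\t{b.chrom}\t{b.start}\t{b.end}\n")


def write_peaks_bed(binding: BindingMap, network: InteractionNetwork, path) -> None:
    """Emit each factor's bound regions as BED records (name = factor)."""
    with open(path, "w") as fh:
        for f in binding.factors:
            for rid in sorted(binding.bound[f]):
                iv = network.regions[rid].interval
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{f}\n")


def peaks_by_factor_from_bed(df: pd.DataFrame) -> dict[str, list[GenomicInterval]]:
    """Group a BED DataFrame (name column = factor) into per-factor peaks."""
    out: dict[str, list[GenomicInterval]] = {}
    for r in df.itertuples():
        out.setdefault(str(r.name), []).append(
            GenomicInterval(str(r.chrom), int(r.start), int(r.end)))
    return out
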