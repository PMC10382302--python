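"""Downstream statistics on attracting/repelling pairs and TF groups.

Covers exact hypergeometric 2x2 enrichment (protein-protein interactions,
domain-domain interactions, gene sets), target-gene assignment by the
at-least-five / at-most-three rule, TSS-distance distributions, and the
frequency of annotated TFs as internal nodes on shortest PPI paths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .cooccur import CALL_ATTRACT, CALL_REPEL
from .intervals import GenomicInterval
from .network import BindingMap, InteractionNetwork

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b, c, d) with columns = class membership (e.g. attracting
    vs avoiding pairs) and rows = annotation (e.g. physically interacting
    or not): a = attracting & interacting, b = avoiding & interacting,
    c = attracting & not, d = avoiding & not."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")


def hypergeom_enrichment(table: ContingencyTable2x2) -> float:
    """One-sided (upper-tail) exact hypergeometric p-value for column 1.

    P(X >= a) for X ~ Hypergeometric(N = a+b+c+d, K = a+b, n = a+c):
    drawing the attracting pairs from the pooled population, how likely is
    an overlap with the annotated set at least as large as observed.
    """
    N = table.a + table.b + table.c + table.d
    K = table.a + table.b
    n = table.a + table.c
    if N == 0 or K == 0 or n == 0:
        logger.warning("degenerate contingency table %s: p = 1", table)
        return 1.0
    return float(hypergeom.sf(table.a - 1, N, K, n))


def _norm_pair(pair: Iterable[str]) -> tuple[str, str]:
    a, b = pair
    return (a, b) if a <= b else (b, a)


def pair_interaction_table(
    calls: pd.DataFrame,
    interacting_pairs: Iterable[tuple[str, str]],
) -> ContingencyTable2x2:
    """2x2 table of attract/repel calls vs membership in an interaction list.

    Attracting = pairs called attract, avoiding = pairs called repel;
    neutral pairs are excluded. ``interacting_pairs`` is an unordered pair
    set (e.g. HIPPIE PPI edges or 3did-derived potentially-interacting
    pairs over the same factor universe).
    """
    inter = {_norm_pair(p) for p in interacting_pairs}
    a = b = c = d = 0
    for r in calls.itertuples():
        pair = _norm_pair((str(r.factor_i), str(r.factor_j)))
        if r.call == CALL_ATTRACT:
            if pair in inter:
                a += 1
            else:
                c += 1
        elif r.call == CALL_REPEL:
            if pair in inter:
                b += 1
            else:
                d += 1
    return ContingencyTable2x2(a, b, c, d)


def domain_interaction_pairs(
    factor_domains: Mapping[str, Iterable[str]],
    domain_pairs: Iterable[tuple[str, str]],
) -> set[tuple[str, str]]:
    """Potentially interacting factor pairs via domain-domain interactions.

    A factor pair is potentially interacting iff any domain of one factor
    is listed as interacting with any domain of the other.
    """
    dpairs = {_norm_pair(p) for p in domain_pairs}
    factors = sorted(factor_domains)
    out = set()
    for i, fi in enumerate(factors):
        for fj in factors[i:]:
            if any(
                _norm_pair((di, dj)) in dpairs
                for di in factor_domains[fi]
                for dj in factor_domains[fj]
            ):
                out.add(_norm_pair((fi, fj)))
    return out


# ---------------------------------------------------------------------------
# Target genes
# ---------------------------------------------------------------------------

@dataclass
class TargetGeneCall:
    gene: str
    count_group1: int
    count_group2: int
    assigned_group: int  # 1, 2, or 0 for none


def _interval_distance(iv: GenomicInterval, other: GenomicInterval) -> int | None:
    if iv.chrom != other.chrom:
        return None
    return max(0, max(iv.start, other.start) - min(iv.end, other.end))


def factor_target_genes(
    binding: BindingMap,
    network: InteractionNetwork,
    tss: Mapping[str, GenomicInterval],
    window: int = 2000,
) -> dict[str, set[str]]:
    """Putative target genes per factor.

    Factor f targets gene g iff f binds a region within ``window`` bp of
    g's TSS (sequential route), or f binds a region with an interaction
    edge to a region within ``window`` bp of g's TSS (spatial route).
    """
    # genes near each region
    near: dict[int, set[str]] = {rid: set() for rid in network.regions}
    for gene, giv in tss.items():
        for rid, region in network.regions.items():
            dist = _interval_distance(region.interval, giv)
            if dist is not None and dist <= window:
                near[rid].add(gene)
    adj = network.adjacency_lists()
    out: dict[str, set[str]] = {}
    for f in binding.factors:
        genes: set[str] = set()
        for rid in binding.bound[f]:
            genes |= near[rid]
            for nb in adj[rid]:
                genes |= near[nb]
        out[f] = genes
    return out


def assign_target_genes(
    binding: BindingMap,
    network: InteractionNetwork,
    tss: Mapping[str, GenomicInterval],
    groups: Mapping[str, int],
    window: int = 2000,
    min_in: int = 5,
    max_out: int = 3,
) -> list[TargetGeneCall]:
    """Assign genes to TF groups by distinct-regulator counts.

    A gene is a group-g target if at least ``min_in`` distinct group-g
    factors target it and at most ``max_out`` factors of the other group
    do. The stricter (3, 0) variant is available via the parameters.
    """
    targets = factor_target_genes(binding, network, tss, window)
    per_gene: dict[str, list[set[str]]] = {}
    for f, genes in targets.items():
        g = groups.get(f)
        if g not in (1, 2):
            continue
        for gene in genes:
            per_gene.setdefault(gene, [set(), set()])[g - 1].add(f)
    calls = []
    for gene in sorted(per_gene):
        c1, c2 = (len(s) for s in per_gene[gene])
        if c1 >= min_in and c2 <= max_out:
            grp = 1
        elif c2 >= min_in and c1 <= max_out:
            grp = 2
        else:
            grp = 0
        calls.append(TargetGeneCall(gene, c1, c2, grp))
    return calls


def gene_set_enrichment(
    targets_group1: Iterable[str],
    targets_group2: Iterable[str],
    reference: Iterable[str],
) -> tuple[float, ContingencyTable2x2]:
    """Hypergeometric enrichment of group-1 vs group-2 targets in a
    reference gene set (e.g. housekeeping genes)."""
    g1, g2, ref = set(targets_group1), set(targets_group2), set(reference)
    if not g1 or not g2:
        raise ValueError("both target-gene sets must be non-empty")
    table = ContingencyTable2x2(
        len(g1 & ref), len(g2 & ref), len(g1 - ref), len(g2 - ref)
    )
    return hypergeom_enrichment(table), table


# ---------------------------------------------------------------------------
# TSS distances
# ---------------------------------------------------------------------------

def tss_distance_cdf(
    peaks_by_factor: Mapping[str, Sequence[GenomicInterval]],
    tss: Mapping[str, GenomicInterval] | Sequence[GenomicInterval],
    use_midpoint: bool = True,
) -> dict[str, np.ndarray]:
    """Sorted distances from each factor's peaks to the nearest TSS.

    The distance anchor is the peak midpoint by default (nearest-edge with
    ``use_midpoint=False``); TSS positions are the start coordinates of
    the supplied intervals. Peaks on chromosomes without any TSS are
    excluded with a warning. The returned sorted arrays are the empirical
    CDF supports: CDF(x) = mean(distances <= x).
    """
    tss_list = list(tss.values()) if isinstance(tss, Mapping) else list(tss)
    if not tss_list:
        raise ValueError("TSS list is empty")
    by_chrom: dict[str, np.ndarray] = {}
    for iv in tss_list:
        by_chrom.setdefault(iv.chrom, [])
    for iv in tss_list:
        by_chrom[iv.chrom].append(iv.start)
    by_chrom = {c: np.sort(np.asarray(v)) for c, v in by_chrom.items()}

    out: dict[str, np.ndarray] = {}
    for factor, peaks in peaks_by_factor.items():
        dists = []
        skipped = 0
        for p in peaks:
            pos = by_chrom.get(p.chrom)
            if pos is None:
                skipped += 1
                continue
            if use_midpoint:
                x = p.midpoint
                i = np.searchsorted(pos, x)
                cand = []
                if i < pos.size:
                    cand.append(abs(int(pos[i]) - x))
                if i > 0:
                    cand.append(abs(x - int(pos[i - 1])))
                dists.append(min(cand))
            else:
                i = np.searchsorted(pos, p.start)
                cand = []
                for j in (i - 1, i, i + 1):
                    if 0 <= j < pos.size:
                        t = int(pos[j])
                        cand.append(0 if p.start <= t < p.end
                                    else min(abs(t - p.start), abs(t - (p.end - 1))))
                dists.append(min(cand))
        if skipped:
            logger.warning("factor %s: %d peaks on chromosomes without TSS excluded",
                           factor, skipped)
        out[factor] = np.sort(np.asarray(dists, dtype=np.int64))
    return out


def pooled_distances(dist_by_factor: Mapping[str, np.ndarray],
                     factors: Iterable[str]) -> np.ndarray:
    """Group-level distance curve: pooled distances of member factors."""
    arrs = [dist_by_factor[f] for f in factors if f in dist_by_factor]
    if not arrs:
        return np.empty(0, dtype=np.int64)
    return np.sort(np.concatenate(arrs))


# ---------------------------------------------------------------------------
# Shortest-PPI-path internal nodes
# ---------------------------------------------------------------------------

@dataclass
class PathNodeFrequency:
    tf: str
    category: str
    count: int


def shortest_path_internal_tfs(
    ppi_edges: Iterable[tuple[str, str]],
    pairs_by_category: Mapping[str, Iterable[tuple[str, str]]],
    annotated_tfs: Iterable[str],
) -> pd.DataFrame:
    """Frequency of annotated TFs strictly inside shortest PPI paths.

    For each factor pair, a node is internal iff it lies on at least one
    shortest path between the two (union over all shortest paths, found
    from d(a, x) + d(x, b) == d(a, b)). Each internal TF counts once per
    pair; counts are aggregated per pair category (e.g. group-1 pairs,
    group-2 pairs, cross-group pairs).
    """
    g = nx.Graph()
    g.add_edges_from(ppi_edges)
    annotated = set(annotated_tfs)
    rows: list[PathNodeFrequency] = []
    counts: dict[tuple[str, str], int] = {}
    for category, pairs in pairs_by_category.items():
        for a, b in pairs:
            if a not in g or b not in g:
                logger.info("pair (%s, %s) absent from PPI graph; skipped", a, b)
                continue
            try:
                da = nx.single_source_shortest_path_length(g, a)
                if b not in da:
                    raise nx.NetworkXNoPath(a, b)
            except nx.NetworkXNoPath:
                logger.info("pair (%s, %s) disconnected in PPI graph", a, b)
                continue
            db = nx.single_source_shortest_path_length(g, b)
            d = da[b]
            internal = {
                x for x, dax in da.items()
                if x not in (a, b) and x in db and dax + db[x] == d
            }
            for tf in internal & annotated:
                counts[(tf, category)] = counts.get((tf, category), 0) + 1
    rows = [PathNodeFrequency(tf, cat, n) for (tf, cat), n in sorted(counts.items())]
    return pd.DataFrame(
        [(r.tf, r.category, r.count) for r in rows],
        columns=["tf", "category", "count"],
    )


# ---------------------------------------------------------------------------
# Side-table readers
# ---------------------------------------------------------------------------

def read_pair_list(path) -> set[tuple[str, str]]:
    """Two-column TSV of unordered pairs (PPI edges, domain pairs...)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["a", "b"], usecols=[0, 1])
    return {_norm_pair((str(r.a), str(r.b))) for r in df.itertuples()}


def read_group_labels(path) -> dict[str, int]:
    """Two-column TSV: factor, group (1 or 2)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["factor", "group"], usecols=[0, 1])
    return {str(r.factor): int(r.group) for r in df.itertuples()}


def read_gene_list(path) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip() and not line.startswith("#")}


def read_tss_bed(path) -> dict[str, GenomicInterval]:
    """BED with name column = gene id -> gene -> TSS interval."""
    from .intervals import read_bed

    df = read_bed(path)
    if "name" not in df.columns:
        raise ValueError("TSS BED requires a name column with gene ids")
    return {
        str(r.name): GenomicInterval(str(r.chrom), int(r.start), int(r.end))
        for r in df.itertuples()
    }
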