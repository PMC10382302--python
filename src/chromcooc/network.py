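"""Chromatin interaction network and bipartite TF-binding map.

The interaction network is an undirected graph whose nodes are merged
genomic regions and whose edges are long-range chromatin contacts (from
ChIA-PET or similar anchor-pair data). The binding map links each factor
(TF, histone mark, or motif model treated as a factor) to the set of
regions it binds.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, merge_intervals

logger = logging.getLogger(__name__)


@dataclass
class Region:
    """A merged genomic region node, labelled with its interaction degree."""

    id: int
    interval: GenomicInterval
    degree: int = 0

    @property
    def length(self) -> int:
        return self.interval.length


class InteractionNetwork:
    """Undirected region-region contact graph.

    Invariants maintained by construction: no self-edges, no duplicate
    edges, every edge endpoint present in ``regions``, and each region's
    ``degree`` equal to its number of incident edges.
    """

    def __init__(self, regions: Mapping[int, Region], edges: Iterable[tuple[int, int]]):
        self.regions: dict[int, Region] = dict(regions)
        es = set()
        for u, v in edges:
            if u == v:
                raise ValueError(f"self-edge on region {u}")
            if u not in self.regions or v not in self.regions:
                raise ValueError(f"edge ({u},{v}) references unknown region")
            es.add((u, v) if u < v else (v, u))
        self.edges: set[tuple[int, int]] = es
        self._recompute_degrees()

    # -- basic structure ----------------------------------------------------

    def _recompute_degrees(self) -> None:
        deg = dict.fromkeys(self.regions, 0)
        for u, v in self.edges:
            deg[u] += 1
            deg[v] += 1
        for rid, d in deg.items():
            self.regions[rid].degree = d

    @property
    def region_ids(self) -> list[int]:
        return sorted(self.regions)

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_array(self) -> np.ndarray:
        """Edges as an (E, 2) int array of region ids, sorted for determinism."""
        if not self.edges:
            return np.empty((0, 2), dtype=np.int64)
        return np.array(sorted(self.edges), dtype=np.int64)

    def degrees(self) -> dict[int, int]:
        return {rid: r.degree for rid, r in self.regions.items()}

    def neighbors(self, rid: int) -> set[int]:
        out = set()
        for u, v in self.edges:
            if u == rid:
                out.add(v)
            elif v == rid:
                out.add(u)
        return out

    def adjacency_lists(self) -> dict[int, list[int]]:
        adj: dict[int, list[int]] = {rid: [] for rid in self.regions}
        for u, v in self.edges:
            adj[u].append(v)
            adj[v].append(u)
        return adj

    def max_degree(self) -> int:
        return max((r.degree for r in self.regions.values()), default=0)

    # -- subsetting ---------------------------------------------------------

    def subnetwork(self, edge_subset: Iterable[tuple[int, int]]) -> "InteractionNetwork":
        """Same regions, restricted edge set (degrees recomputed)."""
        regions = {rid: Region(rid, r.interval) for rid, r in self.regions.items()}
        return InteractionNetwork(regions, edge_subset)

    # -- serialization ------------------------------------------------------

    def node_table(self) -> pd.DataFrame:
        rows = [
            (rid, r.interval.chrom, r.interval.start, r.interval.end, r.degree)
            for rid, r in sorted(self.regions.items())
        ]
        return pd.DataFrame(rows, columns=["id", "chrom", "start", "end", "degree"])

    def edge_table(self) -> pd.DataFrame:
        return pd.DataFrame(sorted(self.edges), columns=["id1", "id2"])

    def write(self, nodes_path, edges_path) -> None:
        self.node_table().to_csv(nodes_path, sep="\t", index=False)
        self.edge_table().to_csv(edges_path, sep="\t", index=False)

    @classmethod
    def read(cls, nodes_path, edges_path) -> "InteractionNetwork":
        nodes = pd.read_csv(nodes_path, sep="\t", comment="#")
        edges = pd.read_csv(edges_path, sep="\t", comment="#")
        regions = {
            int(r.id): Region(int(r.id), GenomicInterval(str(r.chrom), int(r.start), int(r.end)))
            for r in nodes.itertuples()
        }
        return cls(regions, [(int(e.id1), int(e.id2)) for e in edges.itertuples()])

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        for rid, r in self.regions.items():
            g.add_node(rid, chrom=r.interval.chrom, start=r.interval.start,
                       end=r.interval.end, degree=r.degree)
        g.add_edges_from(self.edges)
        return g


@dataclass
class BindingMap:
    """Bipartite factor -> bound-region assignment."""

    factors: list[str]
    bound: dict[str, set[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for f in self.factors:
            self.bound.setdefault(f, set())

    def n_bound(self, factor: str) -> int:
        return len(self.bound[factor])

    def check_consistent(self, network: InteractionNetwork) -> None:
        for f, regions in self.bound.items():
            unknown = regions - set(network.regions)
            if unknown:
                raise ValueError(
                    f"factor {f} bound to region ids absent from network: "
                    f"{sorted(unknown)[:5]}..."
                )

    def to_matrix(self, region_order: Sequence[int]) -> np.ndarray:
        """Boolean (factors x regions) matrix in the given region order."""
        index = {rid: i for i, rid in enumerate(region_order)}
        mat = np.zeros((len(self.factors), len(region_order)), dtype=bool)
        for fi, f in enumerate(self.factors):
            for rid in self.bound[f]:
                mat[fi, index[rid]] = True
        return mat

    def table(self) -> pd.DataFrame:
        rows = [(f, rid) for f in self.factors for rid in sorted(self.bound[f])]
        return pd.DataFrame(rows, columns=["factor", "region_id"])

    def write(self, path) -> None:
        self.table().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path) -> "BindingMap":
        df = pd.read_csv(path, sep="\t", comment="#")
        factors = list(dict.fromkeys(df["factor"].astype(str)))
        bm = cls(factors)
        for f, rid in zip(df["factor"].astype(str), df["region_id"].astype(int)):
            bm.bound[f].add(rid)
        return bm


# ---------------------------------------------------------------------------
# Construction
# ---------------------------------------------------------------------------

class _RegionLocator:
    """Map positions/intervals to disjoint sorted regions, per chromosome."""

    def __init__(self, regions: Mapping[int, Region]):
        self._by_chrom: dict[str, tuple[list[int], list[int], list[int]]] = {}
        per_chrom: dict[str, list[Region]] = {}
        for r in regions.values():
            per_chrom.setdefault(r.interval.chrom, []).append(r)
        for chrom, rs in per_chrom.items():
            rs.sort(key=lambda r: r.interval.start)
            starts = [r.interval.start for r in rs]
            ends = [r.interval.end for r in rs]
            ids = [r.id for r in rs]
            self._by_chrom[chrom] = (starts, ends, ids)

    def containing(self, iv: GenomicInterval) -> int | None:
        """Id of the region fully containing ``iv``, or None."""
        entry = self._by_chrom.get(iv.chrom)
        if entry is None:
            return None
        starts, ends, ids = entry
        i = bisect_right(starts, iv.start) - 1
        if i >= 0 and iv.end <= ends[i]:
            return ids[i]
        return None

    def overlapping(self, iv: GenomicInterval, min_overlap: int = 1) -> list[int]:
        entry = self._by_chrom.get(iv.chrom)
        if entry is None:
            return []
        starts, ends, ids = entry
        out = []
        i = bisect_right(starts, iv.end) - 1
        # walk left while regions can still overlap
        while i >= 0 and ends[i] > iv.start:
            ov = min(ends[i], iv.end) - max(starts[i], iv.start)
            if ov >= min_overlap:
                out.append(ids[i])
            i -= 1
        out.reverse()
        return out


def build_interaction_network(
    pairs: Sequence[tuple[GenomicInterval, GenomicInterval]],
    merge_gap: int = 2000,
    min_span: int = 2000,
    max_degree: int = 20,
    max_length: int = 30000,
    keep_interchromosomal: bool = True,
    iterative_filter: bool = False,
) -> InteractionNetwork:
    """Build the region-region interaction network from anchor pairs.

    Anchors are merged (end-to-start gap <= ``merge_gap``), each pair is
    mapped to the merged regions containing its anchors, self-edges and
    short-range pairs (inter-region gap <= ``min_span`` on the same
    chromosome) are dropped, edges are deduplicated, and regions with
    degree > ``max_degree`` or length > ``max_length`` are removed along
    with their incident edges (degrees recomputed afterwards). Degree and
    length filtering is single-pass by default; ``iterative_filter``
    repeats it until no region violates the thresholds.
    """
    if merge_gap < 0 or min_span < 0 or max_degree <= 0 or max_length <= 0:
        raise ValueError("thresholds must be positive")
    anchors = [iv for pair in pairs for iv in pair]
    merged = merge_intervals(anchors, gap=merge_gap)
    regions = {i: Region(i, iv) for i, iv in enumerate(merged)}
    locator = _RegionLocator(regions)

    edges: set[tuple[int, int]] = set()
    n_self = n_short = n_inter = 0
    for a, b in pairs:
        ra = locator.containing(a)
        rb = locator.containing(b)
        if ra is None or rb is None:
            raise RuntimeError(
                f"anchor {a} or {b} maps to no merged region (internal error)"
            )
        if ra == rb:
            n_self += 1
            continue
        iva, ivb = regions[ra].interval, regions[rb].interval
        if iva.chrom != ivb.chrom:
            if not keep_interchromosomal:
                n_inter += 1
                continue
        else:
            gap = max(iva.start, ivb.start) - min(iva.end, ivb.end)
            if gap <= min_span:
                n_short += 1
                continue
        edges.add((ra, rb) if ra < rb else (rb, ra))

    net = InteractionNetwork(regions, edges)
    logger.info(
        "mapped %d pairs -> %d regions, %d edges (dropped %d self, %d short-range, %d inter-chrom)",
        len(pairs), net.n_regions, net.n_edges, n_self, n_short, n_inter,
    )

    while True:
        bad = {
            rid
            for rid, r in net.regions.items()
            if r.degree > max_degree or r.length > max_length
        }
        if not bad:
            break
        kept_regions = {
            rid: Region(rid, r.interval)
            for rid, r in net.regions.items()
            if rid not in bad
        }
        kept_edges = [
            (u, v) for u, v in net.edges if u not in bad and v not in bad
        ]
        logger.info("removed %d regions violating degree<=%d / length<=%d",
                    len(bad), max_degree, max_length)
        net = InteractionNetwork(kept_regions, kept_edges)
        if not iterative_filter:
            break
    return net


def map_bindings(
    network: InteractionNetwork,
    peaks_by_factor: Mapping[str, Sequence[GenomicInterval]],
    min_overlap: int = 1,
    mode: str = "overlap",
) -> BindingMap:
    """Link each factor to the regions its peaks fall in.

    ``mode='overlap'`` requires >= ``min_overlap`` shared bases between a
    peak and a region; ``mode='midpoint'`` requires the peak midpoint to
    lie inside the region. Multiple peaks in one region yield one link.
    """
    if mode not in ("overlap", "midpoint"):
        raise ValueError(f"unknown binding mode {mode!r}")
    locator = _RegionLocator(network.regions)
    bm = BindingMap(list(peaks_by_factor))
    for factor, peaks in peaks_by_factor.items():
        hits = bm.bound[factor]
        for peak in peaks:
            if mode == "midpoint":
                m = peak.midpoint
                rid = locator.containing(GenomicInterval(peak.chrom, m, m + 1))
                if rid is not None:
                    hits.add(rid)
            else:
                hits.update(locator.overlapping(peak, min_overlap))
        if not hits:
            logger.warning("factor %s maps to zero network regions", factor)
    return bm


def assign_compartments(
    network: InteractionNetwork, compartments: pd.DataFrame
) -> dict[int, str | None]:
    """Label each region with the compartment containing its midpoint.

    ``compartments`` needs columns chrom, start, end, name (e.g. A/B).
    Regions falling in no compartment interval get None.
    """
    comp_regions = {
        i: Region(i, GenomicInterval(str(r.chrom), int(r.start), int(r.end)))
        for i, r in enumerate(compartments.itertuples())
    }
    labels = [str(n) for n in compartments["name"]]
    locator = _RegionLocator(comp_regions)
    out: dict[int, str | None] = {}
    for rid, r in network.regions.items():
        m = r.interval.midpoint
        hit = locator.containing(GenomicInterval(r.interval.chrom, m, m + 1))
        out[rid] = labels[hit] if hit is not None else None
    return out


def restrict_to_compartment(
    network: InteractionNetwork, compartments: pd.DataFrame, label: str
) -> InteractionNetwork:
    """Keep only edges whose two endpoints both lie in compartment ``label``."""
    comp = assign_compartments(network, compartments)
    edges = [(u, v) for u, v in network.edges if comp[u] == label and comp[v] == label]
    return network.subnetwork(edges)
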