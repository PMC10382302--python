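import numpy as np
import pytest

from chromcooc.intervals import GenomicInterval
from chromcooc.network import BindingMap, InteractionNetwork, Region


def make_network(degseq_edges, chrom="chrT", length=1000, gap=5000):
    """Network from an explicit edge list; regions laid out disjointly."""
    n = 1 + max((max(e) for e in degseq_edges), default=0)
    regions = {
        i: Region(i, GenomicInterval(chrom, i * (length + gap),
                                     i * (length + gap) + length))
        for i in range(n)
    }
    return InteractionNetwork(regions, degseq_edges)


@pytest.fixture
def toy_network():
    """12 regions with degrees 0..4: a path, a star, a triangle, loners."""
    edges = [
        (0, 1), (1, 2), (2, 3),          # path
        (4, 5), (4, 6), (4, 7), (4, 8),  # star centred on 4
        (9, 10), (10, 11), (9, 11),      # triangle
    ]
    return make_network(edges)


@pytest.fixture
def toy_binding(toy_network):
    rng = np.random.default_rng(7)
    factors = ["A", "B", "C"]
    bm = BindingMap(factors)
    ids = toy_network.region_ids
    for f in factors:
        k = rng.integers(3, 8)
        bm.bound[f] = set(rng.choice(ids, size=k, replace=False).tolist())
    return bm


def brute_force_spatial(network, binding):
    """O(edges x factors^2) reference spatial co-occurrence counter:
    ordered endpoint assignments per edge, homotypic counted once."""
    factors = binding.factors
    n = len(factors)
    counts = np.zeros((n, n), dtype=int)
    for u, v in network.edges:
        for i, fi in enumerate(factors):
            for j, fj in enumerate(factors):
                if i == j:
                    if u in binding.bound[fi] and v in binding.bound[fi]:
                        counts[i, i] += 1
                else:
                    if u in binding.bound[fi] and v in binding.bound[fj]:
                        counts[i, j] += 1
                    if v in binding.bound[fi] and u in binding.bound[fj]:
                        counts[i, j] += 1
    return counts
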