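"""Position weight matrices: information content, log-likelihood-ratio
scoring, exact score distributions, and motif-instance scanning.

A PWM holds per-position probabilities over A, C, G, T. Scores are
log-likelihood ratios in log2 units against a background model (uniform by
default). The exact distribution of window scores under the background is
computed by dynamic programming on a discretized score grid, which yields
p-values for instance calling at the conventional 1e-4 threshold.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import cached_property
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval
from .network import BindingMap, InteractionNetwork, _RegionLocator

logger = logging.getLogger(__name__)

BASES = "ACGT"
_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")

DEFAULT_PSEUDOCOUNT = 1e-4
FIMO_DEFAULT_P = 1e-4


def encode(seq: str) -> np.ndarray:
    """Sequence -> integer codes (A=0 C=1 G=2 T=3, anything else 4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Background:
    """Zeroth-order background model over A, C, G, T."""

    probs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (4,) or np.any(p < 0) or abs(p.sum() - 1) > 1e-6:
            raise ValueError("background must be 4 non-negative probs summing to 1")


UNIFORM_BG = Background()


@dataclass(frozen=True)
class PWM:
    """A named position weight matrix (L x 4 probabilities)."""

    name: str
    matrix: tuple  # tuple of per-position 4-tuples; hashable/frozen

    @classmethod
    def from_array(cls, name: str, matrix) -> "PWM":
        m = np.asarray(matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4:
            raise ValueError("PWM matrix must be L x 4")
        if np.any(m < 0) or np.any(np.abs(m.sum(axis=1) - 1) > 1e-6):
            raise ValueError("each PWM row must be non-negative and sum to 1")
        return cls(name, tuple(tuple(row) for row in m))

    @cached_property
    def array(self) -> np.ndarray:
        return np.asarray(self.matrix, dtype=float)

    @property
    def length(self) -> int:
        return len(self.matrix)

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.array.argmax(axis=1))

    def log_odds(self, background: Background = UNIFORM_BG,
                 pseudocount: float = DEFAULT_PSEUDOCOUNT) -> np.ndarray:
        """Per-position log2 likelihood-ratio matrix.

        A small pseudocount is added and rows renormalized so zero entries
        never produce -inf; the raw matrix is used for information content.
        """
        w = self.array + pseudocount
        w /= w.sum(axis=1, keepdims=True)
        return np.log2(w) - np.log2(np.asarray(background.probs))

    def reverse_complement(self) -> "PWM":
        return PWM.from_array(self.name, self.array[::-1, ::-1])


def information_score(pwm: PWM) -> float:
    """Total information content in bits: sum over positions of
    2 + sum_b W log2 W, with 0*log2(0) = 0. Ranges over [0, 2L]."""
    w = pwm.array
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(w > 0, w * np.log2(np.where(w > 0, w, 1.0)), 0.0)
    return float(np.sum(2.0 + plogp.sum(axis=1)))


def select_representative(pwms: Sequence[PWM]) -> PWM:
    """Most informative PWM of a cluster; ties broken by name."""
    if not pwms:
        raise ValueError("empty motif cluster")
    return min(pwms, key=lambda p: (-information_score(p), p.name))


def llr_score(window: str, pwm: PWM, background: Background = UNIFORM_BG,
              pseudocount: float = DEFAULT_PSEUDOCOUNT) -> float:
    """LLR (log2) of one window of length L under the PWM vs background."""
    codes = encode(window)
    if codes.size != pwm.length:
        raise ValueError(f"window length {codes.size} != motif length {pwm.length}")
    if np.any(codes > 3):
        raise ValueError("window contains ambiguous bases")
    q = pwm.log_odds(background, pseudocount)
    return float(q[np.arange(pwm.length), codes].sum())


def _window_scores(codes: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Scores of every window; NaN where the window has ambiguous bases."""
    L = q.shape[0]
    n = codes.size - L + 1
    if n <= 0:
        return np.empty(0)
    win = np.lib.stride_tricks.sliding_window_view(codes, L)
    bad = (win > 3).any(axis=1)
    safe = np.where(win > 3, 0, win)
    scores = q[np.arange(L), safe].sum(axis=1)
    scores[bad] = np.nan
    return scores


@dataclass
class PeakMotifScore:
    interval: GenomicInterval
    factor: str
    score: float


def peak_motif_score(sequence: str, pwm: PWM,
                     background: Background = UNIFORM_BG) -> float:
    """Maximum window LLR over both strands of a peak sequence."""
    if len(sequence) < pwm.length:
        raise ValueError("sequence shorter than the motif")
    q = pwm.log_odds(background)
    qrc = pwm.reverse_complement().log_odds(background)
    codes = encode(sequence)
    fwd = _window_scores(codes, q)
    rev = _window_scores(codes, qrc)
    best = np.nanmax(np.concatenate([fwd, rev]))
    if np.isnan(best):
        raise ValueError("no unambiguous window in sequence")
    return float(best)


# ---------------------------------------------------------------------------
# Exact score distribution (discretized dynamic programme)
# ---------------------------------------------------------------------------

@dataclass
class ScoreDistribution:
    """Distribution of single-window LLR scores under the background.

    Built by position-wise convolution on an integer score grid of
    resolution ``eps`` bits; the total probability mass is exactly 1.
    """

    eps: float
    offset: int            # integer score of pmf index 0
    pmf: np.ndarray

    @cached_property
    def _sf(self) -> np.ndarray:
        return np.cumsum(self.pmf[::-1])[::-1]

    @property
    def support(self) -> np.ndarray:
        return (self.offset + np.arange(self.pmf.size)) * self.eps

    def sf(self, score: float) -> float:
        """P(window score >= score) under the background."""
        k = int(np.rint(score / self.eps)) - self.offset
        if k <= 0:
            return 1.0
        if k >= self.pmf.size:
            return 0.0
        return float(self._sf[k])

    def threshold(self, p: float = FIMO_DEFAULT_P) -> float:
        """Smallest score with sf(score) <= p (inf if unattainable)."""
        idx = np.flatnonzero(self._sf <= p)
        if idx.size == 0:
            return math.inf
        return float((self.offset + idx[0]) * self.eps)


def score_distribution(pwm: PWM, background: Background = UNIFORM_BG,
                       bins: int = 1000,
                       pseudocount: float = DEFAULT_PSEUDOCOUNT) -> ScoreDistribution:
    """Exact (up to grid resolution) null distribution of window scores."""
    if bins < 1:
        raise ValueError("bins must be >= 1")
    q = pwm.log_odds(background, pseudocount)
    span = float((q.max(axis=1) - q.min(axis=1)).sum())
    eps = span / bins if span > 0 else 1.0
    iq = np.rint(q / eps).astype(np.int64)
    bg = np.asarray(background.probs)

    lo = int(iq.min(axis=1).sum())
    hi = int(iq.max(axis=1).sum())
    pmf = np.zeros(hi - lo + 1)
    # DP: start with the empty prefix at integer score 0
    cur = np.array([1.0])
    cur_off = 0
    for n in range(pwm.length):
        row = iq[n]
        new_off = cur_off + int(row.min())
        new = np.zeros(cur.size + int(row.max() - row.min()))
        for b in range(4):
            shift = int(row[b]) - int(row.min())
            new[shift:shift + cur.size] += bg[b] * cur
        cur, cur_off = new, new_off
    assert cur_off == lo and cur.size == pmf.size, (cur_off, lo)
    pmf[:] = cur
    return ScoreDistribution(eps=eps, offset=lo, pmf=pmf)


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------

@dataclass
class MotifHit:
    region_id: int
    offset: int          # genomic start of the matched window
    strand: str
    llr: float
    score_pvalue: float


def _fetch(genome, chrom: str, start: int, end: int) -> str:
    """Extract a subsequence from a dict of strings or a pyfaidx Fasta."""
    seq = genome[chrom]
    n = len(seq)
    if end > n:
        logger.warning("region %s:%d-%d clipped to chromosome end %d",
                       chrom, start, end, n)
        end = n
    start = max(0, start)
    sub = seq[start:end]
    return sub if isinstance(sub, str) else str(sub)


def scan_regions(
    genome,
    regions: Mapping[int, GenomicInterval] | InteractionNetwork,
    pwm: PWM,
    background: Background = UNIFORM_BG,
    p_threshold: float = FIMO_DEFAULT_P,
    bins: int = 1000,
) -> list[MotifHit]:
    """All motif instances with score p-value <= ``p_threshold``.

    Both strands are scanned; a '-' strand hit is reported at the genomic
    start of its window on the forward strand.
    """
    if isinstance(regions, InteractionNetwork):
        regions = {rid: r.interval for rid, r in regions.regions.items()}
    dist = score_distribution(pwm, background, bins=bins)
    thr = dist.threshold(p_threshold)
    q = pwm.log_odds(background)
    qrc = pwm.reverse_complement().log_odds(background)
    hits: list[MotifHit] = []
    for rid in sorted(regions):
        iv = regions[rid]
        seq = _fetch(genome, iv.chrom, iv.start, iv.end)
        if len(seq) < pwm.length:
            continue
        codes = encode(seq)
        for strand, mat in (("+", q), ("-", qrc)):
            scores = _window_scores(codes, mat)
            for k in np.flatnonzero(scores >= thr):
                s = float(scores[k])
                hits.append(MotifHit(rid, iv.start + int(k), strand, s, dist.sf(s)))
    return hits


def motif_binding_map(
    hits_by_factor: Mapping[str, Iterable[MotifHit]],
    network: InteractionNetwork,
) -> BindingMap:
    """BindingMap linking each motif (as a factor) to regions with >= 1 hit."""
    bm = BindingMap(list(hits_by_factor))
    valid = set(network.regions)
    for factor, hits in hits_by_factor.items():
        bm.bound[factor] = {h.region_id for h in hits if h.region_id in valid}
    return bm


def read_fimo_tsv(path) -> pd.DataFrame:
    """Read FIMO's TSV output (motif_id, sequence_name, start, stop,
    strand, score, p-value). FIMO coordinates are 1-based inclusive; they
    are converted to 0-based half-open."""
    df = pd.read_csv(path, sep="\t", comment="#")
    df = df.rename(columns={"p-value": "pvalue"})
    need = {"motif_id", "sequence_name", "start", "stop", "strand", "score"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"FIMO table missing columns: {sorted(missing)}")
    df["start"] = df["start"].astype(int) - 1
    df["stop"] = df["stop"].astype(int)
    return df


def fimo_binding_map(fimo: pd.DataFrame, network: InteractionNetwork,
                     p_threshold: float = FIMO_DEFAULT_P) -> BindingMap:
    """Convert FIMO hits (sequence_name = chromosome) to a BindingMap."""
    locator = _RegionLocator(network.regions)
    if "pvalue" in fimo.columns:
        fimo = fimo[fimo["pvalue"] <= p_threshold]
    factors = list(dict.fromkeys(fimo["motif_id"].astype(str)))
    bm = BindingMap(factors)
    for r in fimo.itertuples():
        iv = GenomicInterval(str(r.sequence_name), int(r.start), int(r.stop))
        for rid in locator.overlapping(iv):
            bm.bound[str(r.motif_id)].add(rid)
    return bm


# ---------------------------------------------------------------------------
# Strong-motif / spatial-isolation analysis
# ---------------------------------------------------------------------------

def _assign_peaks(peaks: pd.DataFrame, network: InteractionNetwork) -> pd.Series:
    """Region id of the network region each peak overlaps most, else -1."""
    locator = _RegionLocator(network.regions)
    out = []
    for r in peaks.itertuples():
        iv = GenomicInterval(str(r.chrom), int(r.start), int(r.end))
        rids = locator.overlapping(iv)
        if not rids:
            out.append(-1)
        else:
            best = max(rids, key=lambda rid: (
                min(network.regions[rid].interval.end, iv.end)
                - max(network.regions[rid].interval.start, iv.start)))
            out.append(best)
    return pd.Series(out, index=peaks.index, name="region_id")


def strong_motif_partition(
    peaks: pd.DataFrame,
    network: InteractionNetwork,
    strong_quantile: float = 0.90,
) -> pd.DataFrame:
    """Fraction of strong-motif peaks among isolated vs interacting peaks.

    ``peaks`` needs columns factor, chrom, start, end, score (the peak's
    max-window LLR). Per factor, "strong" means score >= that factor's
    ``strong_quantile`` score percentile (ties included). A peak is
    isolated if it overlaps no network region or only regions of degree 0.
    Factors with fewer than 10 peaks are flagged as unstable.
    """
    peaks = peaks.copy()
    peaks["region_id"] = _assign_peaks(peaks, network)
    degree = network.degrees()
    peaks["isolated"] = [
        rid == -1 or degree[rid] == 0 for rid in peaks["region_id"]
    ]
    rows = []
    for factor, grp in peaks.groupby("factor", sort=True):
        thr = float(np.quantile(grp["score"], strong_quantile))
        strong = grp["score"] >= thr
        iso = grp["isolated"]
        n_iso, n_int = int(iso.sum()), int((~iso).sum())
        rows.append({
            "factor": factor,
            "n_peaks": len(grp),
            "strong_threshold": thr,
            "n_isolated": n_iso,
            "n_interacting": n_int,
            "frac_strong_isolated": float(strong[iso].mean()) if n_iso else np.nan,
            "frac_strong_interacting": float(strong[~iso].mean()) if n_int else np.nan,
            "unstable": len(grp) < 10,
        })
        if len(grp) < 10:
            logger.warning("factor %s has %d peaks; strong-motif quantile unstable",
                           factor, len(grp))
    return pd.DataFrame(rows)


def same_tf_refinement(
    peaks: pd.DataFrame,
    network: InteractionNetwork,
    binding: BindingMap,
    strong_quantile: float = 0.90,
) -> pd.DataFrame:
    """Split interacting peaks by same-factor binding on a neighbour region.

    Among each factor's peaks in interacting regions, compares the strong
    fraction between peaks whose region has >= 1 spatial neighbour bound by
    the same factor and those without.
    """
    peaks = peaks.copy()
    peaks["region_id"] = _assign_peaks(peaks, network)
    degree = network.degrees()
    adj = network.adjacency_lists()
    rows = []
    for factor, grp in peaks.groupby("factor", sort=True):
        thr = float(np.quantile(grp["score"], strong_quantile))
        bound = binding.bound.get(factor, set())
        same, other = [], []
        for r in grp.itertuples():
            rid = r.region_id
            if rid == -1 or degree[rid] == 0:
                continue
            is_strong = r.score >= thr
            if any(nb in bound for nb in adj[rid]):
                same.append(is_strong)
            else:
                other.append(is_strong)
        rows.append({
            "factor": factor,
            "n_same_tf": len(same),
            "n_other": len(other),
            "frac_strong_same_tf": float(np.mean(same)) if same else np.nan,
            "frac_strong_other": float(np.mean(other)) if other else np.nan,
        })
    return pd.DataFrame(rows)


def score_peaks(genome, peaks: pd.DataFrame, pwms: Mapping[str, PWM],
                background: Background = UNIFORM_BG) -> pd.DataFrame:
    """Add a max-window-LLR ``score`` column to a peaks table.

    ``pwms`` maps factor name -> PWM. Peaks of factors without a PWM, or
    shorter than the motif, are dropped with a warning.
    """
    rows = []
    for r in peaks.itertuples():
        factor = str(r.factor)
        pwm = pwms.get(factor)
        if pwm is None:
            continue
        seq = _fetch(genome, str(r.chrom), int(r.start), int(r.end))
        if len(seq) < pwm.length:
            logger.warning("peak %s:%d-%d shorter than motif; excluded",
                           r.chrom, r.start, r.end)
            continue
        rows.append((factor, str(r.chrom), int(r.start), int(r.end),
                     peak_motif_score(seq, pwm, background)))
    return pd.DataFrame(rows, columns=["factor", "chrom", "start", "end", "score"])


# ---------------------------------------------------------------------------
# MEME minimal format I/O
# ---------------------------------------------------------------------------

def read_meme(path) -> list[PWM]:
    """Read motifs from a MEME minimal-format file."""
    from Bio import motifs as bio_motifs

    with open(path) as fh:
        records = bio_motifs.parse(fh, "minimal")
    out = []
    for m in records:
        L = m.length
        mat = np.array([[m.pwm[b][n] for b in BASES] for n in range(L)])
        mat /= mat.sum(axis=1, keepdims=True)
        out.append(PWM.from_array(m.name or m.base_id, mat))
    return out


def write_meme(pwms: Sequence[PWM], path,
               background: Background = UNIFORM_BG) -> None:
    """Write motifs in MEME minimal format."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        fh.write("strands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write("A %.5f C %.5f G %.5f T %.5f\n\n" % tuple(background.probs))
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.name}\n")
            # large nsites: some readers reconstruct counts as prob*nsites
            # and would otherwise quantize the probabilities
            fh.write(
                f"letter-probability matrix: alength= 4 w= {pwm.length} "
                f"nsites= 1000000 E= 0\n"
            )
            for row in pwm.array:
                fh.write(" %10.6f %10.6f %10.6f %10.6f\n" % tuple(row))
            fh.write("\n")


def read_motif_clusters(path) -> dict[str, list[str]]:
    """Two-column TSV (cluster_id, motif_name) -> cluster -> motif names."""
    df = pd.read_csv(path, sep="\t", header=None, names=["cluster", "motif"],
                     comment="#")
    out: dict[str, list[str]] = {}
    for r in df.itertuples():
        out.setdefault(str(r.cluster), []).append(str(r.motif))
    return out


def cluster_representatives(pwms: Sequence[PWM],
                            clusters: Mapping[str, Sequence[str]]) -> dict[str, PWM]:
    """Most informative motif per cluster."""
    by_name = {p.name: p for p in pwms}
    out = {}
    for cid, names in clusters.items():
        members = [by_name[n] for n in names if n in by_name]
        if not members:
            raise ValueError(f"cluster {cid} has no motifs present in the file")
        out[cid] = select_representative(members)
    return out
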