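"""Genomic intervals and interval arithmetic.

All coordinates are 0-based, half-open (BED convention): an interval
``(chrom, start, end)`` covers bases ``start .. end-1``. Two intervals that
merely abut (``a.end == b.start``) share no base, so their overlap is zero
and their gap is zero.
"""

from __future__ import annotations

from typing import Iterable, NamedTuple

import pandas as pd


class GenomicInterval(NamedTuple):
    """A half-open genomic interval."""

    chrom: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def validate(self) -> "GenomicInterval":
        if not self.chrom:
            raise ValueError(f"empty chromosome name in {self!r}")
        if self.start >= self.end:
            raise ValueError(
                f"malformed interval {self.chrom}:{self.start}-{self.end} "
                "(start must be < end)"
            )
        return self


def overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of shared bases; 0 if disjoint or on different chromosomes."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def gap_bp(a: GenomicInterval, b: GenomicInterval) -> int | None:
    """End-to-start gap between two intervals on the same chromosome.

    Overlapping or abutting intervals have gap <= 0. Returns None for
    intervals on different chromosomes (no meaningful linear distance).
    """
    if a.chrom != b.chrom:
        return None
    return max(a.start, b.start) - min(a.end, b.end)


def merge_intervals(
    intervals: Iterable[GenomicInterval], gap: int = 2000
) -> list[GenomicInterval]:
    """Merge intervals lying within ``gap`` bp of each other.

    Intervals on the same chromosome whose end-to-start separation is at
    most ``gap`` are unioned (transitively). The result is sorted by
    (chrom, start) and pairwise separated by more than ``gap``. Merging is
    idempotent: applying it to its own output is a no-op.
    """
    if gap < 0:
        raise ValueError("gap must be >= 0")
    ivs = [GenomicInterval(*iv).validate() for iv in intervals]
    ivs.sort()
    merged: list[GenomicInterval] = []
    for iv in ivs:
        if merged and merged[-1].chrom == iv.chrom and iv.start - merged[-1].end <= gap:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(iv)
    return merged


# ---------------------------------------------------------------------------
# File readers (plain-text, tab-separated)
# ---------------------------------------------------------------------------

def read_interaction_pairs(
    path,
) -> list[tuple[GenomicInterval, GenomicInterval]]:
    """Read anchor pairs from a BEDPE-compatible TSV.

    Expects columns chrom1 start1 end1 chrom2 start2 end2; extra columns
    (e.g. an interaction score) are ignored. Lines starting with '#' are
    skipped.
    """
    pairs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(
                    f"{path}:{lineno}: expected >= 6 tab-separated columns"
                )
            try:
                a = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
                b = GenomicInterval(fields[3], int(fields[4]), int(fields[5]))
                pairs.append((a.validate(), b.validate()))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return pairs


_BED_COLUMNS = [
    "chrom", "start", "end", "name", "score", "strand",
    "signalValue", "pValue", "qValue", "peak",
]


def read_bed(path) -> pd.DataFrame:
    """Read a BED3+ / narrowPeak file into a DataFrame.

    Columns beyond the first three are optional; narrowPeak's signalValue
    (column 7) is retained when present, for use as a peak score.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    ncol = min(df.shape[1], len(_BED_COLUMNS))
    df = df.iloc[:, :ncol]
    df.columns = _BED_COLUMNS[:ncol]
    bad = df["start"] >= df["end"]
    if bad.any():
        i = int(bad.idxmax())
        rec = df.loc[i]
        raise ValueError(
            f"{path}: malformed interval {rec.chrom}:{rec.start}-{rec.end} "
            f"at record {i + 1}"
        )
    return df


def bed_intervals(df: pd.DataFrame) -> list[GenomicInterval]:
    return [
        GenomicInterval(str(c), int(s), int(e))
        for c, s, e in zip(df["chrom"], df["start"], df["end"])
    ]
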