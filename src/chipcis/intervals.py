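"""Genomic-interval data model and interval arithmetic.

Coordinates are 0-based, half-open (BED convention). Summits in narrowPeak
files are stored as offsets relative to the peak start; readers convert them
to absolute positions on load.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "ScoredPeak",
    "intersect",
    "count_distinct_overlapping",
    "filter_peaks",
    "normalize_chrom",
]


def normalize_chrom(name: str, style: str = "chr") -> str:
    """Normalize a chromosome name to the ``chr``-prefixed or bare dialect.

    Parameters
    ----------
    name
        Chromosome name in either dialect (``chr7`` or ``7``).
    style
        ``"chr"`` adds the prefix, ``"bare"`` strips it.
    """
    bare = name[3:] if name.lower().startswith("chr") else name
    if style == "chr":
        return "chr" + bare
    if style == "bare":
        return bare
    raise ValueError(f"unknown chromosome-name style: {style!r}")


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval: [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be '+', '-' or '.', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval", slop: int = 0) -> bool:
        """True if *self*, symmetrically extended by *slop* bp, shares >= 1 bp
        with *other* on the same chromosome."""
        if slop < 0:
            raise ValueError(f"slop must be non-negative, got {slop}")
        return (
            self.chrom == other.chrom
            and self.start - slop < other.end
            and other.start < self.end + slop
        )

    def overlap_length(self, other: "GenomicInterval", slop: int = 0) -> int:
        """Length in bp of the overlap between *self* +- slop and *other*
        (0 when disjoint or on different chromosomes)."""
        if self.chrom != other.chrom:
            return 0
        lo = max(self.start - slop, other.start)
        hi = min(self.end + slop, other.end)
        return max(0, hi - lo)

    def span_with(self, other: "GenomicInterval") -> "GenomicInterval":
        """Union span covering both intervals (same chromosome required)."""
        if self.chrom != other.chrom:
            raise ValueError("cannot span intervals on different chromosomes")
        return GenomicInterval(
            self.chrom, min(self.start, other.start), max(self.end, other.end)
        )


@dataclass(frozen=True)
class ScoredPeak:
    """A called ChIP-seq peak with its caller scores and (optional) counts.

    ``read_count`` / ``background_count`` are reads in the peak and in its
    matched, equal-length background region; they may be absent on load and
    attached later from a coverage track or a counts table.
    """

    interval: GenomicInterval
    summit: int
    fold_change: float
    neg_log10_q: float
    read_count: float | None = None
    background_count: float | None = None
    name: str = "."

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValueError(
                f"summit {self.summit} outside peak "
                f"[{self.interval.start}, {self.interval.end})"
            )
        if self.fold_change <= 0:
            raise ValueError(f"fold_change must be > 0, got {self.fold_change}")
        if self.neg_log10_q < 0:
            raise ValueError(f"neg_log10_q must be >= 0, got {self.neg_log10_q}")
        for label, v in (("read_count", self.read_count),
                         ("background_count", self.background_count)):
            if v is not None and v < 0:
                raise ValueError(f"{label} must be >= 0, got {v}")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    def with_counts(self, read_count: float, background_count: float) -> "ScoredPeak":
        return replace(self, read_count=read_count, background_count=background_count)


def intersect(
    setA: Sequence[GenomicInterval],
    setB: Sequence[GenomicInterval],
    slop: int = 0,
) -> list[tuple[int, int]]:
    """All overlapping index pairs between two interval sets.

    *slop* is applied symmetrically to set-A intervals before testing overlap,
    so a pair (a, b) is reported when ``a.start - slop < b.end`` and
    ``b.start < a.end + slop`` on the same chromosome (>= 1 bp of overlap at
    slop 0; "adjacent" sites are captured by a positive slop).

    Returns pairs sorted by (chrom, a.start, b.start), then by index for full
    determinism.
    """
    if slop < 0:
        raise ValueError(f"slop must be non-negative, got {slop}")
    trees: dict[str, IntervalTree] = {}
    for j, b in enumerate(setB):
        trees.setdefault(b.chrom, IntervalTree()).addi(b.start, b.end, j)
    pairs: list[tuple[str, int, int, int, int]] = []
    for i, a in enumerate(setA):
        tree = trees.get(a.chrom)
        if tree is None:
            continue
        lo = a.start - slop
        hi = a.end + slop
        for hit in tree.overlap(lo, hi):
            pairs.append((a.chrom, a.start, setB[hit.data].start, i, hit.data))
    pairs.sort()
    return [(i, j) for _, _, _, i, j in pairs]


def count_distinct_overlapping(
    setA: Sequence[GenomicInterval],
    setB: Sequence[GenomicInterval],
    slop: int = 0,
) -> tuple[int, int]:
    """Count the distinct members of each set that take part in >= 1 overlap.

    This is the "m of N peaks overlap n of M peaks" statistic: a single A
    interval covering three B intervals counts once on the A side and three
    times on the B side.
    """
    pairs = intersect(setA, setB, slop)
    return len({i for i, _ in pairs}), len({j for _, j in pairs})


def filter_peaks(
    peaks: Iterable[ScoredPeak],
    min_fold_change: float,
    min_neg_log10_q: float,
) -> list[ScoredPeak]:
    """Retain peaks with fold_change and -log10(q) strictly above thresholds.

    Comparisons are strict (">"), so a peak sitting exactly on a threshold is
    removed. Input order is preserved; the operation is idempotent.
    """
    if min_fold_change < 0 or min_neg_log10_q < 0:
        raise ValueError("thresholds must be non-negative")
    return [
        p
        for p in peaks
        if p.fold_change > min_fold_change and p.neg_log10_q > min_neg_log10_q
    ]


#: Published peak-filter presets: (min_fold_change, min_neg_log10_q).
FILTER_PRESETS: dict[str, tuple[float, float]] = {
    "smad3": (5.0, 10.0),
    "tcf21_liberal": (5.0, 25.0),
    "tcf21_standard": (10.0, 60.0),
    "tcf21_stringent": (15.0, 200.0),
}
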