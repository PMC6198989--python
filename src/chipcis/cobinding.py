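"""Differential co-binding of two ChIP-seq'd transcription factors.

At loci where both factors bind, each peak's signal is normalized against its
local background (normalized fold change, nfc), the nfc distributions are put
on a common 0-100 relative scale, and each joint site is classified as biased
toward one factor when the nfc ratio exceeds a fold threshold (default
two-fold). Summit-centered average-coverage profiles provide the metaplot
view of co-binding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .intervals import GenomicInterval, ScoredPeak, intersect

__all__ = [
    "JointSite",
    "BiasSummary",
    "SummitProfile",
    "normalized_fold_change",
    "rescale_0_100",
    "build_joint_sites",
    "summarize_bias",
    "summit_profile",
    "attach_counts_from_coverage",
]

logger = logging.getLogger(__name__)

A_BIASED = "A_biased"
B_BIASED = "B_biased"
UNBIASED = "unbiased"


class CountsUnavailableError(ValueError):
    """Raised when a peak lacks read/background counts.

    Supply a coverage track (see :func:`attach_counts_from_coverage`) or a
    precomputed counts column.
    """


@dataclass(frozen=True)
class JointSite:
    """A matched pair of peaks, one per factor, at a co-bound locus."""

    peakA: ScoredPeak
    peakB: ScoredPeak
    merged: GenomicInterval
    nfcA: float
    nfcB: float
    scaledA: float
    scaledB: float
    bias: str


@dataclass(frozen=True)
class BiasSummary:
    """Tally of bias labels over a set of joint sites.

    ``frac_A``/``frac_B`` are fractions of the *biased* sites (None when no
    site is biased); ``pct_A``/``pct_B`` are the same rounded to the nearest
    integer percentage for display.
    """

    n_joint: int
    n_biased: int
    n_A: int
    n_B: int

    @property
    def frac_A(self) -> float | None:
        return self.n_A / self.n_biased if self.n_biased else None

    @property
    def frac_B(self) -> float | None:
        return self.n_B / self.n_biased if self.n_biased else None

    @property
    def pct_A(self) -> int | None:
        return round(100 * self.frac_A) if self.n_biased else None

    @property
    def pct_B(self) -> int | None:
        return round(100 * self.frac_B) if self.n_biased else None


@dataclass(frozen=True)
class SummitProfile:
    """Per-offset mean signal around peak summits, one series per track."""

    halfwidth: int
    positions: np.ndarray  # offsets -halfwidth .. +halfwidth
    mean_signal: dict[str, np.ndarray]


def normalized_fold_change(peak: ScoredPeak, pseudocount: float = 1.0) -> float:
    """Relative read count of a peak versus its matched background region.

    Computed as ``(read_count + c) / (background_count + c)`` with pseudocount
    ``c`` guarding zero backgrounds; a site with no reads anywhere is neutral
    (nfc = 1).
    """
    if peak.read_count is None or peak.background_count is None:
        raise CountsUnavailableError(
            "counts unavailable; supply coverage track or counts column"
        )
    return (peak.read_count + pseudocount) / (peak.background_count + pseudocount)


def rescale_0_100(values: Sequence[float]) -> list[float]:
    """Min-max rescale non-negative values to the 0-100 relative scale.

    Order-preserving: the minimum maps to 0 and the maximum to 100. Requires
    at least two values with some spread.
    """
    if len(values) < 2:
        raise ValueError("rescale_0_100 requires at least 2 values")
    lo, hi = min(values), max(values)
    if hi == lo:
        raise ValueError("degenerate scale: all values equal")
    # ratio computed first so the extremes map to exactly 0 and 100
    return [(v - lo) / (hi - lo) * 100.0 for v in values]


def _resolve_pairs(
    peaksA: Sequence[ScoredPeak],
    peaksB: Sequence[ScoredPeak],
    slop: int,
) -> list[tuple[int, int]]:
    """One pair per locus: each peak used at most once, greedily keeping the
    pair with the largest bp overlap, ties broken by larger B read count and
    then leftmost coordinate."""
    raw = intersect([p.interval for p in peaksA], [p.interval for p in peaksB], slop)
    scored = []
    for i, j in raw:
        ov = peaksA[i].interval.overlap_length(peaksB[j].interval, slop)
        read_b = peaksB[j].read_count or 0.0
        scored.append(
            (-ov, -read_b, peaksA[i].chrom, peaksA[i].interval.start,
             peaksB[j].interval.start, i, j)
        )
    scored.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    kept: list[tuple[int, int]] = []
    for *_, i, j in scored:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        kept.append((i, j))
    kept.sort(key=lambda ij: (peaksA[ij[0]].chrom, peaksA[ij[0]].interval.start))
    return kept


def build_joint_sites(
    peaksA: Sequence[ScoredPeak],
    peaksB: Sequence[ScoredPeak],
    slop: int = 0,
    bias_threshold: float = 2.0,
    pseudocount: float = 1.0,
) -> list[JointSite]:
    """Match overlapping peaks of two factors and classify binding bias.

    Overlap pairs are resolved to one :class:`JointSite` per locus. A site is
    called biased toward a factor when that factor's nfc exceeds the other's
    by strictly more than ``bias_threshold``-fold (default 2). The 0-100
    scaled values are min-max over this joint-site set only, per factor.
    """
    if bias_threshold <= 1:
        raise ValueError(f"bias_threshold must be > 1, got {bias_threshold}")
    pairs = _resolve_pairs(peaksA, peaksB, slop)
    if not pairs:
        return []
    nfcA = [normalized_fold_change(peaksA[i], pseudocount) for i, _ in pairs]
    nfcB = [normalized_fold_change(peaksB[j], pseudocount) for _, j in pairs]
    try:
        scaledA = rescale_0_100(nfcA)
    except ValueError:
        logger.warning("degenerate factor-A nfc scale; scaled values set to 0")
        scaledA = [0.0] * len(nfcA)
    try:
        scaledB = rescale_0_100(nfcB)
    except ValueError:
        logger.warning("degenerate factor-B nfc scale; scaled values set to 0")
        scaledB = [0.0] * len(nfcB)
    sites = []
    for k, (i, j) in enumerate(pairs):
        if nfcA[k] / nfcB[k] > bias_threshold:
            bias = A_BIASED
        elif nfcB[k] / nfcA[k] > bias_threshold:
            bias = B_BIASED
        else:
            bias = UNBIASED
        sites.append(
            JointSite(
                peakA=peaksA[i],
                peakB=peaksB[j],
                merged=peaksA[i].interval.span_with(peaksB[j].interval),
                nfcA=nfcA[k],
                nfcB=nfcB[k],
                scaledA=scaledA[k],
                scaledB=scaledB[k],
                bias=bias,
            )
        )
    return sites


def summarize_bias(sites: Sequence[JointSite]) -> BiasSummary:
    """Tally bias labels; fractions of biased sites are None when undefined."""
    n_A = sum(1 for s in sites if s.bias == A_BIASED)
    n_B = sum(1 for s in sites if s.bias == B_BIASED)
    return BiasSummary(n_joint=len(sites), n_biased=n_A + n_B, n_A=n_A, n_B=n_B)


def summit_profile(
    summits: Sequence[tuple[str, int]],
    tracks: Mapping[str, Mapping[str, np.ndarray]],
    halfwidth: int = 1000,
) -> SummitProfile:
    """Average signal in +-halfwidth windows around summits, per track.

    ``tracks`` maps track name -> {chrom -> per-base coverage array}. Windows
    truncated at chromosome edges contribute only their defined offsets, so
    each offset's mean is over the summits whose window covers it.
    """
    if not summits:
        raise ValueError("summit_profile requires at least one summit")
    if halfwidth <= 0:
        raise ValueError(f"halfwidth must be positive, got {halfwidth}")
    width = 2 * halfwidth + 1
    positions = np.arange(-halfwidth, halfwidth + 1)
    means: dict[str, np.ndarray] = {}
    for name, cov in tracks.items():
        total = np.zeros(width)
        count = np.zeros(width)
        for chrom, pos in summits:
            arr = cov.get(chrom)
            chrom_len = len(arr) if arr is not None else 0
            lo = max(0, pos - halfwidth)
            hi = min(chrom_len, pos + halfwidth + 1)
            if hi <= lo:
                continue
            off_lo = lo - (pos - halfwidth)
            off_hi = off_lo + (hi - lo)
            total[off_lo:off_hi] += arr[lo:hi]
            count[off_lo:off_hi] += 1
        with np.errstate(invalid="ignore"):
            means[name] = np.where(count > 0, total / np.maximum(count, 1), 0.0)
    return SummitProfile(halfwidth=halfwidth, positions=positions, mean_signal=means)


def attach_counts_from_coverage(
    peaks: Sequence[ScoredPeak],
    coverage: Mapping[str, np.ndarray],
    library_scale: float = 1.0,
) -> list[ScoredPeak]:
    """Derive read and background counts for each peak from a coverage track.

    The read count is the coverage summed over the peak; the local background
    is the average of two flanking windows of equal length placed immediately
    upstream and downstream, rescaled to the peak length where a flank is
    truncated at a chromosome edge. ``library_scale`` multiplies both counts
    (sequencing-depth normalization across libraries).
    """
    out = []
    for p in peaks:
        arr = coverage.get(p.chrom)
        if arr is None:
            raise KeyError(f"no coverage for chromosome {p.chrom!r}")
        s, e = p.interval.start, p.interval.end
        length = e - s
        read = float(np.sum(arr[s:e]))
        flank_sum = 0.0
        flank_len = 0
        left_lo = max(0, s - length)
        if s > left_lo:
            flank_sum += float(np.sum(arr[left_lo:s]))
            flank_len += s - left_lo
        right_hi = min(len(arr), e + length)
        if right_hi > e:
            flank_sum += float(np.sum(arr[e:right_hi]))
            flank_len += right_hi - e
        background = flank_sum * (length / flank_len) if flank_len else 0.0
        out.append(p.with_counts(read * library_scale, background * library_scale))
    return out
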