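"""Regulatory-domain ("basal plus extension") peak-to-gene assignment and
gene-set overlap statistics.

Each gene gets a basal domain around its TSS (default 5 kb upstream, 1 kb
downstream) which is then extended outward up to 1 Mb per side, stopping
early at the nearest flanking gene's basal-domain edge. A peak is assigned to
every gene whose extended domain it overlaps by at least one basepair.
Gene-set overlaps are summarized and tested with a two-sided Fisher exact
test against an explicit background universe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from scipy.stats import fisher_exact

from .intervals import GenomicInterval, intersect

__all__ = [
    "GeneModel",
    "RegulatoryDomain",
    "basal_domain",
    "extend_domains",
    "assign_peaks",
    "gene_overlap_summary",
    "gene_list_fisher",
    "collapse_to_5prime_tss",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneModel:
    """A composite gene model reduced to its TSS."""

    gene_id: str
    chrom: str
    strand: str
    tss: int

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValueError(f"tss must be >= 0, got {self.tss}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass(frozen=True)
class RegulatoryDomain:
    gene_id: str
    basal: GenomicInterval
    extended: GenomicInterval


def collapse_to_5prime_tss(genes: Iterable[GeneModel]) -> list[GeneModel]:
    """Collapse multi-isoform entries to one gene model per id using the
    5'-most TSS (smallest on +, largest on -)."""
    best: dict[str, GeneModel] = {}
    for g in genes:
        cur = best.get(g.gene_id)
        if cur is None:
            best[g.gene_id] = g
        elif (g.strand == "+" and g.tss < cur.tss) or (
            g.strand == "-" and g.tss > cur.tss
        ):
            best[g.gene_id] = g
    return list(best.values())


def basal_domain(gene: GeneModel, up: int = 5000, down: int = 1000) -> GenomicInterval:
    """Basal regulatory interval: *up* bp upstream to *down* bp downstream of
    the TSS, strand-aware, clipped at the chromosome start."""
    if up < 0 or down < 0:
        raise ValueError("up/down must be non-negative")
    if up == 0 and down == 0:
        raise ValueError("basal domain cannot be empty (up and down both 0)")
    if gene.strand == "+":
        start, end = gene.tss - up, gene.tss + down
    else:
        start, end = gene.tss - down, gene.tss + up
    return GenomicInterval(gene.chrom, max(0, start), end, gene.strand)


def extend_domains(
    genes: Sequence[GeneModel],
    up: int = 5000,
    down: int = 1000,
    max_extension: int = 1_000_000,
    chrom_sizes: Mapping[str, int] | None = None,
) -> list[RegulatoryDomain]:
    """Build extended regulatory domains for a gene set.

    Each gene's extended interval reaches outward from its basal domain by up
    to ``max_extension`` bp per side but stops at the nearest flanking gene's
    basal-domain edge when that is closer (regardless of the neighbor's
    strand). Basal domains are never truncated by neighbors, so overlapping
    basal domains simply receive zero extension on that side.
    """
    ids = [g.gene_id for g in genes]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate gene_id(s): {dupes}")
    basals = {g.gene_id: basal_domain(g, up, down) for g in genes}
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    out = []
    for g in genes:
        b = basals[g.gene_id]
        left_bound = 0
        right_bound = chrom_sizes[g.chrom] if chrom_sizes else None
        for other in by_chrom[g.chrom]:
            if other.gene_id == g.gene_id:
                continue
            ob = basals[other.gene_id]
            if ob.start < b.start:
                # flanking (or overlapping) neighbor on the left
                left_bound = max(left_bound, min(ob.end, b.start))
            if ob.end > b.end:
                cand = max(ob.start, b.end)
                right_bound = cand if right_bound is None else min(right_bound, cand)
        ext_start = max(0, b.start - max_extension, left_bound)
        ext_end = b.end + max_extension
        if right_bound is not None:
            ext_end = min(ext_end, right_bound) if right_bound >= b.end else b.end
        ext_end = max(ext_end, b.end)
        out.append(
            RegulatoryDomain(
                gene_id=g.gene_id,
                basal=b,
                extended=GenomicInterval(g.chrom, ext_start, ext_end, g.strand),
            )
        )
    return out


def assign_peaks(
    peaks: Sequence[GenomicInterval],
    domains: Sequence[RegulatoryDomain],
) -> tuple[dict[str, set[int]], dict[int, set[str]], list[int]]:
    """Assign peaks to every gene whose extended domain they overlap >= 1 bp.

    Returns (gene_id -> peak indices, peak index -> gene_ids, unassigned peak
    indices). A peak may map to multiple genes.
    """
    pairs = intersect(list(peaks), [d.extended for d in domains], slop=0)
    gene_to_peaks: dict[str, set[int]] = {}
    peak_to_genes: dict[int, set[str]] = {}
    for pi, di in pairs:
        gid = domains[di].gene_id
        gene_to_peaks.setdefault(gid, set()).add(pi)
        peak_to_genes.setdefault(pi, set()).add(gid)
    unassigned = [i for i in range(len(peaks)) if i not in peak_to_genes]
    return gene_to_peaks, peak_to_genes, unassigned


@dataclass(frozen=True)
class GeneOverlapSummary:
    n_A: int
    n_B: int
    n_shared: int

    @property
    def frac_of_A_shared(self) -> float | None:
        return self.n_shared / self.n_A if self.n_A else None

    @property
    def pct_of_A_shared(self) -> int | None:
        """Shared percentage of set A, rounded to the nearest integer."""
        return round(100 * self.frac_of_A_shared) if self.n_A else None


def gene_overlap_summary(genesA: set, genesB: set) -> GeneOverlapSummary:
    """Cardinalities of two gene sets and the shared fraction of set A."""
    return GeneOverlapSummary(
        n_A=len(genesA), n_B=len(genesB), n_shared=len(genesA & genesB)
    )


def gene_list_fisher(
    listA: set, listB: set, background: set
) -> tuple[float, float]:
    """Two-sided Fisher exact test of gene-list overlap over a background.

    The 2x2 table partitions the background universe by membership in A and
    in B. Genes outside the background are dropped with a warning. Returns
    (odds_ratio, p_value).
    """
    if not background:
        raise ValueError("background universe is empty")
    strayA = listA - background
    strayB = listB - background
    if strayA or strayB:
        logger.warning(
            "dropping %d gene(s) from list A and %d from list B absent "
            "from the background universe",
            len(strayA), len(strayB),
        )
    a = listA & background
    b = listB & background
    n11 = len(a & b)
    n10 = len(a - b)
    n01 = len(b - a)
    n00 = len(background) - n11 - n10 - n01
    odds, p = fisher_exact([[n11, n10], [n01, n00]], alternative="two-sided")
    return float(odds), float(p)
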