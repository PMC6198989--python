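"""GWAS-eQTL effect-size concordance.

Variants passing both a GWAS and a cis-eQTL significance filter are merged
by id, their betas harmonized to a common effect allele, and the two effect
sizes correlated. A strong positive correlation between disease log odds
ratios and expression slopes indicates that the risk alleles act by raising
(or, if negative, lowering) the gene's expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .causality import RegressionResult

__all__ = [
    "SummaryStatsRecord",
    "MergedPair",
    "MergeReport",
    "merge_summary",
    "beta_correlation",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SummaryStatsRecord:
    """One row of a summary-statistics table; beta is a log odds ratio for
    GWAS or an expression slope for eQTL, oriented to ``effect_allele``."""

    variant_id: str
    effect_allele: str
    other_allele: str
    beta: float
    p: float

    def __post_init__(self) -> None:
        if not (0 < self.p <= 1):
            raise ValueError(f"p must be in (0, 1], got {self.p}")
        if self.effect_allele == self.other_allele:
            raise ValueError("effect and other allele must differ")


@dataclass(frozen=True)
class MergedPair:
    """Betas of one variant from both tables, oriented to the same (GWAS)
    effect allele."""

    variant_id: str
    beta_gwas: float
    beta_eqtl: float


@dataclass(frozen=True)
class MergeReport:
    pairs: list[MergedPair]
    n_allele_mismatch: int
    n_flipped: int


def _dedupe(records: Sequence[SummaryStatsRecord], label: str) -> dict[str, SummaryStatsRecord]:
    best: dict[str, SummaryStatsRecord] = {}
    n_dupes = 0
    for rec in records:
        cur = best.get(rec.variant_id)
        if cur is None or rec.p < cur.p:
            if cur is not None:
                n_dupes += 1
            best[rec.variant_id] = rec
        elif cur is not None:
            n_dupes += 1
    if n_dupes:
        logger.warning(
            "%s table: %d duplicate record(s); kept smallest p per variant",
            label, n_dupes,
        )
    return best


def merge_summary(
    gwas: Sequence[SummaryStatsRecord],
    eqtl: Sequence[SummaryStatsRecord],
    gwas_p_max: float = 1e-4,
    eqtl_p_max: float = 0.05,
) -> MergeReport:
    """Inner-join the two tables on variant id after strict p filters, and
    harmonize betas to the GWAS effect allele.

    The eQTL beta sign is flipped when its effect allele matches the GWAS
    record's other allele; variants whose alleles match neither way (e.g.
    strand-ambiguous A/T and C/G records reported on opposite strands) are
    dropped and counted in the report.
    """
    gwas_kept = _dedupe([r for r in gwas if r.p < gwas_p_max], "GWAS")
    eqtl_kept = _dedupe([r for r in eqtl if r.p < eqtl_p_max], "eQTL")
    pairs: list[MergedPair] = []
    n_mismatch = 0
    n_flipped = 0
    for vid in sorted(set(gwas_kept) & set(eqtl_kept)):
        g, e = gwas_kept[vid], eqtl_kept[vid]
        if (e.effect_allele, e.other_allele) == (g.effect_allele, g.other_allele):
            beta_e = e.beta
        elif (e.effect_allele, e.other_allele) == (g.other_allele, g.effect_allele):
            beta_e = -e.beta
            n_flipped += 1
        else:
            n_mismatch += 1
            continue
        pairs.append(MergedPair(variant_id=vid, beta_gwas=g.beta, beta_eqtl=beta_e))
    if n_mismatch:
        logger.warning(
            "dropped %d variant(s) with irreconcilable alleles", n_mismatch
        )
    return MergeReport(pairs=pairs, n_allele_mismatch=n_mismatch, n_flipped=n_flipped)


def beta_correlation(pairs: Sequence[MergedPair]) -> RegressionResult:
    """Pearson correlation between harmonized GWAS and eQTL betas.

    Also returns the OLS slope (eQTL beta regressed on GWAS beta) for the
    trend line; the two-sided p comes from the t distribution on n - 2 df.
    """
    if len(pairs) < 3:
        raise ValueError("insufficient overlap: need at least 3 merged pairs")
    x = np.asarray([p.beta_gwas for p in pairs])
    y = np.asarray([p.beta_eqtl for p in pairs])
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("no variation in one of the beta columns")
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        pearson_r=float(res.rvalue),
        p_value=float(res.pvalue),
        n=len(pairs),
    )
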