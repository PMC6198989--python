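"""Seeded synthetic-data generators for the full pipeline.

Two generators emulate the statistical structure the analysis stages assume:

* :func:`simulate_cobinding` lays out solo and jointly bound peak loci for
  two transcription factors along small chromosomes, draws Poisson read and
  background counts around a per-site signal model with a planted bias
  toward one factor at a chosen subset of joint sites, and emits matching
  per-base coverage tracks plus a truth table of planted labels.

* :func:`simulate_genetics` draws each sample's genotype as the sum of two
  local haplotypes from a small pool, builds expression with an additive
  per-risk-allele effect plus haplotype-group-level and individual-level
  noise, and writes paired GWAS/eQTL summary statistics whose betas carry a
  planted correlation.

Defaults mirror the study conditions at desk scale: 583 joint peak loci with
a 61.4% bias split, a 52-sample cohort, 4 cis risk variants drawn from 6
local haplotypes, and 60 overlapping summary-stats variants at beta-beta
correlation 0.9. All randomness flows from one explicit ``numpy`` generator,
so identical seeds give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from .causality import GenotypeMatrix, Variant
from .concordance import SummaryStatsRecord
from .intervals import GenomicInterval, ScoredPeak

__all__ = [
    "CobindSimConfig",
    "GeneticsSimConfig",
    "CobindSim",
    "GeneticsSim",
    "simulate_cobinding",
    "simulate_genetics",
]

_BASES = ("A", "C", "G", "T")


@dataclass
class CobindSimConfig:
    """Layout and signal model for the co-binding simulation.

    ``biased_multiplier``/``base_multiplier`` set the expected in-peak rate of
    the favored and disfavored factor at a biased site (both relative to the
    background rate); unbiased joint sites and solo peaks use
    ``unbiased_multiplier`` for both factors. With the defaults the expected
    nfc ratio at a biased site is ~4, comfortably beyond the 2-fold call
    threshold, while Poisson noise alone rarely crosses it at unbiased sites.
    """

    n_sites_only_A: int = 300
    n_sites_only_B: int = 300
    n_joint: int = 583
    n_biased: int = 358 + 225
    frac_A_of_biased: float = 358 / 583
    peak_width_mean: int = 300
    peak_width_sd: int = 50
    min_peak_width: int = 100
    locus_spacing: int = 2500
    background_mean: float = 20.0
    biased_multiplier: float = 6.0
    base_multiplier: float = 1.5
    unbiased_multiplier: float = 3.0
    n_chroms: int = 2
    chrom_length: int | None = None  # derived from the layout when None
    make_coverage: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_biased > self.n_joint:
            raise ValueError("n_biased cannot exceed n_joint")
        if not (0 <= self.frac_A_of_biased <= 1):
            raise ValueError("frac_A_of_biased must be in [0, 1]")


@dataclass
class CobindSim:
    peaksA: list[ScoredPeak]
    peaksB: list[ScoredPeak]
    coverageA: dict[str, np.ndarray]
    coverageB: dict[str, np.ndarray]
    truth: pd.DataFrame  # locus, chrom, start, kind, planted_bias


def _draw_peak(
    rng: np.random.Generator,
    chrom: str,
    locus_start: int,
    cfg: CobindSimConfig,
    mean_reads: float,
    offset: int = 0,
) -> ScoredPeak:
    width = max(
        cfg.min_peak_width,
        int(round(rng.normal(cfg.peak_width_mean, cfg.peak_width_sd))),
    )
    start = locus_start + offset
    end = start + width
    summit = int(rng.integers(start + width // 4, end - width // 4))
    read = float(rng.poisson(mean_reads))
    background = float(rng.poisson(cfg.background_mean))
    return ScoredPeak(
        interval=GenomicInterval(chrom, start, end),
        summit=summit,
        fold_change=float(rng.uniform(6, 30)),
        neg_log10_q=float(rng.uniform(15, 300)),
        read_count=read,
        background_count=background,
    )


def simulate_cobinding(config: CobindSimConfig) -> CobindSim:
    """Generate two scored peak sets with a planted co-binding bias structure.

    Joint loci share >= 1 bp between the two factors' peaks; the truth table
    records the planted label (``A``, ``B`` or ``unbiased``) for every joint
    locus and ``only_A``/``only_B`` for solo peaks.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_loci = cfg.n_sites_only_A + cfg.n_sites_only_B + cfg.n_joint
    per_chrom = -(-n_loci // cfg.n_chroms)  # ceil
    needed = (per_chrom + 1) * cfg.locus_spacing + 10 * cfg.peak_width_mean
    chrom_len = cfg.chrom_length if cfg.chrom_length is not None else needed
    if chrom_len < needed:
        raise ValueError(
            f"infeasible geometry: {n_loci} loci at spacing {cfg.locus_spacing} "
            f"need chromosomes of >= {needed} bp, got {chrom_len}"
        )
    chroms = [f"chr{k + 1}" for k in range(cfg.n_chroms)]

    # planted labels, shuffled over the joint loci
    n_a = int(round(cfg.n_biased * cfg.frac_A_of_biased))
    labels = (["A"] * n_a + ["B"] * (cfg.n_biased - n_a)
              + ["unbiased"] * (cfg.n_joint - cfg.n_biased))
    rng.shuffle(labels)
    kinds = labels + ["only_A"] * cfg.n_sites_only_A + ["only_B"] * cfg.n_sites_only_B
    rng.shuffle(kinds)

    peaksA: list[ScoredPeak] = []
    peaksB: list[ScoredPeak] = []
    rows = []
    bg = cfg.background_mean
    for locus, kind in enumerate(kinds):
        chrom = chroms[locus % cfg.n_chroms]
        start = cfg.locus_spacing * (locus // cfg.n_chroms + 1)
        if kind == "only_A":
            peaksA.append(_draw_peak(rng, chrom, start, cfg,
                                     bg * cfg.unbiased_multiplier))
        elif kind == "only_B":
            peaksB.append(_draw_peak(rng, chrom, start, cfg,
                                     bg * cfg.unbiased_multiplier))
        else:
            if kind == "A":
                mean_a = bg * cfg.biased_multiplier
                mean_b = bg * cfg.base_multiplier
            elif kind == "B":
                mean_a = bg * cfg.base_multiplier
                mean_b = bg * cfg.biased_multiplier
            else:
                mean_a = mean_b = bg * cfg.unbiased_multiplier
            pa = _draw_peak(rng, chrom, start, cfg, mean_a)
            # factor-B peak shifted but guaranteed to share >= 1 bp:
            # any B peak is >= min_peak_width long, so a shift magnitude
            # below that (and below the A width) always leaves an overlap
            max_shift = max(1, min(len(pa.interval) // 3, cfg.min_peak_width - 1))
            shift = int(rng.integers(-max_shift, max_shift + 1))
            pb = _draw_peak(rng, chrom, start, cfg, mean_b, offset=shift)
            peaksA.append(pa)
            peaksB.append(pb)
        rows.append({"locus": locus, "chrom": chrom, "start": start,
                     "kind": kind if kind in ("only_A", "only_B") else "joint",
                     "planted_bias": kind if kind in ("A", "B", "unbiased") else ""})
    truth = pd.DataFrame(rows)

    coverageA: dict[str, np.ndarray] = {}
    coverageB: dict[str, np.ndarray] = {}
    if cfg.make_coverage:
        for chrom in chroms:
            coverageA[chrom] = np.zeros(chrom_len, dtype=np.float32)
            coverageB[chrom] = np.zeros(chrom_len, dtype=np.float32)
        for peaks, cov in ((peaksA, coverageA), (peaksB, coverageB)):
            for p in peaks:
                s, e = p.interval.start, p.interval.end
                w = e - s
                cov[p.chrom][s:e] += p.read_count / w
                # flanks carry the background rate so coverage-derived
                # counts reproduce the stored ones in expectation
                left = max(0, s - w)
                cov[p.chrom][left:s] += p.background_count / w
                cov[p.chrom][e:e + w] += p.background_count / w
    return CobindSim(peaksA=peaksA, peaksB=peaksB,
                     coverageA=coverageA, coverageB=coverageB, truth=truth)


@dataclass
class GeneticsSimConfig:
    """Cohort, genetic architecture and summary-stats model.

    ``per_allele_effect`` is in expression units per risk allele;
    ``group_noise_sd`` is shared by all carriers of one haplotype profile
    (the variance component that profile-collapsing removes) and
    ``individual_noise_sd`` is per sample.
    """

    n_samples: int = 52
    n_variants: int = 4
    n_haplotype_profiles: int = 6
    per_allele_effect: float = 0.3
    group_noise_sd: float = 0.5
    individual_noise_sd: float = 0.5
    intercept: float = 10.0
    gene_chrom: str = "chr15"
    gene_start: int = 1_200_000
    gene_end: int = 1_330_000
    cis_window: int = 100_000
    planted_beta_correlation: float = 0.9
    n_overlap_variants: int = 60
    n_gwas_only: int = 15
    n_eqtl_only: int = 15
    n_filtered_out: int = 10
    gwas_beta_sd: float = 0.10
    eqtl_beta_sd: float = 0.20
    frac_allele_swapped: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_haplotype_profiles < 1:
            raise ValueError("n_haplotype_profiles must be >= 1")
        if self.group_noise_sd < 0 or self.individual_noise_sd < 0:
            raise ValueError("noise sds must be non-negative")
        if abs(self.planted_beta_correlation) > 1:
            raise ValueError("planted_beta_correlation must be in [-1, 1]")


@dataclass
class GeneticsSim:
    genotypes: GenotypeMatrix
    expression: dict[str, float]
    gwas: list[SummaryStatsRecord]
    eqtl: list[SummaryStatsRecord]
    truth: dict


def _haplotype_pool(rng: np.random.Generator, n_profiles: int, n_variants: int) -> np.ndarray:
    """Distinct binary haplotypes over the variants (risk allele present/absent)."""
    space = 2 ** n_variants
    if n_profiles > space:
        raise ValueError(
            f"cannot draw {n_profiles} distinct haplotypes over {n_variants} variants"
        )
    codes = rng.choice(space, size=n_profiles, replace=False)
    all_haps = np.array(list(product((0, 1), repeat=n_variants)), dtype=int)
    return all_haps[codes]


def simulate_genetics(config: GeneticsSimConfig) -> GeneticsSim:
    """Generate genotypes, expression and paired summary statistics.

    Each sample's dosage vector is the sum of two haplotypes drawn from the
    pool; expression is intercept + effect x burden + group noise (shared by
    identical dosage profiles) + individual noise. The GWAS and eQTL summary
    betas of the overlapping variants are drawn from a bivariate normal with
    the planted correlation; a configurable fraction of eQTL rows is stored
    with swapped alleles and negated beta to exercise allele harmonization,
    and extra rows fail the join or the p filters on purpose.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    pool = _haplotype_pool(rng, cfg.n_haplotype_profiles, cfg.n_variants)
    freqs = rng.dirichlet(np.ones(cfg.n_haplotype_profiles))
    h1 = rng.choice(cfg.n_haplotype_profiles, size=cfg.n_samples, p=freqs)
    h2 = rng.choice(cfg.n_haplotype_profiles, size=cfg.n_samples, p=freqs)
    dosage = (pool[h1] + pool[h2]).astype(float)

    span = cfg.gene_end - cfg.gene_start + 2 * cfg.cis_window
    positions = np.sort(
        rng.choice(span, size=cfg.n_variants, replace=False)
    ) + cfg.gene_start - cfg.cis_window
    variants = []
    for k in range(cfg.n_variants):
        risk, other = rng.choice(_BASES, size=2, replace=False)
        variants.append(
            Variant(
                variant_id=f"rs{900000 + k}",
                chrom=cfg.gene_chrom,
                pos=int(positions[k]),
                risk_allele=str(risk),
                other_allele=str(other),
                gwas_beta=float(abs(rng.normal(0.1, 0.03))),
                gwas_p=float(10 ** rng.uniform(-9, -6.5)),
            )
        )
    samples = [f"S{i + 1:03d}" for i in range(cfg.n_samples)]
    genotypes = GenotypeMatrix(samples=samples, variants=variants, dosage=dosage)

    burdens = dosage.sum(axis=1)
    profile_keys = [tuple(int(d) for d in row) for row in dosage]
    group_noise = {
        prof: rng.normal(0.0, cfg.group_noise_sd)
        for prof in sorted(set(profile_keys))
    }
    indiv = rng.normal(0.0, cfg.individual_noise_sd, size=cfg.n_samples)
    expr_vals = (cfg.intercept + cfg.per_allele_effect * burdens
                 + np.array([group_noise[p] for p in profile_keys]) + indiv)
    expression = dict(zip(samples, expr_vals.astype(float)))

    # paired summary statistics with planted beta-beta correlation
    rho = cfg.planted_beta_correlation
    z = rng.multivariate_normal(
        [0.0, 0.0], [[1.0, rho], [rho, 1.0]], size=cfg.n_overlap_variants
    )
    gwas: list[SummaryStatsRecord] = []
    eqtl: list[SummaryStatsRecord] = []
    truth_betas = []
    for k in range(cfg.n_overlap_variants):
        vid = f"rs{100000 + k}"
        ea, oa = rng.choice(_BASES, size=2, replace=False)
        bg_ = float(z[k, 0] * cfg.gwas_beta_sd)
        be = float(z[k, 1] * cfg.eqtl_beta_sd)
        gwas.append(SummaryStatsRecord(vid, str(ea), str(oa), bg_,
                                       float(10 ** rng.uniform(-8, -4.1))))
        if rng.random() < cfg.frac_allele_swapped:
            eqtl.append(SummaryStatsRecord(vid, str(oa), str(ea), -be,
                                           float(10 ** rng.uniform(-4, -1.4))))
        else:
            eqtl.append(SummaryStatsRecord(vid, str(ea), str(oa), be,
                                           float(10 ** rng.uniform(-4, -1.4))))
        truth_betas.append((bg_, be))
    for k in range(cfg.n_gwas_only):
        ea, oa = rng.choice(_BASES, size=2, replace=False)
        gwas.append(SummaryStatsRecord(f"rs{200000 + k}", str(ea), str(oa),
                                       float(rng.normal(0, cfg.gwas_beta_sd)),
                                       float(10 ** rng.uniform(-8, -4.1))))
    for k in range(cfg.n_eqtl_only):
        ea, oa = rng.choice(_BASES, size=2, replace=False)
        eqtl.append(SummaryStatsRecord(f"rs{300000 + k}", str(ea), str(oa),
                                       float(rng.normal(0, cfg.eqtl_beta_sd)),
                                       float(10 ** rng.uniform(-4, -1.4))))
    for k in range(cfg.n_filtered_out):
        ea, oa = rng.choice(_BASES, size=2, replace=False)
        vid = f"rs{400000 + k}"
        gwas.append(SummaryStatsRecord(vid, str(ea), str(oa),
                                       float(rng.normal(0, cfg.gwas_beta_sd)),
                                       float(rng.uniform(0.01, 1.0))))
        eqtl.append(SummaryStatsRecord(vid, str(ea), str(oa),
                                       float(rng.normal(0, cfg.eqtl_beta_sd)),
                                       float(rng.uniform(0.06, 1.0))))

    truth = {
        "haplotype_pool": pool,
        "haplotype_freqs": freqs,
        "sample_haplotypes": np.stack([h1, h2], axis=1),
        "burdens": burdens,
        "group_noise": group_noise,
        "per_allele_effect": cfg.per_allele_effect,
        "planted_beta_correlation": rho,
        "overlap_betas": np.asarray(truth_betas),
    }
    return GeneticsSim(genotypes=genotypes, expression=expression,
                       gwas=gwas, eqtl=eqtl, truth=truth)
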