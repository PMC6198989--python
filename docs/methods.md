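# Methods

## Coordinates and peak model

All genomic coordinates are 0-based, half-open (BED convention). A scored
peak carries its interval, an absolute summit position, the caller's fold
enrichment and −log10 q-value, and optional read/background counts. Peak
filtering uses strict inequalities (`fold_change > t_fc` AND
`neg_log10_q > t_q`), so a peak sitting exactly on a threshold is removed;
four presets are bundled (`smad3`: 5/10; `tcf21_liberal`: 5/25;
`tcf21_standard`: 10/60; `tcf21_stringent`: 15/200). Two intervals overlap
when they share at least one basepair; "adjacent" sites are captured by a
symmetric slop applied to the first set before testing (default 0 bp,
1000 bp reproduces the ±1 kb extension analysis). Chromosome names are
compared as exact strings, with an optional normalizer for the `chr`-prefix
dialects. Overlap queries run on an interval tree; correctness is checked
in the tests against an all-pairs brute-force oracle. Both raw pair counts
and distinct per-set counts are exposed, since multi-overlaps make the two
differ.

## Binding-bias classification

The relative-binding measure is the normalized fold change
`nfc = (reads_in_peak + c) / (reads_in_background + c)` with pseudocount
c = 1 (configurable) guarding empty backgrounds. The background of a peak,
when derived from a coverage track, is the average of two flanking windows
of the peak's own length immediately up- and downstream, rescaled where a
flank is truncated at a chromosome edge; local flanking background is the
standard ChIP normalization and keeps the background region length equal to
the peak length. Precomputed counts are accepted as an alternative, and an
optional per-library scale factor handles sequencing-depth differences
(nfc itself is depth-invariant when both counts are scaled together).

Overlap pairs are resolved to one joint site per locus: when a peak
overlaps several partners, the pair with the largest basepair overlap wins,
ties broken by larger partner read count and then leftmost coordinate. A
joint site is biased toward a factor when its nfc exceeds the other's by
strictly more than two-fold (threshold configurable, must exceed 1); the
published split of 358 vs 225 among 583 biased sites is the worked example
the summary statistics reproduce (61%/39% after integer rounding). The
0–100 relative scale is min-max scaling of each factor's nfc values across
the joint-site set only — not genome-wide — because the relative scale is
meaningful only among the co-bound loci; whether the original scale was
min-max or rank-based is not documented anywhere, so the choice is isolated
in one function (`rescale_0_100`). If a joint-site set is too small or
degenerate to scale (fewer than two sites, or all nfc equal), scaled values
fall back to 0 with a warning rather than aborting the run.

Summit profiles average a coverage track over ±halfwidth windows (default
1 kb) centered on peak summits; windows truncated at chromosome edges
contribute only their defined offsets, so each offset's mean is over the
summits that cover it.

## Gene assignment

The basal regulatory domain is 5 kb upstream / 1 kb downstream of the TSS
(strand-aware, clipped at position 0); the extended domain reaches outward
up to 1 Mb per side but stops at the nearest flanking gene's basal-domain
edge when that is closer, regardless of the neighbor's strand. Basal
domains are never truncated by neighbors: overlapping basal domains simply
receive zero extension on that side. Only this association rule is
implemented — not the binomial genomic-fraction enrichment statistic of the
full GREAT tool, because only the assignment feeds the downstream numbers.
One TSS per gene is assumed; a helper collapses multi-isoform tables to the
5′-most TSS per gene id. A peak is assigned to every gene whose extended
domain it overlaps by ≥ 1 bp, so one peak can serve several genes and
unassigned ("gene desert") peaks are reported.

Gene-set overlap is summarized as cardinalities plus the shared percentage
of the first set (rounded to integer for display; 3,143 of 4,647 → 68%).
Enrichment uses the two-sided Fisher exact test on the 2×2 membership table
over an explicitly supplied background universe; genes outside the universe
are dropped with a warning rather than silently kept. The test agrees with
exhaustive hypergeometric enumeration to 1e-10 on backgrounds up to 500.

## Causality and direction of effect

Cis risk variants are those on the gene's chromosome within 100 kb of the
gene span (inclusive window) at GWAS p strictly below 1e-6, with betas
oriented so positive means the risk allele increases disease odds. The
single-variant eQTL test is OLS of expression on additive 0/1/2 dosage,
reporting slope, Pearson r and the two-sided p from the t distribution on
n − 2 df.

A *haplotype profile* is operationalized as the unphased dosage vector over
the selected variants: phase is not needed for collapse-and-average, and
high-coverage WGS genotypes make missingness negligible (samples with any
missing dosage are dropped with a logged count, not imputed). Samples with
identical profiles are collapsed to one observation at their mean
expression; collapsing provably conserves the sample count and the
grand weighted mean, and removes the within-profile variance component
(inter-individual and technical noise), which is why the collapsed
regression's mean |r| exceeds the per-sample regression's in the paired
simulations. The burden regression is then OLS of group mean expression on
the group's total risk-allele count; weighting groups by their size is
available but off by default, since plain averaging over unique profiles is
the described procedure. Both the slope and Pearson r are always reported
because a single "regression coefficient" is ambiguous between them.

## Concordance

Summary tables are filtered at GWAS p < 1e-4 and eQTL p < 0.05 (both
strict), deduplicated keeping the smallest p per variant id, and
inner-joined on variant id. The eQTL beta is flipped when its effect allele
equals the GWAS record's other allele; records whose alleles match neither
way — including strand-ambiguous A/T and C/G variants reported on opposite
strands, which cannot be resolved without strand information — are dropped
and counted. GWAS betas are treated as signed log odds ratios oriented to
the stated effect allele with no blanket negation: negating them would flip
the sign of the correlation, contradicting a positive correlation for a
risk-raising eQTL. The concordance statistic is the Pearson correlation of
the harmonized beta pairs with its two-sided t-based p; the OLS slope is
reported for the trend line (a loess smoother would not change the
correlation).

## Synthetic data

The co-binding generator lays out solo and joint loci on 2 chromosomes at
2.5 kb spacing (peak widths ~ Normal(300, 50) bp truncated at 100 bp), and
draws Poisson read counts around a signal model expressed as multipliers of
the mean background count (20): 6× for the favored and 1.5× for the
disfavored factor at a biased site (expected nfc ratio ≈ 4, comfortably
beyond the 2-fold call threshold), 3× for both at unbiased and solo sites.
Defaults plant 583 joint sites, all biased, with a 61.4% share toward
factor A — the published biased-site accounting — alongside 300 solo peaks
per factor; the full ~30,000-peak genome is deliberately scaled down, since
the bias statistics depend only on the joint sites. Coverage tracks are
piecewise-constant (count spread uniformly over the peak, background over
equal flanks) so coverage-derived counts reproduce the stored ones in
expectation. A truth table records every planted label. Setting
`n_biased = 0` gives the equal-affinity control pair, whose biased fraction
stays below ~8% — Poisson noise alone rarely crosses two-fold at these
depths.

The genetics generator draws 6 distinct binary haplotypes over 4 cis
variants (a realistic number of common local haplotypes in a 100 kb
window), haplotype frequencies from a flat Dirichlet, and each of 52
samples as the dosage sum of two haplotypes. Expression is
`10 + 0.3 × burden + group noise (sd 0.5, shared by identical profiles) +
individual noise (sd 0.5)`. Summary statistics comprise 60 overlapping
variants with (GWAS, eQTL) betas from a bivariate normal at correlation
0.9 (scales 0.1 and 0.2), ~30% of eQTL rows stored allele-swapped with
negated beta to exercise harmonization, plus join-only and filtered-out
rows. What this does **not** emulate: linkage-disequilibrium decay,
realistic allele-frequency spectra, winner's-curse inflation of summary
betas, or population structure — so passing tests demonstrate correct
recovery of the modeled additive/correlated structure, not robustness to
those real-data complications. All randomness flows from one
`numpy.random.default_rng(seed)` per generator call; identical seeds give
byte-identical outputs.

## Numerical and reporting choices

Regressions use `scipy.stats.linregress` (weighted burden fits use
statsmodels WLS, with the weighted Pearson r computed from weighted
moments). The 0–100 rescale computes the ratio before multiplying so the
extremes map to exactly 0 and 100. Display percentages round to the nearest
integer; underlying fractions are kept alongside. Degenerate inputs signal
errors by exception with specific messages (monomorphic variant, no burden
variation, insufficient overlap, degenerate scale) rather than returning
NaNs. Every CLI stage writes a `manifest.json` (version, resolved config,
seed, SHA-256 of inputs and outputs, warning count) with no timestamps, so
reruns on identical inputs produce byte-identical manifests; on failure,
partially written outputs are removed.

## Validation problem sizes

The replicate studies use 200 simulated cohorts (sign recovery, collapsing
gain, correlation recovery) and 500 (null calibration) of 52 samples each,
and 100 random instances for the interval-intersection oracle check — sizes
at which the binomial/simulation tolerances in the acceptance checks are
informative while the whole suite runs in well under a minute per study.

## Known limitations

Joint-site resolution is greedy one-to-one; a locus where one broad peak
legitimately spans two partner peaks yields a single joint site. The Fisher
test conditions on the supplied universe — results are only as meaningful
as that background. The burden regression treats burden as exact (no
genotype uncertainty), and the concordance test is correlation, not formal
colocalization: shared LD structure can produce concordant betas without a
shared causal variant.
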