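"""Readers and writers for the formats shared across pipeline stages.

BED6, ENCODE narrowPeak, bedGraph coverage, VCF genotypes (read-only, GT to
risk-allele dosage) and the headered TSV tables used for counts, gene
annotation, expression, GWAS variants and summary statistics. All parse
errors name the offending file and line.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .causality import CollapsedGroup, GenotypeMatrix, RegressionResult, Variant
from .cobinding import BiasSummary, JointSite, SummitProfile
from .concordance import MergedPair, SummaryStatsRecord
from .intervals import GenomicInterval, ScoredPeak, normalize_chrom

__all__ = [
    "ParseError",
    "read_bed6",
    "write_bed6",
    "read_narrowpeak",
    "write_narrowpeak",
    "read_bedgraph",
    "write_bedgraph",
    "read_counts_tsv",
    "attach_counts_from_table",
    "read_gene_table",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_gwas_variants_tsv",
    "write_gwas_variants_tsv",
    "read_summary_stats_tsv",
    "write_summary_stats_tsv",
    "read_dosage_tsv",
    "write_dosage_tsv",
    "read_vcf_dosages",
    "write_joint_sites_tsv",
    "write_bias_summary_tsv",
    "write_profile_tsv",
    "write_assignment_tsv",
    "write_gene_set",
    "read_gene_set",
    "write_collapsed_groups_tsv",
    "write_regression_tsv",
    "write_merged_pairs_tsv",
]

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """Malformed input; message carries ``path:line``."""

    def __init__(self, path: str | Path, lineno: int, message: str) -> None:
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


def _data_lines(path: str | Path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split("\t")


def _to_int(path, lineno, field, value) -> int:
    try:
        return int(value)
    except ValueError:
        raise ParseError(path, lineno, f"{field} is not an integer: {value!r}") from None


def _to_float(path, lineno, field, value) -> float:
    try:
        return float(value)
    except ValueError:
        raise ParseError(path, lineno, f"{field} is not a number: {value!r}") from None


def read_bed6(path: str | Path, chrom_style: str | None = None) -> list[GenomicInterval]:
    """Read a BED file (>= 3 columns) into genomic intervals.

    ``chrom_style`` optionally normalizes chromosome names to the ``"chr"``
    or ``"bare"`` dialect.
    """
    out = []
    for lineno, f in _data_lines(path):
        if len(f) < 3:
            raise ParseError(path, lineno, f"expected >= 3 BED columns, got {len(f)}")
        chrom = normalize_chrom(f[0], chrom_style) if chrom_style else f[0]
        start = _to_int(path, lineno, "start", f[1])
        end = _to_int(path, lineno, "end", f[2])
        strand = f[5] if len(f) >= 6 and f[5] in ("+", "-") else "."
        try:
            out.append(GenomicInterval(chrom, start, end, strand))
        except ValueError as exc:
            raise ParseError(path, lineno, str(exc)) from None
    return out


def write_bed6(intervals: Sequence[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t0\t{iv.strand}\n")


def read_narrowpeak(path: str | Path, chrom_style: str | None = None) -> list[ScoredPeak]:
    """Read an ENCODE narrowPeak (10-column BED6+4) file into scored peaks.

    signalValue maps to fold_change, qValue to neg_log10_q, and the peak
    column (summit offset from start; -1 or "." = unknown) to an absolute
    summit position, defaulting to the interval midpoint when unknown.
    """
    out = []
    for lineno, f in _data_lines(path):
        if len(f) < 10:
            raise ParseError(
                path, lineno, f"expected 10 narrowPeak columns, got {len(f)}"
            )
        chrom = normalize_chrom(f[0], chrom_style) if chrom_style else f[0]
        start = _to_int(path, lineno, "start", f[1])
        end = _to_int(path, lineno, "end", f[2])
        fold = 1.0 if f[6] in (".", "-1") else _to_float(path, lineno, "signalValue", f[6])
        q = f[8]
        neg_log10_q = 0.0 if q in (".", "-1") else _to_float(path, lineno, "qValue", q)
        if neg_log10_q < 0:
            neg_log10_q = 0.0  # -1 sentinel means "not available"
        peak_off = f[9]
        if peak_off in (".", "-1"):
            summit = start + (end - start) // 2
        else:
            summit = start + _to_int(path, lineno, "peak", peak_off)
        try:
            out.append(
                ScoredPeak(
                    interval=GenomicInterval(chrom, start, end,
                                             f[5] if f[5] in ("+", "-") else "."),
                    summit=summit,
                    fold_change=fold,
                    neg_log10_q=neg_log10_q,
                    name=f[3],
                )
            )
        except ValueError as exc:
            raise ParseError(path, lineno, str(exc)) from None
    return out


def write_narrowpeak(peaks: Sequence[ScoredPeak], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            iv = p.interval
            fh.write(
                "\t".join(
                    [
                        iv.chrom, str(iv.start), str(iv.end), p.name, "0", iv.strand,
                        f"{p.fold_change:g}", "-1", f"{p.neg_log10_q:g}",
                        str(p.summit - iv.start),
                    ]
                )
                + "\n"
            )


def read_bedgraph(path: str | Path) -> dict[str, np.ndarray]:
    """Read a bedGraph into per-chromosome per-base coverage arrays (sized to
    the last covered position of each chromosome)."""
    spans: dict[str, list[tuple[int, int, float]]] = {}
    for lineno, f in _data_lines(path):
        if len(f) < 4:
            raise ParseError(path, lineno, f"expected 4 bedGraph columns, got {len(f)}")
        chrom = f[0]
        start = _to_int(path, lineno, "start", f[1])
        end = _to_int(path, lineno, "end", f[2])
        value = _to_float(path, lineno, "value", f[3])
        if end <= start or start < 0:
            raise ParseError(path, lineno, f"bad interval [{f[1]}, {f[2]})")
        spans.setdefault(chrom, []).append((start, end, value))
    out = {}
    for chrom, items in spans.items():
        arr = np.zeros(max(e for _, e, _ in items), dtype=np.float32)
        for s, e, v in items:
            arr[s:e] = v
        out[chrom] = arr
    return out


def write_bedgraph(coverage: Mapping[str, np.ndarray], path: str | Path) -> None:
    """Write per-base coverage as run-length-encoded bedGraph (zero runs are
    omitted)."""
    with open(path, "w") as fh:
        for chrom in sorted(coverage):
            arr = np.asarray(coverage[chrom])
            if arr.size == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [arr.size]])
            for s, e in zip(starts, ends):
                v = arr[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def read_counts_tsv(path: str | Path) -> dict[tuple[str, int, int], tuple[float, float]]:
    """Read precomputed counts keyed by peak coordinates. Columns: chrom,
    start, end, read_count, background_count (with header)."""
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "start", "end", "read_count", "background_count"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(path, 1, f"missing column(s): {sorted(missing)}")
    return {
        (str(r.chrom), int(r.start), int(r.end)): (float(r.read_count),
                                                   float(r.background_count))
        for r in df.itertuples()
    }


def attach_counts_from_table(
    peaks: Sequence[ScoredPeak],
    counts: Mapping[tuple[str, int, int], tuple[float, float]],
) -> list[ScoredPeak]:
    out = []
    n_missing = 0
    for p in peaks:
        key = (p.chrom, p.interval.start, p.interval.end)
        if key in counts:
            out.append(p.with_counts(*counts[key]))
        else:
            n_missing += 1
            out.append(p)
    if n_missing:
        logger.warning("%d peak(s) had no row in the counts table", n_missing)
    return out


def read_gene_table(path: str | Path, chrom_style: str | None = None) -> list:
    """Read a gene annotation TSV (gene_id, chrom, strand, tss; with header)
    or a BED6 of TSSs (name column = gene id) into gene models."""
    from .gene_assignment import GeneModel

    with open(path) as fh:
        first = fh.readline().rstrip("\n").split("\t")
    genes = []
    if "gene_id" in first:
        df = pd.read_csv(path, sep="\t")
        for i, r in enumerate(df.itertuples(), start=2):
            chrom = normalize_chrom(str(r.chrom), chrom_style) if chrom_style else str(r.chrom)
            try:
                genes.append(GeneModel(str(r.gene_id), chrom, str(r.strand), int(r.tss)))
            except ValueError as exc:
                raise ParseError(path, i, str(exc)) from None
    else:
        for lineno, f in _data_lines(path):
            if len(f) < 6:
                raise ParseError(path, lineno, "TSS BED needs 6 columns")
            chrom = normalize_chrom(f[0], chrom_style) if chrom_style else f[0]
            try:
                genes.append(GeneModel(f[3], chrom, f[5], _to_int(path, lineno, "start", f[1])))
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from None
    return genes


def read_expression_tsv(path: str | Path) -> dict[str, float]:
    """Two-column TSV (sample, value), header optional."""
    out: dict[str, float] = {}
    for lineno, f in _data_lines(path):
        if len(f) < 2:
            raise ParseError(path, lineno, "expected 2 columns (sample, value)")
        if f[0].lower() in ("sample", "sample_id"):
            continue
        out[f[0]] = _to_float(path, lineno, "value", f[1])
    return out


def write_expression_tsv(expression: Mapping[str, float], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tvalue\n")
        for s in expression:
            fh.write(f"{s}\t{expression[s]:.6g}\n")


_GWAS_COLS = ["variant_id", "chrom", "pos", "risk_allele", "other_allele", "beta", "p"]


def read_gwas_variants_tsv(path: str | Path) -> list[Variant]:
    df = pd.read_csv(path, sep="\t")
    missing = set(_GWAS_COLS) - set(df.columns)
    if missing:
        raise ParseError(path, 1, f"missing column(s): {sorted(missing)}")
    out = []
    for i, r in enumerate(df.itertuples(), start=2):
        try:
            out.append(
                Variant(str(r.variant_id), str(r.chrom), int(r.pos),
                        str(r.risk_allele), str(r.other_allele),
                        float(r.beta), float(r.p))
            )
        except ValueError as exc:
            raise ParseError(path, i, str(exc)) from None
    return out


def write_gwas_variants_tsv(variants: Sequence[Variant], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_GWAS_COLS) + "\n")
        for v in variants:
            fh.write(
                f"{v.variant_id}\t{v.chrom}\t{v.pos}\t{v.risk_allele}\t"
                f"{v.other_allele}\t{v.gwas_beta:.6g}\t{v.gwas_p:.6g}\n"
            )


_SUMSTAT_COLS = ["variant_id", "effect_allele", "other_allele", "beta", "p"]


def read_summary_stats_tsv(path: str | Path) -> list[SummaryStatsRecord]:
    df = pd.read_csv(path, sep="\t")
    missing = set(_SUMSTAT_COLS) - set(df.columns)
    if missing:
        raise ParseError(path, 1, f"missing column(s): {sorted(missing)}")
    out = []
    for i, r in enumerate(df.itertuples(), start=2):
        try:
            out.append(
                SummaryStatsRecord(str(r.variant_id), str(r.effect_allele),
                                   str(r.other_allele), float(r.beta), float(r.p))
            )
        except ValueError as exc:
            raise ParseError(path, i, str(exc)) from None
    return out


def write_summary_stats_tsv(records: Sequence[SummaryStatsRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_SUMSTAT_COLS) + "\n")
        for r in records:
            fh.write(
                f"{r.variant_id}\t{r.effect_allele}\t{r.other_allele}\t"
                f"{r.beta:.6g}\t{r.p:.6g}\n"
            )


def read_dosage_tsv(path: str | Path, variants: Sequence[Variant]) -> GenotypeMatrix:
    """Read a dosage matrix TSV: first column ``sample``, one column per
    variant id; values 0/1/2 or NA."""
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "sample":
        raise ParseError(path, 1, "first column must be 'sample'")
    missing = [v.variant_id for v in variants if v.variant_id not in df.columns]
    if missing:
        raise ParseError(path, 1, f"missing variant column(s): {missing}")
    dosage = df[[v.variant_id for v in variants]].to_numpy(dtype=float)
    return GenotypeMatrix(
        samples=[str(s) for s in df["sample"]],
        variants=list(variants),
        dosage=dosage,
    )


def write_dosage_tsv(genotypes: GenotypeMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\t" + "\t".join(v.variant_id for v in genotypes.variants) + "\n")
        for i, s in enumerate(genotypes.samples):
            vals = [
                "NA" if np.isnan(d) else str(int(d)) for d in genotypes.dosage[i]
            ]
            fh.write(s + "\t" + "\t".join(vals) + "\n")


def read_vcf_dosages(path: str | Path, variants: Sequence[Variant]) -> GenotypeMatrix:
    """Read risk-allele dosages from a VCF (GT field only).

    Each requested variant is matched by chrom/pos; the dosage is the number
    of alleles equal to the risk allele (missing genotypes become NaN).
    Variants absent from the VCF raise a KeyError.
    """
    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    wanted = {(v.chrom, v.pos): k for k, v in enumerate(variants)}
    dosage = np.full((len(samples), len(variants)), np.nan)
    found = set()
    for rec in vf:
        key = (rec.chrom, rec.pos - 1)  # VCF is 1-based
        k = wanted.get(key)
        if k is None:
            continue
        found.add(k)
        risk = variants[k].risk_allele
        alleles = (rec.ref,) + tuple(rec.alts or ())
        for i, sample in enumerate(samples):
            try:
                gt = rec.samples[sample]["GT"]
            except KeyError:
                gt = None
            if gt is None or any(a is None for a in gt):
                continue
            dosage[i, k] = sum(1 for a in gt if alleles[a] == risk)
    vf.close()
    absent = [variants[k].variant_id for k in range(len(variants)) if k not in found]
    if absent:
        raise KeyError(f"variant(s) not found in VCF: {absent}")
    return GenotypeMatrix(samples=samples, variants=list(variants), dosage=dosage)


# ---------------------------------------------------------------------------
# result writers

def write_joint_sites_tsv(sites: Sequence[JointSite], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "chrom\tstartA\tendA\tstartB\tendB\tnfcA\tnfcB\t"
            "scaledA\tscaledB\tbias\n"
        )
        for s in sites:
            fh.write(
                f"{s.merged.chrom}\t{s.peakA.interval.start}\t{s.peakA.interval.end}\t"
                f"{s.peakB.interval.start}\t{s.peakB.interval.end}\t"
                f"{s.nfcA:.6g}\t{s.nfcB:.6g}\t{s.scaledA:.6g}\t{s.scaledB:.6g}\t"
                f"{s.bias}\n"
            )


def write_bias_summary_tsv(summary: BiasSummary, path: str | Path) -> None:
    na = "NA"
    with open(path, "w") as fh:
        fh.write("n_joint\tn_biased\tn_A\tn_B\tpct_A\tpct_B\n")
        fh.write(
            f"{summary.n_joint}\t{summary.n_biased}\t{summary.n_A}\t{summary.n_B}\t"
            f"{summary.pct_A if summary.n_biased else na}\t"
            f"{summary.pct_B if summary.n_biased else na}\n"
        )


def write_profile_tsv(profile: SummitProfile, path: str | Path) -> None:
    names = list(profile.mean_signal)
    with open(path, "w") as fh:
        fh.write("offset\t" + "\t".join(names) + "\n")
        for i, off in enumerate(profile.positions):
            vals = "\t".join(f"{profile.mean_signal[n][i]:.6g}" for n in names)
            fh.write(f"{off}\t{vals}\n")


def write_assignment_tsv(
    peaks: Sequence[GenomicInterval],
    peak_to_genes: Mapping[int, set],
    path: str | Path,
) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tgenes\n")
        for i, p in enumerate(peaks):
            genes = ",".join(sorted(peak_to_genes.get(i, ()))) or "."
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{genes}\n")


def write_gene_set(genes: set, path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(f"{g}\n")


def read_gene_set(path: str | Path) -> set:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def write_collapsed_groups_tsv(groups: Sequence[CollapsedGroup], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("profile\tburden\tn_members\tmean_expression\n")
        for g in groups:
            prof = "/".join(str(d) for d in g.profile)
            fh.write(f"{prof}\t{g.burden}\t{g.n_members}\t{g.mean_expression:.6g}\n")


def write_regression_tsv(result: RegressionResult, path: str | Path, label: str = "regression") -> None:
    with open(path, "w") as fh:
        fh.write("analysis\tslope\tpearson_r\tp_value\tn\n")
        fh.write(
            f"{label}\t{result.slope:.6g}\t{result.pearson_r:.6g}\t"
            f"{result.p_value:.6g}\t{result.n}\n"
        )


def write_merged_pairs_tsv(pairs: Sequence[MergedPair], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("variant_id\tbeta_gwas\tbeta_eqtl\n")
        for p in pairs:
            fh.write(f"{p.variant_id}\t{p.beta_gwas:.6g}\t{p.beta_eqtl:.6g}\n")
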