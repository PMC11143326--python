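"""Assign direction-concordant differential peaks to regulated genes.

A differential peak is concordant with a condition when its interval overlaps
the closed window [TSS - w, TSS + w] (w = 200 kb by default, strand
independent) of at least one gene regulated in the matching direction:
fasted-opened peaks pair with fasting-induced genes, fasted-closed with
fasting-repressed, leptin-opened with leptin-induced and leptin-closed with
leptin-repressed. The module also computes the descriptive association
statistics (fraction of regulated genes with a concordant peak, one-tailed
Fisher test against neutral genes, peaks-per-gene histogram, Spearman rho of
peak count vs |log2FC|) and the strand-aware genomic feature annotation of
peaks (promoter > exonic > intronic > intergenic).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from cistf.io_formats import GeneModel, Peak

#: peak condition -> direction-matched gene condition
CONDITION_PAIRING = {
    "fasted_opened": "fasting_induced",
    "fasted_closed": "fasting_repressed",
    "leptin_opened": "leptin_induced",
    "leptin_closed": "leptin_repressed",
}


@dataclass
class ConcordantPeakSet:
    """Concordant peaks for one condition with the supporting-gene mappings."""

    condition: str
    peak_ids: list[str] = field(default_factory=list)
    peak_to_genes: dict[str, list[str]] = field(default_factory=dict)
    gene_to_peaks: dict[str, list[str]] = field(default_factory=dict)


@dataclass
class AssociationStats:
    condition: str
    n_genes: int
    n_genes_with_peak: int
    fraction: float
    p_value: float
    peaks_per_gene: dict[int, int]
    rho: float


def _windowed_gene_hits(peak: Peak, tss_sorted: np.ndarray, ids_sorted: np.ndarray,
                        window_bp: int) -> np.ndarray:
    """Gene ids whose closed TSS window [tss-w, tss+w] overlaps the peak interval."""
    # overlap <=> tss in [start - w, (end - 1) + w]
    lo = np.searchsorted(tss_sorted, peak.start - window_bp, side="left")
    hi = np.searchsorted(tss_sorted, peak.end - 1 + window_bp, side="right")
    return ids_sorted[lo:hi]


def _tss_index(genes: Iterable[GeneModel]) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append((g.tss, g.gene_id))
    out = {}
    for chrom, pairs in by_chrom.items():
        pairs.sort()
        out[chrom] = (np.array([p[0] for p in pairs]), np.array([p[1] for p in pairs]))
    return out


def assign_concordant_peaks(peaks: Sequence[Peak], genes: Sequence[GeneModel], reg,
                            window_bp: int = 200_000,
                            chrom_allowlist: set[str] | None = None,
                            ) -> dict[str, ConcordantPeakSet]:
    """Concordant peak assignment for all four conditions.

    ``reg`` provides the four regulated gene-id sets and four peak-id sets
    (a :class:`~cistf.diff_classify.RegulatedSets`). Peaks on chromosomes
    outside ``chrom_allowlist`` (when given) are excluded, mirroring the
    removal of non-chromosomal scaffolds. Output ordering is canonical
    (genomic coordinates), so it is invariant to input order.
    """
    if window_bp < 0:
        raise ValueError(f"window_bp must be nonnegative, got {window_bp}")
    peaks_sorted = sorted(peaks, key=lambda p: (p.chrom, p.start, p.end, p.peak_id))
    result: dict[str, ConcordantPeakSet] = {}
    for condition, gene_condition in CONDITION_PAIRING.items():
        cond_peaks = reg.peak_set(condition)
        cond_genes = reg.gene_set(gene_condition)
        index = _tss_index(g for g in genes if g.gene_id in cond_genes)
        cps = ConcordantPeakSet(condition=condition)
        for p in peaks_sorted:
            if p.peak_id not in cond_peaks:
                continue
            if chrom_allowlist is not None and p.chrom not in chrom_allowlist:
                continue
            if p.chrom not in index:
                continue
            tss_arr, id_arr = index[p.chrom]
            hits = _windowed_gene_hits(p, tss_arr, id_arr, window_bp)
            if hits.size == 0:
                continue
            support = sorted(str(g) for g in hits)
            cps.peak_ids.append(p.peak_id)
            cps.peak_to_genes[p.peak_id] = support
            for g in support:
                cps.gene_to_peaks.setdefault(g, []).append(p.peak_id)
        result[condition] = cps
    return result


def association_stats(cond_gene_set: set[str], cond_peak_set: ConcordantPeakSet,
                      neutral_gene_set: set[str], genes: Sequence[GeneModel],
                      peaks: Sequence[Peak], window_bp: int = 200_000,
                      reg_peak_ids: set[str] | None = None) -> AssociationStats:
    """Association of regulated genes with concordant peaks.

    Fraction of condition genes with at least one concordant peak, with a
    one-tailed Fisher exact p-value against the fraction of neutral genes
    having at least one same-direction differential peak within the window.
    ``reg_peak_ids`` is that same-direction differential peak-id set (defaults
    to the peaks present in ``cond_peak_set``).
    """
    if not cond_gene_set:
        raise ValueError("condition gene set is empty")
    gene_by_id = {g.gene_id: g for g in genes}
    n_genes = len(cond_gene_set)
    with_peak = {g for g in cond_gene_set if cond_peak_set.gene_to_peaks.get(g)}
    n_with = len(with_peak)

    if reg_peak_ids is None:
        reg_peak_ids = set(cond_peak_set.peak_ids)
    diff_peaks = [p for p in peaks if p.peak_id in reg_peak_ids]
    index = _tss_index(gene_by_id[g] for g in neutral_gene_set if g in gene_by_id)
    neutral_with = set()
    for p in diff_peaks:
        if p.chrom in index:
            tss_arr, id_arr = index[p.chrom]
            neutral_with.update(str(g) for g in _windowed_gene_hits(p, tss_arr, id_arr, window_bp))
    n_neutral = len(neutral_gene_set)
    n_neutral_with = len(neutral_with)
    table = [[n_with, n_genes - n_with], [n_neutral_with, n_neutral - n_neutral_with]]
    p_value = float(stats.fisher_exact(table, alternative="greater")[1]) if n_neutral else float("nan")

    counts = {g: len(cond_peak_set.gene_to_peaks.get(g, [])) for g in cond_gene_set}
    hist: dict[int, int] = {}
    for g in with_peak:
        hist[counts[g]] = hist.get(counts[g], 0) + 1
    lfc = np.array([abs(gene_by_id[g].log2fc) for g in sorted(cond_gene_set) if g in gene_by_id])
    npk = np.array([counts[g] for g in sorted(cond_gene_set) if g in gene_by_id])
    if len(lfc) > 1 and np.std(lfc) > 0 and np.std(npk) > 0 and not np.isnan(lfc).any():
        rho = float(stats.spearmanr(npk, lfc)[0])
    else:
        rho = float("nan")
    return AssociationStats(
        condition=cond_peak_set.condition,
        n_genes=n_genes,
        n_genes_with_peak=n_with,
        fraction=n_with / n_genes,
        p_value=p_value,
        peaks_per_gene=hist,
        rho=rho,
    )


def annotate_peak_features(peaks: Sequence[Peak], genes: Sequence[GeneModel],
                           promoter_bp: int = 1000) -> dict[str, str]:
    """Annotate each peak as promoter, exonic, intronic or intergenic.

    Promoter = strand-aware window of ``promoter_bp`` immediately upstream of
    the TSS ([tss-1000, tss) on +, (tss, tss+1000] on -). Precedence across
    all genes: promoter > exonic > intronic > intergenic. Genes without exon
    intervals contribute their full span as generic genic (ranked exonic).
    """
    promoters: dict[str, list[tuple[int, int]]] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    bodies: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        if g.strand == "+":
            promoters.setdefault(g.chrom, []).append((max(0, g.tss - promoter_bp), g.tss))
        else:
            promoters.setdefault(g.chrom, []).append((g.tss + 1, g.tss + 1 + promoter_bp))
        start = g.start if g.start is not None else g.tss
        end = g.end if g.end is not None else g.tss + 1
        if g.exons:
            bodies.setdefault(g.chrom, []).append((start, end))
            for e in g.exons:
                exons.setdefault(g.chrom, []).append(e)
        else:
            exons.setdefault(g.chrom, []).append((start, end))

    def overlaps(p: Peak, intervals: Mapping[str, list[tuple[int, int]]]) -> bool:
        return any(p.start < e and p.end > s for s, e in intervals.get(p.chrom, ()))

    out: dict[str, str] = {}
    for p in peaks:
        if overlaps(p, promoters):
            out[p.peak_id] = "promoter"
        elif overlaps(p, exons):
            out[p.peak_id] = "exonic"
        elif overlaps(p, bodies):
            out[p.peak_id] = "intronic"
        else:
            out[p.peak_id] = "intergenic"
    return out


def feature_fractions(annotations: Mapping[str, str]) -> dict[str, float]:
    """Fraction of peaks per genomic feature class."""
    total = len(annotations)
    out = {}
    for feat in ("promoter", "exonic", "intronic", "intergenic"):
        out[feat] = sum(1 for v in annotations.values() if v == feat) / total if total else 0.0
    return out
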