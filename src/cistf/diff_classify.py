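"""Classify differential genes and peaks into regulated sets.

Thresholds follow the study design: genes are called at |log2FC| strictly
greater than 0.5, peaks at |log2FC| >= 0.5, both at FDR < 0.05 with a
1-CPM expression/accessibility floor. A Welch-t stand-in differential test on
log2 CPM is provided so fully synthetic runs need no external DE tool; it is
deliberately simple and is NOT a reimplementation of edgeR's quasi-likelihood
GLM — externally produced differential tables are the recommended input for
real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from cistf.io_formats import CONTRAST_GROUPS, DiffTable, FormatError


@dataclass(frozen=True)
class ThresholdConfig:
    """Cutoffs for calling regulated genes and peaks.

    Genes use strict inequalities (log2fc > gene_lfc_min, CPM > gene_cpm_min),
    peaks inclusive ones (log2fc >= peak_lfc_min, CPM >= peak_cpm_min); the
    FDR cutoff is strict for both.
    """

    gene_lfc_min: float = 0.5
    peak_lfc_min: float = 0.5
    fdr_max: float = 0.05
    gene_cpm_min: float = 1.0
    peak_cpm_min: float = 1.0
    cpm_rule: str = "any_group"  # or "all_groups"

    def __post_init__(self) -> None:
        if min(self.gene_lfc_min, self.peak_lfc_min, self.gene_cpm_min, self.peak_cpm_min) < 0:
            raise ValueError("thresholds must be >= 0")
        if not (0 < self.fdr_max <= 1):
            raise ValueError("fdr_max must lie in (0, 1]")
        if self.cpm_rule not in {"any_group", "all_groups"}:
            raise ValueError(f"unknown cpm_rule {self.cpm_rule!r}")


@dataclass
class RegulatedSets:
    """The four regulated gene sets and four regulated peak sets."""

    fasting_induced: set[str] = field(default_factory=set)
    fasting_repressed: set[str] = field(default_factory=set)
    leptin_induced: set[str] = field(default_factory=set)
    leptin_repressed: set[str] = field(default_factory=set)
    fasted_opened: set[str] = field(default_factory=set)
    fasted_closed: set[str] = field(default_factory=set)
    leptin_opened: set[str] = field(default_factory=set)
    leptin_closed: set[str] = field(default_factory=set)

    def gene_set(self, condition: str) -> set[str]:
        return getattr(self, condition)

    def peak_set(self, condition: str) -> set[str]:
        return getattr(self, condition)


@dataclass
class BidirectionalSets:
    fast_up_leptin_down: set[str]
    fast_down_leptin_up: set[str]


def _cpm_passes(table: DiffTable, cpm_min: float, strict: bool, rule: str) -> np.ndarray:
    cols = table.cpm_columns()
    if not cols:
        # fall back to a single mean_cpm column
        if "mean_cpm" not in table.df.columns:
            raise FormatError("differential table has no mean_cpm column(s)")
        vals = table.df[["mean_cpm"]].to_numpy(dtype=float)
    else:
        vals = table.df[cols].to_numpy(dtype=float)
    per_group = vals > cpm_min if strict else vals >= cpm_min
    return per_group.any(axis=1) if rule == "any_group" else per_group.all(axis=1)


def classify_diff_genes(table: DiffTable, cfg: ThresholdConfig = ThresholdConfig()
                        ) -> tuple[set[str], set[str]]:
    """Split a gene table into (induced, repressed) id sets.

    Induced: log2fc > gene_lfc_min, FDR < fdr_max and mean CPM > gene_cpm_min
    in at least one compared group (configurable to both); repressed mirrors
    with log2fc < -gene_lfc_min.
    """
    if table.kind != "gene":
        raise FormatError(f"expected a gene table, got kind={table.kind!r}")
    lfc = table.df["log2fc"].to_numpy(dtype=float)
    fdr = table.df["fdr"].to_numpy(dtype=float)
    ok = (fdr < cfg.fdr_max) & _cpm_passes(table, cfg.gene_cpm_min, strict=True, rule=cfg.cpm_rule)
    ids = table.df["id"].astype(str).to_numpy()
    induced = set(ids[ok & (lfc > cfg.gene_lfc_min)])
    repressed = set(ids[ok & (lfc < -cfg.gene_lfc_min)])
    return induced, repressed


def classify_diff_peaks(table: DiffTable, cfg: ThresholdConfig = ThresholdConfig()
                        ) -> tuple[set[str], set[str]]:
    """Split a peak table into (opened, closed) id sets (inclusive |log2fc| >= cutoff)."""
    if table.kind != "peak":
        raise FormatError(f"expected a peak table, got kind={table.kind!r}")
    lfc = table.df["log2fc"].to_numpy(dtype=float)
    fdr = table.df["fdr"].to_numpy(dtype=float)
    ok = (fdr < cfg.fdr_max) & _cpm_passes(table, cfg.peak_cpm_min, strict=False, rule=cfg.cpm_rule)
    ids = table.df["id"].astype(str).to_numpy()
    opened = set(ids[ok & (lfc >= cfg.peak_lfc_min)])
    closed = set(ids[ok & (lfc <= -cfg.peak_lfc_min)])
    return opened, closed


def classify_all(gene_tables: dict[str, DiffTable], peak_tables: dict[str, DiffTable],
                 cfg: ThresholdConfig = ThresholdConfig()) -> RegulatedSets:
    """Build the full RegulatedSets from per-contrast gene and peak tables."""
    reg = RegulatedSets()
    if "fasted_vs_fed" in gene_tables:
        reg.fasting_induced, reg.fasting_repressed = classify_diff_genes(
            gene_tables["fasted_vs_fed"], cfg)
    if "leptin_vs_fasted" in gene_tables:
        reg.leptin_induced, reg.leptin_repressed = classify_diff_genes(
            gene_tables["leptin_vs_fasted"], cfg)
    if "fasted_vs_fed" in peak_tables:
        reg.fasted_opened, reg.fasted_closed = classify_diff_peaks(
            peak_tables["fasted_vs_fed"], cfg)
    if "leptin_vs_fasted" in peak_tables:
        reg.leptin_opened, reg.leptin_closed = classify_diff_peaks(
            peak_tables["leptin_vs_fasted"], cfg)
    return reg


def bidirectional_sets(reg: RegulatedSets) -> BidirectionalSets:
    """Genes regulated oppositely by fasting and leptin (set intersections)."""
    return BidirectionalSets(
        fast_up_leptin_down=reg.fasting_induced & reg.leptin_repressed,
        fast_down_leptin_up=reg.fasting_repressed & reg.leptin_induced,
    )


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def cpm(counts: pd.DataFrame, pseudo: float = 0.0) -> pd.DataFrame:
    """Counts-per-million with an optional per-cell pseudo-count offset."""
    shifted = counts + pseudo
    return shifted / shifted.sum(axis=0) * 1e6


def simple_de_test(counts: pd.DataFrame, groups: dict[str, str], contrast: str,
                   kind: str = "gene", moderation_df: float = 20.0) -> DiffTable:
    """Two-group differential test on log2 CPM with a +0.5 pseudo-offset.

    ``counts`` is features x samples; ``groups`` maps sample name to condition.
    log2FC is treatment over reference of the group-mean CPM. The test is a
    two-sample t on log2 CPM whose pooled per-feature variance is shrunk
    toward the across-feature mean variance with ``moderation_df`` prior
    degrees of freedom (empirical-Bayes style): at typical small replicate
    numbers a plain per-feature t is too unstable to be useful. Set
    ``moderation_df=0`` for the unmoderated test. Features with no variance
    and no mean difference get p = 1. This is a documented stand-in for a
    count-model DE test, chosen for determinism and light dependencies.
    """
    treat, ref = CONTRAST_GROUPS[contrast]
    t_samples = [s for s in counts.columns if groups.get(s) == treat]
    r_samples = [s for s in counts.columns if groups.get(s) == ref]
    if len(t_samples) < 2 or len(r_samples) < 2:
        raise ValueError(
            f"contrast {contrast}: need >= 2 samples per group, got "
            f"{len(t_samples)} {treat} and {len(r_samples)} {ref}"
        )
    cpm_all = cpm(counts[t_samples + r_samples], pseudo=0.5)
    log_cpm = np.log2(cpm_all)
    mean_t = cpm_all[t_samples].mean(axis=1)
    mean_r = cpm_all[r_samples].mean(axis=1)
    log2fc = np.log2(mean_t / mean_r)

    x = log_cpm[t_samples].to_numpy()
    y = log_cpm[r_samples].to_numpy()
    n1, n2 = x.shape[1], y.shape[1]
    df_res = n1 + n2 - 2
    s2 = ((n1 - 1) * x.var(axis=1, ddof=1) + (n2 - 1) * y.var(axis=1, ddof=1)) / df_res
    s2_prior = float(np.mean(s2)) if np.any(s2 > 0) else 0.0
    s2_mod = (moderation_df * s2_prior + df_res * s2) / (moderation_df + df_res)
    delta = x.mean(axis=1) - y.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = delta / np.sqrt(s2_mod * (1.0 / n1 + 1.0 / n2))
        pval = 2.0 * stats.t.sf(np.abs(tstat), df=moderation_df + df_res)
    pval = np.asarray(pval, dtype=float)
    log2fc = np.asarray(log2fc, dtype=float)
    # degenerate features (zero variance in both groups): no evidence either way
    degenerate = np.isnan(pval)
    pval[degenerate] = 1.0
    # all-zero features carry no signal at all: force the null exactly
    all_zero = (counts[t_samples + r_samples].to_numpy() == 0).all(axis=1)
    log2fc[all_zero] = 0.0
    pval[all_zero] = 1.0
    fdr = bh_adjust(pval)

    df = pd.DataFrame(
        {
            "id": counts.index.astype(str),
            "log2fc": log2fc,
            "p": pval,
            "fdr": fdr,
            f"mean_cpm_{treat}": mean_t.to_numpy(),
            f"mean_cpm_{ref}": mean_r.to_numpy(),
        }
    )
    return DiffTable(df=df, contrast=contrast, kind=kind)
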