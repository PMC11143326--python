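"""End-to-end orchestration: classify -> concord -> enrich -> prioritize.

``analyze_bundle`` runs the whole analysis in memory; the ``stage_*``
functions are the file-level equivalents used by the CLI, each reading its
inputs from disk and writing deterministic TSV/JSON outputs plus a stage
manifest, so chaining the stages by hand is byte-identical to ``run-all``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from cistf import __version__
from cistf.concordance import (
    AssociationStats,
    ConcordantPeakSet,
    CONDITION_PAIRING,
    annotate_peak_features,
    assign_concordant_peaks,
    association_stats,
)
from cistf.diff_classify import (
    RegulatedSets,
    ThresholdConfig,
    classify_all,
    simple_de_test,
)
from cistf.io_formats import (
    CONTRASTS,
    DiffTable,
    FLOAT_FMT,
    GeneModel,
    GenomeSequences,
    PEAK_CONDITIONS,
    Peak,
    PWMMotif,
    config_hash,
    extract_peak_sequences,
    read_bed,
    read_diff_table,
    read_fasta,
    read_gene_models,
    read_meme_motifs,
    write_diff_table,
)
from cistf.motif_enrichment import (
    EnrichmentResult,
    build_background_suite,
    genome_base_frequencies,
    run_enrichment_suite,
)
from cistf.prioritization import (
    MotifConsensus,
    TFPriorityRecord,
    build_priority_records,
    consensus_call,
    rank_and_export,
)

logger = logging.getLogger(__name__)

CONTRAST_OF_CONDITION = {
    "fasted_opened": "fasted_vs_fed",
    "fasted_closed": "fasted_vs_fed",
    "leptin_opened": "leptin_vs_fasted",
    "leptin_closed": "leptin_vs_fasted",
}


@dataclass
class RunConfig:
    """Paths and parameters of a full pipeline run."""

    genome: str
    genes: str
    peaks: str
    motifs: str
    outdir: str
    gene_counts: str | None = None
    peak_counts: str | None = None
    gene_tables: dict[str, str] = field(default_factory=dict)
    peak_tables: dict[str, str] = field(default_factory=dict)
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    window_bp: int = 200_000
    alpha: float = 0.05
    pseudocount: float = 0.01
    seed: int = 0
    scoring: str = "max"
    chrom_allowlist: list[str] | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        thr = ThresholdConfig(**doc.pop("thresholds", {}))
        return cls(thresholds=thr, **doc)

    def to_doc(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        # outdir is where results land, not what they are: keep it out of the hash
        doc = self.to_doc()
        doc.pop("outdir", None)
        return config_hash(doc)

    def validate(self) -> None:
        for name in ("genome", "genes", "peaks", "motifs"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name} file not found: {p}")


@dataclass
class PipelineResult:
    reg: RegulatedSets
    gene_tables: dict[str, DiffTable]
    peak_tables: dict[str, DiffTable]
    concordant: dict[str, ConcordantPeakSet]
    enrichment: dict[str, dict[str, dict[str, EnrichmentResult]]]  # cond -> motif -> bg
    consensus: dict[str, dict[str, MotifConsensus]]  # motif -> cond
    records: list[TFPriorityRecord]
    table: pd.DataFrame
    radar: dict
    association: dict[str, AssociationStats]


def _condition_seed(seed: int, idx: int) -> int:
    return int(np.random.default_rng([seed, idx]).integers(2**31))


def analyze_bundle(genome: GenomeSequences, genes: list[GeneModel], peaks: list[Peak],
                   gene_tables: Mapping[str, DiffTable],
                   peak_tables: Mapping[str, DiffTable],
                   motifs: list[PWMMotif],
                   thresholds: ThresholdConfig = ThresholdConfig(),
                   window_bp: int = 200_000, alpha: float = 0.05,
                   pseudocount: float = 0.01, seed: int = 0,
                   scoring: str = "max",
                   chrom_allowlist: set[str] | None = None) -> PipelineResult:
    """Run the full in-memory analysis from differential tables onward."""
    reg = classify_all(dict(gene_tables), dict(peak_tables), thresholds)
    concordant = assign_concordant_peaks(peaks, genes, reg, window_bp=window_bp,
                                         chrom_allowlist=chrom_allowlist)
    bg_freq = genome_base_frequencies(genome)
    peak_by_id = {p.peak_id: p for p in peaks}

    enrichment: dict[str, dict[str, dict[str, EnrichmentResult]]] = {}
    for idx, cond in enumerate(PEAK_CONDITIONS):
        cps = concordant[cond]
        if not cps.peak_ids:
            logger.warning("condition %s has no concordant peaks; skipping enrichment", cond)
            continue
        suite = build_background_suite(
            cond, cps, peaks, reg, genes, genome, window_bp=window_bp,
            rng_seed=_condition_seed(seed, idx), chrom_allowlist=chrom_allowlist)
        fg_seqs = extract_peak_sequences(genome, [peak_by_id[i] for i in cps.peak_ids])
        enrichment[cond] = run_enrichment_suite(
            fg_seqs, suite, motifs, background=bg_freq,
            pseudocount=pseudocount, scoring=scoring, foreground_label=cond)

    consensus: dict[str, dict[str, MotifConsensus]] = {}
    for motif in motifs:
        per_cond = {}
        for cond in PEAK_CONDITIONS:
            if cond not in enrichment:
                continue
            per_cond[cond] = consensus_call(
                list(enrichment[cond][motif.motif_id].values()), alpha=alpha)
        if len(per_cond) == len(PEAK_CONDITIONS):
            consensus[motif.motif_id] = per_cond
    records = build_priority_records(consensus)
    table, radar = rank_and_export(records)

    association: dict[str, AssociationStats] = {}
    for cond in PEAK_CONDITIONS:
        gene_cond = CONDITION_PAIRING[cond]
        contrast = CONTRAST_OF_CONDITION[cond]
        if contrast not in gene_tables:
            continue
        gt = gene_tables[contrast]
        lfc = dict(zip(gt.df["id"].astype(str), gt.df["log2fc"].astype(float)))
        genes_lfc = [dataclasses.replace(g, log2fc=lfc.get(g.gene_id, float("nan")))
                     for g in genes]
        cond_genes = reg.gene_set(gene_cond)
        if not cond_genes:
            continue
        induced, repressed = {
            "fasted_vs_fed": (reg.fasting_induced, reg.fasting_repressed),
            "leptin_vs_fasted": (reg.leptin_induced, reg.leptin_repressed),
        }[contrast]
        neutral = {g.gene_id for g in genes} - induced - repressed
        association[cond] = association_stats(
            cond_genes, concordant[cond], neutral, genes_lfc, peaks,
            window_bp=window_bp, reg_peak_ids=reg.peak_set(cond))

    return PipelineResult(
        reg=reg, gene_tables=dict(gene_tables), peak_tables=dict(peak_tables),
        concordant=concordant, enrichment=enrichment, consensus=consensus,
        records=records, table=table, radar=radar, association=association)


# ---------------------------------------------------------------------------
# File-level stages
# ---------------------------------------------------------------------------


def _write_json(doc, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (set, frozenset)):
        return sorted(o)
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(type(o).__name__)


def _stage_manifest(cfg: RunConfig, stage: str, outputs: list[str]) -> None:
    outdir = Path(cfg.outdir)
    _write_json(
        {"stage": stage, "seed": cfg.seed, "config_hash": cfg.hash(),
         "version": __version__, "outputs": sorted(outputs)},
        outdir / f"manifest_{stage}.json")


def _load_tables(cfg: RunConfig, kind: str) -> dict[str, DiffTable]:
    outdir = Path(cfg.outdir)
    paths = cfg.gene_tables if kind == "gene" else cfg.peak_tables
    counts_path = cfg.gene_counts if kind == "gene" else cfg.peak_counts
    tables: dict[str, DiffTable] = {}
    if paths:
        for contrast, path in paths.items():
            tables[contrast] = read_diff_table(path, contrast, kind)
    elif counts_path:
        # tables were produced by stage_classify; reload them from the run dir
        for contrast in CONTRASTS:
            p = outdir / f"diff_{kind}_{contrast}.tsv"
            tables[contrast] = read_diff_table(p, contrast, kind)
    else:
        raise FileNotFoundError(f"no {kind} differential tables or counts configured")
    return tables


def stage_classify(cfg: RunConfig) -> None:
    """Differential tables (from counts if needed) -> regulated set JSON."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs = []
    gene_tables: dict[str, DiffTable] = {}
    peak_tables: dict[str, DiffTable] = {}
    for kind, counts_path, tables in (("gene", cfg.gene_counts, gene_tables),
                                      ("peak", cfg.peak_counts, peak_tables)):
        paths = cfg.gene_tables if kind == "gene" else cfg.peak_tables
        if paths:
            for contrast, path in paths.items():
                tables[contrast] = read_diff_table(path, contrast, kind)
        elif counts_path:
            counts = pd.read_csv(counts_path, sep="\t", index_col=0)
            groups = {s: s.rsplit("_", 1)[0] for s in counts.columns}
            for contrast in CONTRASTS:
                t = simple_de_test(counts, groups, contrast, kind=kind)
                tables[contrast] = t
                p = outdir / f"diff_{kind}_{contrast}.tsv"
                write_diff_table(t, p)
                outputs.append(p.name)
        else:
            raise FileNotFoundError(f"no {kind} differential tables or counts configured")
    reg = classify_all(gene_tables, peak_tables, cfg.thresholds)
    sets_doc = {f: sorted(getattr(reg, f)) for f in (
        "fasting_induced", "fasting_repressed", "leptin_induced", "leptin_repressed",
        "fasted_opened", "fasted_closed", "leptin_opened", "leptin_closed")}
    _write_json(sets_doc, outdir / "regulated_sets.json")
    outputs.append("regulated_sets.json")
    _stage_manifest(cfg, "classify", outputs)


def _load_reg(cfg: RunConfig) -> RegulatedSets:
    with open(Path(cfg.outdir) / "regulated_sets.json") as fh:
        doc = json.load(fh)
    return RegulatedSets(**{k: set(v) for k, v in doc.items()})


def stage_concord(cfg: RunConfig) -> None:
    """Regulated sets + annotation -> concordant peak TSVs, association, features."""
    outdir = Path(cfg.outdir)
    reg = _load_reg(cfg)
    genes = read_gene_models(cfg.genes)
    peaks = read_bed(cfg.peaks)
    allow = set(cfg.chrom_allowlist) if cfg.chrom_allowlist else None
    concordant = assign_concordant_peaks(peaks, genes, reg, window_bp=cfg.window_bp,
                                         chrom_allowlist=allow)
    peak_by_id = {p.peak_id: p for p in peaks}
    outputs = []
    for cond, cps in concordant.items():
        rows = []
        for pid in cps.peak_ids:
            p = peak_by_id[pid]
            support = cps.peak_to_genes[pid]
            rows.append({"peak_id": pid, "chrom": p.chrom, "start": p.start, "end": p.end,
                         "supporting_gene_ids": ",".join(support), "n_support": len(support)})
        name = f"concordant_{cond}.tsv"
        pd.DataFrame(rows, columns=["peak_id", "chrom", "start", "end",
                                    "supporting_gene_ids", "n_support"]
                     ).to_csv(outdir / name, sep="\t", index=False)
        outputs.append(name)

    gene_tables = _load_tables(cfg, "gene")
    assoc_doc = {}
    for cond in PEAK_CONDITIONS:
        contrast = CONTRAST_OF_CONDITION[cond]
        gene_cond = CONDITION_PAIRING[cond]
        cond_genes = reg.gene_set(gene_cond)
        if not cond_genes or contrast not in gene_tables:
            continue
        gt = gene_tables[contrast]
        lfc = dict(zip(gt.df["id"].astype(str), gt.df["log2fc"].astype(float)))
        genes_lfc = [dataclasses.replace(g, log2fc=lfc.get(g.gene_id, float("nan")))
                     for g in genes]
        induced, repressed = {
            "fasted_vs_fed": (reg.fasting_induced, reg.fasting_repressed),
            "leptin_vs_fasted": (reg.leptin_induced, reg.leptin_repressed),
        }[contrast]
        neutral = {g.gene_id for g in genes} - induced - repressed
        st = association_stats(cond_genes, concordant[cond], neutral, genes_lfc, peaks,
                               window_bp=cfg.window_bp, reg_peak_ids=reg.peak_set(cond))
        assoc_doc[cond] = dataclasses.asdict(st)
    _write_json(assoc_doc, outdir / "association.json")
    outputs.append("association.json")

    features = annotate_peak_features(peaks, genes)
    pd.DataFrame(sorted(features.items()), columns=["peak_id", "feature"]).to_csv(
        outdir / "peak_features.tsv", sep="\t", index=False)
    outputs.append("peak_features.tsv")
    _stage_manifest(cfg, "concord", outputs)


def stage_enrich(cfg: RunConfig) -> None:
    """Concordant peaks + genome + motif library -> enrichment matrix TSV."""
    outdir = Path(cfg.outdir)
    reg = _load_reg(cfg)
    genome = read_fasta(cfg.genome)
    genes = read_gene_models(cfg.genes)
    peaks = read_bed(cfg.peaks)
    motifs = read_meme_motifs(cfg.motifs)
    allow = set(cfg.chrom_allowlist) if cfg.chrom_allowlist else None
    bg_freq = genome_base_frequencies(genome)
    peak_by_id = {p.peak_id: p for p in peaks}
    rows = []
    for idx, cond in enumerate(PEAK_CONDITIONS):
        df = pd.read_csv(outdir / f"concordant_{cond}.tsv", sep="\t")
        cps = ConcordantPeakSet(condition=cond, peak_ids=[str(i) for i in df["peak_id"]])
        if not cps.peak_ids:
            continue
        suite = build_background_suite(
            cond, cps, peaks, reg, genes, genome, window_bp=cfg.window_bp,
            rng_seed=_condition_seed(cfg.seed, idx), chrom_allowlist=allow)
        fg_seqs = extract_peak_sequences(genome, [peak_by_id[i] for i in cps.peak_ids])
        res = run_enrichment_suite(fg_seqs, suite, motifs, background=bg_freq,
                                   pseudocount=cfg.pseudocount, scoring=cfg.scoring,
                                   foreground_label=cond)
        for motif_id, per_bg in res.items():
            for bg_label, r in per_bg.items():
                rows.append({
                    "foreground": cond, "motif_id": motif_id, "background_label": bg_label,
                    "threshold_star": r.threshold_star, "p_raw": r.p_raw, "p_adj": r.p_adj,
                    "log_p_raw": r.log_p_raw, "log_p_adj": r.log_p_adj,
                    "fg_hits": r.fg_hits, "fg_total": r.fg_total,
                    "bg_hits": r.bg_hits, "bg_total": r.bg_total,
                    "n_thresholds": r.n_thresholds,
                })
    pd.DataFrame(rows).to_csv(outdir / "enrichment.tsv", sep="\t", index=False,
                              float_format=FLOAT_FMT)
    _stage_manifest(cfg, "enrich", ["enrichment.tsv"])


def stage_prioritize(cfg: RunConfig) -> None:
    """Enrichment matrix -> consensus, categories, ranked table, radar JSON."""
    outdir = Path(cfg.outdir)
    df = pd.read_csv(outdir / "enrichment.tsv", sep="\t")
    consensus: dict[str, dict[str, MotifConsensus]] = {}
    for motif_id, mdf in df.groupby("motif_id"):
        per_cond = {}
        for cond, cdf in mdf.groupby("foreground"):
            results = [
                EnrichmentResult(
                    motif_id=str(motif_id), foreground=str(cond),
                    background_label=str(r.background_label),
                    threshold_star=float(r.threshold_star),
                    log_p_raw=float(r.log_p_raw), log_p_adj=float(r.log_p_adj),
                    fg_hits=int(r.fg_hits), fg_total=int(r.fg_total),
                    bg_hits=int(r.bg_hits), bg_total=int(r.bg_total),
                    n_thresholds=int(r.n_thresholds))
                for r in cdf.itertuples(index=False)
            ]
            per_cond[str(cond)] = consensus_call(results, alpha=cfg.alpha)
        if len(per_cond) == len(PEAK_CONDITIONS):
            consensus[str(motif_id)] = per_cond
    records = build_priority_records(consensus)
    table, radar = rank_and_export(records)
    table.to_csv(outdir / "tf_priority.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
    _write_json({"metadata": {"seed": cfg.seed, "config_hash": cfg.hash(),
                              "version": __version__}, "radar": radar},
                outdir / "radar.json")
    _stage_manifest(cfg, "prioritize", ["tf_priority.tsv", "radar.json"])


def run_pipeline(cfg: RunConfig) -> Path:
    """Run all four stages; returns the results directory."""
    cfg.validate()
    stage_classify(cfg)
    stage_concord(cfg)
    stage_enrich(cfg)
    stage_prioritize(cfg)
    return Path(cfg.outdir)
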