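"""Readers, writers and the internal data model for every format the pipeline touches.

Coordinate conventions
----------------------
All internal coordinates are 0-based half-open. BED is read as-is (already
0-based half-open); GTF is 1-based inclusive and converted on read. The TSS of
a ``+`` gene is the gene start, of a ``-`` gene the last base of the gene.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")

#: Conditions of the two contrasts, in canonical order.
PEAK_CONDITIONS = ("fasted_opened", "fasted_closed", "leptin_opened", "leptin_closed")
GENE_CONDITIONS = ("fasting_induced", "fasting_repressed", "leptin_induced", "leptin_repressed")
CONTRASTS = ("fasted_vs_fed", "leptin_vs_fasted")
#: Sample groups compared in each contrast (treatment, reference).
CONTRAST_GROUPS = {"fasted_vs_fed": ("fasted", "fed"), "leptin_vs_fasted": ("leptin", "fasted")}


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class GenomeSequences:
    """Chromosome name -> uppercase nucleotide string over {A,C,G,T,N}."""

    sequences: dict[str, str]

    @property
    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def __getitem__(self, chrom: str) -> str:
        return self.sequences[chrom]


@dataclass(frozen=True)
class Peak:
    """A genomic interval (0-based half-open) with optional differential statistics."""

    chrom: str
    start: int
    end: int
    peak_id: str
    log2fc: float = float("nan")
    fdr: float = float("nan")
    mean_cpm: float = float("nan")

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"peak {self.peak_id}: invalid interval [{self.start}, {self.end})"
            )


@dataclass
class GeneModel:
    """A gene with its TSS, strand and optional exon structure and statistics."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    start: int | None = None
    end: int | None = None
    exons: list[tuple[int, int]] = field(default_factory=list)
    log2fc: float = float("nan")
    fdr: float = float("nan")
    group_mean_cpm: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise FormatError(f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}")


@dataclass
class PWMMotif:
    """Position probability matrix, rows = positions, columns = A,C,G,T."""

    motif_id: str
    matrix: np.ndarray
    alt_name: str = ""
    nsites: int | None = None
    source_background: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4 or self.matrix.shape[0] < 1:
            raise FormatError(f"motif {self.motif_id}: matrix must be Lx4 with L >= 1")
        if (self.matrix < 0).any():
            raise FormatError(f"motif {self.motif_id}: negative probability")
        sums = self.matrix.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 0.05):
            bad = int(np.argmax(np.abs(sums - 1.0)))
            raise FormatError(
                f"motif {self.motif_id}: probability row {bad} sums to {sums[bad]:.4g}, not 1"
            )
        # renormalize away rounding slack
        self.matrix = self.matrix / sums[:, None]

    @property
    def length(self) -> int:
        return self.matrix.shape[0]


@dataclass
class DiffTable:
    """A per-feature differential table for one contrast.

    ``df`` has columns ``id``, ``log2fc``, ``fdr`` and ``mean_cpm_<group>``
    for each compared group.
    """

    df: pd.DataFrame
    contrast: str
    kind: str  # "gene" or "peak"

    def __post_init__(self) -> None:
        if self.contrast not in CONTRASTS:
            raise FormatError(f"unknown contrast {self.contrast!r}")
        if self.kind not in {"gene", "peak"}:
            raise FormatError(f"unknown feature kind {self.kind!r}")
        required = {"id", "log2fc", "fdr"}
        missing = required - set(self.df.columns)
        if missing:
            raise FormatError(f"differential table missing columns: {sorted(missing)}")
        if self.df["id"].duplicated().any():
            dup = self.df["id"][self.df["id"].duplicated()].iloc[0]
            raise FormatError(f"duplicate feature id {dup!r} in differential table")
        fdr = self.df["fdr"].to_numpy(dtype=float)
        if np.any((fdr < 0) | (fdr > 1)):
            raise FormatError("fdr values must lie in [0, 1]")

    @property
    def groups(self) -> tuple[str, str]:
        return CONTRAST_GROUPS[self.contrast]

    def cpm_columns(self) -> list[str]:
        return [f"mean_cpm_{g}" for g in self.groups if f"mean_cpm_{g}" in self.df.columns]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> GenomeSequences:
    """Read a (multi-)FASTA file into uppercase sequences over {A,C,G,T,N}."""
    path = Path(path)
    sequences: dict[str, str] = {}
    with open(path) as handle:
        first = handle.readline()
        if first and not first.startswith(">"):
            raise FormatError(f"{path}: line 1 is not a FASTA header: {first.strip()!r}")
        handle.seek(0)
        for record in SeqIO.parse(handle, "fasta"):
            name = record.id
            if not name:
                raise FormatError(f"{path}: FASTA record with empty header")
            if name in sequences:
                raise FormatError(f"{path}: duplicate chromosome name {name!r}")
            seq = str(record.seq).upper()
            if not seq:
                raise FormatError(f"{path}: empty sequence for record {name!r}")
            bad = set(seq) - VALID_BASES
            if bad:
                raise FormatError(
                    f"{path}: record {name!r} contains invalid characters {sorted(bad)}"
                )
            sequences[name] = seq
    if not sequences:
        raise FormatError(f"{path}: no FASTA records found")
    return GenomeSequences(sequences)


def write_fasta(genome: GenomeSequences, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


def read_bed(path: str | Path) -> list[Peak]:
    """Read BED3/BED6 into peaks; a missing name column yields ``chrom:start-end`` ids."""
    path = Path(path)
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 tab-separated columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start {start} >= end {end}")
            if start < 0:
                raise FormatError(f"{path}:{lineno}: negative start {start}")
            name = fields[3] if len(fields) > 3 and fields[3] not in {"", "."} else f"{chrom}:{start}-{end}"
            peaks.append(Peak(chrom, start, end, name))
    return peaks


def write_bed(peaks: Sequence[Peak], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.peak_id}\n")


# ---------------------------------------------------------------------------
# Gene models (GTF or TSS TSV)
# ---------------------------------------------------------------------------

_GTF_ATTR_RE = re.compile(r'gene_id "([^"]+)"')


def _looks_like_gtf(path: Path) -> bool:
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            return len(line.rstrip("\n").split("\t")) == 9
    return False


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene models from GTF (gene/exon features) or a TSS TSV.

    The TSV dialect has a header row with at least ``gene_id``, ``chrom``,
    ``strand`` and ``tss`` (0-based). Genes without a resolvable TSS or with
    an unknown strand are dropped and counted in the log.
    """
    path = Path(path)
    if _looks_like_gtf(path):
        return _read_gtf(path)
    return _read_tss_tsv(path)


def _read_gtf(path: Path) -> list[GeneModel]:
    genes: dict[str, GeneModel] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    n_dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GTF columns")
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = fields
            if feature not in {"gene", "exon"}:
                continue
            m = _GTF_ATTR_RE.search(attrs)
            if m is None:
                raise FormatError(f"{path}:{lineno}: missing gene_id attribute")
            gene_id = m.group(1)
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if strand not in {"+", "-"}:
                if strand == ".":
                    n_dropped += 1
                    continue
                raise FormatError(f"{path}:{lineno}: unknown strand symbol {strand!r}")
            start0, end0 = start1 - 1, end1  # GTF 1-based inclusive -> half-open
            if feature == "exon":
                exons.setdefault(gene_id, []).append((start0, end0))
                continue
            tss = start0 if strand == "+" else end0 - 1
            genes[gene_id] = GeneModel(gene_id, chrom, strand, tss, start=start0, end=end0)
    for gene_id, ex in exons.items():
        if gene_id in genes:
            genes[gene_id].exons = sorted(ex)
    if n_dropped:
        logger.info("read_gene_models: dropped %d record(s) without a resolvable TSS", n_dropped)
    return list(genes.values())


def _read_tss_tsv(path: Path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "chrom", "strand", "tss"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: TSS table missing columns {sorted(missing)}")
    out: list[GeneModel] = []
    n_dropped = 0
    for row in df.itertuples(index=False):
        strand = str(row.strand)
        if strand not in {"+", "-"}:
            if strand == ".":
                n_dropped += 1
                continue
            raise FormatError(f"{path}: unknown strand symbol {strand!r} for {row.gene_id}")
        if pd.isna(row.tss):
            n_dropped += 1
            continue
        out.append(GeneModel(str(row.gene_id), str(row.chrom), strand, int(row.tss)))
    if n_dropped:
        logger.info("read_gene_models: dropped %d record(s) without a resolvable TSS", n_dropped)
    return out


def write_gtf(genes: Sequence[GeneModel], path: str | Path, source: str = "cistf") -> None:
    """Write gene (and exon) features in GTF 2.2 (1-based inclusive)."""
    with open(path, "w") as fh:
        for g in genes:
            start0 = g.start if g.start is not None else (g.tss if g.strand == "+" else g.tss)
            end0 = g.end if g.end is not None else start0 + 1
            attrs = f'gene_id "{g.gene_id}";'
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{start0 + 1}\t{end0}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for (es, ee) in g.exons:
                fh.write(
                    f"{g.chrom}\t{source}\texon\t{es + 1}\t{ee}\t.\t{g.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# MEME minimal motif format
# ---------------------------------------------------------------------------


def read_meme_motifs(path: str | Path) -> list[PWMMotif]:
    """Read a MEME minimal motif file (version line, optional background, MOTIF blocks)."""
    path = Path(path)
    motifs: list[PWMMotif] = []
    background: np.ndarray | None = None
    with open(path) as fh:
        lines = fh.readlines()
    if not any(l.strip().lower().startswith("meme version") for l in lines):
        raise FormatError(f"{path}: missing 'MEME version' line")
    i = 0
    n = len(lines)
    while i < n:
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            i += 1
            tokens: list[str] = []
            while i < n and lines[i].strip() and not lines[i].startswith("MOTIF"):
                tokens.extend(lines[i].split())
                i += 1
            freq = {tokens[j]: float(tokens[j + 1]) for j in range(0, len(tokens), 2)}
            background = np.array([freq.get(b, 0.25) for b in "ACGT"])
            continue
        if line.startswith("MOTIF"):
            parts = line.split()
            if len(parts) < 2:
                raise FormatError(f"{path}: MOTIF line without an identifier")
            motif_id = parts[1]
            alt_name = parts[2] if len(parts) > 2 else ""
            i += 1
            while i < n and "letter-probability matrix" not in lines[i]:
                if lines[i].startswith("MOTIF"):
                    raise FormatError(f"{path}: motif {motif_id} has no letter-probability matrix")
                i += 1
            if i >= n:
                raise FormatError(f"{path}: motif {motif_id} has no letter-probability matrix")
            header = lines[i]
            wm = re.search(r"w\s*=\s*(\d+)", header)
            nm = re.search(r"nsites\s*=\s*(\d+)", header)
            declared_w = int(wm.group(1)) if wm else None
            nsites = int(nm.group(1)) if nm else None
            i += 1
            rows: list[list[float]] = []
            while i < n:
                s = lines[i].strip()
                if not s or s.startswith(("MOTIF", "URL", "Background")):
                    break
                try:
                    vals = [float(x) for x in s.split()]
                except ValueError as exc:
                    raise FormatError(f"{path}: motif {motif_id}: bad matrix row {s!r}") from exc
                if len(vals) != 4:
                    raise FormatError(f"{path}: motif {motif_id}: matrix row with {len(vals)} values")
                rows.append(vals)
                i += 1
            if declared_w is not None and declared_w != len(rows):
                raise FormatError(
                    f"{path}: motif {motif_id}: declared w={declared_w} but {len(rows)} matrix rows"
                )
            if not rows:
                raise FormatError(f"{path}: motif {motif_id}: empty matrix")
            motifs.append(
                PWMMotif(motif_id, np.array(rows), alt_name=alt_name, nsites=nsites,
                         source_background=background)
            )
            continue
        i += 1
    if not motifs:
        raise FormatError(f"{path}: no MOTIF blocks found")
    return motifs


def write_meme_motifs(motifs: Sequence[PWMMotif], path: str | Path,
                      background: Sequence[float] | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        if background is not None:
            b = np.asarray(background, dtype=float)
            fh.write("Background letter frequencies\n")
            fh.write("A %.5f C %.5f G %.5f T %.5f\n\n" % tuple(b))
        for m in motifs:
            name = f"MOTIF {m.motif_id}" + (f" {m.alt_name}" if m.alt_name else "")
            fh.write(name + "\n")
            nsites = m.nsites if m.nsites is not None else 20
            fh.write(f"letter-probability matrix: alength= 4 w= {m.length} nsites= {nsites} E= 0\n")
            for row in m.matrix:
                fh.write(" ".join("%.6f" % v for v in row) + "\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# Sequence extraction
# ---------------------------------------------------------------------------


def extract_peak_sequences(genome: GenomeSequences, peaks: Iterable[Peak],
                           max_n_fraction: float = 0.5) -> dict[str, str]:
    """Extract ``genome[chrom][start:end]`` for each peak.

    Peaks whose sequence is more than ``max_n_fraction`` N are dropped (and
    logged); a peak extending past its chromosome end is an error.
    """
    out: dict[str, str] = {}
    n_dropped = 0
    for p in peaks:
        if p.chrom not in genome:
            raise KeyError(f"peak {p.peak_id}: chromosome {p.chrom!r} not in genome")
        seq = genome[p.chrom]
        if p.end > len(seq):
            raise ValueError(
                f"peak {p.peak_id}: interval [{p.start}, {p.end}) exceeds "
                f"{p.chrom} length {len(seq)}"
            )
        s = seq[p.start : p.end]
        if s.count("N") > max_n_fraction * len(s):
            n_dropped += 1
            continue
        out[p.peak_id] = s
    if n_dropped:
        logger.info("extract_peak_sequences: dropped %d N-heavy peak(s)", n_dropped)
    return out


# ---------------------------------------------------------------------------
# Generic results writer
# ---------------------------------------------------------------------------

FLOAT_FMT = "%.17g"  # round-trips float64 exactly while giving >= 6 sig digits


def _to_records(records) -> tuple[list[dict], list[str]]:
    if isinstance(records, pd.DataFrame):
        return records.to_dict(orient="records"), list(records.columns)
    out = []
    columns: list[str] = []
    for r in records:
        if dataclasses.is_dataclass(r):
            d = dataclasses.asdict(r)
        elif isinstance(r, Mapping):
            d = dict(r)
        else:
            raise TypeError(f"cannot serialize record of type {type(r).__name__}")
        if not columns:
            columns = list(d.keys())
        out.append(d)
    return out, columns


def _render(value) -> str:
    if value is None:
        return "NA"
    if isinstance(value, float):
        return FLOAT_FMT % value
    if isinstance(value, (list, tuple, set, frozenset)):
        return ",".join(str(v) for v in sorted(value) if not isinstance(value, (list, tuple))) \
            if isinstance(value, (set, frozenset)) else ",".join(str(v) for v in value)
    return str(value)


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (set, frozenset)):
        return sorted(o)
    raise TypeError(f"not JSON serializable: {type(o).__name__}")


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration object."""
    payload = json.dumps(obj, sort_keys=True, default=_json_default)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_results(records, path: str | Path, fmt: str = "tsv",
                  metadata: Mapping | None = None) -> None:
    """Write records deterministically as TSV or JSON.

    Column order follows dataclass field order (or DataFrame column order);
    floats are rendered with full precision. JSON output carries a metadata
    block (seed, config hash, version) when provided. Records exposing the
    four per-condition score axes (TF priority records) additionally emit a
    ``radar`` block in JSON, one entry of four axes per motif.
    """
    path = Path(path)
    if fmt not in {"tsv", "json"}:
        raise ValueError(f"unknown format {fmt!r}")
    rows, columns = _to_records(records)
    if fmt == "tsv":
        with open(path, "w") as fh:
            fh.write("\t".join(columns) + "\n")
            for row in rows:
                fh.write("\t".join(_render(row.get(c)) for c in columns) + "\n")
        return
    from cistf import __version__

    doc: dict = {"metadata": dict(metadata or {})}
    doc["metadata"].setdefault("version", __version__)
    doc["records"] = rows
    if rows and {"motif_id", "rep_log2p"} <= set(rows[0].keys()):
        doc["radar"] = {
            row["motif_id"]: {c: max(0.0, row["rep_log2p"][c]) for c in PEAK_CONDITIONS}
            for row in rows
        }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True, default=_json_default)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Differential tables on disk
# ---------------------------------------------------------------------------


def read_diff_table(path: str | Path, contrast: str, kind: str) -> DiffTable:
    df = pd.read_csv(path, sep="\t")
    return DiffTable(df=df, contrast=contrast, kind=kind)


def write_diff_table(table: DiffTable, path: str | Path) -> None:
    table.df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
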