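"""Self-contained synthetic fixture generator with known planted structure.

The generator emulates the statistical shape of a three-condition (fed,
fasted, leptin-treated) gene-expression + chromatin-accessibility study:

* a random genome partitioned into blocks, each owning at most one gene, so
  that designed concordant peak-gene links fall inside the +/-200 kb TSS
  window and everything else falls outside it;
* negative-binomial count matrices (Var = mu + alpha*mu^2) for genes and
  peaks, with sparse planted log2 effects per condition and per-sample
  library-size factors;
* two causal motifs planted at an elevated rate into the concordant peaks of
  their target condition pair (hunger: fasted-opened + leptin-closed;
  satiety: leptin-opened + fasted-closed), plus column-shuffled decoys.

Every artifact is a pure function of the configuration (including its seed);
per-stage RNG substreams keep the stages individually reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from cistf.io_formats import (
    GeneModel,
    GenomeSequences,
    Peak,
    PWMMotif,
    config_hash,
    write_bed,
    write_fasta,
    write_gtf,
    write_meme_motifs,
)

BASES = "ACGT"

#: (fasting effect sign, leptin effect sign) per gene class
GENE_CLASSES = {
    "fast_up": (1, 0),
    "fast_down": (-1, 0),
    "lep_up": (0, 1),
    "lep_down": (0, -1),
    "bidir_hunger": (1, -1),   # fasting-induced, leptin-repressed
    "bidir_satiety": (-1, 1),  # fasting-repressed, leptin-induced
    "neutral": (0, 0),
}

#: condition -> sign pattern selecting the peaks/genes that belong to it
CONDITION_SIGNS = {
    "fasted_opened": ("fast", 1),
    "fasted_closed": ("fast", -1),
    "leptin_opened": ("lep", 1),
    "leptin_closed": ("lep", -1),
}

# Near-consensus causal motifs (AP-1-like and STAT-like consensus cores).
HUNGER_CONSENSUS = "ATGACTCATCCG"
SATIETY_CONSENSUS = "TTCCCGGAAACT"


def consensus_pwm(consensus: str, dominance: float = 0.88) -> np.ndarray:
    rest = (1.0 - dominance) / 3.0
    mat = np.full((len(consensus), 4), rest)
    for i, b in enumerate(consensus):
        mat[i, BASES.index(b)] = dominance
    return mat


@dataclass(frozen=True)
class SimConfig:
    """Study-shaped simulation parameters; defaults are the fixture conditions."""

    seed: int = 0
    n_chroms: int = 2
    block_bp: int = 420_000
    peak_length_bp: tuple[int, int] = (250, 350)
    tss_jitter_bp: int = 10_000
    link_dist_max: int = 150_000
    # gene class sizes
    n_fast_up: int = 18
    n_fast_down: int = 18
    n_lep_up: int = 18
    n_lep_down: int = 18
    n_bidir_hunger: int = 12
    n_bidir_satiety: int = 12
    n_neutral: int = 40
    peaks_per_gene: int = 2
    n_nonconcordant_per_condition: int = 25
    n_neutral_per_gene_block: int = 2
    n_far_neutral: int = 30
    # unplaced neutral features: dilute library-composition bias in CPM like
    # the bulk of a real transcriptome/cistrome that does not change
    n_filler_genes: int = 600
    n_filler_peaks: int = 1200
    # counts model
    n_replicates: int = 4
    effect_size: float = 2.0
    effect_magnitudes: tuple[float, ...] = ()  # per-gene |log2FC| choices; empty = fixed
    scale_peaks_with_effect: bool = False
    dispersion: float = 0.05
    gene_mean_log: tuple[float, float] = (4.6, 0.6)
    peak_mean_log: tuple[float, float] = (4.4, 0.5)
    library_size_sigma: float = 0.1
    # genome & motifs
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    p_fg: float = 0.8
    p_bg: float = 0.05
    n_decoys: int = 6
    motif_dominance: float = 0.95

    def __post_init__(self) -> None:
        if not (0 <= self.p_bg <= 1 and 0 <= self.p_fg <= 1):
            raise ValueError("plant probabilities must lie in [0, 1]")
        if self.n_replicates < 2:
            raise ValueError("need >= 2 replicates per condition")
        if abs(sum(self.base_composition) - 1.0) > 1e-6:
            raise ValueError("base composition must sum to 1")

    @property
    def gene_class_counts(self) -> dict[str, int]:
        return {
            "fast_up": self.n_fast_up,
            "fast_down": self.n_fast_down,
            "lep_up": self.n_lep_up,
            "lep_down": self.n_lep_down,
            "bidir_hunger": self.n_bidir_hunger,
            "bidir_satiety": self.n_bidir_satiety,
            "neutral": self.n_neutral,
        }

    @property
    def n_genes(self) -> int:
        return sum(self.gene_class_counts.values())

    @property
    def n_blocks(self) -> int:
        nonconc_blocks = math.ceil(4 * self.n_nonconcordant_per_condition / 8)
        far_blocks = math.ceil(self.n_far_neutral / 5) if self.n_far_neutral else 0
        return self.n_genes + nonconc_blocks + far_blocks

    @property
    def chrom_lengths(self) -> dict[str, int]:
        per_chrom = math.ceil(self.n_blocks / self.n_chroms)
        return {f"chr{i + 1}": per_chrom * self.block_bp for i in range(self.n_chroms)}

    def _rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stage])


@dataclass
class GroundTruth:
    """Planted structure of a simulated fixture."""

    gene_class: dict[str, str] = field(default_factory=dict)
    gene_effects: dict[str, tuple[float, float]] = field(default_factory=dict)
    peak_effects: dict[str, tuple[float, float]] = field(default_factory=dict)
    designed_links: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    designed_concordant: dict[str, list[str]] = field(default_factory=dict)
    planted: dict[str, list[tuple[str, int, str]]] = field(default_factory=dict)
    causal_motifs: dict[str, str] = field(default_factory=dict)

    def bidirectional_genes(self, direction: str) -> set[str]:
        cls = "bidir_hunger" if direction == "fast_up_leptin_down" else "bidir_satiety"
        return {g for g, c in self.gene_class.items() if c == cls}

    def to_json(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_json(cls, doc: dict) -> "GroundTruth":
        gt = cls()
        gt.gene_class = dict(doc["gene_class"])
        gt.gene_effects = {k: tuple(v) for k, v in doc["gene_effects"].items()}
        gt.peak_effects = {k: tuple(v) for k, v in doc["peak_effects"].items()}
        gt.designed_links = {k: [tuple(x) for x in v] for k, v in doc["designed_links"].items()}
        gt.designed_concordant = {k: list(v) for k, v in doc["designed_concordant"].items()}
        gt.planted = {k: [(p, int(i), s) for p, i, s in v] for k, v in doc["planted"].items()}
        gt.causal_motifs = dict(doc["causal_motifs"])
        return gt


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------


def generate_genome(cfg: SimConfig) -> tuple[GenomeSequences, GroundTruth]:
    """I.i.d. random genome at the configured base composition (stage-seeded)."""
    rng = cfg._rng(0)
    sequences = {}
    base_bytes = np.frombuffer("ACGT".encode(), dtype=np.uint8)
    comp = np.asarray(cfg.base_composition)
    uniform = np.allclose(comp, 0.25)
    cum = np.cumsum(comp)
    for chrom, length in cfg.chrom_lengths.items():
        if uniform:
            idx = rng.integers(0, 4, size=length)
        else:
            # inverse-CDF sampling: much faster than rng.choice for long genomes
            idx = np.searchsorted(cum, rng.random(length), side="right")
        sequences[chrom] = base_bytes[idx].tobytes().decode("ascii")
    return GenomeSequences(sequences), GroundTruth()


# ---------------------------------------------------------------------------
# Annotation: genes, peaks, designed links
# ---------------------------------------------------------------------------


def _blocks(cfg: SimConfig) -> list[tuple[str, int]]:
    """(chrom, center) of every block, row-major across chromosomes."""
    out = []
    per_chrom = math.ceil(cfg.n_blocks / cfg.n_chroms)
    for chrom in cfg.chrom_lengths:
        for i in range(per_chrom):
            out.append((chrom, i * cfg.block_bp + cfg.block_bp // 2))
    return out


def generate_annotation(cfg: SimConfig, genome: GenomeSequences,
                        truth: GroundTruth | None = None
                        ) -> tuple[list[GeneModel], list[Peak], GroundTruth]:
    """Place genes and peaks block-wise and record the designed structure.

    Each gene owns one block; its designed concordant peaks lie within
    ``link_dist_max`` (< window) of its TSS, while every peak of any other
    block lies beyond the window of that gene by construction.
    """
    truth = truth or GroundTruth()
    rng = cfg._rng(1)
    if cfg.block_bp < 2 * (cfg.link_dist_max + cfg.tss_jitter_bp + max(cfg.peak_length_bp)):
        raise ValueError("block_bp too small for the configured link distances")

    gene_specs: list[str] = []
    for cls, n in cfg.gene_class_counts.items():
        gene_specs.extend([cls] * n)
    order = rng.permutation(len(gene_specs))
    gene_specs = [gene_specs[i] for i in order]

    blocks = _blocks(cfg)
    genes: list[GeneModel] = []
    peaks: list[Peak] = []
    truth.designed_links = {c: [] for c in CONDITION_SIGNS}
    truth.designed_concordant = {c: [] for c in CONDITION_SIGNS}

    def place_peak(chrom: str, center: int, offset: int, peak_id: str,
                   effects: tuple[float, float]) -> Peak:
        length = int(rng.integers(cfg.peak_length_bp[0], cfg.peak_length_bp[1] + 1))
        start = max(0, center + offset - length // 2)
        end = min(len(genome[chrom]), start + length)
        p = Peak(chrom, start, end, peak_id)
        peaks.append(p)
        truth.peak_effects[peak_id] = effects
        return p

    def conditions_of(effects: tuple[float, float]) -> list[str]:
        out = []
        for cond, (axis, sign) in CONDITION_SIGNS.items():
            eff = effects[0] if axis == "fast" else effects[1]
            if np.sign(eff) == sign:
                out.append(cond)
        return out

    # gene blocks
    for gi, cls in enumerate(gene_specs):
        chrom, center = blocks[gi]
        gene_id = f"gene{gi:04d}"
        tss = center + int(rng.integers(-cfg.tss_jitter_bp, cfg.tss_jitter_bp + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            start, end = tss, tss + 5000
        else:
            start, end = tss - 4999, tss + 1
        exons = [(start, start + 500), (end - 500, end)]
        g = GeneModel(gene_id, chrom, strand, tss, start=start, end=end, exons=exons)
        genes.append(g)

        fsign, lsign = GENE_CLASSES[cls]
        if cfg.effect_magnitudes:
            mag = float(rng.choice(np.asarray(cfg.effect_magnitudes)))
        else:
            mag = cfg.effect_size
        effects = (fsign * mag, lsign * mag)
        truth.gene_class[gene_id] = cls
        truth.gene_effects[gene_id] = effects

        if cls != "neutral":
            n_pk = cfg.peaks_per_gene
            if cfg.scale_peaks_with_effect:
                n_pk = int(np.clip(round(mag), 1, 4))
            for k in range(n_pk):
                offset = int(rng.integers(-cfg.link_dist_max, cfg.link_dist_max + 1))
                pid = f"peak_{gene_id}_{k}"
                place_peak(chrom, tss, offset, pid, effects)
                for cond in conditions_of(effects):
                    truth.designed_links[cond].append((pid, gene_id))
                    truth.designed_concordant[cond].append(pid)
        # neutral flanking peaks in every gene block
        for k in range(cfg.n_neutral_per_gene_block):
            offset = int(rng.integers(-cfg.link_dist_max, cfg.link_dist_max + 1))
            place_peak(chrom, tss, offset, f"peak_neutral_{gene_id}_{k}", (0.0, 0.0))

    # non-concordant differential peaks in geneless blocks
    free = blocks[len(gene_specs):]
    cond_effects = {
        "fasted_opened": (cfg.effect_size, 0.0),
        "fasted_closed": (-cfg.effect_size, 0.0),
        "leptin_opened": (0.0, cfg.effect_size),
        "leptin_closed": (0.0, -cfg.effect_size),
    }
    n_nonconc_blocks = math.ceil(4 * cfg.n_nonconcordant_per_condition / 8)
    nonconc_blocks = free[:n_nonconc_blocks]
    bi = 0
    for cond, eff in cond_effects.items():
        for k in range(cfg.n_nonconcordant_per_condition):
            chrom, center = nonconc_blocks[bi % len(nonconc_blocks)]
            bi += 1
            offset = int(rng.integers(-cfg.link_dist_max, cfg.link_dist_max + 1))
            place_peak(chrom, center, offset, f"peak_nonconc_{cond}_{k}", eff)

    # far neutral peaks (not near any TSS)
    far_blocks = free[n_nonconc_blocks:]
    for k in range(cfg.n_far_neutral):
        chrom, center = far_blocks[k % len(far_blocks)]
        offset = int(rng.integers(-cfg.link_dist_max, cfg.link_dist_max + 1))
        place_peak(chrom, center, offset, f"peak_far_{k}", (0.0, 0.0))

    # unplaced neutral filler features (count matrices only, no coordinates)
    for k in range(cfg.n_filler_genes):
        gid = f"filler_gene_{k:04d}"
        truth.gene_class[gid] = "filler"
        truth.gene_effects[gid] = (0.0, 0.0)
    for k in range(cfg.n_filler_peaks):
        truth.peak_effects[f"filler_peak_{k:04d}"] = (0.0, 0.0)

    return genes, peaks, truth


# ---------------------------------------------------------------------------
# Motifs and planting
# ---------------------------------------------------------------------------


def make_motif_library(cfg: SimConfig) -> tuple[list[PWMMotif], GroundTruth]:
    """Two causal motifs plus column-shuffled decoys (stage-seeded)."""
    rng = cfg._rng(2)
    hunger = PWMMotif("HUNGER_TF", consensus_pwm(HUNGER_CONSENSUS, cfg.motif_dominance),
                      alt_name="ap1_like")
    satiety = PWMMotif("SATIETY_TF", consensus_pwm(SATIETY_CONSENSUS, cfg.motif_dominance),
                       alt_name="stat_like")
    motifs = [hunger, satiety]
    sources = [hunger, satiety]
    for d in range(cfg.n_decoys):
        src = sources[d % 2]
        perm = rng.permutation(src.length)
        # shuffle positions so information content matches but sequence does not
        mat = src.matrix[perm]
        motifs.append(PWMMotif(f"DECOY_{d:02d}", mat, alt_name=f"shuffled_{src.motif_id}"))
    truth = GroundTruth()
    truth.causal_motifs = {"hunger": "HUNGER_TF", "satiety": "SATIETY_TF"}
    return motifs, truth


def sample_motif_instance(motif: PWMMotif, rng: np.random.Generator) -> str:
    rows = [BASES[int(rng.choice(4, p=row))] for row in motif.matrix]
    return "".join(rows)


_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def plant_motif_instances(cfg: SimConfig, genome: GenomeSequences, peaks: list[Peak],
                          truth: GroundTruth, motifs: list[PWMMotif]
                          ) -> tuple[GenomeSequences, GroundTruth]:
    """Overwrite genome bases with sampled motif instances (coordinates stay fixed).

    Each causal motif lands in each concordant-designated peak of its target
    condition pair with probability p_fg, and in every other peak with
    probability p_bg, at a uniform position and strand.
    """
    rng = cfg._rng(3)
    by_id = {m.motif_id: m for m in motifs}
    targets = {
        truth.causal_motifs["hunger"]: set(truth.designed_concordant["fasted_opened"])
        | set(truth.designed_concordant["leptin_closed"]),
        truth.causal_motifs["satiety"]: set(truth.designed_concordant["leptin_opened"])
        | set(truth.designed_concordant["fasted_closed"]),
    }
    buffers = {c: bytearray(s.encode("ascii")) for c, s in genome.sequences.items()}
    truth.planted = {m: [] for m in targets}
    for motif_id, target_ids in targets.items():
        motif = by_id[motif_id]
        for p in peaks:
            prob = cfg.p_fg if p.peak_id in target_ids else cfg.p_bg
            if rng.random() >= prob:
                continue
            inst = sample_motif_instance(motif, rng)
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                inst = revcomp(inst)
            width = p.end - p.start
            if width <= len(inst):
                continue
            off = int(rng.integers(0, width - len(inst) + 1))
            pos = p.start + off
            buffers[p.chrom][pos : pos + len(inst)] = inst.encode("ascii")
            truth.planted[motif_id].append((p.peak_id, off, strand))
    mutated = GenomeSequences({c: b.decode("ascii") for c, b in buffers.items()})
    return mutated, truth


# ---------------------------------------------------------------------------
# Counts
# ---------------------------------------------------------------------------


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion <= 0:
        return rng.poisson(mu)
    r = 1.0 / dispersion
    p = r / (r + mu)
    return rng.negative_binomial(r, p)


def simulate_counts(cfg: SimConfig, truth: GroundTruth
                    ) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, str]]:
    """NB count matrices for genes and peaks across fed/fasted/leptin samples.

    Per-condition means are the base mean times 2^(planted log2 effect); the
    leptin effect applies on top of the fasted state (the leptin contrast is
    leptin vs fasted). Returns (gene_counts, peak_counts, sample->condition).
    """
    rng = cfg._rng(4)
    conditions = ["fed", "fasted", "leptin"]
    samples = [f"{c}_{i + 1}" for c in conditions for i in range(cfg.n_replicates)]
    groups = {s: s.rsplit("_", 1)[0] for s in samples}
    lib_factors = np.exp(rng.normal(0.0, cfg.library_size_sigma, size=len(samples)))

    def matrix(ids: list[str], effects: dict[str, tuple[float, float]],
               mean_log: tuple[float, float]) -> pd.DataFrame:
        base = np.exp(rng.normal(mean_log[0], mean_log[1], size=len(ids)))
        fast = np.array([effects[i][0] for i in ids])
        lep = np.array([effects[i][1] for i in ids])
        mult = np.stack(
            [np.ones(len(ids)), 2.0 ** fast, 2.0 ** (fast + lep)], axis=1
        )  # fed, fasted, leptin
        data = np.empty((len(ids), len(samples)), dtype=np.int64)
        for j, s in enumerate(samples):
            ci = conditions.index(groups[s])
            mu = base * mult[:, ci] * lib_factors[j]
            data[:, j] = _nb_draw(rng, mu, cfg.dispersion)
        return pd.DataFrame(data, index=pd.Index(ids, name="id"), columns=samples)

    gene_ids = sorted(truth.gene_effects)
    peak_ids = sorted(truth.peak_effects)
    gene_counts = matrix(gene_ids, truth.gene_effects, cfg.gene_mean_log)
    peak_counts = matrix(peak_ids, truth.peak_effects, cfg.peak_mean_log)
    return gene_counts, peak_counts, groups


# ---------------------------------------------------------------------------
# Bundles
# ---------------------------------------------------------------------------


@dataclass
class SimBundle:
    """In-memory fixture: everything the pipeline consumes plus the truth."""

    cfg: SimConfig
    genome: GenomeSequences
    genes: list[GeneModel]
    peaks: list[Peak]
    motifs: list[PWMMotif]
    gene_counts: pd.DataFrame
    peak_counts: pd.DataFrame
    groups: dict[str, str]
    truth: GroundTruth


def simulate_bundle(cfg: SimConfig) -> SimBundle:
    """Run all generator stages and return the in-memory fixture."""
    genome, truth = generate_genome(cfg)
    genes, peaks, truth = generate_annotation(cfg, genome, truth)
    motifs, motif_truth = make_motif_library(cfg)
    truth.causal_motifs = motif_truth.causal_motifs
    genome, truth = plant_motif_instances(cfg, genome, peaks, truth, motifs)
    gene_counts, peak_counts, groups = simulate_counts(cfg, truth)
    return SimBundle(cfg, genome, genes, peaks, motifs, gene_counts, peak_counts, groups, truth)


def generate_fixture_bundle(cfg: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Write the complete fixture (FASTA, GTF, BED, counts, motifs, truth, manifest)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = simulate_bundle(cfg)
    paths = {
        "genome": outdir / "genome.fa",
        "genes": outdir / "genes.gtf",
        "peaks": outdir / "peaks.bed",
        "counts_genes": outdir / "counts_genes.tsv",
        "counts_peaks": outdir / "counts_peaks.tsv",
        "motifs": outdir / "motifs.meme",
        "truth": outdir / "truth.json",
        "manifest": outdir / "manifest.json",
    }
    write_fasta(bundle.genome, paths["genome"])
    write_gtf(bundle.genes, paths["genes"])
    write_bed(bundle.peaks, paths["peaks"])
    bundle.gene_counts.to_csv(paths["counts_genes"], sep="\t")
    bundle.peak_counts.to_csv(paths["counts_peaks"], sep="\t")
    write_meme_motifs(bundle.motifs, paths["motifs"],
                      background=np.asarray(cfg.base_composition))
    with open(paths["truth"], "w") as fh:
        json.dump(bundle.truth.to_json(), fh, indent=1, sort_keys=True)
        fh.write("\n")
    cfg_doc = dataclasses.asdict(cfg)
    manifest = {"seed": cfg.seed, "config": cfg_doc, "config_hash": config_hash(cfg_doc)}
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths


def load_truth(path: str | Path) -> GroundTruth:
    with open(path) as fh:
        return GroundTruth.from_json(json.load(fh))
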