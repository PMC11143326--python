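"""Optimal-threshold Fisher motif enrichment of peak sets against six backgrounds.

Each motif is turned into a log2-odds scanner; every sequence gets one score
(by default the maximum log-odds over all positions on both strands). For a
foreground/background pair the enrichment p-value is the minimum, over all
observed foreground score thresholds, of the one-tailed hypergeometric upper
tail of the resulting 2x2 hit table, Bonferroni-corrected first for the
number of thresholds tried and then for the motif library size.

All p-values are carried as natural logarithms end to end, so enrichment as
extreme as p ~ 1e-5000 stays finite and -log2(p) is always computable; no
imputation or clamping is needed on the default path (an e^-300 clamp is
available behind a flag for parity with workflows that need one).

The six background sets are: (1) neutral peaks genome-wide; (2) neutral peaks
near neutral genes; (3) neutral peaks near significant genes; (4) neutral
peaks near any TSS; (5) non-concordant differential peaks of the condition;
(6) dinucleotide-preserving shuffles of the foreground sequences.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import gammaln, logsumexp

from cistf.concordance import ConcordantPeakSet, _tss_index, _windowed_gene_hits
from cistf.io_formats import GeneModel, GenomeSequences, PWMMotif, Peak, extract_peak_sequences

logger = logging.getLogger(__name__)

BACKGROUND_LABELS = (
    "neutral_all",
    "neutral_near_neutral_genes",
    "neutral_near_significant_genes",
    "neutral_near_tss",
    "non_concordant",
    "shuffled_foreground",
)

_BASE_INDEX = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _BASE_INDEX[ord(_b)] = _i
    _BASE_INDEX[ord(_b.lower())] = _i

LOG_CLAMP = -300.0  # optional parity clamp: ln-space floor at e^-300... see pvalue_floor


# ---------------------------------------------------------------------------
# Log-odds scanning
# ---------------------------------------------------------------------------


@dataclass
class LogOddsMatrix:
    """Position-specific log2-odds scores derived from a PWM."""

    motif_id: str
    matrix: np.ndarray  # (L, 4) log2-odds
    background: np.ndarray  # (4,)
    pseudocount: float

    @property
    def length(self) -> int:
        return self.matrix.shape[0]


@dataclass
class SequenceScore:
    peak_id: str
    score: float
    position: int | None
    strand: str | None


def pwm_to_log_odds(motif: PWMMotif, background: Sequence[float] | None = None,
                    pseudocount: float = 0.01) -> LogOddsMatrix:
    """Smooth the PWM and take log2 odds against the background.

    Smoothing is p' = (p + c) / (1 + 4c) with pseudocount c (equivalently
    p·(1−4ε′)+ε′ with ε′ = c/(1+4c)), which keeps rows normalized and leaves
    uniform rows at log-odds zero under a uniform background.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    bg = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
    if bg.shape != (4,) or np.any(bg <= 0):
        raise ValueError("background must be 4 strictly positive probabilities")
    if abs(bg.sum() - 1.0) > 1e-6:
        raise ValueError("background probabilities must sum to 1")
    smoothed = (motif.matrix + pseudocount) / (1.0 + 4.0 * pseudocount)
    return LogOddsMatrix(
        motif_id=motif.motif_id,
        matrix=np.log2(smoothed / bg[None, :]),
        background=bg,
        pseudocount=pseudocount,
    )


def _revcomp_matrix(matrix: np.ndarray) -> np.ndarray:
    # reverse positions and swap A<->T, C<->G
    return matrix[::-1, ::-1]


def _padded(matrix: np.ndarray) -> np.ndarray:
    # column 4 = NaN sentinel for N; windows containing N score NaN
    pad = np.full((matrix.shape[0], 1), np.nan)
    return np.hstack([matrix, pad])


def _strand_window_scores(idx: np.ndarray, lom: LogOddsMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-window log2-odds on (forward, reverse-complement) strands; NaN where a window has N."""
    L = lom.length
    windows = sliding_window_view(idx, L)
    fwd_m = _padded(lom.matrix)
    rev_m = _padded(_revcomp_matrix(lom.matrix))
    pos = np.arange(L)
    fwd = fwd_m[pos[None, :], windows].sum(axis=1)
    rev = rev_m[pos[None, :], windows].sum(axis=1)
    return fwd, rev


def encode_sequence(seq: str) -> np.ndarray:
    return _BASE_INDEX[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)].astype(np.intp)


def score_sequence(seq: str, lom: LogOddsMatrix, scoring: str = "max",
                   peak_id: str = "") -> SequenceScore:
    """Score one sequence: max (or log2 average) odds over both strands.

    Windows containing N are skipped; a sequence with no valid window scores
    -inf and is excluded from enrichment by the callers.
    """
    if not seq:
        raise ValueError("empty sequence")
    if len(seq) < lom.length:
        return SequenceScore(peak_id, float("-inf"), None, None)
    fwd, rev = _strand_window_scores(encode_sequence(seq), lom)
    both = np.concatenate([fwd, rev])
    valid = ~np.isnan(both)
    if not valid.any():
        return SequenceScore(peak_id, float("-inf"), None, None)
    if scoring == "max":
        best = int(np.nanargmax(both))
        n = len(fwd)
        strand = "+" if best < n else "-"
        return SequenceScore(peak_id, float(both[best]), best % n, strand)
    if scoring == "avg":
        vals = both[valid]
        # log2 of the mean odds, computed stably in log space
        score = float(logsumexp(vals * math.log(2.0)) / math.log(2.0) - math.log2(vals.size))
        return SequenceScore(peak_id, score, None, None)
    raise ValueError(f"unknown scoring mode {scoring!r}")


def score_sequences(seqs: Mapping[str, str], lom: LogOddsMatrix,
                    scoring: str = "max") -> dict[str, float]:
    """Score a whole sequence set; returns peak_id -> score."""
    return {sid: score_sequence(s, lom, scoring=scoring, peak_id=sid).score
            for sid, s in seqs.items()}


# ---------------------------------------------------------------------------
# Fisher upper tail in log space
# ---------------------------------------------------------------------------


def _log_comb(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def log_fisher_upper_tail(fg_hits: int, fg_total: int, bg_hits: int, bg_total: int) -> float:
    """Natural log of P(X >= fg_hits) for the hypergeometric 2x2 upper tail.

    Computed by log-space summation over the tail terms, so values down to
    p ~ 1e-5000 and far beyond remain finite and accurate to ~1e-14 relative.
    """
    for name, v in (("fg_hits", fg_hits), ("fg_total", fg_total),
                    ("bg_hits", bg_hits), ("bg_total", bg_total)):
        if v < 0 or v != int(v):
            raise ValueError(f"{name} must be a nonnegative integer, got {v}")
    if fg_hits > fg_total or bg_hits > bg_total:
        raise ValueError("hits cannot exceed totals")
    N = fg_total + bg_total
    K = fg_hits + bg_hits
    n = fg_total
    if fg_hits == 0:
        return 0.0
    i = np.arange(max(fg_hits, n - (N - K)), min(n, K) + 1)
    if i.size == 0:
        return 0.0
    log_terms = _log_comb(K, i) + _log_comb(N - K, n - i) - _log_comb(N, n)
    return float(min(0.0, logsumexp(log_terms)))


def fisher_upper_tail(fg_hits: int, fg_total: int, bg_hits: int, bg_total: int) -> float:
    """One-tailed Fisher (hypergeometric upper-tail) p-value for a 2x2 table."""
    return math.exp(log_fisher_upper_tail(fg_hits, fg_total, bg_hits, bg_total))


# ---------------------------------------------------------------------------
# Optimal-threshold enrichment
# ---------------------------------------------------------------------------


@dataclass
class OptimalEnrichment:
    threshold_star: float
    log_p_raw: float
    log_p_adj_thresholds: float
    n_thresholds: int
    fg_hits: int
    fg_total: int
    bg_hits: int
    bg_total: int

    @property
    def p_raw(self) -> float:
        return math.exp(self.log_p_raw)

    @property
    def p_adj_thresholds(self) -> float:
        return math.exp(self.log_p_adj_thresholds)


def ame_optimal_enrichment(fg_scores, bg_scores) -> OptimalEnrichment:
    """Minimum Fisher upper-tail p over all observed foreground score thresholds.

    A hit at threshold t is score >= t. Candidate thresholds are the distinct
    finite foreground scores; restricting to them loses nothing for the
    upper-tail statistic (raising t between foreground values only sheds
    background hits). The threshold-level Bonferroni factor is the number of
    candidates tried. Ties in p resolve to the smallest threshold.
    """
    fg = np.asarray(fg_scores, dtype=float)
    bg = np.asarray(bg_scores, dtype=float)
    fg = fg[np.isfinite(fg)]
    bg = bg[np.isfinite(bg)]
    if fg.size == 0 or bg.size == 0:
        raise ValueError("need at least one finite foreground and background score")
    fg_sorted = np.sort(fg)
    bg_sorted = np.sort(bg)
    thresholds = np.unique(fg_sorted)
    best_log_p = np.inf
    best = None
    for t in thresholds:
        k = fg.size - int(np.searchsorted(fg_sorted, t, side="left"))
        b = bg.size - int(np.searchsorted(bg_sorted, t, side="left"))
        log_p = log_fisher_upper_tail(k, fg.size, b, bg.size)
        if log_p < best_log_p - 1e-12:
            best_log_p = log_p
            best = (float(t), k, b)
    threshold_star, fg_hits, bg_hits = best
    n_thr = int(thresholds.size)
    return OptimalEnrichment(
        threshold_star=threshold_star,
        log_p_raw=best_log_p,
        log_p_adj_thresholds=min(0.0, best_log_p + math.log(n_thr)),
        n_thresholds=n_thr,
        fg_hits=fg_hits,
        fg_total=int(fg.size),
        bg_hits=bg_hits,
        bg_total=int(bg.size),
    )


# ---------------------------------------------------------------------------
# Dinucleotide-preserving shuffle
# ---------------------------------------------------------------------------


def dinuc_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Altschul-Erickson dinucleotide-preserving shuffle.

    The output has exactly the same dinucleotide count multiset as the input
    and the same first and last residue; it is a uniform-ish random Eulerian
    path through the dinucleotide multigraph.
    """
    if len(seq) < 2:
        return seq
    chars = list(seq)
    edges: dict[str, list[str]] = {}
    for a, b in zip(chars, chars[1:]):
        edges.setdefault(a, []).append(b)
    last = chars[-1]

    # pick random "last exit" edges whose graph is a tree into the terminal vertex
    while True:
        last_edge = {
            v: lst[int(rng.integers(len(lst)))] for v, lst in edges.items() if v != last
        }
        ok = True
        for v in last_edge:
            seen = set()
            u = v
            while u != last:
                if u in seen or (u not in last_edge):
                    ok = False
                    break
                seen.add(u)
                u = last_edge[u]
            if not ok:
                break
        if ok:
            break

    new_edges: dict[str, list[str]] = {}
    for v, lst in edges.items():
        rest = lst.copy()
        if v != last:
            rest.remove(last_edge[v])
        order = rng.permutation(len(rest))
        rest = [rest[i] for i in order]
        if v != last:
            rest.append(last_edge[v])
        new_edges[v] = rest

    out = [chars[0]]
    ptr = {v: 0 for v in new_edges}
    u = chars[0]
    for _ in range(len(chars) - 1):
        nxt = new_edges[u][ptr[u]]
        ptr[u] += 1
        out.append(nxt)
        u = nxt
    return "".join(out)


# ---------------------------------------------------------------------------
# Background suite
# ---------------------------------------------------------------------------


@dataclass
class BackgroundSuite:
    """The six labeled background sequence sets for one condition."""

    condition: str
    sets: dict[str, dict[str, str]]
    seed: int | None = None
    peak_ids: dict[str, list[str]] | None = None


def genome_base_frequencies(genome: GenomeSequences) -> np.ndarray:
    """Genome-wide mononucleotide frequencies over A,C,G,T (N excluded)."""
    counts = np.zeros(4)
    for seq in genome.sequences.values():
        idx = encode_sequence(seq)
        counts += np.bincount(idx[idx < 4], minlength=4)
    total = counts.sum()
    if total == 0:
        return np.full(4, 0.25)
    return counts / total


def build_background_suite(condition: str, concordant: ConcordantPeakSet,
                           peaks: Sequence[Peak], reg, genes: Sequence[GeneModel],
                           genome: GenomeSequences, window_bp: int = 200_000,
                           rng_seed: int = 0,
                           chrom_allowlist: set[str] | None = None) -> BackgroundSuite:
    """Build the six background sequence sets for one condition.

    Neutral peaks/genes are those significant in neither direction of the
    condition's contrast. Sets 2-4 use the same +/-window as the concordance
    step; set 5 is the condition's differential peaks that were not
    concordant; set 6 is a seeded dinucleotide shuffle of the foreground.
    """
    contrast_fasted = condition.startswith("fasted")
    if contrast_fasted:
        sig_peaks = reg.fasted_opened | reg.fasted_closed
        sig_genes = reg.fasting_induced | reg.fasting_repressed
    else:
        sig_peaks = reg.leptin_opened | reg.leptin_closed
        sig_genes = reg.leptin_induced | reg.leptin_repressed

    def allowed(p: Peak) -> bool:
        return chrom_allowlist is None or p.chrom in chrom_allowlist

    neutral_peaks = [p for p in peaks if p.peak_id not in sig_peaks and allowed(p)]
    gene_by_id = {g.gene_id: g for g in genes}
    neutral_genes = [g for g in genes if g.gene_id not in sig_genes]
    significant_genes = [gene_by_id[g] for g in sig_genes if g in gene_by_id]

    def near(peak_list: list[Peak], gene_list: list[GeneModel]) -> list[Peak]:
        index = _tss_index(gene_list)
        out = []
        for p in peak_list:
            if p.chrom in index:
                tss_arr, id_arr = index[p.chrom]
                if _windowed_gene_hits(p, tss_arr, id_arr, window_bp).size:
                    out.append(p)
        return out

    cond_ids = reg.peak_set(condition)
    fg_ids = set(concordant.peak_ids)
    non_concordant = [p for p in peaks if p.peak_id in cond_ids - fg_ids and allowed(p)]

    peak_sets: dict[str, list[Peak]] = {
        "neutral_all": neutral_peaks,
        "neutral_near_neutral_genes": near(neutral_peaks, neutral_genes),
        "neutral_near_significant_genes": near(neutral_peaks, significant_genes),
        "neutral_near_tss": near(neutral_peaks, list(genes)),
        "non_concordant": non_concordant,
    }
    sets: dict[str, dict[str, str]] = {}
    ids: dict[str, list[str]] = {}
    for label, plist in peak_sets.items():
        if not plist:
            raise ValueError(f"background set {label!r} is empty for condition {condition}")
        sets[label] = extract_peak_sequences(genome, plist)
        ids[label] = [p.peak_id for p in plist]

    fg_peaks = [p for p in peaks if p.peak_id in fg_ids]
    fg_seqs = extract_peak_sequences(genome, fg_peaks)
    if not fg_seqs:
        raise ValueError(f"foreground for condition {condition} is empty")
    rng = np.random.default_rng(rng_seed)
    sets["shuffled_foreground"] = {
        f"{sid}_shuf": dinuc_shuffle(s, rng) for sid, s in sorted(fg_seqs.items())
    }
    ids["shuffled_foreground"] = list(sets["shuffled_foreground"].keys())
    return BackgroundSuite(condition=condition, sets=sets, seed=rng_seed, peak_ids=ids)


# ---------------------------------------------------------------------------
# Enrichment suite
# ---------------------------------------------------------------------------


@dataclass
class EnrichmentResult:
    motif_id: str
    foreground: str
    background_label: str
    threshold_star: float
    log_p_raw: float
    log_p_adj: float  # Bonferroni over thresholds and motifs, natural log
    fg_hits: int
    fg_total: int
    bg_hits: int
    bg_total: int
    n_thresholds: int

    @property
    def p_raw(self) -> float:
        return math.exp(self.log_p_raw)

    @property
    def p_adj(self) -> float:
        return math.exp(self.log_p_adj)


def pvalue_floor(log_p: float, clamp: bool = False) -> float:
    """Optional parity clamp at e^-300 for workflows that cannot keep log-space p."""
    return max(log_p, LOG_CLAMP) if clamp else log_p


def run_enrichment_suite(fg_seqs: Mapping[str, str], suite: BackgroundSuite,
                         motifs: Sequence[PWMMotif],
                         background: Sequence[float] | None = None,
                         pseudocount: float = 0.01, scoring: str = "max",
                         foreground_label: str | None = None,
                         ) -> dict[str, dict[str, EnrichmentResult]]:
    """Optimal-threshold enrichment of every motif against all six backgrounds.

    The final adjusted p is Bonferroni-corrected twice: by the number of
    candidate thresholds (inside the optimal-threshold scan) and by the motif
    library size.
    """
    if not motifs:
        raise ValueError("need at least one motif")
    n_motifs = len(motifs)
    label = foreground_label or suite.condition
    results: dict[str, dict[str, EnrichmentResult]] = {}
    for motif in motifs:
        lom = pwm_to_log_odds(motif, background=background, pseudocount=pseudocount)
        fg_scores = score_sequences(fg_seqs, lom, scoring=scoring)
        # backgrounds 1-4 overlap heavily; score each unique sequence id once
        cache: dict[str, float] = {}

        def cached_scores(seqs: Mapping[str, str]) -> list[float]:
            out = []
            for sid, s in seqs.items():
                if sid not in cache:
                    cache[sid] = score_sequence(s, lom, scoring=scoring, peak_id=sid).score
                out.append(cache[sid])
            return out

        per_bg: dict[str, EnrichmentResult] = {}
        for bg_label, bg_seqs in suite.sets.items():
            bg_scores = cached_scores(bg_seqs)
            opt = ame_optimal_enrichment(list(fg_scores.values()), bg_scores)
            log_p_adj = min(0.0, opt.log_p_adj_thresholds + math.log(n_motifs))
            per_bg[bg_label] = EnrichmentResult(
                motif_id=motif.motif_id,
                foreground=label,
                background_label=bg_label,
                threshold_star=opt.threshold_star,
                log_p_raw=opt.log_p_raw,
                log_p_adj=log_p_adj,
                fg_hits=opt.fg_hits,
                fg_total=opt.fg_total,
                bg_hits=opt.bg_hits,
                bg_total=opt.bg_total,
                n_thresholds=opt.n_thresholds,
            )
        results[motif.motif_id] = per_bg
    return results
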