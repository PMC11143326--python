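"""Consensus calling, exclusivity classification and ranking of TF motifs.

A motif is "enriched" in a peak set when its adjusted enrichment p-value
clears alpha against at least 5 of the 6 background sets. Its representative
p is the most significant of the significant p-values when enriched, and the
most significant of the non-significant ones otherwise. Motifs are then
classified by which of the four concordant sets they are enriched in:
candidate hunger-promoting TFs are enriched in fasted-opened and leptin-closed
but neither of the other two (or in fasted-opened alone); candidate
hunger-suppressing TFs mirror this on the leptin-opened / fasted-closed side.
Pair-exclusive motifs rank by the sum of their two representative -log2(p)
scores; single-exclusive motifs by their single score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from cistf.io_formats import PEAK_CONDITIONS
from cistf.motif_enrichment import BACKGROUND_LABELS, EnrichmentResult

LN2 = math.log(2.0)

CATEGORIES = (
    "hunger_pair_exclusive",
    "hunger_single_exclusive",
    "satiety_pair_exclusive",
    "satiety_single_exclusive",
    "mixed",
    "none",
)

HUNGER_PAIR = ("fasted_opened", "leptin_closed")
SATIETY_PAIR = ("leptin_opened", "fasted_closed")


@dataclass
class MotifConsensus:
    """Consensus over the six per-background enrichment results for one motif/condition."""

    motif_id: str
    condition: str
    n_significant: int
    enriched: bool
    rep_log_p: float  # natural log of the representative p
    rep_log2p: float  # -log2 of the representative p

    @property
    def rep_p(self) -> float:
        return math.exp(self.rep_log_p)


@dataclass
class TFPriorityRecord:
    motif_id: str
    enriched: dict[str, bool]
    rep_log2p: dict[str, float]
    summed_score_hunger: float | None
    summed_score_satiety: float | None
    category: str
    rank: int | None = None


def consensus_call(results: list[EnrichmentResult], alpha: float = 0.05) -> MotifConsensus:
    """Apply the >=5-of-6 rule and pick the representative p-value.

    ``results`` must hold exactly one result per background label. Significance
    is adjusted p < alpha (compared in log space). When enriched, the
    representative p is the minimum of the significant adjusted p-values;
    otherwise the minimum of the non-significant ones.
    """
    if len(results) != len(BACKGROUND_LABELS):
        raise ValueError(f"expected {len(BACKGROUND_LABELS)} results, got {len(results)}")
    labels = {r.background_label for r in results}
    if labels != set(BACKGROUND_LABELS):
        raise ValueError(f"results must cover all background labels, got {sorted(labels)}")
    log_alpha = math.log(alpha)
    sig = [r.log_p_adj for r in results if r.log_p_adj < log_alpha]
    nonsig = [r.log_p_adj for r in results if r.log_p_adj >= log_alpha]
    enriched = len(sig) >= 5
    rep_log_p = min(sig) if enriched else min(nonsig)
    return MotifConsensus(
        motif_id=results[0].motif_id,
        condition=results[0].foreground,
        n_significant=len(sig),
        enriched=enriched,
        rep_log_p=rep_log_p,
        rep_log2p=-rep_log_p / LN2,
    )


def classify_tf_category(consensus: dict[str, MotifConsensus]) -> str:
    """Map the four enrichment flags onto the exclusivity category partition."""
    e = {c: consensus[c].enriched for c in PEAK_CONDITIONS}
    fo, fc, lo, lc = (e["fasted_opened"], e["fasted_closed"],
                      e["leptin_opened"], e["leptin_closed"])
    if fo and lc and not lo and not fc:
        return "hunger_pair_exclusive"
    if fo and not lc and not lo and not fc:
        return "hunger_single_exclusive"
    if lo and fc and not fo and not lc:
        return "satiety_pair_exclusive"
    if lo and not fc and not fo and not lc:
        return "satiety_single_exclusive"
    if any(e.values()):
        return "mixed"
    return "none"


def summed_pair_score(consensus: dict[str, MotifConsensus], pair: str) -> float | None:
    """Sum of the two representative -log2(p) scores, or None unless both enriched."""
    conds = HUNGER_PAIR if pair == "hunger" else SATIETY_PAIR if pair == "satiety" else None
    if conds is None:
        raise ValueError(f"pair must be 'hunger' or 'satiety', got {pair!r}")
    a, b = (consensus[c] for c in conds)
    if not (a.enriched and b.enriched):
        return None
    return a.rep_log2p + b.rep_log2p


def build_priority_records(consensus_by_motif: dict[str, dict[str, MotifConsensus]]
                           ) -> list[TFPriorityRecord]:
    records = []
    for motif_id in sorted(consensus_by_motif):
        cons = consensus_by_motif[motif_id]
        records.append(
            TFPriorityRecord(
                motif_id=motif_id,
                enriched={c: cons[c].enriched for c in PEAK_CONDITIONS},
                rep_log2p={c: cons[c].rep_log2p for c in PEAK_CONDITIONS},
                summed_score_hunger=summed_pair_score(cons, "hunger"),
                summed_score_satiety=summed_pair_score(cons, "satiety"),
                category=classify_tf_category(cons),
            )
        )
    return records


def _rank_key(r: TFPriorityRecord) -> tuple[float, str]:
    if r.category == "hunger_pair_exclusive":
        score = r.summed_score_hunger
    elif r.category == "satiety_pair_exclusive":
        score = r.summed_score_satiety
    elif r.category == "hunger_single_exclusive":
        score = r.rep_log2p["fasted_opened"]
    elif r.category == "satiety_single_exclusive":
        score = r.rep_log2p["leptin_opened"]
    else:
        score = float("-inf")
    return (-(score if score is not None else float("-inf")), r.motif_id)


def rank_and_export(records: list[TFPriorityRecord]) -> tuple[pd.DataFrame, dict]:
    """Rank records within category and build the flat table plus radar data.

    Pair-exclusive motifs rank by descending summed score, single-exclusive
    ones by their single representative score; ties break lexicographically on
    motif id. The radar data carries, per motif, the four -log2(p) axes
    (floored at 0 when the representative p is >= 1).
    """
    by_cat: dict[str, list[TFPriorityRecord]] = {}
    for r in records:
        by_cat.setdefault(r.category, []).append(r)
    for cat, rs in by_cat.items():
        rs.sort(key=_rank_key)
        for i, r in enumerate(rs, start=1):
            r.rank = i if cat not in {"mixed", "none"} else None

    rows = []
    for r in sorted(records, key=lambda r: (CATEGORIES.index(r.category), _rank_key(r))):
        row = {"motif_id": r.motif_id, "category": r.category, "rank": r.rank}
        for c in PEAK_CONDITIONS:
            row[f"enriched_{c}"] = r.enriched[c]
        for c in PEAK_CONDITIONS:
            row[f"rep_log2p_{c}"] = r.rep_log2p[c]
        row["summed_score_hunger"] = r.summed_score_hunger
        row["summed_score_satiety"] = r.summed_score_satiety
        rows.append(row)
    table = pd.DataFrame(rows)

    radar = {
        r.motif_id: {c: max(0.0, r.rep_log2p[c]) for c in PEAK_CONDITIONS}
        for r in records
    }
    return table, radar
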