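# Methods

This note documents the statistical model behind `cistf`, the parameters that
matter, what the synthetic data generator does and does not emulate, and the
design choices made where more than one reasonable option existed.

## Differential classification

Inputs are per-feature tables (id, log2FC, FDR, mean CPM per compared group)
for two contrasts: fasted vs fed and leptin vs fasted. Thresholds follow the
study design and are deliberately asymmetric between genes and peaks:

| parameter       | default | semantics |
|-----------------|---------|-----------|
| `gene_lfc_min`  | 0.5     | strict: a gene at exactly 0.5 is excluded |
| `peak_lfc_min`  | 0.5     | inclusive: a peak at exactly 0.5 is included |
| `fdr_max`       | 0.05    | strict, both kinds |
| `gene_cpm_min`  | 1 CPM   | strict, mean CPM in ≥ 1 compared group |
| `peak_cpm_min`  | 1 CPM   | inclusive |

The CPM filter's "at least one compared group" reading is configurable to
"all groups" (`cpm_rule`). FDR adjustment is Benjamini–Hochberg
(statsmodels). Bidirectional gene sets are plain intersections
(fasting-induced ∩ leptin-repressed and its mirror).

### The stand-in differential test

`simple_de_test` exists so fully synthetic runs need no external DE tool. It
is a two-sample t on log2 CPM (counts + 0.5 pseudo-offset) whose pooled
per-feature variance is shrunk toward the across-feature mean variance with
`moderation_df = 20` prior degrees of freedom, and the t reference
distribution gains those degrees of freedom. The moderation matters: at
n = 4 per group an unmoderated per-feature t has ~6 df, its variance
estimate is so unstable that features with a 4-fold true change routinely
fail a 5% FDR, and the designed properties of the synthetic study (≥ 90%
recovery of planted effects, ≥ 50 concordant peaks per condition) cannot be
met. Setting `moderation_df = 0` recovers the plain test. This is **not** a
negative-binomial GLM: it ignores the mean–variance relation of counts and
uses naive CPM normalization (no trimmed-mean correction), so externally
produced differential tables from a count-model tool are the recommended
input for real data. All-zero features are forced to log2FC = 0, p = 1.

## Concordance

A peak supports a gene when the peak interval overlaps the closed window
[TSS − w, TSS + w], w = 200 kb by default (`--window-kb`). Any overlapping
base qualifies — the alternative (peak-center distance) would make boundary
behavior depend on peak length. The window is strand-independent; w = 0
degenerates to the single base at the TSS; negative w is an error. Genes
contribute exactly one TSS (the annotated gene start, strand-aware).
Chromosomes outside an optional allow-list (scaffold filtering) are excluded
from concordance. Implementation is a per-chromosome sorted-TSS binary
search; tests compare it against a full all-pairs boolean matrix up to
5 000 × 1 000.

Association statistics per condition: the fraction of regulated genes with
≥ 1 concordant peak is compared against the fraction of neutral genes
(significant in neither direction) with ≥ 1 same-direction differential peak
in the window, with a one-tailed Fisher exact test; the choice of test is a
convention of this package, documented rather than inherited. Spearman's rho
between per-gene concordant peak count and |log2FC| is reported when both
vary. Peak feature annotation uses precedence promoter > exonic > intronic >
intergenic, with the promoter defined strand-aware as the 1 kb immediately
upstream of the TSS.

## Motif enrichment

**Scanner.** PWMs are smoothed as p′ = (p + c)/(1 + 4c) with pseudocount
c = 0.01 and converted to log2-odds against a background model, by default
the genome-wide mononucleotide frequencies of the supplied genome
(configurable to uniform or the motif file's own background). The default
sequence score is the maximum log-odds over all windows on both strands;
windows containing N are skipped, and a sequence with no valid window is
excluded. An average-odds mode (`--scoring avg`, log2 of the mean odds over
valid windows) is available; max scoring is the default because it has an
exact brute-force oracle and a direct reading (best single site).

**Test.** For foreground scores F and background scores B, the enrichment
p-value is min over thresholds t ∈ distinct(F) of the hypergeometric upper
tail of the 2×2 hit table at {score ≥ t}. Restricting candidate thresholds
to observed foreground values loses nothing: between two adjacent foreground
values the foreground hit count is constant and the background hit count is
minimized at the upper end, and the upper-tail p is monotone in background
hits. The reported adjusted p multiplies by the number of thresholds tried
and then by the motif library size (both Bonferroni factors logged in the
output). The hypergeometric tail is summed in log space with `gammaln` +
`logsumexp`; a table as extreme as 660/660 vs 0/660 (p ≈ 1e-396) keeps a
finite log-p and a finite −log2(p) with no clamping. A floor at e^−300
(`pvalue_floor`) exists only for parity with workflows that must leave log
space.

**Backgrounds.** Six sets per condition: (1) all neutral peaks; (2) neutral
peaks within the window of a neutral gene; (3) of a significant gene; (4) of
any TSS; (5) the condition's differential-but-non-concordant peaks; (6) a
seeded dinucleotide-preserving shuffle of the foreground (same cardinality
and per-sequence lengths). Sets 1–4 are used in full, without subsampling to
the foreground size — the Fisher test conditions on both margins, so
size-matching is unnecessary. The shuffle is Altschul–Erickson: a random
Eulerian path through the dinucleotide multigraph with fixed endpoints, so
the dinucleotide count multiset and terminal residues are preserved exactly.

## Prioritization

Significance per background is adjusted p < α (default 0.05, configurable —
the consensus cutoff is a package convention). Enriched ⇔ significant
against ≥ 5 of 6 backgrounds. Representative p: minimum of the significant
adjusted p-values when enriched, minimum of the non-significant ones
otherwise; scores are −log2(p) computed from the log-space p. Categories
partition the motif library by the four enrichment flags: pair-exclusive
(hunger: fasted-opened ∧ leptin-closed ∧ ¬others; satiety mirrored),
single-exclusive (exactly one set), `mixed` (enriched somewhere but no
exclusive pattern), `none`. Summed pair scores are only defined when both
pair members are enriched; an undefined score is an explicit missing value,
never 0, so it cannot fake a rank. Ties in ranking break lexicographically
on motif id. Radar export floors the four axes at 0 when a representative p
is ≥ 1.

## Synthetic data generator

The generator emulates the statistical shape of a three-condition
TRAP-seq + ATAC-seq study, with every artifact a pure function of the
configuration (per-stage RNG substreams keep stages individually
reproducible).

* **Geometry.** The genome is partitioned into 420 kb blocks, each owning at
  most one gene (TSS near the block center, ±10 kb jitter). Designed
  concordant peaks lie within 150 kb of their gene's TSS; peaks of any other
  block are ≥ 250 kb from that TSS, safely outside the 200 kb window. This
  makes designed links and non-links exactly recoverable, at the cost of an
  unrealistically regular gene spacing.
* **Gene classes.** 18 genes per single-contrast class, 12 per bidirectional
  class, 40 placed neutral genes; regulated genes carry ±2 log2 effects
  (fasting and/or leptin, with the leptin effect applied on top of the
  fasted state, since that contrast is leptin vs fasted). Two designed
  concordant peaks per regulated gene give ~60 concordant peaks per
  condition. 25 non-concordant differential peaks per condition and ~300
  neutral peaks populate the background sets.
* **Counts.** Negative binomial with Var = μ + αμ², α = 0.05 (tight, so
  small fixtures are informative), log-normal base means (~100 CPM scale),
  log-normal library-size factors (σ = 0.1), n = 4 replicates per condition.
  600 filler genes and 1200 filler peaks with no genomic placement dilute
  library-composition bias: without them the regulated fraction is so large
  that CPM normalization alone shifts neutral features by ~0.6 log2 units,
  which no real mostly-unchanging transcriptome exhibits.
* **Motifs.** Two causal near-consensus PWMs (12 bp, dominant base
  probability 0.95): a hunger motif planted into concordant fasted-opened
  and leptin-closed peaks with probability 0.8 (0.05 elsewhere), and a
  satiety motif mirrored on leptin-opened/fasted-closed. Decoys are
  position-shuffled copies of the causal PWMs, so they match information
  content but not sequence. Instances overwrite genome bases (coordinates
  stay fixed) at a uniform position and strand.

What the generator does **not** emulate: read-level artifacts (fragment
models, Tn5 bias, GC effects), batch effects, realistic gene spacing or peak
width distributions, overlapping regulatory domains, motif co-occurrence and
clustering, and the mean–variance trends of real libraries. A passing
end-to-end test therefore demonstrates the correctness of the pipeline's
logic and statistics under a controlled model — not that any particular real
dataset would yield the same TF list.

## Numerical and edge-case choices

* All p-values are natural-log floats end to end; exponentiation happens
  only for display (and may report 0.0 for extreme tails; the log columns in
  the output TSVs are authoritative).
* Threshold ties in the optimal scan resolve to the smallest threshold
  attaining the minimum (within 1e-12 in log space).
* Sequences > 50% N are dropped before scanning (threshold configurable);
  remaining N-containing windows are skipped.
* Classification outputs and concordance mappings are sorted canonically, so
  results are invariant to input ordering, and identical configurations
  produce byte-identical output files (the basis of the `run-all` =
  chained-subcommands equivalence test).
* Problem sizes in the test suite — e.g. 20 replicate simulations for
  end-to-end recovery, 10 random fixtures up to 5 000 × 1 000 for the
  concordance oracle, 200 decoy motifs for null calibration — were chosen as
  the smallest sizes at which the checked properties are statistically
  meaningful.

## Known limitations

* The stand-in DE test is not a count model; see above.
* AME-style scoring here implements the max- and average-odds score with the
  Fisher optimal-threshold test only; rank-sum/Spearman variants and
  E-value calibration are out of scope.
* One TSS per gene; alternative promoters are collapsed.
* Nearest-gene, looping, or TAD-aware peak-to-gene assignment is out of
  scope; every gene within the window supports a peak.
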