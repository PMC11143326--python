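import math

import numpy as np
import pytest

from cistf.concordance import (
    annotate_peak_features,
    assign_concordant_peaks,
    association_stats,
    feature_fractions,
)
from cistf.diff_classify import RegulatedSets
from cistf.io_formats import GeneModel, Peak

W = 200_000


def _gene(gene_id, tss, chrom="chr1", strand="+", **kw):
    return GeneModel(gene_id, chrom, strand, tss, **kw)


def _reg(peaks, genes):
    """All peaks fasted_opened, all genes fasting_induced."""
    return RegulatedSets(fasted_opened={p.peak_id for p in peaks},
                         fasting_induced={g.gene_id for g in genes})


def brute_force_concordant(peaks, genes, cond_peaks, cond_genes, window):
    """O(n*m) oracle: any-overlap of peak with the closed TSS window."""
    out = {}
    for p in peaks:
        if p.peak_id not in cond_peaks:
            continue
        support = sorted(
            g.gene_id for g in genes
            if g.gene_id in cond_genes and g.chrom == p.chrom
            and p.start <= g.tss + window and p.end - 1 >= g.tss - window
        )
        if support:
            out[p.peak_id] = support
    return out


class TestWindowBoundary:
    def test_peak_overlapping_window_end_is_concordant(self):
        genes = [_gene("g", 1_000_000)]
        peaks = [Peak("chr1", 1_199_900, 1_200_100, "p")]
        res = assign_concordant_peaks(peaks, genes, _reg(peaks, genes), window_bp=W)
        assert res["fasted_opened"].peak_ids == ["p"]

    def test_peak_one_base_past_window_is_not(self):
        genes = [_gene("g", 1_000_000)]
        peaks = [Peak("chr1", 1_200_001, 1_200_050, "p")]
        res = assign_concordant_peaks(peaks, genes, _reg(peaks, genes), window_bp=W)
        assert res["fasted_opened"].peak_ids == []

    def test_distance_symmetry(self):
        genes = [_gene("g", 1_000_000)]
        for d in (0, 1, 150_000, 199_999, 200_000, 200_001):
            up = [Peak("chr1", max(0, 1_000_000 - d - 10), 1_000_000 - d + 10 if d else 1_000_010, "u")]
            down = [Peak("chr1", 1_000_000 + d - 10 if d else 999_990, 1_000_000 + d + 10, "d")]
            r_up = assign_concordant_peaks(up, genes, _reg(up, genes), window_bp=W)
            r_dn = assign_concordant_peaks(down, genes, _reg(down, genes), window_bp=W)
            assert bool(r_up["fasted_opened"].peak_ids) == bool(r_dn["fasted_opened"].peak_ids)

    def test_zero_window_is_single_base_at_tss(self):
        genes = [_gene("g", 100)]
        hit = [Peak("chr1", 90, 101, "hit")]
        miss = [Peak("chr1", 90, 100, "miss")]
        assert assign_concordant_peaks(hit, genes, _reg(hit, genes), window_bp=0)[
            "fasted_opened"].peak_ids == ["hit"]
        assert assign_concordant_peaks(miss, genes, _reg(miss, genes), window_bp=0)[
            "fasted_opened"].peak_ids == []

    def test_negative_window_raises(self):
        genes = [_gene("g", 100)]
        peaks = [Peak("chr1", 0, 10, "p")]
        with pytest.raises(ValueError):
            assign_concordant_peaks(peaks, genes, _reg(peaks, genes), window_bp=-1)


def _random_fixture(rng, n_peaks, n_genes, chrom_len=5_000_000):
    chroms = ["chr1", "chr2"]
    peaks = []
    for i in range(n_peaks):
        start = int(rng.integers(0, chrom_len - 500))
        peaks.append(Peak(str(rng.choice(chroms)), start,
                          start + int(rng.integers(100, 500)), f"p{i}"))
    genes = [_gene(f"g{i}", int(rng.integers(0, chrom_len)), chrom=str(rng.choice(chroms)))
             for i in range(n_genes)]
    return peaks, genes


class TestOracleEquivalence:
    def test_matches_brute_force_on_random_fixture(self):
        rng = np.random.default_rng(7)
        peaks, genes = _random_fixture(rng, 1000, 200)
        cond_peaks = {p.peak_id for p in peaks if rng.random() < 0.5}
        cond_genes = {g.gene_id for g in genes if rng.random() < 0.5}
        reg = RegulatedSets(fasted_opened=cond_peaks, fasting_induced=cond_genes)
        res = assign_concordant_peaks(peaks, genes, reg, window_bp=W)["fasted_opened"]
        oracle = brute_force_concordant(peaks, genes, cond_peaks, cond_genes, W)
        assert res.peak_to_genes == oracle

    def test_invariant_to_input_ordering(self):
        rng = np.random.default_rng(3)
        peaks, genes = _random_fixture(rng, 300, 50)
        reg = _reg(peaks, genes)
        a = assign_concordant_peaks(peaks, genes, reg, window_bp=W)
        b = assign_concordant_peaks(peaks[::-1], genes[::-1], reg, window_bp=W)
        for cond in a:
            assert a[cond].peak_ids == b[cond].peak_ids
            assert a[cond].peak_to_genes == b[cond].peak_to_genes

    def test_scaffold_allowlist_excludes_peaks(self):
        genes = [_gene("g", 1000)]
        peaks = [Peak("chr1", 900, 1100, "p1"), Peak("scaffold_1", 900, 1100, "p2")]
        reg = RegulatedSets(fasted_opened={"p1", "p2"}, fasting_induced={"g"})
        res = assign_concordant_peaks(peaks, genes, reg, window_bp=W,
                                      chrom_allowlist={"chr1"})
        assert res["fasted_opened"].peak_ids == ["p1"]


class TestAssociationStats:
    def _setup(self, n_cond=10, n_neutral=100):
        genes = [_gene(f"c{i}", 10_000 + 500_000 * i, log2fc=2.0) for i in range(n_cond)]
        neutral = [_gene(f"n{i}", 100_000_000 + 500_000 * i, log2fc=0.0)
                   for i in range(n_neutral)]
        peaks = [Peak("chr1", g.tss + 100, g.tss + 300, f"pk{i}")
                 for i, g in enumerate(genes)]
        return genes, neutral, peaks

    def test_perfect_separation_small_p(self):
        genes, neutral, peaks = self._setup()
        reg = RegulatedSets(fasted_opened={p.peak_id for p in peaks},
                            fasting_induced={g.gene_id for g in genes})
        cps = assign_concordant_peaks(peaks, genes + neutral, reg, window_bp=W)["fasted_opened"]
        st = association_stats({g.gene_id for g in genes}, cps,
                               {g.gene_id for g in neutral}, genes + neutral, peaks, W)
        assert st.fraction == 1.0
        # hypergeometric enumeration: all 10 "with peak" drawn into the 10 condition slots
        assert st.p_value == pytest.approx(1.0 / math.comb(110, 10), rel=1e-6)
        assert sum(st.peaks_per_gene.values()) == st.n_genes_with_peak

    def test_null_composition_p_near_one(self):
        # neutral genes have the same per-gene peak coverage as condition genes
        genes, _, peaks = self._setup(n_cond=10, n_neutral=0)
        neutral = [_gene(f"n{i}", g.tss) for i, g in enumerate(genes)]
        reg = RegulatedSets(fasted_opened={p.peak_id for p in peaks},
                            fasting_induced={g.gene_id for g in genes})
        cps = assign_concordant_peaks(peaks, genes + neutral, reg, window_bp=W)["fasted_opened"]
        st = association_stats({g.gene_id for g in genes}, cps,
                               {g.gene_id for g in neutral}, genes + neutral, peaks, W)
        assert st.p_value > 0.5

    def test_empty_gene_set_raises(self):
        genes, neutral, peaks = self._setup()
        reg = RegulatedSets(fasted_opened={p.peak_id for p in peaks},
                            fasting_induced={g.gene_id for g in genes})
        cps = assign_concordant_peaks(peaks, genes, reg, window_bp=W)["fasted_opened"]
        with pytest.raises(ValueError):
            association_stats(set(), cps, {"n0"}, genes, peaks, W)

    def test_peak_count_tracks_fold_change(self, rng):
        # planted: number of concordant peaks grows with |log2fc|
        genes = [_gene(f"g{i}", 1_000_000 * (i + 1), log2fc=0.5 * (i + 1))
                 for i in range(8)]
        peaks = []
        for i, g in enumerate(genes):
            for k in range(i + 1):
                peaks.append(Peak("chr1", g.tss + 200 * k, g.tss + 200 * k + 150,
                                  f"pk{i}_{k}"))
        reg = RegulatedSets(fasted_opened={p.peak_id for p in peaks},
                            fasting_induced={g.gene_id for g in genes})
        cps = assign_concordant_peaks(peaks, genes, reg, window_bp=1000)["fasted_opened"]
        st = association_stats({g.gene_id for g in genes}, cps, {"none"},
                               genes + [_gene("none", 50_000_000)], peaks, 1000)
        assert st.rho > 0.9


class TestAnnotatePeakFeatures:
    GENES = [
        GeneModel("gp", "chr1", "+", 10_000, start=10_000, end=20_000,
                  exons=[(10_000, 11_000), (19_000, 20_000)]),
    ]

    def test_promoter_window_plus_strand(self):
        ann = annotate_peak_features([Peak("chr1", 9_200, 9_800, "p")], self.GENES)
        assert ann["p"] == "promoter"

    def test_promoter_precedence_over_exon(self):
        other = GeneModel("g2", "chr1", "+", 9_500, start=9_500, end=9_900,
                          exons=[(9_500, 9_900)])
        ann = annotate_peak_features([Peak("chr1", 9_000, 9_600, "p")],
                                     self.GENES + [other])
        assert ann["p"] == "promoter"

    def test_exon_intron_intergenic(self):
        peaks = [Peak("chr1", 10_100, 10_200, "ex"),
                 Peak("chr1", 15_000, 15_100, "in"),
                 Peak("chr1", 500_000, 500_100, "ig"),
                 Peak("chrM", 0, 100, "nochrom")]
        ann = annotate_peak_features(peaks, self.GENES)
        assert ann == {"ex": "exonic", "in": "intronic",
                       "ig": "intergenic", "nochrom": "intergenic"}

    def test_minus_strand_promoter_is_downstream_in_coords(self):
        gm = GeneModel("gm", "chr1", "-", 30_000, start=20_001, end=30_001)
        ann = annotate_peak_features([Peak("chr1", 30_500, 30_600, "p")], [gm])
        assert ann["p"] == "promoter"

    def test_fraction_summary(self):
        peaks = [Peak("chr1", 9_200, 9_800, "a"), Peak("chr1", 500_000, 500_100, "b")]
        fr = feature_fractions(annotate_peak_features(peaks, self.GENES))
        assert fr["promoter"] == 0.5 and fr["intergenic"] == 0.5
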