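import numpy as np
import pandas as pd
import pytest

from cistf.diff_classify import simple_de_test
from cistf.io_formats import CONTRASTS, DiffTable
from cistf.pipeline import analyze_bundle
from cistf.synthetic_data import SimConfig, simulate_bundle


def make_diff_table(rows, contrast="fasted_vs_fed", kind="gene"):
    """Build a DiffTable from (id, log2fc, fdr, cpm_treat, cpm_ref) tuples."""
    treat, ref = {"fasted_vs_fed": ("fasted", "fed"),
                  "leptin_vs_fasted": ("leptin", "fasted")}[contrast]
    df = pd.DataFrame(rows, columns=["id", "log2fc", "fdr",
                                     f"mean_cpm_{treat}", f"mean_cpm_{ref}"])
    return DiffTable(df=df, contrast=contrast, kind=kind)


TINY_CFG = dict(
    n_fast_up=5, n_fast_down=5, n_lep_up=5, n_lep_down=5,
    n_bidir_hunger=4, n_bidir_satiety=4, n_neutral=10,
    n_filler_genes=150, n_filler_peaks=300,
    n_nonconcordant_per_condition=8, n_far_neutral=8,
    n_decoys=2,
)


@pytest.fixture(scope="session")
def tiny_cfg():
    return SimConfig(seed=7, **TINY_CFG)


@pytest.fixture(scope="session")
def tiny_bundle(tiny_cfg):
    return simulate_bundle(tiny_cfg)


@pytest.fixture(scope="session")
def default_bundle():
    return simulate_bundle(SimConfig(seed=101))


@pytest.fixture(scope="session")
def default_tables(default_bundle):
    b = default_bundle
    gene_tables = {c: simple_de_test(b.gene_counts, b.groups, c, kind="gene")
                   for c in CONTRASTS}
    peak_tables = {c: simple_de_test(b.peak_counts, b.groups, c, kind="peak")
                   for c in CONTRASTS}
    return gene_tables, peak_tables


@pytest.fixture(scope="session")
def default_analysis(default_bundle, default_tables):
    b = default_bundle
    gene_tables, peak_tables = default_tables
    return analyze_bundle(b.genome, b.genes, b.peaks, gene_tables, peak_tables,
                          b.motifs, seed=101)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
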