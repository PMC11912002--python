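import sys
from pathlib import Path

import matplotlib
import pandas as pd
import pytest

matplotlib.use("Agg")

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

import locusplot as lp


@pytest.fixture
def tiny_stats():
    """Three variants on two chromosomes, deliberately unsorted on input."""
    df = pd.DataFrame(
        {
            "chrom": ["2", "1", "1"],
            "pos": [500, 150, 50],
            "p": [0.5, 1e-9, 0.01],
            "id": ["rs3", "rs2", "rs1"],
        }
    )
    return lp.from_dataframe(df)


@pytest.fixture
def sim_stats():
    """Synthetic genome-wide stats with three well-separated planted peaks."""
    peaks = [
        lp.PeakSpec("1", 10_000_000, height=10, decay_scale=50_000),
        lp.PeakSpec("1", 30_000_000, height=9, decay_scale=50_000),
        lp.PeakSpec("2", 15_000_000, height=12, decay_scale=50_000),
    ]
    stats = lp.simulate_gwas(
        20_000, {"1": 40_000_000, "2": 30_000_000}, peaks, seed=11
    )
    return stats, peaks


@pytest.fixture
def demo_locus(sim_stats):
    """A 1 Mb locus around the first planted peak, with genes and overlays."""
    stats, _ = sim_stats
    ann = lp.simulate_genes("1", (9_500_001, 10_500_000), 12, seed=5)
    locus = lp.make_locus(stats, region=("1", 9_500_001, 10_500_000), annotation=ann)
    ld = lp.simulate_ld(locus, seed=6)
    recomb = lp.simulate_recomb("1", 40_000_000, 300, seed=7)
    eqtl = lp.simulate_eqtl(locus, gene="GENE1", seed=8)
    return lp.attach_overlays(locus, ld=ld, recomb=recomb, eqtl=eqtl)
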