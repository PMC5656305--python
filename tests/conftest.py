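import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import chromconverge as cc

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_genome():
    """Two 2-Mb chromosomes with 200 genes."""
    layout, annotation = cc.make_genome(
        n_chromosomes=2, chrom_length=2_000_000, n_genes=200, seed=11
    )
    return layout, annotation


@pytest.fixture(scope="session")
def peak_simulation(small_genome):
    """Default-condition peak replicates: 120 true promoter, 30 true distal,
    50 low-signal, 50 discordant."""
    layout, annotation = small_genome
    rep1, rep2, reads, truth = cc.simulate_peak_replicates(
        annotation, layout,
        n_true_promoter=120, n_true_distal=30, n_low_signal=50, n_discordant=50,
        mean_depth=500.0, dispersion=0.05, seed=7,
    )
    return rep1, rep2, reads, truth


@pytest.fixture(scope="session")
def counts_simulation():
    matrices, truth = cc.simulate_counts(
        n_genes=2000, n_reps_per_group=3, de_fraction=0.1,
        shared_de_fraction=0.05, lfc=2.0, dispersion=0.05, seed=13,
    )
    return matrices, truth


@pytest.fixture()
def regular_annotation():
    """50 plus-strand genes of 6 kb evenly spaced every 20 kb on one 1-Mb chromosome.

    Promoter windows (+/-1 kb, closed) cover ~10% of the genome, termination
    windows another ~10%, gene-body interiors ~20%.
    """
    rows = [
        (f"g{i:03d}", "chr1", "+", 10_000 + 20_000 * i, 16_000 + 20_000 * i)
        for i in range(50)
    ]
    annotation = pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "tss", "tes"])
    layout = cc.GenomeLayout({"chr1": 1_000_000})
    return layout, annotation


def uniform_peaks(layout, n, width=200, seed=0):
    """Peaks placed uniformly at random over the genome (fixed width)."""
    rng = np.random.default_rng(seed)
    chroms = list(layout.chrom_lengths)
    lengths = np.array([layout.chrom_lengths[c] for c in chroms], dtype=float)
    ci = rng.choice(len(chroms), size=n, p=lengths / lengths.sum())
    starts = (rng.random(n) * (lengths[ci] - width)).astype(int)
    return pd.DataFrame(
        {
            "chrom": np.array(chroms, dtype=object)[ci],
            "start": starts,
            "end": starts + width,
            "name": [f"peak{i:05d}" for i in range(n)],
        }
    )
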