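"""Synthetic data with known ground truth for every pipeline stage.

The generators emulate the structure of a two-replicate ChIP experiment on a
compact genome, negative-binomial RNA-seq count matrices for two mutant-vs-
control contrasts with a controlled fraction of shared differentially
expressed genes, and beta-distributed courtship indices with genotype-specific
suppression in trained flies. Everything is seeded and deterministic; the
returned :class:`SimTruth` records which simulated objects are real effects
and which are planted artifacts, so recovery rates can be measured exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import CountMatrix

__all__ = [
    "GenomeLayout",
    "SimTruth",
    "CapacityError",
    "make_genome",
    "simulate_peak_replicates",
    "simulate_counts",
    "simulate_courtship",
]

MIN_GENE_BODY = 2000  # bp; smallest simulated gene body


class CapacityError(ValueError):
    """Requested objects cannot be packed into the genome."""


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome names and lengths of a simulated genome."""

    chrom_lengths: dict[str, int]

    def __post_init__(self):
        if len(self.chrom_lengths) == 0:
            raise ValueError("at least one chromosome required")
        for name, length in self.chrom_lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")

    @property
    def total_length(self) -> int:
        return int(sum(self.chrom_lengths.values()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chrom": list(self.chrom_lengths), "length": list(self.chrom_lengths.values())}
        )


@dataclass
class SimTruth:
    """Ground-truth labels attached to one simulated dataset."""

    true_peaks: list[str] = field(default_factory=list)
    spurious_peaks: dict[str, str] = field(default_factory=dict)  # id -> reason
    de_truth: dict[str, pd.DataFrame] = field(default_factory=dict)  # contrast -> table
    courtship_truth: pd.DataFrame | None = None


def make_genome(
    n_chromosomes: int,
    chrom_length: int,
    n_genes: int,
    seed: int,
) -> tuple[GenomeLayout, pd.DataFrame]:
    """Lay out ``n_genes`` non-overlapping gene bodies on equal-length chromosomes.

    Gene bodies are 2-8 kb, strands random. TSS/TES follow transcription
    orientation: on the minus strand the TSS is the higher genomic coordinate.

    Raises
    ------
    CapacityError
        If the requested genes cannot fit on the chromosomes.
    """
    if n_chromosomes < 1 or chrom_length < 1:
        raise ValueError("n_chromosomes and chrom_length must be positive")
    if n_genes < 0:
        raise ValueError("n_genes must be >= 0")
    rng = np.random.default_rng(seed)
    chroms = [f"chr{i + 1}" for i in range(n_chromosomes)]
    layout = GenomeLayout({c: chrom_length for c in chroms})
    if n_genes == 0:
        empty = pd.DataFrame(columns=["gene_id", "chrom", "strand", "tss", "tes"])
        return layout, empty

    per_chrom = np.full(n_chromosomes, n_genes // n_chromosomes, dtype=int)
    per_chrom[: n_genes % n_chromosomes] += 1

    rows = []
    gene_no = 0
    for chrom, n_on_chrom in zip(chroms, per_chrom):
        if n_on_chrom == 0:
            continue
        lengths = rng.integers(MIN_GENE_BODY, 4 * MIN_GENE_BODY + 1, size=n_on_chrom)
        slack = chrom_length - int(lengths.sum())
        if slack < 0:
            raise CapacityError(
                f"{n_on_chrom} gene bodies totalling {lengths.sum()} bp "
                f"do not fit on a {chrom_length} bp chromosome"
            )
        # distribute the free space as sorted uniform gaps (stick breaking)
        gaps = np.sort(rng.integers(0, slack + 1, size=n_on_chrom))
        starts = gaps + np.concatenate([[0], np.cumsum(lengths[:-1])])
        for start, length in zip(starts, lengths):
            end = int(start + length)
            strand = "+" if rng.random() < 0.5 else "-"
            tss, tes = (int(start), end - 1) if strand == "+" else (end - 1, int(start))
            rows.append((f"g{gene_no:05d}", chrom, strand, tss, tes))
            gene_no += 1
    annotation = pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "tss", "tes"])
    return layout, annotation


def _nb_draw(rng, mean, dispersion, size=None):
    """NB draws with variance mean + dispersion * mean^2."""
    mean = np.asarray(mean, dtype=float)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size)


def simulate_peak_replicates(
    annotation: pd.DataFrame,
    layout: GenomeLayout,
    n_true_promoter: int,
    n_true_distal: int,
    n_low_signal: int,
    n_discordant: int,
    mean_depth: float = 500.0,
    dispersion: float = 0.05,
    low_signal_mean: float = 20.0,
    discordant_ratio: float = 3.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, pd.DataFrame], SimTruth]:
    """Two replicate peak tables plus per-replicate read positions and truth.

    True promoter peaks are centred within 1 kb of a TSS; true distal peaks sit
    away from every TSS. Low-signal peaks have expected mean ``low_signal_mean``
    (well below the concordance filter's read threshold) and discordant peaks
    have an expected replicate ratio of ``discordant_ratio``. Replicate peak
    boundaries are jittered by a few bp so merging is exercised.

    Returns ``(peaks_rep1, peaks_rep2, reads, truth)`` where ``reads`` maps
    replicate name to a (chrom, pos) table of 5' read coordinates.
    """
    for name, v in [
        ("n_true_promoter", n_true_promoter),
        ("n_true_distal", n_true_distal),
        ("n_low_signal", n_low_signal),
        ("n_discordant", n_discordant),
    ]:
        if v < 0:
            raise ValueError(f"{name} must be >= 0")
    if dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    rng = np.random.default_rng(seed)
    half_width = 250  # regions are ~500 bp, like sonicated ChIP fragments

    n_total = n_true_promoter + n_true_distal + n_low_signal + n_discordant
    truth = SimTruth()
    if n_total == 0:
        empty = pd.DataFrame(columns=["chrom", "start", "end", "name"])
        reads = {
            "rep1": pd.DataFrame(columns=["chrom", "pos"]),
            "rep2": pd.DataFrame(columns=["chrom", "pos"]),
        }
        return empty.copy(), empty.copy(), reads, truth

    # promoter-class centres come from distinct TSSs
    centres: list[tuple[str, int]] = []
    if n_true_promoter > 0:
        if len(annotation) < n_true_promoter:
            raise CapacityError("not enough genes for the requested promoter peaks")
        picked = annotation.sample(n=n_true_promoter, random_state=rng.integers(2**31))
        for _, g in picked.iterrows():
            offset = int(rng.integers(-500, 501))
            centres.append((g["chrom"], int(g["tss"]) + offset))

    # non-promoter centres on a 5 kb grid, >= 2 kb from every TSS
    n_other = n_total - n_true_promoter
    if n_other > 0:
        tss_by_chrom = {
            c: np.sort(sub["tss"].to_numpy())
            for c, sub in annotation.groupby("chrom")
        }
        candidates = []
        for chrom, length in layout.chrom_lengths.items():
            grid = np.arange(2500, length - 2500, 5000)
            tss = tss_by_chrom.get(chrom, np.array([]))
            if tss.size:
                idx = np.searchsorted(tss, grid)
                left = np.abs(grid - tss[np.clip(idx - 1, 0, tss.size - 1)])
                right = np.abs(tss[np.clip(idx, 0, tss.size - 1)] - grid)
                grid = grid[np.minimum(left, right) >= 2000]
            candidates.extend((chrom, int(p)) for p in grid)
        if len(candidates) < n_other:
            raise CapacityError("genome too small for the requested non-promoter peaks")
        order = rng.permutation(len(candidates))[:n_other]
        centres.extend(candidates[i] for i in order)

    classes = (
        ["true_promoter"] * n_true_promoter
        + ["true_distal"] * n_true_distal
        + ["low_signal"] * n_low_signal
        + ["discordant"] * n_discordant
    )

    rep_rows: dict[str, list] = {"rep1": [], "rep2": []}
    read_rows: dict[str, list] = {"rep1": [], "rep2": []}
    for i, ((chrom, centre), cls) in enumerate(zip(centres, classes)):
        region_id = f"peak{i:05d}"
        start = max(centre - half_width, 0)
        end = centre + half_width
        if cls in ("true_promoter", "true_distal"):
            means = (mean_depth, mean_depth)
            truth.true_peaks.append(region_id)
        elif cls == "low_signal":
            means = (low_signal_mean, low_signal_mean)
            truth.spurious_peaks[region_id] = "low_signal"
        else:
            # alternate the inflated replicate so library depths stay matched
            hi = mean_depth * discordant_ratio
            flip = len(truth.spurious_peaks) % 2 == 0
            means = (mean_depth, hi) if flip else (hi, mean_depth)
            truth.spurious_peaks[region_id] = "discordant"
        for rep, mu in zip(("rep1", "rep2"), means):
            count = int(_nb_draw(rng, mu, dispersion))
            jitter = int(rng.integers(-20, 21))
            rep_rows[rep].append((chrom, max(start + jitter, 0), end + jitter, region_id))
            if count:
                pos = rng.integers(start, end, size=count)
                read_rows[rep].extend((chrom, int(p)) for p in pos)

    peaks = {
        rep: pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
        .sort_values(["chrom", "start"])
        .reset_index(drop=True)
        for rep, rows in rep_rows.items()
    }
    reads = {
        rep: pd.DataFrame(rows, columns=["chrom", "pos"]) for rep, rows in read_rows.items()
    }
    return peaks["rep1"], peaks["rep2"], reads, truth


def simulate_counts(
    n_genes: int,
    n_reps_per_group: int,
    contrasts: tuple[str, str] = ("trr", "G9a"),
    de_fraction: float = 0.1,
    shared_de_fraction: float = 0.05,
    lfc: float = 2.0,
    dispersion: float = 0.05,
    lowly_expressed_fraction: float = 0.1,
    base_mean: float = 200.0,
    seed: int = 0,
) -> tuple[dict[str, CountMatrix], SimTruth]:
    """NB count matrices for two mutant-vs-control contrasts with shared DE genes.

    ``de_fraction`` of genes are differentially expressed in each contrast and
    ``shared_de_fraction`` of genes (a subset of both DE sets) are shared
    between contrasts; directions are assigned independently per contrast.
    ``lowly_expressed_fraction`` of genes have total expected counts below 10
    to exercise the background filter. DE genes have group means differing by
    exactly ``2**lfc``.
    """
    for name, v in [
        ("de_fraction", de_fraction),
        ("shared_de_fraction", shared_de_fraction),
        ("lowly_expressed_fraction", lowly_expressed_fraction),
    ]:
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must be in [0, 1]")
    if shared_de_fraction > de_fraction:
        raise ValueError("shared_de_fraction cannot exceed de_fraction")
    if n_reps_per_group < 2:
        raise ValueError("need >= 2 replicates per group")
    if dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    if de_fraction > 0 and lfc == 0:
        raise ValueError("a DE gene with zero log2 fold change is contradictory")
    if len(contrasts) != 2 or contrasts[0] == contrasts[1]:
        raise ValueError("two distinct contrast labels required")

    rng = np.random.default_rng(seed)
    genes = np.array([f"g{i:05d}" for i in range(n_genes)])
    n_de = int(round(de_fraction * n_genes))
    n_shared = int(round(shared_de_fraction * n_genes))
    n_low = int(round(lowly_expressed_fraction * n_genes))

    order = rng.permutation(n_genes)
    shared_idx = order[:n_shared]
    excl_a = order[n_shared:n_de]
    excl_b = order[n_de : 2 * n_de - n_shared]
    if 2 * n_de - n_shared > n_genes:
        raise ValueError("DE assignments exceed the number of genes")
    de_idx = {contrasts[0]: np.concatenate([shared_idx, excl_a]),
              contrasts[1]: np.concatenate([shared_idx, excl_b])}

    # baseline expression; a slice of genes forced below the background filter
    base = rng.lognormal(mean=np.log(base_mean), sigma=1.0, size=n_genes)
    de_all = np.unique(np.concatenate(list(de_idx.values()))) if n_de else np.array([], int)
    low_candidates = np.setdiff1d(order[::-1], de_all)[:n_low]
    base[low_candidates] = 9.0 / (2 * n_reps_per_group) / 2.0  # total expectation < 10

    matrices: dict[str, CountMatrix] = {}
    truth = SimTruth()
    for contrast in contrasts:
        direction = np.zeros(n_genes, dtype=int)
        idx = de_idx[contrast]
        if idx.size:
            direction[idx] = rng.choice([-1, 1], size=idx.size)
        true_lfc = direction * lfc
        mu_control = np.tile(base[:, None], (1, n_reps_per_group))
        mu_mutant = np.tile((base * 2.0**true_lfc)[:, None], (1, n_reps_per_group))
        counts = np.concatenate(
            [
                _nb_draw(rng, mu_control, dispersion),
                _nb_draw(rng, mu_mutant, dispersion),
            ],
            axis=1,
        )
        samples = [f"{contrast}_control_{j + 1}" for j in range(n_reps_per_group)] + [
            f"{contrast}_mutant_{j + 1}" for j in range(n_reps_per_group)
        ]
        conditions = ["control"] * n_reps_per_group + ["mutant"] * n_reps_per_group
        matrices[contrast] = CountMatrix(
            pd.DataFrame(counts, index=genes, columns=samples),
            pd.Series(conditions, index=samples),
        )
        status = np.where(direction > 0, "up", np.where(direction < 0, "down", "null"))
        truth.de_truth[contrast] = pd.DataFrame(
            {"gene_id": genes, "status": status, "true_log2fc": true_lfc}
        )
    return matrices, truth


def simulate_courtship(
    n_per_group: dict[str, tuple[int, int]],
    naive_mean: float = 0.7,
    trained_mean_by_genotype: dict[str, float] | None = None,
    concentration: float = 20.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, SimTruth]:
    """Beta-distributed courtship indices per genotype and condition.

    ``n_per_group`` maps genotype to (n_naive, n_trained). Fractions are drawn
    from Beta distributions parameterised by mean and concentration: a genotype
    that remembers training has a trained mean below its naive mean, giving a
    positive learning index (naive_mean - trained_mean) / naive_mean.
    """
    if not 0 < naive_mean < 1:
        raise ValueError("naive_mean must be in (0, 1)")
    if concentration <= 0:
        raise ValueError("concentration must be > 0")
    trained = trained_mean_by_genotype or {}
    for g, m in trained.items():
        if not 0 < m < 1:
            raise ValueError(f"trained mean for {g!r} must be in (0, 1)")

    rng = np.random.default_rng(seed)
    rows = []
    truth_rows = []
    for genotype, (n_naive, n_trained) in n_per_group.items():
        t_mean = trained.get(genotype, naive_mean)
        for condition, n, mean in [("naive", n_naive, naive_mean), ("trained", n_trained, t_mean)]:
            a, b = mean * concentration, (1 - mean) * concentration
            cis = rng.beta(a, b, size=n)
            rows.extend(
                (f"{genotype}_{condition}_{j + 1}", genotype, condition, float(ci))
                for j, ci in enumerate(cis)
            )
        truth_rows.append(
            (genotype, naive_mean, t_mean, (naive_mean - t_mean) / naive_mean)
        )
    table = pd.DataFrame(rows, columns=["fly_id", "genotype", "condition", "ci"])
    truth = SimTruth()
    truth.courtship_truth = pd.DataFrame(
        truth_rows, columns=["genotype", "naive_mean", "trained_mean", "true_li"]
    )
    return table, truth
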