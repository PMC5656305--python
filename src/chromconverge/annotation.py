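"""Peak-to-feature assignment, promoter enrichment, and TSS metaprofiles.

A peak is assigned by its midpoint: within the promoter window (closed,
+/- ``promoter_halfwidth`` of a TSS) it is a promoter peak of that gene;
failing that, the transcription-termination window, then the gene body, then
intergenic. With TSS/TES-only annotation the finer exon/intron/UTR categories
collapse into ``gene_body``. Enrichment compares category fractions against
width-matched random genomic positions; the metaprofile averages binned,
strand-oriented read counts across all TSSs.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .simulate import GenomeLayout

__all__ = [
    "assign_nearest_feature",
    "feature_enrichment",
    "tss_metaprofile",
    "genome_coverage_fraction",
    "promoter_genes",
]

CATEGORIES = ["promoter_tss", "tts", "gene_body", "intergenic"]


def _assign_positions(
    chroms: np.ndarray,
    mids: np.ndarray,
    annotation: pd.DataFrame,
    promoter_halfwidth: int,
) -> pd.DataFrame:
    """Category, nearest gene and signed TSS distance for midpoint positions."""
    ann = annotation.copy()
    ann["sign"] = np.where(ann["strand"] == "+", 1, -1)
    ann["body_start"] = np.minimum(ann["tss"], ann["tes"])
    ann["body_end"] = np.maximum(ann["tss"], ann["tes"])

    category = np.full(len(mids), "intergenic", dtype=object)
    nearest = np.full(len(mids), "", dtype=object)
    distance = np.full(len(mids), np.nan)

    for chrom in np.unique(chroms):
        sel = np.flatnonzero(chroms == chrom)
        sub = ann[ann["chrom"] == chrom]
        if sub.empty:
            continue
        pos = mids[sel]

        # nearest TSS; ties broken toward the lexicographically smaller gene_id
        order = np.lexsort((sub["gene_id"].to_numpy(), sub["tss"].to_numpy()))
        tss = sub["tss"].to_numpy()[order]
        sign = sub["sign"].to_numpy()[order]
        gids = sub["gene_id"].to_numpy()[order]
        idx = np.searchsorted(tss, pos)
        left = np.clip(idx - 1, 0, tss.size - 1)
        right = np.clip(idx, 0, tss.size - 1)
        d_left = np.abs(pos - tss[left])
        d_right = np.abs(tss[right] - pos)
        # on equal distance prefer the smaller gene_id of the two neighbours
        tie = d_left == d_right
        pick_left = (d_left < d_right) | (tie & (gids[left] <= gids[right]))
        best = np.where(pick_left, left, right)
        dist = (pos - tss[best]) * sign[best]
        nearest[sel] = gids[best]
        distance[sel] = dist

        is_promoter = np.abs(pos - tss[best]) <= promoter_halfwidth
        category[sel[is_promoter]] = "promoter_tss"

        # termination-site window, then gene body, for the rest
        rest = sel[~is_promoter]
        if rest.size:
            pos_r = mids[rest]
            tes_order = np.argsort(sub["tes"].to_numpy())
            tes = sub["tes"].to_numpy()[tes_order]
            i2 = np.searchsorted(tes, pos_r)
            l2 = np.clip(i2 - 1, 0, tes.size - 1)
            r2 = np.clip(i2, 0, tes.size - 1)
            d_tes = np.minimum(np.abs(pos_r - tes[l2]), np.abs(tes[r2] - pos_r))
            near_tes = d_tes <= promoter_halfwidth
            category[rest[near_tes]] = "tts"

            rest2 = rest[~near_tes]
            if rest2.size:
                pos_b = mids[rest2]
                b_order = np.argsort(sub["body_start"].to_numpy())
                b_start = sub["body_start"].to_numpy()[b_order]
                b_end = sub["body_end"].to_numpy()[b_order]
                j = np.searchsorted(b_start, pos_b, side="right") - 1
                inside = (j >= 0) & (pos_b < b_end[np.clip(j, 0, None)])
                category[rest2[inside]] = "gene_body"

    return pd.DataFrame(
        {"category": category, "nearest_gene": nearest, "tss_distance": distance}
    )


def assign_nearest_feature(
    peaks: pd.DataFrame,
    annotation: pd.DataFrame,
    promoter_halfwidth: int = 1000,
) -> pd.DataFrame:
    """Assign each peak (by midpoint) to a feature category and nearest gene.

    The signed TSS distance is transcription-oriented: negative values lie
    upstream of the TSS. Returns one row per peak with peak name, category,
    nearest_gene and tss_distance.
    """
    if annotation.empty:
        raise ValueError("annotation is empty")
    if peaks.empty:
        return pd.DataFrame(
            columns=["name", "chrom", "midpoint", "category", "nearest_gene", "tss_distance"]
        )
    mids = ((peaks["start"] + peaks["end"]) // 2).to_numpy()
    chroms = peaks["chrom"].to_numpy()
    assigned = _assign_positions(chroms, mids, annotation, promoter_halfwidth)
    names = peaks["name"] if "name" in peaks else pd.Series(
        [f"peak{i:05d}" for i in range(len(peaks))]
    )
    out = pd.DataFrame(
        {
            "name": names.to_numpy(),
            "chrom": chroms,
            "midpoint": mids,
        }
    )
    return pd.concat([out, assigned], axis=1)


def promoter_genes(assignments: pd.DataFrame) -> list[str]:
    """Unique genes with at least one promoter-assigned peak, sorted."""
    sub = assignments[assignments["category"] == "promoter_tss"]
    return sorted(sub["nearest_gene"].unique())


def feature_enrichment(
    assignments: pd.DataFrame,
    annotation: pd.DataFrame,
    layout: GenomeLayout,
    peaks: pd.DataFrame,
    n_random: int = 50_000,
    promoter_halfwidth: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-category fold enrichment of peaks over random genomic positions.

    Random positions are width-matched (widths resampled from the peaks) and
    placed uniformly, chromosomes weighted by length. A category with zero
    random mass reports +inf with a warning.
    """
    if assignments.empty:
        raise ValueError("no peaks to test")
    if n_random < len(assignments):
        raise ValueError("n_random must be >= number of peaks")
    rng = np.random.default_rng(seed)

    widths = (peaks["end"] - peaks["start"]).to_numpy()
    rand_widths = rng.choice(widths, size=n_random, replace=True)
    chrom_names = list(layout.chrom_lengths)
    lengths = np.array([layout.chrom_lengths[c] for c in chrom_names], dtype=float)
    chrom_idx = rng.choice(len(chrom_names), size=n_random, p=lengths / lengths.sum())
    chrom_arr = np.array(chrom_names, dtype=object)[chrom_idx]
    max_start = np.maximum(lengths[chrom_idx] - rand_widths, 1)
    starts = (rng.random(n_random) * max_start).astype(int)
    rand_mids = starts + rand_widths // 2

    rand_assign = _assign_positions(chrom_arr, rand_mids, annotation, promoter_halfwidth)

    obs = assignments["category"].value_counts(normalize=True)
    ran = rand_assign["category"].value_counts(normalize=True)
    rows = []
    for cat in CATEGORIES:
        o = float(obs.get(cat, 0.0))
        r = float(ran.get(cat, 0.0))
        if r == 0.0 and o > 0.0:
            warnings.warn(f"category {cat!r} has zero random mass; fold is +inf",
                          stacklevel=2)
            fold = np.inf
        elif r == 0.0:
            fold = np.nan
        else:
            fold = o / r
        rows.append((cat, o, r, fold))
    return pd.DataFrame(
        rows, columns=["category", "observed_fraction", "random_fraction", "fold"]
    )


def tss_metaprofile(
    reads: pd.DataFrame,
    annotation: pd.DataFrame,
    bin_size: int = 50,
    window: int = 2000,
) -> pd.DataFrame:
    """Average strand-oriented read occupancy in bins around every TSS.

    Counts in [tss - window/2, tss + window/2) are binned after flipping minus-
    strand genes so bins run upstream -> downstream, averaged over genes, and
    scaled per million total reads. Returns (bin_offset, mean_occupancy) with
    bin_offset the bin's left edge relative to the TSS.
    """
    if window % bin_size:
        raise ValueError("window must be a multiple of bin_size")
    if annotation.empty:
        raise ValueError("annotation is empty")
    n_bins = window // bin_size
    half = window // 2
    total = np.zeros(n_bins)
    total_reads = len(reads)
    by_chrom = {c: np.sort(s["pos"].to_numpy()) for c, s in reads.groupby("chrom")}
    for _, gene in annotation.iterrows():
        pos = by_chrom.get(gene["chrom"])
        if pos is None:
            continue
        tss = int(gene["tss"])
        if gene["strand"] == "+":
            lo, hi = np.searchsorted(pos, [tss - half, tss + half])
            offsets = pos[lo:hi] - tss
        else:
            # oriented window (tss-half, tss+half] maps onto [-half, half)
            lo, hi = np.searchsorted(pos, [tss - half, tss + half], side="right")
            offsets = tss - pos[lo:hi]
        if hi == lo:
            continue
        bins = (offsets + half) // bin_size
        np.add.at(total, np.clip(bins, 0, n_bins - 1), 1)
    mean = total / max(len(annotation), 1)
    scale = 1e6 / total_reads if total_reads else 0.0
    return pd.DataFrame(
        {
            "bin_offset": bin_size * np.arange(n_bins) - half,
            "mean_occupancy": mean * scale,
        }
    )


def genome_coverage_fraction(peaks: pd.DataFrame, layout: GenomeLayout) -> float:
    """Fraction of the genome covered by (disjoint) peaks."""
    if peaks.empty:
        return 0.0
    covered = (peaks["end"] - peaks["start"]).sum()
    return float(covered) / layout.total_length
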