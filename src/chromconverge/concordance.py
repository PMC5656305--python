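"""Replicate-concordance filtering of ChIP peak calls.

The cascade merges the two replicates' peak calls into one set of candidate
binding regions, counts reads per region in each replicate, rescales counts to
a common library size, and keeps regions whose mean normalized count exceeds a
read threshold and whose replicate ratio stays below a fold threshold (both
strict). An optional k-means QC step on centred read-intensity profiles flags
clusters with unusually weak signal at the peak centre.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

__all__ = [
    "ConcordanceThresholds",
    "merge_regions",
    "count_reads_in_regions",
    "normalize_to_library_size",
    "concordance_filter",
    "cluster_qc",
    "run_concordance",
    "map_regions_to_sources",
]


@dataclass(frozen=True)
class ConcordanceThresholds:
    """Strict thresholds: keep iff mean > min_mean and ratio < max_ratio."""

    min_mean: float = 100.0
    max_ratio: float = 2.0

    def __post_init__(self):
        if self.min_mean < 0:
            raise ValueError("min_mean must be >= 0")
        if self.max_ratio <= 1:
            raise ValueError("max_ratio must be > 1")


def _validate_intervals(df: pd.DataFrame) -> None:
    if df.empty:
        return
    bad = df["start"] >= df["end"]
    if bad.any():
        row = df[bad].iloc[0]
        raise ValueError(
            f"malformed interval {row['chrom']}:{row['start']}-{row['end']} (start >= end)"
        )


def merge_regions(peaks_rep1: pd.DataFrame, peaks_rep2: pd.DataFrame) -> pd.DataFrame:
    """Union of both replicates' intervals as disjoint, sorted regions.

    Book-ended intervals ([a,b) and [b,c)) are merged. Output columns:
    chrom, start, end, name (region ids ``region00000``...).
    """
    frames = [df for df in (peaks_rep1, peaks_rep2) if df is not None and not df.empty]
    if not frames:
        return pd.DataFrame(columns=["chrom", "start", "end", "name"])
    combined = pd.concat(
        [df[["chrom", "start", "end"]] for df in frames], ignore_index=True
    )
    _validate_intervals(combined)
    combined = combined.sort_values(["chrom", "start", "end"]).reset_index(drop=True)

    rows = []
    for chrom, sub in combined.groupby("chrom", sort=True):
        starts = sub["start"].to_numpy()
        ends = np.maximum.accumulate(sub["end"].to_numpy())
        # a new block starts where an interval begins beyond the running max end
        new_block = np.concatenate([[True], starts[1:] > ends[:-1]])
        block = np.cumsum(new_block) - 1
        for b in range(block[-1] + 1):
            sel = block == b
            rows.append((chrom, int(starts[sel].min()), int(ends[sel].max())))
    merged = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    merged = merged.sort_values(["chrom", "start"]).reset_index(drop=True)
    merged["name"] = [f"region{i:05d}" for i in range(len(merged))]
    return merged


def map_regions_to_sources(
    merged: pd.DataFrame, *sources: pd.DataFrame
) -> dict[str, set[str]]:
    """Map each merged region to the names of the source peaks it covers.

    Useful for scoring recovery against a simulation truth whose ids live on
    the per-replicate tables that were merged.
    """
    out: dict[str, set[str]] = {name: set() for name in merged["name"]}
    for source in sources:
        if source is None or source.empty or "name" not in source:
            continue
        for chrom, msub in merged.groupby("chrom"):
            ssub = source[source["chrom"] == chrom]
            if ssub.empty:
                continue
            m_start = msub["start"].to_numpy()
            m_end = msub["end"].to_numpy()
            order = np.argsort(m_start)
            for s_start, s_end, s_name in zip(
                ssub["start"], ssub["end"], ssub["name"]
            ):
                i = np.searchsorted(m_start[order], s_start, side="right") - 1
                for j in (i, i + 1):
                    if 0 <= j < len(order):
                        k = order[j]
                        if s_start < m_end[k] and m_start[k] < s_end:
                            out[msub["name"].iloc[k]].add(s_name)
    return out


def count_reads_in_regions(
    regions: pd.DataFrame, reads: dict[str, pd.DataFrame]
) -> pd.DataFrame:
    """Count 5' read coordinates falling in each half-open region, per sample.

    Regions must be disjoint (each read lands in at most one region).
    """
    _validate_intervals(regions)
    out = pd.DataFrame(0, index=regions["name"], columns=list(reads), dtype=int)
    for sample, table in reads.items():
        if table.empty:
            continue
        for chrom, sub in regions.groupby("chrom"):
            pos = np.sort(table.loc[table["chrom"] == chrom, "pos"].to_numpy())
            if pos.size == 0:
                continue
            lo = np.searchsorted(pos, sub["start"].to_numpy(), side="left")
            hi = np.searchsorted(pos, sub["end"].to_numpy(), side="left")
            out.loc[sub["name"], sample] = hi - lo
    return out


def normalize_to_library_size(
    raw: pd.DataFrame, library_sizes: dict[str, float] | pd.Series
) -> pd.DataFrame:
    """Rescale counts so both replicates sit at the mean library size."""
    libs = pd.Series(library_sizes).astype(float).loc[raw.columns]
    if (libs <= 0).any():
        raise ValueError("library sizes must be > 0")
    return raw * (libs.mean() / libs)


def concordance_filter(
    peaks: pd.DataFrame,
    thresholds: ConcordanceThresholds = ConcordanceThresholds(),
    count_cols: tuple[str, str] = ("norm_rep1", "norm_rep2"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split peaks into (kept, rejected) on mean and replicate ratio.

    Adds ``mean``, ``ratio`` and ``qc_flags`` columns. A region with one zero
    count has ratio +inf (rejected, high_ratio); with both zero the ratio is
    undefined and the region is rejected with low_mean.
    """
    a = peaks[count_cols[0]].to_numpy(dtype=float)
    b = peaks[count_cols[1]].to_numpy(dtype=float)
    mean = (a + b) / 2.0
    hi, lo = np.maximum(a, b), np.minimum(a, b)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        ratio = np.where(lo > 0, hi / lo, np.where(hi > 0, np.inf, np.nan))

    low_mean = ~(mean > thresholds.min_mean)
    high_ratio = ~(ratio < thresholds.max_ratio) & ~np.isnan(ratio)
    both_zero = np.isnan(ratio)

    flags = []
    for lm, hr, bz in zip(low_mean, high_ratio, both_zero):
        f = set()
        if lm or bz:
            f.add("low_mean")
        if hr:
            f.add("high_ratio")
        flags.append(",".join(sorted(f)))

    annotated = peaks.copy()
    annotated["mean"] = mean
    annotated["ratio"] = ratio
    annotated["qc_flags"] = flags
    existing = annotated.get("qc_flags_prior")
    if existing is not None:
        merged = [
            ",".join(sorted(set(filter(None, f"{a0},{b0}".split(",")))))
            for a0, b0 in zip(existing.fillna(""), annotated["qc_flags"])
        ]
        annotated["qc_flags"] = merged
        annotated = annotated.drop(columns=["qc_flags_prior"])
    rejected_mask = annotated["qc_flags"].str.len() > 0
    return annotated[~rejected_mask].copy(), annotated[rejected_mask].copy()


def _profiles(
    peaks: pd.DataFrame,
    reads: dict[str, pd.DataFrame],
    bin_size: int,
    window: int,
) -> np.ndarray:
    """Binned read-intensity profile in +/- window/2 around each peak midpoint."""
    n_bins = window // bin_size
    half = window // 2
    prof = np.zeros((len(peaks), n_bins))
    mids = ((peaks["start"] + peaks["end"]) // 2).to_numpy()
    chroms = peaks["chrom"].to_numpy()
    pooled = pd.concat(list(reads.values()), ignore_index=True) if reads else pd.DataFrame(
        columns=["chrom", "pos"]
    )
    by_chrom = {c: np.sort(s["pos"].to_numpy()) for c, s in pooled.groupby("chrom")}
    for i, (chrom, mid) in enumerate(zip(chroms, mids)):
        pos = by_chrom.get(chrom)
        if pos is None:
            continue
        edges = mid - half + bin_size * np.arange(n_bins + 1)
        prof[i] = np.diff(np.searchsorted(pos, edges))
    return prof


def cluster_qc(
    peaks: pd.DataFrame,
    reads: dict[str, pd.DataFrame],
    k: int = 8,
    bin_size: int = 50,
    window: int = 1000,
    seed: int = 0,
    weak_fraction: float = 0.25,
) -> tuple[pd.Series, list[int]]:
    """K-means on centred read profiles; flag clusters weak at the centre.

    A cluster is flagged when its mean centre-bin intensity falls below
    ``weak_fraction`` of the global mean centre-bin intensity. Returns the
    cluster label per peak and the flagged cluster ids.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if window % bin_size:
        raise ValueError("window must be a multiple of bin_size")
    if k > len(peaks):
        raise ValueError(f"k={k} exceeds the number of peaks ({len(peaks)})")
    prof = _profiles(peaks, reads, bin_size, window)
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    labels = km.fit_predict(np.log1p(prof))
    centre = prof[:, prof.shape[1] // 2]
    global_centre = centre.mean()
    flagged = [
        c
        for c in range(k)
        if centre[labels == c].mean() < weak_fraction * global_centre
    ]
    return pd.Series(labels, index=peaks.index, name="cluster"), flagged


def run_concordance(
    peaks_rep1: pd.DataFrame,
    peaks_rep2: pd.DataFrame,
    reads: dict[str, pd.DataFrame],
    thresholds: ConcordanceThresholds = ConcordanceThresholds(),
    exclude_chroms: tuple[str, ...] = (),
    cluster_k: int | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full cascade: merge -> count -> normalize -> (cluster QC) -> filter.

    Returns (kept, rejected) region tables with counts, mean, ratio, flags.
    Library sizes are the total read counts of each replicate.
    """
    merged = merge_regions(peaks_rep1, peaks_rep2)
    if exclude_chroms:
        merged = merged[~merged["chrom"].isin(exclude_chroms)].reset_index(drop=True)
    if merged.empty:
        empty = merged.assign(mean=[], ratio=[], qc_flags=[])
        return empty, empty.copy()
    raw = count_reads_in_regions(merged, reads)
    libs = {s: max(len(t), 1) for s, t in reads.items()}
    norm = normalize_to_library_size(raw, libs)
    rep1, rep2 = list(reads)[:2]
    table = merged.assign(
        raw_rep1=raw[rep1].to_numpy(),
        raw_rep2=raw[rep2].to_numpy(),
        norm_rep1=norm[rep1].to_numpy(),
        norm_rep2=norm[rep2].to_numpy(),
    )
    if cluster_k is not None and cluster_k <= len(table):
        labels, flagged = cluster_qc(table, reads, k=cluster_k, seed=seed)
        table["cluster"] = labels
        table["qc_flags_prior"] = np.where(
            labels.isin(flagged), "bad_cluster", ""
        )
    return concordance_filter(table, thresholds)
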