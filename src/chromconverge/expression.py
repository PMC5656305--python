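"""Background filtering and a minimal negative-binomial differential-expression stage.

The test is a deliberately small two-group NB procedure: median-of-ratios size
factors, method-of-moments gene-wise dispersions shrunk toward a fitted
mean-dispersion trend, and a Wald-type test on the log2 fold change with the
NB variance. It applies the classic thresholds (BH-adjusted p < alpha and
|fold change| beyond a multiplicative cutoff) but makes no claim of numerical
equivalence with full GLM-based DE packages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CountMatrix",
    "background_filter",
    "size_factors",
    "nb_de_test",
    "sample_distance_qc",
]


@dataclass
class CountMatrix:
    """Gene-by-sample integer counts with a condition label per sample."""

    counts: pd.DataFrame
    conditions: pd.Series

    def __post_init__(self):
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate gene ids")
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        missing = set(self.counts.columns) - set(self.conditions.index)
        if missing:
            raise ValueError(f"unlabeled samples: {sorted(missing)}")
        self.conditions = self.conditions.loc[self.counts.columns]
        values = self.counts.to_numpy()
        if (values < 0).any():
            raise ValueError("negative counts")
        if not np.issubdtype(values.dtype, np.integer):
            if not (values == np.round(values)).all():
                raise ValueError("counts must be integral")
            self.counts = self.counts.astype(int)

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def subset_genes(self, genes) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(genes)], self.conditions.copy())


def background_filter(
    cm: CountMatrix, min_total: int = 10
) -> tuple[list[str], list[str]]:
    """Split genes into (background, excluded) by total raw count.

    A gene is excluded iff its total count across all samples is strictly
    below ``min_total``; a gene at exactly the threshold is kept.
    """
    if cm.counts.empty:
        raise ValueError("empty count matrix")
    totals = cm.counts.sum(axis=1)
    keep = totals >= min_total
    return list(cm.counts.index[keep]), list(cm.counts.index[~keep])


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (geometric-mean reference)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        log_counts = np.log(counts.to_numpy(dtype=float))
        log_ref = log_counts.mean(axis=1)
    usable = np.isfinite(log_ref)
    if not usable.any():
        raise ValueError("no gene has non-zero counts in every sample")
    ratios = log_counts[usable] - log_ref[usable, None]
    sf = np.exp(np.median(ratios, axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def _dispersion_trend(means: np.ndarray, disps: np.ndarray) -> np.ndarray:
    """Fit d(mu) = a0 + a1/mu by least squares on gene-wise estimates."""
    ok = (means > 0) & np.isfinite(disps)
    if ok.sum() < 2:
        return np.full_like(means, max(float(np.nanmean(disps)), 1e-8))
    X = np.column_stack([np.ones(ok.sum()), 1.0 / means[ok]])
    coef, *_ = np.linalg.lstsq(X, disps[ok], rcond=None)
    with np.errstate(divide="ignore"):
        trend = coef[0] + coef[1] / np.maximum(means, 1e-8)
    return np.clip(trend, 1e-8, None)


def nb_de_test(
    cm: CountMatrix,
    alpha: float = 0.05,
    fc_threshold: float = 1.5,
    control: str = "control",
    treatment: str | None = None,
) -> pd.DataFrame:
    """Two-group NB Wald test with a fold-change threshold.

    Returns one row per gene: baseMean, log2fc (treatment vs control), p, padj
    (Benjamini-Hochberg) and status in {up, down, ns}. ``up`` means
    padj < alpha and 2**log2fc > fc_threshold; ``down`` the mirror image.
    """
    labels = cm.conditions
    groups = [g for g in pd.unique(labels) if g != control]
    if control not in set(labels):
        raise ValueError(f"no samples labeled {control!r}")
    if treatment is None:
        if len(groups) != 1:
            raise ValueError("specify treatment when more than two conditions exist")
        treatment = groups[0]
    c_cols = labels.index[labels == control]
    t_cols = labels.index[labels == treatment]
    if len(c_cols) < 2 or len(t_cols) < 2:
        raise ValueError("each condition needs >= 2 samples")

    sf = size_factors(cm.counts)
    norm = cm.counts.to_numpy(dtype=float) / sf.to_numpy()[None, :]
    c_idx = [cm.samples.index(s) for s in c_cols]
    t_idx = [cm.samples.index(s) for s in t_cols]
    nc, nt = len(c_idx), len(t_idx)

    mu_c = norm[:, c_idx].mean(axis=1)
    mu_t = norm[:, t_idx].mean(axis=1)
    base_mean = norm.mean(axis=1)

    # method-of-moments dispersion pooled over within-group residuals
    var_within = (
        norm[:, c_idx].var(axis=1, ddof=1) * (nc - 1)
        + norm[:, t_idx].var(axis=1, ddof=1) * (nt - 1)
    ) / (nc + nt - 2)
    grand_mu = (mu_c * nc + mu_t * nt) / (nc + nt)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp_gene = (var_within - grand_mu) / grand_mu**2
    disp_gene = np.clip(np.nan_to_num(disp_gene, nan=1e-8), 1e-8, None)
    disp = np.clip(
        0.5 * (disp_gene + _dispersion_trend(grand_mu, disp_gene)), 1e-8, None
    )

    # half-count floor keeps the log defined for all-zero groups
    eps = 0.5
    mu_c_s = np.maximum(mu_c, eps)
    mu_t_s = np.maximum(mu_t, eps)
    log2fc = np.log2(mu_t_s / mu_c_s)

    inv_sf = 1.0 / sf.to_numpy()
    # Var(mean of normalized counts) with NB variance mu*s + d*(mu*s)^2 per sample
    var_mean_c = (mu_c_s * inv_sf[c_idx].sum() / nc**2) + disp * mu_c_s**2 / nc
    var_mean_t = (mu_t_s * inv_sf[t_idx].sum() / nt**2) + disp * mu_t_s**2 / nt
    se_log2fc = np.sqrt(var_mean_c / mu_c_s**2 + var_mean_t / mu_t_s**2) / np.log(2)

    with np.errstate(divide="ignore", invalid="ignore"):
        wald = log2fc / se_log2fc
    p = 2 * stats.norm.sf(np.abs(wald))
    p = np.where(np.isfinite(p), p, 1.0)
    # identical group means give a zero statistic, not a NaN
    p[se_log2fc == 0] = 1.0

    padj = multipletests(p, method="fdr_bh")[1]
    fc = 2.0**log2fc
    status = np.where(
        (padj < alpha) & (fc > fc_threshold),
        "up",
        np.where((padj < alpha) & (fc < 1.0 / fc_threshold), "down", "ns"),
    )
    return pd.DataFrame(
        {
            "gene_id": cm.genes,
            "baseMean": base_mean,
            "log2fc": log2fc,
            "p": p,
            "padj": padj,
            "status": status,
        }
    ).set_index("gene_id", drop=False)


def sample_distance_qc(cm: CountMatrix) -> dict:
    """Sample-level QC: distances, correlations, and a dendrogram leaf order.

    Counts are transformed as log2(normalized + 1) — a documented stand-in for
    a variance-stabilizing transform — then Euclidean distances and Pearson
    correlations are computed between samples, with average-linkage ordering.
    """
    if len(cm.samples) < 2:
        raise ValueError("need >= 2 samples")
    try:
        sf = size_factors(cm.counts)
        norm = cm.counts.to_numpy(dtype=float) / sf.to_numpy()[None, :]
    except ValueError:
        norm = cm.counts.to_numpy(dtype=float)
    logged = np.log2(norm + 1.0).T  # samples x genes

    dist = squareform(pdist(logged, metric="euclidean"))
    distances = pd.DataFrame(dist, index=cm.samples, columns=cm.samples)

    correlations = None
    if logged.shape[1] < 2 or np.allclose(logged.std(axis=1), 0):
        warnings.warn("correlation undefined (fewer than 2 varying genes); omitted",
                      stacklevel=2)
    else:
        correlations = pd.DataFrame(
            np.corrcoef(logged), index=cm.samples, columns=cm.samples
        )

    order = [cm.samples[i] for i in leaves_list(average(pdist(logged)))]
    return {"distances": distances, "correlations": correlations, "linkage_order": order}
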