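"""Courtship-conditioning statistics.

The courtship index (CI) is the fraction of a fixed observation period a male
spends courting; the learning index LI = (mean naive CI - mean trained CI) /
mean naive CI measures memory-dependent courtship suppression. Within a
genotype, naive and trained groups are compared with a Mann-Whitney test;
between genotypes, the difference in LI is tested with a seeded bootstrap
randomization test against a condition-wise pooled null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LearningResult",
    "learning_index",
    "mann_whitney_ci",
    "randomization_test_li",
    "genotype_summary",
]


@dataclass(frozen=True)
class LearningResult:
    genotype: str
    mean_ci_naive: float
    mean_ci_trained: float
    li: float
    n_naive: int
    n_trained: int
    mann_whitney_u: float
    mann_whitney_p: float
    mann_whitney_method: str


def learning_index(naive_cis, trained_cis) -> float:
    """LI from group means; negative when trained flies court more."""
    naive = np.asarray(naive_cis, dtype=float)
    trained = np.asarray(trained_cis, dtype=float)
    if naive.size == 0 or trained.size == 0:
        raise ValueError("both groups must be non-empty")
    mean_naive = naive.mean()
    if mean_naive <= 0:
        raise ValueError("mean naive CI is zero; LI undefined")
    return float((mean_naive - trained.mean()) / mean_naive)


def mann_whitney_ci(group_a, group_b) -> tuple[float, float, str]:
    """Mann-Whitney U with exact p for small untied samples.

    Exact enumeration when the combined n <= 12 and there are no ties;
    otherwise the normal approximation with tie and continuity corrections.
    Returns (U, two-sided p, method).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    if a.size + b.size <= 12 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    if np.array_equal(np.sort(a), np.sort(b)) and has_ties and np.unique(a).size == 1:
        # fully tied constant groups: U is central, no evidence either way
        return float(a.size * b.size / 2), 1.0, "degenerate"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue), method


def _li_from_pool(naive_pool, trained_pool, idx_naive, idx_trained):
    """Vectorised LI for resampled index matrices (replicates x n)."""
    mean_naive = naive_pool[idx_naive].mean(axis=1)
    mean_trained = trained_pool[idx_trained].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return (mean_naive - mean_trained) / mean_naive


def randomization_test_li(
    observations: pd.DataFrame,
    genotype_a: str,
    genotype_b: str,
    n_replicates: int = 10_000,
    seed: int = 0,
    scheme: str = "bootstrap",
) -> dict:
    """Bootstrap randomization test of the LI difference between genotypes.

    Under the null the genotypes share one CI distribution per condition, so
    the naive CIs of both genotypes are pooled, as are the trained CIs.
    Each replicate resamples (with replacement, ``scheme='bootstrap'``; or by
    label permutation, ``scheme='permutation'``) groups of the original
    per-genotype-per-condition sizes and recomputes the LI difference. The
    two-sided p uses the (1 + exceedances) / (1 + replicates) estimator, so
    p is never exactly zero.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if scheme not in ("bootstrap", "permutation"):
        raise ValueError("scheme must be 'bootstrap' or 'permutation'")
    groups = {}
    for genotype in (genotype_a, genotype_b):
        sub = observations[observations["genotype"] == genotype]
        for condition in ("naive", "trained"):
            cis = sub.loc[sub["condition"] == condition, "ci"].to_numpy(dtype=float)
            if cis.size == 0:
                raise ValueError(f"genotype {genotype!r} has no {condition} flies")
            groups[(genotype, condition)] = cis

    li_a = learning_index(groups[(genotype_a, "naive")], groups[(genotype_a, "trained")])
    li_b = learning_index(groups[(genotype_b, "naive")], groups[(genotype_b, "trained")])
    observed = li_a - li_b

    naive_pool = np.concatenate(
        [groups[(genotype_a, "naive")], groups[(genotype_b, "naive")]]
    )
    trained_pool = np.concatenate(
        [groups[(genotype_a, "trained")], groups[(genotype_b, "trained")]]
    )
    n_an, n_bn = len(groups[(genotype_a, "naive")]), len(groups[(genotype_b, "naive")])
    n_at, n_bt = len(groups[(genotype_a, "trained")]), len(groups[(genotype_b, "trained")])

    rng = np.random.default_rng(seed)
    B = n_replicates
    if scheme == "bootstrap":
        idx_an = rng.integers(0, naive_pool.size, size=(B, n_an))
        idx_bn = rng.integers(0, naive_pool.size, size=(B, n_bn))
        idx_at = rng.integers(0, trained_pool.size, size=(B, n_at))
        idx_bt = rng.integers(0, trained_pool.size, size=(B, n_bt))
    else:
        perm_n = np.argsort(rng.random((B, naive_pool.size)), axis=1)
        perm_t = np.argsort(rng.random((B, trained_pool.size)), axis=1)
        idx_an, idx_bn = perm_n[:, :n_an], perm_n[:, n_an:]
        idx_at, idx_bt = perm_t[:, :n_at], perm_t[:, n_at:]

    null_a = _li_from_pool(naive_pool, trained_pool, idx_an, idx_at)
    null_b = _li_from_pool(naive_pool, trained_pool, idx_bn, idx_bt)
    null = null_a - null_b
    null = null[np.isfinite(null)]
    exceed = int(np.sum(np.abs(null) >= abs(observed)))
    p = (1 + exceed) / (1 + len(null))
    return {
        "delta_li": float(observed),
        "li_a": float(li_a),
        "li_b": float(li_b),
        "p": float(p),
        "n_replicates": int(len(null)),
        "scheme": scheme,
    }


def genotype_summary(observations: pd.DataFrame) -> list[LearningResult]:
    """Per-genotype means, LI and within-genotype Mann-Whitney comparison."""
    results = []
    for genotype, sub in observations.groupby("genotype", sort=True):
        naive = sub.loc[sub["condition"] == "naive", "ci"].to_numpy(dtype=float)
        trained = sub.loc[sub["condition"] == "trained", "ci"].to_numpy(dtype=float)
        if naive.size == 0 or trained.size == 0:
            raise ValueError(f"genotype {genotype!r} is missing a condition")
        u, p, method = mann_whitney_ci(naive, trained)
        results.append(
            LearningResult(
                genotype=str(genotype),
                mean_ci_naive=float(naive.mean()),
                mean_ci_trained=float(trained.mean()),
                li=learning_index(naive, trained),
                n_naive=int(naive.size),
                n_trained=int(trained.size),
                mann_whitney_u=u,
                mann_whitney_p=p,
                mann_whitney_method=method,
            )
        )
    return results
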