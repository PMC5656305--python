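"""Gene-set convergence statistics.

Hypergeometric overlap tests (upper tail, enrichment), fold enrichments and
Venn counts; classification of differentially expressed genes into potentially
direct and potentially indirect targets of an activator or repressor; the
directional breakdown of shared DE genes; hub-gene intersection; and generic
gene-set enrichment with multiplicity correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSet",
    "OverlapResult",
    "hypergeom_overlap",
    "classify_targets",
    "directional_breakdown",
    "hub_genes",
    "set_enrichment",
]


@dataclass(frozen=True)
class GeneSet:
    label: str
    members: frozenset[str]

    def __post_init__(self):
        if not self.label:
            raise ValueError("label must be non-empty")
        object.__setattr__(self, "members", frozenset(self.members))

    def __len__(self):
        return len(self.members)


@dataclass(frozen=True)
class OverlapResult:
    """One hypergeometric overlap test: P(X >= k) for X ~ Hypergeom(N, K, n)."""

    K: int
    n: int
    k: int
    N: int
    expected: float
    fold: float
    p: float
    venn: tuple[int, int, int] = field(default=(0, 0, 0))  # (A only, A&B, B only)

    def as_dict(self) -> dict:
        return {
            "K": self.K, "n": self.n, "k": self.k, "N": self.N,
            "expected": self.expected, "fold": self.fold, "p": self.p,
            "venn_a_only": self.venn[0], "venn_shared": self.venn[1],
            "venn_b_only": self.venn[2],
        }


def hypergeom_overlap(
    set_a: GeneSet,
    set_b: GeneSet,
    universe: GeneSet,
    strict: bool = False,
    lower_tail: bool = False,
) -> OverlapResult:
    """Exact overlap test of two gene sets against a finite universe.

    ``p`` is the upper-tail probability P(X >= k) (enrichment); pass
    ``lower_tail=True`` for a depletion test. Genes outside the universe are
    added to it with a warning in lenient mode (the default) or raise in
    strict mode. The fold is the observed overlap over the independence
    expectation K*n/N.
    """
    if len(universe) == 0:
        raise ValueError("empty universe")
    members_u = set(universe.members)
    outside = (set_a.members | set_b.members) - members_u
    if outside:
        if strict:
            raise ValueError(
                f"genes outside the universe: {sorted(outside)[:10]}"
                + ("..." if len(outside) > 10 else "")
            )
        warnings.warn(
            f"{len(outside)} query genes absent from the universe were added to it",
            stacklevel=2,
        )
        members_u |= outside
    a = set_a.members & members_u
    b = set_b.members & members_u
    return overlap_from_counts(len(a), len(b), len(a & b), len(members_u), lower_tail)


def overlap_from_counts(
    K: int, n: int, k: int, N: int, lower_tail: bool = False
) -> OverlapResult:
    """Hypergeometric overlap test from the four counts directly."""
    if N <= 0:
        raise ValueError("universe size must be positive")
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError("set sizes must lie within the universe")
    if k > min(K, n) or k < max(0, K + n - N):
        raise ValueError(f"overlap k={k} impossible for K={K}, n={n}, N={N}")
    expected = K * n / N
    fold = k / expected if expected > 0 else float("nan")
    if lower_tail:
        p = float(stats.hypergeom.cdf(k, N, K, n))
    else:
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return OverlapResult(K, n, k, N, expected, fold, p, venn=(K - k, k, n - k))


def classify_targets(
    factor_mode: str,
    evidence: GeneSet,
    de: pd.DataFrame,
) -> pd.DataFrame:
    """Split a factor's DE genes into potentially direct and indirect targets.

    For an activator, direct targets are evidence-carrying genes that are
    downregulated on its loss; for a repressor, evidence-carrying genes that
    are upregulated. Every other DE gene is potentially indirect.
    """
    if factor_mode not in ("activator", "repressor"):
        raise ValueError("factor_mode must be 'activator' or 'repressor'")
    de_genes = de[de["status"] != "ns"]
    expected_direction = "down" if factor_mode == "activator" else "up"
    rows = []
    for gene, status in zip(de_genes["gene_id"], de_genes["status"]):
        direct = gene in evidence.members and status == expected_direction
        rows.append((gene, "potential_direct" if direct else "potential_indirect"))
    return pd.DataFrame(rows, columns=["gene_id", "class"])


def directional_breakdown(
    de_a: pd.DataFrame, de_b: pd.DataFrame, labels: tuple[str, str] = ("A", "B")
) -> dict:
    """2x2 direction table of genes DE in both contrasts, plus enrichment.

    Cells count shared DE genes by (direction in A) x (direction in B); the
    four cells always sum to the shared total. Per-cell fold is observed over
    the independence expectation from the margins; the two-sided Fisher exact
    p tests independence of the two directions.
    """
    a = de_a[de_a["status"] != "ns"].set_index("gene_id")["status"]
    b = de_b[de_b["status"] != "ns"].set_index("gene_id")["status"]
    shared = sorted(set(a.index) & set(b.index))
    table = pd.DataFrame(0, index=["up", "down"], columns=["up", "down"])
    for g in shared:
        table.loc[a[g], b[g]] += 1
    table.index.name = f"direction_{labels[0]}"
    table.columns.name = f"direction_{labels[1]}"
    total = int(table.to_numpy().sum())
    result = {"table": table, "shared_total": total}
    if total == 0:
        warnings.warn("no shared DE genes; enrichment undefined", stacklevel=2)
        result["fold"] = None
        result["fisher_p"] = None
        return result
    expected = (
        table.sum(axis=1).to_numpy()[:, None]
        * table.sum(axis=0).to_numpy()[None, :]
        / total
    )
    result["fold"] = table / expected
    result["fisher_p"] = float(stats.fisher_exact(table.to_numpy())[1])
    return result


def hub_genes(genomic_overlap: GeneSet, de_overlap: GeneSet) -> list[str]:
    """Genes that are both shared genomic targets and shared DE genes, sorted."""
    return sorted(genomic_overlap.members & de_overlap.members)


def set_enrichment(
    query: GeneSet,
    collections: list[GeneSet],
    universe: GeneSet,
    correction: str = "BH",
    strict: bool = False,
) -> pd.DataFrame:
    """One hypergeometric test per collection, with multiplicity correction."""
    if not collections:
        raise ValueError("collections must be non-empty")
    if correction not in ("BH", "bonferroni", "none"):
        raise ValueError("correction must be BH, bonferroni or none")
    rows = []
    for coll in collections:
        res = hypergeom_overlap(query, coll, universe, strict=strict)
        rows.append({"collection": coll.label, **res.as_dict()})
    out = pd.DataFrame(rows)
    if correction == "none":
        out["padj"] = out["p"]
    else:
        method = "fdr_bh" if correction == "BH" else "bonferroni"
        out["padj"] = multipletests(out["p"], method=method)[1]
    return out
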