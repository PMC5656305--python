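"""End-to-end orchestration: concordance -> annotation -> DE -> convergence.

A run is driven by one flat JSON config of input paths and thresholds. Every
stage logs its inputs, parameters and row counts; the run directory receives
each stage's table, the resolved config, a line-oriented log, and a
machine-readable ``summary.json`` with the headline numbers (filtered peak
count, promoter gene count, DE counts per contrast, overlap k/fold/p,
direct/indirect counts, hub genes, and optional behavioral statistics).
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import annotation as ann_mod
from . import behavior as behavior_mod
from . import concordance as conc_mod
from . import expression as expr_mod
from . import io as cc_io
from . import overlap as ov_mod
from .simulate import GenomeLayout

__all__ = ["ConfigError", "PipelineConfig", "run_pipeline"]


class ConfigError(ValueError):
    """The config is invalid; nothing has run."""


@dataclass
class PipelineConfig:
    """Paths and thresholds for one convergence run."""

    peaks_rep1: str
    peaks_rep2: str
    reads_rep1: str
    reads_rep2: str
    annotation: str
    chrom_sizes: str
    counts: dict[str, str]  # contrast label -> count-matrix TSV
    courtship: str | None = None
    courtship_genotypes: tuple[str, str] | None = None
    factor_modes: dict[str, str] = field(default_factory=dict)
    min_mean: float = 100.0
    max_ratio: float = 2.0
    promoter_halfwidth: int = 1000
    alpha: float = 0.05
    fc: float = 1.5
    min_total: int = 10
    n_random: int = 50_000
    n_replicates: int = 10_000
    seed: int = 0
    exclude_chroms: tuple[str, ...] = ()
    universe_strict: bool = False

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        try:
            cfg = cls(**raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.max_ratio <= 1:
            raise ConfigError("max_ratio must be > 1")
        if self.min_mean < 0:
            raise ConfigError("min_mean must be >= 0")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must be in (0, 1)")
        if self.fc <= 1:
            raise ConfigError("fc must be > 1")
        if self.promoter_halfwidth <= 0:
            raise ConfigError("promoter_halfwidth must be > 0")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")
        if len(self.counts) != 2:
            raise ConfigError("exactly two contrasts are expected")
        paths = [self.peaks_rep1, self.peaks_rep2, self.reads_rep1, self.reads_rep2,
                 self.annotation, self.chrom_sizes, *self.counts.values()]
        if self.courtship:
            paths.append(self.courtship)
        missing = [p for p in paths if not Path(p).exists()]
        if missing:
            raise ConfigError(f"missing input files: {missing}")

    def to_dict(self) -> dict:
        out = dict(self.__dict__)
        out["exclude_chroms"] = list(self.exclude_chroms)
        if self.courtship_genotypes:
            out["courtship_genotypes"] = list(self.courtship_genotypes)
        return out


def _read_layout(path: str | Path) -> GenomeLayout:
    sizes = pd.read_csv(path, sep="\t", names=["chrom", "length"], dtype={"chrom": str})
    return GenomeLayout(dict(zip(sizes["chrom"], sizes["length"].astype(int))))


def _load_count_matrix(path: str) -> expr_mod.CountMatrix:
    counts = cc_io.read_count_matrix(path)
    conditions = pd.Series(
        ["control" if "control" in s else "mutant" for s in counts.columns],
        index=counts.columns,
    )
    if set(conditions) != {"control", "mutant"}:
        raise ValueError(
            f"{path}: sample names must mark conditions with 'control'/'mutant'"
        )
    return expr_mod.CountMatrix(counts, conditions)


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run every stage in order and return the summary dictionary."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "pipeline.log"
    log_lines: list[str] = []

    def log(stage: str, message: str) -> None:
        line = f"{time.strftime('%Y-%m-%dT%H:%M:%S')}\t{stage}\t{message}"
        log_lines.append(line)
        log_path.write_text("".join(f"{ln}\n" for ln in log_lines))

    (out / "config.resolved.json").write_text(json.dumps(config.to_dict(), indent=2))
    summary: dict = {}
    stage = "setup"
    try:
        stage = "concordance"
        rep1 = cc_io.read_bed(config.peaks_rep1)
        rep2 = cc_io.read_bed(config.peaks_rep2)
        reads = {
            "rep1": cc_io.read_read_positions(config.reads_rep1),
            "rep2": cc_io.read_read_positions(config.reads_rep2),
        }
        log(stage, f"rep1={len(rep1)} rep2={len(rep2)} peaks; "
                   f"reads rep1={len(reads['rep1'])} rep2={len(reads['rep2'])}; "
                   f"min_mean={config.min_mean} max_ratio={config.max_ratio} "
                   f"exclude={list(config.exclude_chroms)}")
        thresholds = conc_mod.ConcordanceThresholds(config.min_mean, config.max_ratio)
        kept, rejected = conc_mod.run_concordance(
            rep1, rep2, reads, thresholds, exclude_chroms=config.exclude_chroms,
            seed=config.seed,
        )
        kept_bed = kept.rename(columns={"mean": "score"})
        cc_io.write_bed(kept_bed, out / "peaks.filtered.bed")
        qc = pd.concat([kept, rejected]).sort_values(["chrom", "start"])
        qc.to_csv(out / "peaks.qc.tsv", sep="\t", index=False)
        log(stage, f"kept={len(kept)} rejected={len(rejected)}")
        summary["filtered_peak_count"] = int(len(kept))

        stage = "annotation"
        annotation = cc_io.read_annotation(config.annotation)
        layout = _read_layout(config.chrom_sizes)
        assignments = ann_mod.assign_nearest_feature(
            kept, annotation, config.promoter_halfwidth
        )
        assignments.to_csv(out / "peaks.assignments.tsv", sep="\t", index=False)
        promoter = ann_mod.promoter_genes(assignments)
        cc_io.write_gene_list(promoter, out / "promoter_genes.txt")
        coverage = ann_mod.genome_coverage_fraction(kept, layout)
        log(stage, f"promoter_genes={len(promoter)} coverage={coverage:.4%} "
                   f"halfwidth={config.promoter_halfwidth}")
        summary["promoter_gene_count"] = len(promoter)
        summary["genome_coverage_fraction"] = coverage
        if len(assignments) and config.n_random >= len(assignments):
            enrich = ann_mod.feature_enrichment(
                assignments, annotation, layout, kept,
                n_random=config.n_random,
                promoter_halfwidth=config.promoter_halfwidth, seed=config.seed,
            )
            enrich.to_csv(out / "feature_enrichment.tsv", sep="\t", index=False)
            prom = enrich.set_index("category").loc["promoter_tss", "fold"]
            summary["promoter_fold_enrichment"] = float(prom)
            log(stage, f"promoter fold={prom:.3f} n_random={config.n_random}")

        stage = "differential_expression"
        de_tables: dict[str, pd.DataFrame] = {}
        summary["de"] = {}
        for contrast, path in config.counts.items():
            cm = _load_count_matrix(path)
            background, excluded = expr_mod.background_filter(cm, config.min_total)
            de = expr_mod.nb_de_test(
                cm.subset_genes(background), alpha=config.alpha,
                fc_threshold=config.fc,
            )
            de.to_csv(out / f"de.{contrast}.tsv", sep="\t", index=False)
            de_tables[contrast] = de
            n_up = int((de["status"] == "up").sum())
            n_down = int((de["status"] == "down").sum())
            summary["de"][contrast] = {
                "background": len(background),
                "excluded": len(excluded),
                "up": n_up,
                "down": n_down,
                "total": n_up + n_down,
            }
            log(stage, f"{contrast}: background={len(background)} "
                       f"excluded={len(excluded)} up={n_up} down={n_down} "
                       f"alpha={config.alpha} fc={config.fc}")

        stage = "classification"
        evidence = ov_mod.GeneSet("promoter_evidence", frozenset(promoter))
        summary["targets"] = {}
        for contrast, de in de_tables.items():
            mode = config.factor_modes.get(contrast, "activator")
            classified = ov_mod.classify_targets(mode, evidence, de)
            classified.to_csv(out / f"targets.{contrast}.tsv", sep="\t", index=False)
            counts = classified["class"].value_counts()
            summary["targets"][contrast] = {
                "mode": mode,
                "potential_direct": int(counts.get("potential_direct", 0)),
                "potential_indirect": int(counts.get("potential_indirect", 0)),
            }
            log(stage, f"{contrast} ({mode}): "
                       f"direct={counts.get('potential_direct', 0)} "
                       f"indirect={counts.get('potential_indirect', 0)}")

        stage = "overlap"
        (label_a, de_a), (label_b, de_b) = de_tables.items()
        universe_genes = set(de_a["gene_id"]) | set(de_b["gene_id"])
        universe = ov_mod.GeneSet("background", frozenset(universe_genes))
        set_a = ov_mod.GeneSet(
            label_a, frozenset(de_a.loc[de_a["status"] != "ns", "gene_id"])
        )
        set_b = ov_mod.GeneSet(
            label_b, frozenset(de_b.loc[de_b["status"] != "ns", "gene_id"])
        )
        result = ov_mod.hypergeom_overlap(
            set_a, set_b, universe, strict=config.universe_strict
        )
        breakdown = ov_mod.directional_breakdown(de_a, de_b, labels=(label_a, label_b))
        pd.DataFrame([result.as_dict()]).to_csv(
            out / "de_overlap.tsv", sep="\t", index=False
        )
        breakdown["table"].to_csv(out / "directional_breakdown.tsv", sep="\t")
        summary["de_overlap"] = result.as_dict()
        summary["directional_breakdown"] = {
            f"{a}_{b}": int(breakdown["table"].loc[a, b])
            for a in ("up", "down") for b in ("up", "down")
        }
        shared = ov_mod.GeneSet("shared_de", set_a.members & set_b.members)
        hubs = ov_mod.hub_genes(evidence, shared)
        cc_io.write_gene_list(hubs, out / "hub_genes.txt")
        summary["hub_genes"] = hubs
        log(stage, f"k={result.k} fold={result.fold:.3f} p={result.p:.3g} "
                   f"hubs={len(hubs)}")

        if config.courtship and config.courtship_genotypes:
            stage = "behavior"
            table = cc_io.read_courtship(config.courtship)
            geno_a, geno_b = config.courtship_genotypes
            rand = behavior_mod.randomization_test_li(
                table, geno_a, geno_b,
                n_replicates=config.n_replicates, seed=config.seed,
            )
            per_geno = {
                r.genotype: {
                    "li": r.li,
                    "mean_ci_naive": r.mean_ci_naive,
                    "mean_ci_trained": r.mean_ci_trained,
                    "mann_whitney_p": r.mann_whitney_p,
                }
                for r in behavior_mod.genotype_summary(table)
            }
            summary["behavior"] = {"genotypes": per_geno, "randomization": rand}
            log(stage, f"delta_li={rand['delta_li']:.3f} p={rand['p']:.4f} "
                       f"replicates={rand['n_replicates']}")
    except ConfigError:
        raise
    except Exception as exc:
        log(stage, f"FAILED: {exc}")
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    log("done", "summary written")
    return summary
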