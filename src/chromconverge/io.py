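"""Readers and writers for the plain-text formats the pipeline consumes.

Coordinates are 0-based half-open internally (BED convention). Annotation
tables whose coordinates are 1-based can be converted at the reader with
``one_based=True``. Malformed lines are reported with their line number.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import pandas as pd

__all__ = [
    "FormatError",
    "read_bed",
    "write_bed",
    "read_annotation",
    "write_annotation",
    "read_count_matrix",
    "write_count_matrix",
    "read_read_positions",
    "write_read_positions",
    "read_gene_list",
    "write_gene_list",
    "read_gmt",
    "read_courtship",
    "write_courtship",
]


class FormatError(ValueError):
    """A file violated its format contract; the message names the line."""


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED file into a DataFrame (chrom, start, end[, name, score, strand]).

    Track/browser/comment lines are ignored. Intervals with start >= end are
    rejected with the offending line number.
    """
    rows = []
    names = ["chrom", "start", "end", "name", "score", "strand"]
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: BED needs >= 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start >= end:
                raise FormatError(
                    f"{path}:{lineno}: start >= end ({start} >= {end})"
                )
            rows.append([fields[0], start, end, *fields[3:6]])
    if not rows:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    width = max(len(r) for r in rows)
    df = pd.DataFrame(rows, columns=names[:width])
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    if "score" in df.columns:
        df["score"] = pd.to_numeric(df["score"], errors="coerce")
    return df


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in ["chrom", "start", "end", "name", "score", "strand"] if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_annotation(path: str | Path, one_based: bool = False) -> pd.DataFrame:
    """Read a gene annotation TSV (gene_id, chrom, strand, tss, tes)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str, "strand": str})
    required = {"gene_id", "chrom", "strand", "tss", "tes"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: annotation missing columns {sorted(missing)}")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise FormatError(f"{path}: duplicate gene_id {dup!r}")
    bad = ~df["strand"].isin(["+", "-"])
    if bad.any():
        raise FormatError(f"{path}: invalid strand {df.loc[bad, 'strand'].iloc[0]!r}")
    if one_based:
        df = df.assign(tss=df["tss"] - 1, tes=df["tes"] - 1)
    return df


def write_annotation(df: pd.DataFrame, path: str | Path) -> None:
    df[["gene_id", "chrom", "strand", "tss", "tes"]].to_csv(path, sep="\t", index=False)


def read_count_matrix(path: str | Path, allow_float: bool = False) -> pd.DataFrame:
    """Read a gene-by-sample count matrix (first column gene ids, header row samples).

    Counts must be integral; ``allow_float=True`` rounds with a warning instead
    of raising.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    values = df.to_numpy()
    if not (values == values.round()).all():
        if not allow_float:
            raise FormatError(f"{path}: non-integer counts (pass allow_float to coerce)")
        warnings.warn(f"{path}: rounding non-integer counts", stacklevel=2)
    if (values < 0).any():
        raise FormatError(f"{path}: negative counts")
    return df.round().astype(int)


def write_count_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id")


def read_read_positions(path: str | Path) -> pd.DataFrame:
    """Read 5' read coordinates as a 2-column TSV (chrom, pos)."""
    df = pd.read_csv(path, sep="\t", names=["chrom", "pos"], dtype={"chrom": str})
    if df["pos"].isna().any():
        raise FormatError(f"{path}: missing read position")
    df["pos"] = df["pos"].astype(int)
    return df


def write_read_positions(df: pd.DataFrame, path: str | Path) -> None:
    df[["chrom", "pos"]].to_csv(path, sep="\t", header=False, index=False)


def read_gene_list(path: str | Path) -> list[str]:
    """One gene id per line; blank lines and # comments ignored."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line.split("\t")[0])
    return out


def write_gene_list(genes, path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in sorted(genes)))


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT gene-set collections: label, description, then members, tab separated."""
    collections: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT needs label, description, members")
            collections[fields[0]] = set(fields[2:])
    return collections


def read_courtship(path: str | Path) -> pd.DataFrame:
    """Tidy courtship table: fly_id, genotype, condition (naive|trained), ci in [0,1]."""
    df = pd.read_csv(path, sep="\t", dtype={"fly_id": str, "genotype": str, "condition": str})
    required = {"fly_id", "genotype", "condition", "ci"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: courtship table missing columns {sorted(missing)}")
    if not df["condition"].isin(["naive", "trained"]).all():
        raise FormatError(f"{path}: condition must be 'naive' or 'trained'")
    if ((df["ci"] < 0) | (df["ci"] > 1)).any():
        raise FormatError(f"{path}: courtship index outside [0, 1]")
    return df


def write_courtship(df: pd.DataFrame, path: str | Path) -> None:
    df[["fly_id", "genotype", "condition", "ci"]].to_csv(path, sep="\t", index=False)
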