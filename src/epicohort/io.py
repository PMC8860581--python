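"""Readers and writers for the tabular genomics formats the pipeline consumes.

All interval-bearing formats are converted to 0-based half-open coordinates on
read (NarrowPeak and BED are native; GTF is 1-based closed and shifted).
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable

import pandas as pd

NARROWPEAK_COLUMNS = [
    "chrom", "start", "end", "name", "score", "strand",
    "signalValue", "pValue", "qValue", "peak",
]


def read_narrowpeak(path: str | Path) -> pd.DataFrame:
    """Read an ENCODE NarrowPeak (BED6+4) file.

    Returns a DataFrame with the ten standard columns; an empty file yields an
    empty frame with the same schema.
    """
    path = Path(path)
    if path.stat().st_size == 0:
        return pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
            NARROWPEAK_COLUMNS,
            ["str", "int64", "int64", "str", "int64", "str",
             "float64", "float64", "float64", "int64"])})
    df = pd.read_csv(path, sep="\t", header=None, names=NARROWPEAK_COLUMNS,
                     comment="#")
    _check_intervals(df, path)
    return df


def write_narrowpeak(df: pd.DataFrame, path: str | Path) -> None:
    df = df.reindex(columns=NARROWPEAK_COLUMNS)
    df.to_csv(path, sep="\t", header=False, index=False)


def read_bed_segments(path: str | Path) -> pd.DataFrame:
    """Read a labelled BED (chrom, start, end, state) such as a ChromHMM
    segmentation. File order is preserved in a ``file_order`` column because
    downstream tie-breaking is first-in-file."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "state"],
                     usecols=[0, 1, 2, 3])
    df["file_order"] = range(len(df))
    _check_intervals(df, path)
    return df


def write_bed_segments(df: pd.DataFrame, path: str | Path) -> None:
    df[["chrom", "start", "end", "state"]].to_csv(
        path, sep="\t", header=False, index=False)


_GTF_ATTR = re.compile(r'(\w+) "([^"]*)"')


def read_gtf_genes(path: str | Path) -> pd.DataFrame:
    """Read gene records from a GTF file into 0-based half-open coordinates.

    Only rows with feature type ``gene`` are used; the ``gene_id`` attribute is
    required. Returns columns gene_id, chrom, start, end, strand.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != "gene":
                continue
            attrs = dict(_GTF_ATTR.findall(parts[8]))
            if "gene_id" not in attrs:
                raise ValueError(f"GTF gene record without gene_id: {line!r}")
            rows.append((attrs["gene_id"], parts[0],
                         int(parts[3]) - 1, int(parts[4]), parts[6]))
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end",
                                     "strand"])
    _check_intervals(df, path)
    return df


def write_gtf_genes(genes: pd.DataFrame, path: str | Path,
                    source: str = "epicohort") -> None:
    """Write gene models as GTF ``gene`` records (converting back to 1-based
    closed coordinates)."""
    with open(path, "w") as fh:
        for g in genes.itertuples(index=False):
            attrs = f'gene_id "{g.gene_id}";'
            fh.write("\t".join([
                g.chrom, source, "gene", str(g.start + 1), str(g.end),
                ".", g.strand, ".", attrs]) + "\n")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT gene-set file (name, description, members...)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            if parts[0] in sets:
                raise ValueError(f"duplicate gene-set name {parts[0]!r}")
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def write_gmt(sets: dict[str, Iterable[str]], path: str | Path,
              description: str = "epicohort") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *sorted(genes)]) + "\n")


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples count TSV (first column = gene id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.values < 0).any():
        raise ValueError(f"negative counts in {path}")
    return df


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a sample metadata TSV (sample_id, genotype, tissue, stage,
    replicate)."""
    df = pd.read_csv(path, sep="\t", dtype={"replicate": int})
    required = {"sample_id", "genotype", "tissue", "stage", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_ids in metadata")
    return df


def _check_intervals(df: pd.DataFrame, path: Path | str) -> None:
    if len(df) and (df["start"] >= df["end"]).any():
        bad = df[df["start"] >= df["end"]].iloc[0]
        raise ValueError(
            f"malformed interval in {path}: start {bad['start']} >= end "
            f"{bad['end']}")
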