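"""Readers and writers for the pipeline's plain-text exchange formats.

All stage inputs and outputs are tab-separated text: expression matrices
(first column gene id, header row of sample ids), two-column stage maps,
GMT gene-set collections, and two-column PPI edge lists. A minimal reader
for the GEO series-matrix text layout (comment lines starting with "!")
is provided for convenience.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples log2-intensity matrix.

    Rows containing missing values are dropped (and logged); duplicate gene
    ids keep the first occurrence.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    n_missing = int(df.isna().any(axis=1).sum())
    if n_missing:
        logger.warning("dropping %d rows with missing values", n_missing)
        df = df.dropna(axis=0)
    if df.index.has_duplicates:
        n_dup = int(df.index.duplicated().sum())
        logger.warning("collapsing %d duplicate gene ids (first occurrence wins)", n_dup)
        df = df[~df.index.duplicated(keep="first")]
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df.astype(float)


def write_expression_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="gene")


def read_stage_map(path: str | Path) -> dict[str, str]:
    """Read a two-column sample→stage TSV (with or without a header line)."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if list(df.iloc[0]) == ["sample", "stage"]:
        df = df.iloc[1:]
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_stage_map(stage_of_sample: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tstage\n")
        for sample, stage in stage_of_sample.items():
            fh.write(f"{sample}\t{stage}\n")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT collection: set name TAB description TAB member genes."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line (needs >=3 fields): {line!r}")
            name, _desc, *members = fields
            members = [m for m in members if m]
            if name in sets:
                raise ValueError(f"duplicate set name in GMT: {name!r}")
            sets[name] = members
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


def read_ppi_edges(path: str | Path) -> list[tuple[str, str]]:
    """Read an undirected PPI edge list as a two-column TSV."""
    edges = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            a, b = line.split("\t")[:2]
            edges.append((a, b))
    return edges


def read_geo_series_matrix(path: str | Path) -> pd.DataFrame:
    """Read the tabular block of a GEO series-matrix text file.

    Metadata lines beginning with "!" are skipped; the remaining block is the
    probe x sample table with a header row.
    """
    df = pd.read_csv(path, sep="\t", comment="!", index_col=0)
    df = df.dropna(axis=0)
    df.index = df.index.astype(str)
    return df.astype(float)
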