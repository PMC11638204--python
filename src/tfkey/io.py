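"""Readers and writers for the plain-text formats used across the pipeline.

All tabular formats are tab-separated text; expression matrices may be
gzip-compressed (detected from the ``.gz`` suffix by pandas). Gene-set files
come in two dialects:

* the ranked 3-column TSV (``set_id  gene_id  rank_score``), the native
  output of the promoter scanner, and
* plain GMT (``set_id  description  gene1  gene2 ...``), in which case every
  member receives a rank score of 1.0.
"""

from __future__ import annotations

import os
from typing import Mapping

import numpy as np
import pandas as pd

RESULT_COLUMNS = [
    "set_id",
    "sample_id",
    "n_overlap",
    "tau",
    "z",
    "p",
    "q",
    "direction",
    "signed_score",
]


def read_expression(path: str | os.PathLike) -> pd.DataFrame:
    """Read a genes x samples expression TSV (first column = gene id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def write_expression(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", float_format="%.6f", index_label="gene_id")


def write_gene_list(scores: pd.Series, path: str | os.PathLike) -> None:
    """Write a ranked gene list as 2-column TSV (gene_id, score), best first."""
    ordered = scores.sort_values(ascending=False, kind="mergesort")
    ordered.rename("score").to_csv(path, sep="\t", header=True,
                                   index_label="gene_id", float_format="%.6g")


def read_gene_list(path: str | os.PathLike) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError(f"gene list {path!s} needs two columns (gene_id, score)")
    s = pd.Series(df.iloc[:, 1].to_numpy(float), index=df.iloc[:, 0].astype(str))
    return s


def read_gene_sets(path: str | os.PathLike) -> dict[str, dict[str, float]]:
    """Read ranked gene sets from a 3-column TSV or a GMT file."""
    path = os.fspath(path)
    sets: dict[str, dict[str, float]] = {}
    if path.endswith(".gmt"):
        with open(path) as fh:
            for line in fh:
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 3 or not fields[0]:
                    continue
                sets.setdefault(fields[0], {}).update(
                    {g: 1.0 for g in fields[2:] if g}
                )
        return sets
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns")
            try:
                score = float(fields[2])
            except ValueError:
                if lineno == 1:  # tolerated header row
                    continue
                raise
            sets.setdefault(fields[0], {})[fields[1]] = score
    return sets


def write_gene_sets(sets: Mapping[str, Mapping[str, float]],
                    path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("set_id\tgene_id\trank_score\n")
        for set_id in sorted(sets):
            members = sets[set_id]
            for gene in sorted(members):
                fh.write(f"{set_id}\t{gene}\t{members[gene]:.6g}\n")


def write_site_table(table: pd.DataFrame, path: str | os.PathLike) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def site_table_to_bed(table: pd.DataFrame, widths: Mapping[str, int],
                      path: str | os.PathLike) -> None:
    """Export a site table as BED6 (0-based half-open; score = Jindex)."""
    with open(path, "w") as fh:
        for row in table.itertuples(index=False):
            w = widths[row.tf_id]
            start = int(row.offset) - 1
            fh.write(
                f"{row.gene_id}\t{start}\t{start + w}\t{row.tf_id}"
                f"\t{row.jindex:.6g}\t{row.strand}\n"
            )


def write_results(results: pd.DataFrame, path: str | os.PathLike) -> None:
    results.to_csv(path, sep="\t", index=False, float_format="%.10g", na_rep="NA")


def read_results(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    for col in ("set_id", "sample_id"):
        df[col] = df[col].astype(str)
    return df


def write_score_matrix(scores: pd.DataFrame, path: str | os.PathLike) -> None:
    scores.to_csv(path, sep="\t", float_format="%.10g", na_rep="NA",
                  index_label="set_id")


def read_score_matrix(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df
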