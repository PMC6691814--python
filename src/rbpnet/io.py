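"""Readers and writers for the package's tabular and graph artifacts.

All tables are plain TSV.  Edge lists use the STRING dump dialect
(``protein1 protein2 combined_score``, space- or tab-delimited, header
optional).  Writers are deterministic: fixed column order, rows sorted by
primary key, floats at 6 significant digits.
"""

from __future__ import annotations

import logging
import os
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    CountMatrix,
    EdgeList,
    IDMap,
    validate_annotation,
    validate_sample_table,
)

logger = logging.getLogger("rbpnet")


def read_counts(path) -> CountMatrix:
    """Read a gene × sample count matrix from TSV.

    The header row carries sample identifiers; the first column carries
    gene identifiers.  Row and column order are preserved.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return CountMatrix(df)


def write_counts(cm: CountMatrix, path) -> None:
    cm.counts.to_csv(path, sep="\t", index_label="gene")


def read_sample_table(path, counts: CountMatrix | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "group": str})
    return validate_sample_table(df, counts)


def read_annotation(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "rbp_class": str})
    return validate_annotation(df)


def read_edge_list(path) -> EdgeList:
    """Read a STRING-dialect edge list.

    Accepts space- or tab-delimited files.  A header line is auto-detected
    by a non-numeric third field.  Canonicalization (endpoint ordering,
    self-edge dropping, max-score deduplication) happens here; the
    confidence filter does not — readers keep all edges.
    """
    records = []
    with open(path) as fh:
        first = True
        for line_no, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 3:
                raise ValueError(
                    f"{path}: line {line_no} has {len(parts)} column(s); "
                    "need protein1, protein2, combined_score"
                )
            if first:
                first = False
                try:
                    float(parts[2])
                except ValueError:
                    continue  # header line
            score = float(parts[2])
            if not score.is_integer() or not (0 <= score <= 1000):
                raise ValueError(
                    f"{path}: line {line_no}: combined_score {parts[2]} "
                    "outside the STRING 0-1000 integer scale"
                )
            records.append((parts[0], parts[1], int(score)))
    return EdgeList.from_records(records)


def write_edge_list(edges: EdgeList, path) -> None:
    edges.edges.to_csv(path, sep="\t", index=False)


def read_id_map(path) -> IDMap:
    """Read a two-column gene↔protein TSV (header optional, auto-detected)."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.empty:
        raise ValueError(f"{path}: id map is empty")
    if list(df.iloc[0]) == ["gene", "protein"]:
        df = df.iloc[1:]
    if df.shape[1] < 2:
        raise ValueError(f"{path}: id map needs two columns (gene, protein)")
    df = df.iloc[:, :2]
    df.columns = ["gene", "protein"]
    idmap = IDMap(df.reset_index(drop=True))
    logger.info("id map: %s", idmap.mapping_summary())
    return idmap


def write_id_map(idmap: IDMap, path) -> None:
    idmap.pairs.sort_values(["gene", "protein"]).to_csv(
        path, sep="\t", index=False, header=False
    )


def _format_value(v) -> str:
    if isinstance(v, (float, np.floating)):
        return f"{v:.6g}"
    if isinstance(v, (bool, np.bool_)):
        return str(bool(v))
    return str(v)


def write_table(rows: pd.DataFrame, path, sort_by: str | None = None) -> None:
    """Write a result table as TSV with a header.

    Floats are printed at 6 significant digits; rows are sorted by
    ``sort_by`` (default: the first column) so output is deterministic.
    """
    if sort_by is None and len(rows.columns):
        sort_by = rows.columns[0]
    out = rows.copy()
    if sort_by is not None and len(out):
        out = out.sort_values(sort_by, kind="mergesort")
    path = Path(path)
    if path.parent and not path.parent.exists():
        os.makedirs(path.parent, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("\t".join(map(str, out.columns)) + "\n")
        for row in out.itertuples(index=False):
            fh.write("\t".join(_format_value(v) for v in row) + "\n")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
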