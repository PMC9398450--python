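"""Readers and writers for the plain-text interchange formats.

Dense TSV (genes in rows, header row of observation ids) is the canonical
format; a MatrixMarket-style triplet format with sidecar gene/observation
label files is supported for sparse single-cell inputs.  Interaction graphs
come as two-column edge lists, localization annotations as two-column
(gene, term) tables.  Gene identifiers are case-sensitive symbols
throughout; no alias resolution is attempted.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    ExpressionMatrix,
    FormatError,
    InteractionGraph,
    InterfaceTable,
    LocalizationTable,
)

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "read_edge_list",
    "write_edge_list",
    "read_localization_table",
    "write_localization_table",
    "load_interface_fixture",
    "read_interface_table",
    "write_interface_table",
]


def read_expression_matrix(
    path: str | Path,
    format: str = "dense_tsv",
    *,
    gene_file: str | Path | None = None,
    obs_file: str | Path | None = None,
    group_file: str | Path | None = None,
) -> ExpressionMatrix:
    """Read an expression matrix.

    ``dense_tsv``: header row of observation ids, first column gene ids.
    ``triplet``: three whitespace-separated columns (gene index, obs index,
    value; 1-based) with ``gene_file``/``obs_file`` giving row/column labels
    one per line.  ``group_file`` optionally maps obs id -> group label
    (two tab-separated columns).
    """
    path = Path(path)
    if format == "dense_tsv":
        mat = _read_dense(path)
    elif format == "triplet":
        if gene_file is None or obs_file is None:
            raise FormatError("triplet format requires gene_file and obs_file")
        mat = _read_triplet(path, Path(gene_file), Path(obs_file))
    else:
        raise FormatError(f"unknown expression format {format!r}")
    groups = None
    if group_file is not None:
        gdf = pd.read_csv(group_file, sep="\t", header=None, names=["obs", "group"], dtype=str)
        groups = pd.Series(gdf["group"].values, index=gdf["obs"].values)
    return ExpressionMatrix(mat, groups)


def _read_dense(path: Path) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise FormatError(f"{path}:1: empty file or blank header")
        obs_ids = header.rstrip("\n").split("\t")[1:]
        if not obs_ids:
            raise FormatError(f"{path}:1: header has no observation ids")
        genes, rows = [], []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(obs_ids) + 1:
                raise FormatError(
                    f"{path}:{lineno}: expected {len(obs_ids) + 1} fields, got {len(fields)}"
                )
            try:
                vals = [float(x) for x in fields[1:]]
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric value ({exc})") from None
            if any(v < 0 for v in vals):
                raise FormatError(f"{path}:{lineno}: negative expression value")
            genes.append(fields[0])
            rows.append(vals)
    if not genes:
        raise FormatError(f"{path}: no data rows")
    if len(set(genes)) != len(genes):
        raise FormatError(f"{path}: duplicate gene ids")
    return pd.DataFrame(np.asarray(rows, dtype=float), index=genes, columns=obs_ids)


def _read_triplet(path: Path, gene_file: Path, obs_file: Path) -> pd.DataFrame:
    genes = [l.strip() for l in open(gene_file) if l.strip()]
    obs = [l.strip() for l in open(obs_file) if l.strip()]
    arr = np.zeros((len(genes), len(obs)))
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("%"):
                continue
            fields = line.split()
            if len(fields) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 fields, got {len(fields)}")
            try:
                i, j, v = int(fields[0]), int(fields[1]), float(fields[2])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: malformed triplet") from None
            if not (1 <= i <= len(genes) and 1 <= j <= len(obs)):
                raise FormatError(f"{path}:{lineno}: index out of range")
            if v < 0:
                raise FormatError(f"{path}:{lineno}: negative expression value")
            arr[i - 1, j - 1] += v
    return pd.DataFrame(arr, index=genes, columns=obs)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write as dense TSV with full float precision (round-trips exactly)."""
    matrix.values.to_csv(path, sep="\t", float_format="%.17g", index_label="gene")


def read_edge_list(path: str | Path) -> InteractionGraph:
    """Two tab-separated gene symbols per line; '#' lines are comments."""
    path = Path(path)
    edges = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 fields, got {len(fields)}")
            edges.append((fields[0], fields[1]))
    return InteractionGraph.from_edges(edges)


def write_edge_list(graph: InteractionGraph, path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in graph.graph.edges()):
            fh.write(f"{a}\t{b}\n")


def read_localization_table(path: str | Path) -> LocalizationTable:
    """Two tab-separated columns: gene symbol, localization term (one per line)."""
    path = Path(path)
    entries: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 fields, got {len(fields)}")
            entries.setdefault(fields[0], set()).add(fields[1])
    return LocalizationTable(entries)


def write_localization_table(table: LocalizationTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(table.entries):
            for term in sorted(table.entries[gene]):
                fh.write(f"{gene}\t{term}\n")


def load_interface_fixture() -> InterfaceTable:
    """The packaged 39-pair in-silico TE-EEC interface table.

    Each row pairs
    an endometrial epithelial (EEC) gene with its cognate trophectoderm (TE)
    binding partner, with the TE-subset hypernetwork cluster membership and
    the random-forest classifier call for syncytiotrophoblast differentiation.
    """
    ref = importlib.resources.files("trophonet") / "data" / "interface_table.tsv"
    with importlib.resources.as_file(ref) as p:
        return read_interface_table(p)


def read_interface_table(path: str | Path) -> InterfaceTable:
    rows = pd.read_csv(path, sep="\t", dtype=str)
    return InterfaceTable(rows)


def write_interface_table(table: InterfaceTable, path: str | Path) -> None:
    table.rows.to_csv(path, sep="\t", index=False)
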