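"""Readers and writers for the plain-text interchange formats.

Expression matrices are TSV with a leading ``gene`` column; sample
annotations are TSV with ``sample_id``, ``condition`` and ``dataset_id``
columns; edge lists and centrality tables round-trip as TSV.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .errors import DataError
from .simulate import ExpressionStudy


def read_study(expression_path, annotation_path) -> ExpressionStudy:
    expr = pd.read_csv(expression_path, sep="\t")
    if expr.columns[0] != "gene":
        raise DataError(f"{expression_path}: first column must be 'gene'")
    if expr["gene"].duplicated().any():
        dupes = expr.loc[expr["gene"].duplicated(), "gene"].tolist()[:5]
        raise DataError(f"{expression_path}: duplicate gene ids {dupes}")
    values = expr.set_index("gene")
    values.index = values.index.astype(str)

    ann = pd.read_csv(annotation_path, sep="\t", dtype=str)
    required = {"sample_id", "condition"}
    if not required <= set(ann.columns):
        raise DataError(f"{annotation_path}: needs columns {sorted(required)}")
    missing = set(values.columns) - set(ann["sample_id"])
    if missing:
        raise DataError(f"{annotation_path}: no annotation for samples {sorted(missing)[:5]}")
    condition = ann.set_index("sample_id")["condition"].reindex(values.columns)
    dataset_id = str(ann["dataset_id"].iloc[0]) if "dataset_id" in ann.columns else "dataset"
    return ExpressionStudy(values=values, condition=condition, dataset_id=dataset_id)


def write_de_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_de_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    needed = {"gene", "fold_change", "p_adj", "is_deg"}
    if not needed <= set(table.columns):
        raise DataError(f"{path}: DE table needs columns {sorted(needed)}")
    table["gene"] = table["gene"].astype(str)
    return table


def write_gene_list(genes, path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in sorted(genes)))


def write_edges(edges: pd.DataFrame, path) -> None:
    edges.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_edges(path) -> pd.DataFrame:
    edges = pd.read_csv(path, sep="\t", dtype={"gene_i": str, "gene_j": str})
    if not {"gene_i", "gene_j"} <= set(edges.columns):
        raise DataError(f"{path}: edge list needs gene_i and gene_j columns")
    return edges


def write_centrality(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_centrality(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype={"node": str})
    if not {"node", "betweenness"} <= set(table.columns):
        raise DataError(f"{path}: centrality table needs node and betweenness columns")
    return table
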