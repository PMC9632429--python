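"""On-disk formats: TSV tables, YAML design/config, JSON reports, GraphML.

All matrices and tables are tab-separated UTF-8 with ``#`` comment headers;
networks export to edge-list TSV and GraphML; configuration round-trips
through YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import pandas as pd
import yaml

from .deg import ContrastTable
from .design import StudyDesign
from .matrix import ExpressionMatrix
from .network import AssociationNetwork


def write_tsv(df: pd.DataFrame, path: Path | str, index_label: str | None = None) -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_tsv(path: Path | str, index_col: int | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col, comment="#")


# ----------------------------------------------------------------- expression
def write_expression(expr: ExpressionMatrix, values_path: Path | str, samples_path: Path | str) -> None:
    write_tsv(expr.values, values_path, index_label="gene")
    write_tsv(expr.samples, samples_path, index_label="sample")


def read_expression(values_path: Path | str, samples_path: Path | str) -> ExpressionMatrix:
    return ExpressionMatrix(
        values=read_tsv(values_path), samples=read_tsv(samples_path)
    )


# ------------------------------------------------------------------ contrasts
def write_contrast(contrast: ContrastTable, path: Path | str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# contrast: {contrast.name}\n")
        fh.write(f"# group_a: {','.join(contrast.group_a)}\n")
        fh.write(f"# group_b: {','.join(contrast.group_b)}\n")
        contrast.table.to_csv(fh, sep="\t", index_label="gene")


def read_contrast(path: Path | str) -> ContrastTable:
    meta = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].partition(":")
            meta[key.strip()] = value.strip()
    table = read_tsv(path)
    groups = {
        k: [s for s in meta.get(k, "").split(",") if s] for k in ("group_a", "group_b")
    }
    return ContrastTable(
        name=meta.get("contrast", Path(path).stem),
        table=table,
        group_a=groups["group_a"],
        group_b=groups["group_b"],
    )


# --------------------------------------------------------------------- design
def write_design(design: StudyDesign, path: Path | str) -> None:
    payload = {
        "genotypes": list(design.genotypes),
        "replicates": design.replicates,
        "lt50": {g: float(design.lt50[g]) for g in design.genotypes},
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False), encoding="utf-8")


def read_design(path: Path | str) -> StudyDesign:
    payload = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    return StudyDesign(
        genotypes=tuple(payload["genotypes"]),
        replicates=int(payload["replicates"]),
        lt50={k: float(v) for k, v in payload["lt50"].items()},
    )


# ------------------------------------------------------------------- networks
def write_network(net: AssociationNetwork, edges_path: Path | str, graphml_path: Path | str | None = None) -> None:
    write_tsv(net.edge_list().set_index("node_a"), edges_path, index_label="node_a")
    if graphml_path is not None:
        nx.write_graphml(net.graph, graphml_path)


# --------------------------------------------------------------------- report
def write_json(payload: dict, path: Path | str) -> None:
    Path(path).write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )


def write_gene_list(genes: set[str], path: Path | str) -> None:
    Path(path).write_text("\n".join(sorted(genes)) + "\n", encoding="utf-8")


def read_gene_list(path: Path | str) -> set[str]:
    return {
        line.strip()
        for line in Path(path).read_text(encoding="utf-8").splitlines()
        if line.strip() and not line.startswith("#")
    }
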