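"""Readers and writers for the plain-text formats the pipeline consumes.

Expression matrices travel as TSV (gene rows, sample columns), sample
metadata as CSV, PPI and regulatory tables as TSV, gene lists as one id per
line, gene sets as GMT, and networks as GraphML plus an edge-list TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import pandas as pd


def read_expression(path) -> pd.DataFrame:
    """Genes x samples TSV with gene ids in the first column."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if frame.index.duplicated().any():
        dup = frame.index[frame.index.duplicated()].tolist()
        raise ValueError(f"duplicate gene ids: {dup}")
    if frame.columns.duplicated().any():
        raise ValueError("duplicate sample ids")
    if frame.isna().any().any():
        raise ValueError("missing values in expression matrix; impute upstream")
    return frame


def write_expression(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index_label="gene")


def read_samples(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_samples(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def read_gene_list(path) -> list[str]:
    """One gene id per line; blank lines and '#' comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def read_gmt(path) -> dict[str, set[str]]:
    """GMT gene sets: name <tab> description <tab> member genes."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        sets[fields[0]] = {g for g in fields[2:] if g}
    return sets


def read_biotypes(path) -> dict[str, str]:
    """Two-column TSV: gene id, biotype."""
    frame = pd.read_csv(path, sep="\t", header=None,
                        names=["gene", "biotype"], comment="#")
    return dict(zip(frame["gene"].astype(str), frame["biotype"].astype(str)))


def read_ppi(path) -> pd.DataFrame:
    """PPI edge list TSV: two gene columns, optional extras."""
    return pd.read_csv(path, sep="\t")


def write_network(network: nx.Graph, prefix) -> None:
    """GraphML + edge-list TSV + JSON report next to ``prefix``."""
    prefix = Path(prefix)
    export = network.copy()
    report = export.graph.pop("prune_report", None)
    nx.write_graphml(export, prefix.with_suffix(".graphml"))
    edges = pd.DataFrame(network.edges, columns=["gene_a", "gene_b"])
    edges.to_csv(prefix.with_suffix(".edges.tsv"), sep="\t", index=False)
    if report is not None:
        prefix.with_suffix(".report.json").write_text(json.dumps(report, indent=2))


def read_network(path) -> nx.Graph:
    return nx.read_graphml(path)
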