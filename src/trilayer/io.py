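"""Readers and writers: GMT gene sets, TSV tables, GraphML/SIF networks.

All tabular formats are plain tab-separated text; gene identifiers are
matched case-sensitively after whitespace trimming.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import networkx as nx
import pandas as pd

__all__ = [
    "read_gmt",
    "write_gmt",
    "read_expression",
    "write_expression",
    "read_samples",
    "read_physiology",
    "export_network",
]


class GmtParseError(ValueError):
    pass


def read_gmt(path) -> dict:
    """Read a GMT file: one gene set per line, tab-separated
    ``name<TAB>description<TAB>member...``.

    Duplicate members within a line are dropped with a warning (first
    occurrence kept); duplicate set names or empty sets are errors.
    """
    path = Path(path)
    sets: dict[str, list] = {}
    name_lines: dict[str, int] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        if not line.strip():
            continue
        fields = [f.strip() for f in line.split("\t")]
        if len(fields) < 3:
            raise GmtParseError(
                f"{path.name}:{lineno}: expected >=3 tab-separated fields, "
                f"got {len(fields)}"
            )
        name, _desc, *members = fields
        members = [m for m in members if m]
        if name in sets:
            raise GmtParseError(
                f"{path.name}:{lineno}: duplicate set name {name!r} "
                f"(first defined at line {name_lines[name]})"
            )
        seen = set()
        unique = []
        for m in members:
            if m in seen:
                continue
            seen.add(m)
            unique.append(m)
        if len(unique) < len(members):
            warnings.warn(
                f"{path.name}:{lineno}: {len(members) - len(unique)} "
                f"duplicate members in set {name!r} dropped"
            )
        if not unique:
            raise GmtParseError(f"{path.name}:{lineno}: set {name!r} is empty")
        sets[name] = unique
        name_lines[name] = lineno
    return sets


def write_gmt(collection: dict, path, descriptions: dict | None = None) -> None:
    """Write a name -> members mapping as GMT (member order preserved)."""
    path = Path(path)
    descriptions = descriptions or {}
    with path.open("w") as fh:
        for name, members in collection.items():
            members = list(members)
            if not members:
                raise ValueError(f"cannot write empty set {name!r}")
            desc = descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_expression(path) -> pd.DataFrame:
    """Gene x sample TSV with a ``gene`` index column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str).str.strip()
    df.index.name = "gene"
    if df.index.duplicated().any():
        raise ValueError(f"{path}: duplicate gene ids")
    return df


def write_expression(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="gene")


def read_samples(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    for col in ("diet", "timepoint"):
        if col not in df.columns:
            raise ValueError(f"{path}: sample table needs a {col!r} column")
    return df


def read_physiology(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def _edge_table(net: nx.Graph) -> pd.DataFrame:
    rows = [
        (
            f"{a} ({data['relationship']}) {b}",
            data["relationship"],
            data["overlap_size"],
            data["similarity_coefficient"],
        )
        for a, b, data in net.edges(data=True)
    ]
    return pd.DataFrame(
        rows,
        columns=["edge_id", "relationship", "overlap_size", "similarity_coefficient"],
    )


def _node_table(net: nx.Graph) -> pd.DataFrame:
    rows = [
        (
            node,
            data.get("layer", ""),
            data.get("set_size", ""),
            data.get("score", ""),
            data.get("direction", ""),
            data.get("p_value", ""),
        )
        for node, data in net.nodes(data=True)
    ]
    return pd.DataFrame(
        rows, columns=["node", "layer", "set_size", "score", "direction", "p_value"]
    )


def export_network(net: nx.Graph, fmt: str, path) -> None:
    """Write a layered network as ``graphml``, ``sif`` or ``tsv``.

    The ``tsv`` format writes the edge table (columns edge_id,
    relationship, overlap_size, similarity_coefficient) to ``path`` and
    the node table next to it with a ``.nodes.tsv`` suffix.  Backing
    gene sets (the ``genes`` node attribute) are not serialised.
    """
    path = Path(path)
    if fmt == "graphml":
        g = net.copy()
        for _, data in g.nodes(data=True):
            data.pop("genes", None)
        nx.write_graphml(g, path, named_key_ids=True)
    elif fmt == "sif":
        with path.open("w") as fh:
            connected = set()
            for a, b, data in net.edges(data=True):
                fh.write(f"{a}\t{data['relationship']}\t{b}\n")
                connected.update((a, b))
            for node in net.nodes:
                if node not in connected:
                    fh.write(f"{node}\n")
    elif fmt == "tsv":
        _edge_table(net).to_csv(path, sep="\t", index=False)
        _node_table(net).to_csv(
            path.with_suffix(".nodes.tsv"), sep="\t", index=False
        )
    else:
        raise ValueError(f"unknown network format {fmt!r}")
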