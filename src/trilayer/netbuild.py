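"""Assembly of the three-layered gene-set overlap network.

Nodes come from the three upstream stages — enriched biological
processes, clustered transcription regulators, and linked physiological
parameters — each backed by a gene set (process members in the
universe, DE targets, correlated genes).  Edges connect nodes whose
backing sets overlap, weighted by a set-similarity coefficient; the
physiology-process layer pair uses a laxer cutoff (0.3) than all other
pairs (0.5), mirroring the sparser gene sets behind phenotype nodes.
Topology statistics (degree, betweenness, clustering) are computed on
the assembled graph.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "LayerNode",
    "NetworkConfig",
    "similarity",
    "process_layer",
    "regulator_layer",
    "physiology_layer",
    "build_network",
    "topology_stats",
]

LAYERS = ("process", "regulator", "physiology")

DEFAULT_RELATIONSHIPS = frozenset(
    {
        frozenset({"process"}),               # process-process
        frozenset({"regulator", "process"}),
        frozenset({"regulator", "physiology"}),
        frozenset({"physiology", "process"}),
    }
)


@dataclass(frozen=True)
class LayerNode:
    """A network node: an id, its layer, and the gene set backing it."""

    id: str
    layer: str
    genes: frozenset
    score: float | None = None     # signed -log10 p; None for physiology
    direction: str | None = None
    p_value: float | None = None

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}")
        if not self.genes:
            raise ValueError(f"node {self.id!r} has an empty backing set")


@dataclass(frozen=True)
class NetworkConfig:
    node_p_cutoff: float = 0.05
    coefficient_cutoff: float = 0.5
    physiology_process_cutoff: float = 0.3
    similarity_method: str = "overlap"  # overlap | jaccard | combined
    combine_k: float = 0.5
    allowed_relationships: frozenset = DEFAULT_RELATIONSHIPS

    def __post_init__(self) -> None:
        for c in (
            self.node_p_cutoff,
            self.coefficient_cutoff,
            self.physiology_process_cutoff,
            self.combine_k,
        ):
            if not (0.0 <= c <= 1.0):
                raise ValueError("cutoffs must lie in [0, 1]")
        if self.similarity_method not in ("overlap", "jaccard", "combined"):
            raise ValueError("similarity method must be overlap|jaccard|combined")

    def cutoff_for(self, layer_a: str, layer_b: str) -> float:
        if {layer_a, layer_b} == {"physiology", "process"}:
            return self.physiology_process_cutoff
        return self.coefficient_cutoff


def similarity(
    set_a, set_b, method: str = "overlap", combine_k: float = 0.5
) -> tuple[int, float]:
    """Overlap size and similarity coefficient of two gene sets.

    ``overlap``: |A∩B| / min(|A|, |B|); ``jaccard``: |A∩B| / |A∪B|;
    ``combined``: k*overlap + (1-k)*jaccard.
    """
    a, b = frozenset(set_a), frozenset(set_b)
    if not a or not b:
        raise ValueError("similarity of an empty set is undefined")
    inter = len(a & b)
    if method == "overlap":
        coef = inter / min(len(a), len(b))
    elif method == "jaccard":
        coef = inter / len(a | b)
    elif method == "combined":
        ov = inter / min(len(a), len(b))
        jc = inter / len(a | b)
        coef = combine_k * ov + (1.0 - combine_k) * jc
    else:
        raise ValueError(f"unknown similarity method {method!r}")
    return inter, coef


def process_layer(
    classified: pd.DataFrame,
    collection: dict,
    universe,
    p_cutoff: float = 0.05,
) -> list[LayerNode]:
    """Process nodes: significant directed enrichment records.

    The backing set is the full gene-set membership intersected with the
    tested universe (enrichment-map convention), not the leading edge.
    """
    uni = set(universe)
    nodes = []
    for _, row in classified.iterrows():
        if not row["significant"] or row["p_value"] >= p_cutoff:
            continue
        genes = frozenset(collection[row["set"]]) & uni
        if not genes:
            continue
        nodes.append(
            LayerNode(
                id=str(row["set"]),
                layer="process",
                genes=frozenset(genes),
                score=float(row["node_score"]),
                direction=str(row["direction"]),
                p_value=float(row["p_value"]),
            )
        )
    return sorted(nodes, key=lambda n: n.id)


def regulator_layer(
    records: pd.DataFrame, p_cutoff: float = 0.05
) -> list[LayerNode]:
    """Regulator nodes: significant cluster representatives only."""
    nodes = []
    for _, row in records.iterrows():
        if not row.get("is_representative", True):
            continue
        if row["p_value"] >= p_cutoff or not row["de_targets"]:
            continue
        direction = (
            "up" if row["z"] > 0 else "down" if row["z"] < 0 else "both"
        )
        nodes.append(
            LayerNode(
                id=str(row["tf"]),
                layer="regulator",
                genes=frozenset(row["de_targets"]),
                score=float(row["activation_score"]),
                direction=direction,
                p_value=float(row["p_value"]),
            )
        )
    return sorted(nodes, key=lambda n: n.id)


def physiology_layer(correlations: pd.DataFrame) -> list[LayerNode]:
    """Physiology nodes: every parameter with a nonempty correlated set."""
    nodes = []
    for param, sub in correlations.groupby("parameter"):
        if not len(sub):
            continue
        nodes.append(
            LayerNode(
                id=str(param),
                layer="physiology",
                genes=frozenset(sub["gene"]),
            )
        )
    return sorted(nodes, key=lambda n: n.id)


def _relationship(layer_a: str, layer_b: str) -> str:
    order = {layer: i for i, layer in enumerate(LAYERS)}
    a, b = sorted((layer_a, layer_b), key=order.get)
    return f"{a}-{b}"


def build_network(
    process_nodes: list[LayerNode],
    regulator_nodes: list[LayerNode],
    physiology_nodes: list[LayerNode],
    cfg: NetworkConfig | None = None,
) -> nx.Graph:
    """Assemble the layered network from the three node lists.

    Edges join every allowed layer pair whose backing sets share at
    least one gene and whose similarity coefficient meets the layer-pair
    cutoff (boundary inclusive).  Node and edge insertion order is
    deterministic, so serialisations are byte-stable.
    """
    cfg = cfg or NetworkConfig()
    nodes = sorted(
        list(process_nodes) + list(regulator_nodes) + list(physiology_nodes),
        key=lambda n: (LAYERS.index(n.layer), n.id),
    )
    ids = [n.id for n in nodes]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate node ids across layers: {dup[:5]}")

    g = nx.Graph()
    for node in nodes:
        attrs = {"layer": node.layer, "set_size": len(node.genes)}
        if node.score is not None:
            attrs["score"] = float(node.score)
        if node.direction is not None:
            attrs["direction"] = node.direction
        if node.p_value is not None:
            attrs["p_value"] = float(node.p_value)
        g.add_node(node.id, **attrs)
        g.nodes[node.id]["genes"] = node.genes  # not serialised to GraphML

    n_edges = 0
    for i, a in enumerate(nodes):
        for b in nodes[i + 1 :]:
            pair = frozenset({a.layer, b.layer}) if a.layer != b.layer else frozenset({a.layer})
            if pair not in cfg.allowed_relationships:
                continue
            overlap, coef = similarity(
                a.genes, b.genes, cfg.similarity_method, cfg.combine_k
            )
            if overlap < 1 or coef < cfg.cutoff_for(a.layer, b.layer):
                continue
            g.add_edge(
                a.id,
                b.id,
                relationship=_relationship(a.layer, b.layer),
                overlap_size=int(overlap),
                similarity_coefficient=float(coef),
            )
            n_edges += 1
    if g.number_of_nodes() == 0:
        warnings.warn("network is empty: no layer produced nodes")
    log.info(
        "network: %d nodes (%s), %d edges",
        g.number_of_nodes(),
        ", ".join(
            f"{layer} {sum(1 for _, d in g.nodes(data=True) if d['layer'] == layer)}"
            for layer in LAYERS
        ),
        g.number_of_edges(),
    )
    return g


def topology_stats(net: nx.Graph) -> tuple[pd.DataFrame, dict]:
    """Per-node degree / betweenness / clustering, plus global counts.

    Betweenness is the unnormalised shortest-path count (undirected, so
    each pair contributes once).  The per-node table is sorted by
    descending betweenness, the hub criterion used to single out
    processes such as "signal transduction".
    """
    if net.number_of_nodes() == 0:
        raise ValueError("network has no nodes")
    betweenness = nx.betweenness_centrality(net, normalized=False)
    clustering = nx.clustering(net)
    rows = [
        (
            node,
            net.nodes[node].get("layer", ""),
            net.degree[node],
            betweenness[node],
            clustering[node],
        )
        for node in net.nodes
    ]
    df = pd.DataFrame(
        rows, columns=["node", "layer", "degree", "betweenness", "clustering"]
    ).sort_values(["betweenness", "node"], ascending=[False, True], ignore_index=True)
    summary = {
        "n_nodes": net.number_of_nodes(),
        "n_edges": net.number_of_edges(),
        "density": nx.density(net),
    }
    return df, summary
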