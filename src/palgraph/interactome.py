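"""Interactome construction: merge a pathway collection into one graph.

Pathway node sets overlap heavily between source databases, so pathways are
combined on coinciding gene products: two nodes are the same interactome node
iff their member-gene sets are identical (merging complexes by display label
across databases is unsafe). Edges are the union over pathways of typed
directed interactions between merged nodes, deduplicated by
(source, target, type); the same node pair may carry several parallel edges
of different types (e.g. activation from one pathway, inhibition from
another — both are retained). Symmetric relation types (binding/association,
compound) are stored as written with a flag that traversal honors in both
directions.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass

import networkx as nx

from .pathway_db import SYMMETRIC_TYPES, PathwayCollection

logger = logging.getLogger(__name__)

#: Graph node key: the sorted tuple of member gene symbols.
NodeKey = tuple[str, ...]


def node_key(members) -> NodeKey:
    return tuple(sorted(members))


@dataclass
class GraphStats:
    """Whole-graph statistics.

    density uses the undirected-pair denominator E / (N(N-1)/2); avg_degree is
    edges per node (E/N). Connectivity ignores edge direction.
    """

    n_nodes: int
    n_edges: int
    density: float
    avg_degree: float
    connected: bool

    def to_dict(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "density": self.density,
            "avg_degree": self.avg_degree,
            "connected": self.connected,
        }


class InteractomeGraph:
    """Merged node-level directed multigraph with gene-level expansion index.

    Thin wrapper around a :class:`networkx.MultiDiGraph` keyed by member-gene
    sets. Node attributes: ``label`` (first occurrence wins), ``members``
    (frozenset of gene symbols). Edge key is the interaction type; edge
    attributes: ``itype``, ``symmetric``, ``provenance`` (set of contributing
    pathway names).
    """

    def __init__(self) -> None:
        self.g = nx.MultiDiGraph()
        #: gene symbol -> set of node keys whose member set contains it
        self.gene_to_nodes: dict[str, set[NodeKey]] = {}

    # -- construction -------------------------------------------------------

    def add_node(self, members, label: str) -> NodeKey:
        key = node_key(members)
        if key not in self.g:
            self.g.add_node(key, label=label, members=frozenset(members))
            for gene in members:
                self.gene_to_nodes.setdefault(gene, set()).add(key)
        return key

    def add_edge(self, source: NodeKey, target: NodeKey, itype: str, pathway: str) -> None:
        if self.g.has_edge(source, target, key=itype):
            self.g.edges[source, target, itype]["provenance"].add(pathway)
        else:
            self.g.add_edge(
                source,
                target,
                key=itype,
                itype=itype,
                symmetric=itype in SYMMETRIC_TYPES,
                provenance={pathway},
            )

    # -- queries ------------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.g.number_of_edges()

    @property
    def gene_count(self) -> int:
        return len(self.gene_to_nodes)

    def members(self, key: NodeKey) -> frozenset[str]:
        return self.g.nodes[key]["members"]

    def label(self, key: NodeKey) -> str:
        return self.g.nodes[key]["label"]

    def nodes_for_gene(self, gene: str) -> set[NodeKey]:
        return self.gene_to_nodes.get(gene.upper(), set())

    def neighbors_undirected(self, key: NodeKey):
        """Successors and predecessors (symmetric edges traverse both ways)."""
        yield from self.g.successors(key)
        yield from self.g.predecessors(key)

    def neighbors_downstream(self, key: NodeKey):
        """Successors plus predecessors reachable through symmetric edges."""
        yield from self.g.successors(key)
        for pred in self.g.predecessors(key):
            if any(d["symmetric"] for d in self.g[pred][key].values()):
                yield pred


def merge_pathways(c: PathwayCollection) -> InteractomeGraph:
    """Union all pathway graphs into one interactome.

    Nodes merge when their member-gene sets coincide exactly; the display
    label of the first occurrence is kept. Edges between merged nodes are
    deduplicated by (source, target, type) with provenance recording every
    contributing pathway. An empty collection yields an empty graph with a
    warning.
    """
    graph = InteractomeGraph()
    if not c.pathways:
        logger.warning("merging an empty pathway collection: empty interactome")
        return graph
    for p in c.pathways:
        local: dict[str, NodeKey] = {}
        for node in p.nodes:
            local[node.node_id] = graph.add_node(node.members, node.label)
        for edge in p.interactions:
            graph.add_edge(local[edge.source], local[edge.target], edge.itype, p.name)
    return graph


def graph_stats(g: InteractomeGraph) -> GraphStats:
    """Node/edge counts, density, average degree and undirected connectivity.

    Conventions match the usual interactome bookkeeping: avg_degree = E/N
    (each typed directed edge counted once) and density = E / (N(N-1)/2).
    Raises ValueError for graphs with fewer than two nodes, where density is
    undefined.
    """
    n, e = g.n_nodes, g.n_edges
    if n < 2:
        raise ValueError(f"density undefined for a graph with {n} node(s)")
    density = e / (n * (n - 1) / 2)
    avg_degree = e / n
    connected = nx.is_connected(nx.Graph(g.g))
    return GraphStats(n_nodes=n, n_edges=e, density=density, avg_degree=avg_degree, connected=connected)


def export_graphml(g: InteractomeGraph, path: str | os.PathLike) -> None:
    """Write standard GraphML: node label + ";"-joined members, edge type."""
    out = nx.MultiDiGraph()
    for key, data in g.g.nodes(data=True):
        out.add_node(
            "|".join(key),
            label=data["label"],
            members=";".join(sorted(data["members"])),
        )
    for u, v, k, data in g.g.edges(keys=True, data=True):
        out.add_edge(
            "|".join(u),
            "|".join(v),
            key=k,
            itype=data["itype"],
            provenance=";".join(sorted(data["provenance"])),
        )
    nx.write_graphml(out, os.fspath(path))


def import_graphml(path: str | os.PathLike) -> InteractomeGraph:
    """Read a GraphML file written by :func:`export_graphml`."""
    raw = nx.read_graphml(os.fspath(path), force_multigraph=True)
    graph = InteractomeGraph()
    keys: dict[str, NodeKey] = {}
    for node, data in raw.nodes(data=True):
        members = data["members"].split(";") if data.get("members") else node.split("|")
        keys[node] = graph.add_node(members, data.get("label", node))
    for u, v, _, data in raw.edges(keys=True, data=True):
        for pathway in data.get("provenance", "").split(";"):
            graph.add_edge(keys[u], keys[v], data["itype"], pathway)
    return graph
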