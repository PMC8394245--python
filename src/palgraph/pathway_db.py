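"""Pathway collections: the knowledge base an interactome is built from.

A pathway is a small directed, typed graph whose nodes are gene products or
multi-gene complexes (e.g. an "extracellular matrix" node holding several
genes). Each pathway may carry per-gene activator/repressor roles (ARR),
weights in {-1, -0.5, 0, 0.5, 1} encoding whether a gene product activates
(+) or inhibits (-) the pathway, with 0 for an ambiguous role.

The on-disk dialect is JSON (one object per pathway) with an alternative
three-table TSV layout; a standard GMT export is provided for
interoperability with gene-set tooling. Gene symbols are HGNC-style strings
compared exactly after upper-casing; no alias resolution is attempted.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

logger = logging.getLogger(__name__)

#: The closed set of molecular interaction types.
INTERACTION_TYPES = frozenset(
    {
        "activation",
        "compound",
        "inhibition",
        "phosphorylation",
        "dissociation",
        "repression",
        "dephosphorylation",
        "binding/association",
        "ubiquitination",
    }
)

#: Interaction types that denote a symmetric (direction-free) relation.
#: They are stored as written but traversed in both directions.
SYMMETRIC_TYPES = frozenset({"binding/association", "compound"})

#: Allowed activator/repressor role values.
ARR_VALUES = frozenset({-1.0, -0.5, 0.0, 0.5, 1.0})


class PathwayFormatError(ValueError):
    """Malformed pathway record (parse- or validation-time)."""


@dataclass(frozen=True)
class PathwayNode:
    """A pathway node: a single gene product or a multi-gene complex."""

    node_id: str
    label: str
    members: frozenset[str]

    @property
    def is_complex(self) -> bool:
        return len(self.members) > 1


@dataclass(frozen=True)
class Interaction:
    """A typed directed interaction between two pathway nodes."""

    source: str
    target: str
    itype: str


@dataclass
class Pathway:
    name: str
    nodes: list[PathwayNode]
    interactions: list[Interaction]
    #: gene symbol -> ARR value in {-1, -0.5, 0, 0.5, 1}; may be empty when
    #: roles are to be assigned algorithmically downstream.
    arr: dict[str, float] = field(default_factory=dict)

    def gene_set(self) -> set[str]:
        out: set[str] = set()
        for node in self.nodes:
            out |= node.members
        return out

    def node_by_id(self, node_id: str) -> PathwayNode:
        for node in self.nodes:
            if node.node_id == node_id:
                return node
        raise KeyError(node_id)


@dataclass
class PathwayCollection:
    pathways: list[Pathway]
    #: gene symbol -> set of pathway names containing it.
    gene_index: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.gene_index:
            self.gene_index = build_gene_index(self.pathways)

    def __len__(self) -> int:
        return len(self.pathways)

    def pathway_by_name(self, name: str) -> Pathway:
        for p in self.pathways:
            if p.name == name:
                return p
        raise KeyError(name)


def build_gene_index(pathways: list[Pathway]) -> dict[str, set[str]]:
    index: dict[str, set[str]] = {}
    for p in pathways:
        for gene in p.gene_set():
            index.setdefault(gene, set()).add(p.name)
    return index


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------


def _parse_pathway_record(rec: dict, where: str) -> Pathway:
    try:
        name = rec["name"]
        raw_nodes = rec["nodes"]
        raw_edges = rec.get("interactions", [])
        raw_arr = rec.get("arr", {}) or {}
    except (KeyError, TypeError) as exc:
        raise PathwayFormatError(f"{where}: missing field {exc}") from exc

    nodes = []
    node_ids = set()
    for i, nd in enumerate(raw_nodes):
        try:
            members = frozenset(str(m).upper() for m in nd["members"])
            node = PathwayNode(
                node_id=str(nd["id"]),
                label=str(nd.get("label", nd["id"])),
                members=members,
            )
        except (KeyError, TypeError) as exc:
            raise PathwayFormatError(f"{where}, node #{i}: malformed record ({exc})") from exc
        if not node.members:
            raise PathwayFormatError(f"{where}, node {node.node_id!r}: empty member set")
        nodes.append(node)
        node_ids.add(node.node_id)

    seen: set[tuple[str, str, str]] = set()
    interactions = []
    for i, ed in enumerate(raw_edges):
        try:
            edge = Interaction(str(ed["source"]), str(ed["target"]), str(ed["type"]))
        except (KeyError, TypeError) as exc:
            raise PathwayFormatError(f"{where}, interaction #{i}: malformed record ({exc})") from exc
        if edge.itype not in INTERACTION_TYPES:
            raise PathwayFormatError(
                f"{where}, interaction #{i} ({edge.source}->{edge.target}): "
                f"unknown interaction type {edge.itype!r}"
            )
        key = (edge.source, edge.target, edge.itype)
        if key in seen:
            logger.warning("%s: duplicate interaction %s collapsed", where, key)
            continue
        seen.add(key)
        interactions.append(edge)

    arr = {str(g).upper(): float(v) for g, v in raw_arr.items()}
    return Pathway(name=str(name), nodes=nodes, interactions=interactions, arr=arr)


def load_collection(path: str | os.PathLike, format: str = "json") -> PathwayCollection:
    """Read and validate a pathway collection.

    ``format="json"``: a JSON file holding a list of pathway objects
    (``{"name", "nodes": [{"id","label","members"}], "interactions":
    [{"source","target","type"}], "arr": {gene: value}}``).

    ``format="tsv"``: a directory with three linked tables ``nodes.tsv``
    (pathway, node_id, label, members ";"-joined), ``interactions.tsv``
    (pathway, source, target, type) and ``arr.tsv`` (pathway, gene, arr).

    Gene symbols are upper-cased; duplicate (source, target, type) triples
    within one pathway are collapsed with a warning. Raises
    :class:`PathwayFormatError` on malformed records or unknown interaction
    types, and on any type-invariant violation.
    """
    if format == "json":
        with open(path) as fh:
            try:
                data = json.load(fh)
            except json.JSONDecodeError as exc:
                raise PathwayFormatError(f"{path}: not valid JSON ({exc})") from exc
        if not isinstance(data, list):
            raise PathwayFormatError(f"{path}: expected a JSON list of pathways")
        pathways = [
            _parse_pathway_record(rec, f"{path} pathway #{i}") for i, rec in enumerate(data)
        ]
    elif format == "tsv":
        pathways = _load_tsv_tables(os.fspath(path))
    else:
        raise ValueError(f"unknown format {format!r}")

    collection = PathwayCollection(pathways)
    violations = validate_collection(collection)
    if violations:
        raise PathwayFormatError("; ".join(violations))
    return collection


def _read_tsv(path: str, columns: list[str]) -> list[dict[str, str]]:
    rows = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != columns:
            raise PathwayFormatError(f"{path}: expected columns {columns}, found {header}")
        for ln, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(columns):
                raise PathwayFormatError(f"{path}, line {ln}: expected {len(columns)} fields")
            rows.append(dict(zip(columns, fields)))
    return rows


def _load_tsv_tables(directory: str) -> list[Pathway]:
    node_rows = _read_tsv(os.path.join(directory, "nodes.tsv"), ["pathway", "node_id", "label", "members"])
    edge_rows = _read_tsv(os.path.join(directory, "interactions.tsv"), ["pathway", "source", "target", "type"])
    arr_path = os.path.join(directory, "arr.tsv")
    arr_rows = _read_tsv(arr_path, ["pathway", "gene", "arr"]) if os.path.exists(arr_path) else []

    names: list[str] = []
    records: dict[str, dict] = {}
    for row in node_rows:
        name = row["pathway"]
        if name not in records:
            names.append(name)
            records[name] = {"name": name, "nodes": [], "interactions": [], "arr": {}}
        records[name]["nodes"].append(
            {"id": row["node_id"], "label": row["label"], "members": row["members"].split(";")}
        )
    for row in edge_rows:
        if row["pathway"] not in records:
            raise PathwayFormatError(f"interactions.tsv: unknown pathway {row['pathway']!r}")
        records[row["pathway"]]["interactions"].append(
            {"source": row["source"], "target": row["target"], "type": row["type"]}
        )
    for row in arr_rows:
        if row["pathway"] not in records:
            raise PathwayFormatError(f"arr.tsv: unknown pathway {row['pathway']!r}")
        try:
            records[row["pathway"]]["arr"][row["gene"]] = float(row["arr"])
        except ValueError as exc:
            raise PathwayFormatError(f"arr.tsv: non-numeric arr for {row['gene']!r}") from exc
    return [_parse_pathway_record(records[name], f"{directory} pathway {name!r}") for name in names]


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def validate_collection(c: PathwayCollection) -> list[str]:
    """Return a list of invariant violations (empty iff the collection is valid).

    Checks: unique pathway names; non-empty node member sets and unique node
    ids within a pathway; interaction endpoints resolve to nodes of the owning
    pathway and use a known type; ARR values restricted to {-1,-0.5,0,0.5,1}
    and assigned only to member genes; gene_index consistent with membership.
    """
    violations: list[str] = []
    seen_names: set[str] = set()
    for p in c.pathways:
        if p.name in seen_names:
            violations.append(f"pathway {p.name!r}: duplicate pathway name")
        seen_names.add(p.name)

        node_ids: set[str] = set()
        for node in p.nodes:
            if not node.members:
                violations.append(f"pathway {p.name!r}, node {node.node_id!r}: empty member set")
            if any(not m for m in node.members):
                violations.append(f"pathway {p.name!r}, node {node.node_id!r}: empty gene symbol")
            if node.node_id in node_ids:
                violations.append(f"pathway {p.name!r}, node {node.node_id!r}: duplicate node id")
            node_ids.add(node.node_id)

        seen_edges: set[tuple[str, str, str]] = set()
        for edge in p.interactions:
            if edge.itype not in INTERACTION_TYPES:
                violations.append(
                    f"pathway {p.name!r}, edge {edge.source}->{edge.target}: "
                    f"unknown type {edge.itype!r}"
                )
            for endpoint in (edge.source, edge.target):
                if endpoint not in node_ids:
                    violations.append(
                        f"pathway {p.name!r}, edge {edge.source}->{edge.target}: "
                        f"endpoint {endpoint!r} is not a node of this pathway"
                    )
            key = (edge.source, edge.target, edge.itype)
            if key in seen_edges:
                violations.append(f"pathway {p.name!r}: duplicate interaction {key}")
            seen_edges.add(key)

        genes = p.gene_set()
        for gene, value in p.arr.items():
            if value not in ARR_VALUES:
                violations.append(
                    f"pathway {p.name!r}, gene {gene!r}: ARR {value} not in "
                    "{-1, -0.5, 0, 0.5, 1}"
                )
            if gene not in genes:
                violations.append(
                    f"pathway {p.name!r}, gene {gene!r}: ARR assigned to a non-member gene"
                )

    expected_index = build_gene_index(c.pathways)
    if c.gene_index != expected_index:
        violations.append("gene_index inconsistent with pathway memberships")
    return violations


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def collection_to_records(c: PathwayCollection) -> list[dict]:
    """Serialize to the JSON dialect (deterministic ordering)."""
    records = []
    for p in c.pathways:
        records.append(
            {
                "name": p.name,
                "nodes": [
                    {"id": n.node_id, "label": n.label, "members": sorted(n.members)}
                    for n in p.nodes
                ],
                "interactions": [
                    {"source": e.source, "target": e.target, "type": e.itype}
                    for e in p.interactions
                ],
                "arr": {g: p.arr[g] for g in sorted(p.arr)},
            }
        )
    return records


def write_collection(c: PathwayCollection, path: str | os.PathLike) -> None:
    """Write the collection in the JSON dialect (round-trips via load_collection)."""
    with open(path, "w") as fh:
        json.dump(collection_to_records(c), fh, indent=1)
        fh.write("\n")


def write_gmt(c: PathwayCollection, path: str | os.PathLike) -> None:
    """Export gene sets as a standard GMT file.

    One line per pathway: name, description (the name again), then the
    tab-separated union of node member symbols, sorted for determinism.
    """
    with open(path, "w") as fh:
        for p in c.pathways:
            genes = sorted(p.gene_set())
            fh.write("\t".join([p.name, p.name, *genes]) + "\n")


def read_gmt(path: str | os.PathLike) -> dict[str, set[str]]:
    """Read a GMT file back as {set name: gene set} (for round-trip checks)."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                continue
            out[fields[0]] = set(fields[2:])
    return out
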