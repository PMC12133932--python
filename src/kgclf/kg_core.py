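"""Typed knowledge-graph data model: schema, nodes, triples, fusion, adjacency.

The default schema describes a syndrome-centred clinical knowledge graph:
eleven entity types, three of them attribute-rich (Syndrome, Symptoms, Herb),
and nine typed relation signatures.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np

from .errors import FusionError, SchemaError

logger = logging.getLogger(__name__)

#: Attribute lists of the attribute-rich entity types.
_DEFAULT_ATTRIBUTES: dict[str, tuple[str, ...]] = {
    "Syndrome": (
        "Syndrome_name",
        "Syndrome_English",
        "Syndrome_PinYin",
        "Syndrome_definition",
    ),
    "Symptoms": (
        "TCM_symptom_name",
        "Symptom_PinYin",
        "Symptom_definition",
        "Symptom_locus",
        "Symptom_property",
    ),
    "Herb": (
        "Chinese_name",
        "Pinyin_name",
        "English_name",
        "Properties_Chinese",
        "Meridians_Chinese",
    ),
    "Treatment": ("name",),
    "Disease": ("name",),
    "Drugs": ("name",),
    "Flavor": ("name",),
    "Form": ("name",),
    "Patients": ("name",),
    "Dgroup": ("name",),
    "Fgroup": ("name",),
}

#: The nine typed relation signatures of the default schema.
_DEFAULT_RELATIONS: tuple[tuple[str, str, str], ...] = (
    ("Syndrome", "Has_disease", "Disease"),
    ("Syndrome", "Has_symptom", "Symptoms"),
    ("Syndrome", "Has_treatment", "Treatment"),
    ("Treatment", "Common pharmaceuticals", "Drugs"),
    ("Drugs", "Has_flavor", "Flavor"),
    ("Drugs", "Dosage form", "Form"),
    ("Disease", "Common patients", "Patients"),
    ("Disease", "IspartofD", "Dgroup"),
    ("Drugs", "IspartofP", "Fgroup"),
)


@dataclass(frozen=True)
class EntitySchema:
    """Entity types, their attribute lists, and typed relation signatures."""

    entity_types: frozenset[str]
    attributes: Mapping[str, tuple[str, ...]]
    relation_types: frozenset[tuple[str, str, str]]

    def __post_init__(self) -> None:
        for etype in self.entity_types:
            attrs = self.attributes.get(etype, ())
            if not attrs:
                raise SchemaError(f"entity type {etype!r} has an empty attribute list")
            if len(set(attrs)) != len(attrs):
                raise SchemaError(f"entity type {etype!r} has duplicate attributes")
        for head_t, rel, tail_t in self.relation_types:
            for endpoint in (head_t, tail_t):
                if endpoint not in self.entity_types:
                    raise SchemaError(
                        f"relation {rel!r} references undeclared entity type {endpoint!r}"
                    )

    @property
    def relation_names(self) -> frozenset[str]:
        return frozenset(r for _, r, _ in self.relation_types)

    def relation_signature(self, relation: str) -> tuple[str, str]:
        """Return the unique (head_type, tail_type) of a relation name.

        Raises SchemaError when the name is unknown or ambiguous.
        """
        sigs = [(h, t) for h, r, t in self.relation_types if r == relation]
        if not sigs:
            raise SchemaError(f"unknown relation {relation!r}")
        if len(sigs) > 1:
            raise SchemaError(f"relation {relation!r} has multiple typed signatures")
        return sigs[0]

    def validate_attributes(self, entity_type: str, attributes: Mapping[str, str]) -> None:
        if entity_type not in self.entity_types:
            raise SchemaError(f"unknown entity type {entity_type!r}")
        allowed = set(self.attributes[entity_type])
        extra = set(attributes) - allowed
        if extra:
            raise SchemaError(
                f"attributes {sorted(extra)} not declared for entity type {entity_type!r}"
            )


def default_schema() -> EntitySchema:
    """The built-in syndrome-centred schema (11 entity types, 9 relations)."""
    return EntitySchema(
        entity_types=frozenset(_DEFAULT_ATTRIBUTES),
        attributes=dict(_DEFAULT_ATTRIBUTES),
        relation_types=frozenset(_DEFAULT_RELATIONS),
    )


def load_schema(source: str | Path | Mapping | None = None) -> EntitySchema:
    """Load a schema from a JSON document (path or mapping).

    With no source, return the built-in default schema.  The document shape is
    ``{"entity_types": {type: [attr, ...]}, "relations": [[head, rel, tail], ...]}``.
    """
    if source is None:
        return default_schema()
    if isinstance(source, (str, Path)):
        with open(source, encoding="utf-8") as fh:
            doc = json.load(fh)
    else:
        doc = source
    raw_attrs = doc.get("entity_types", {})
    if len(raw_attrs) != len(set(raw_attrs)):  # pragma: no cover - dict dedups keys
        raise SchemaError("duplicate entity type")
    attributes = {etype: tuple(attrs) for etype, attrs in raw_attrs.items()}
    relations = frozenset(tuple(row) for row in doc.get("relations", ()))
    for row in relations:
        if len(row) != 3:
            raise SchemaError(f"relation row must have 3 fields, got {row!r}")
    return EntitySchema(
        entity_types=frozenset(attributes),
        attributes=attributes,
        relation_types=relations,
    )


@dataclass
class Node:
    """A typed graph node. ``embedding`` holds the learned vector, if any."""

    id: int
    entity_type: str
    canonical_name: str
    attributes: dict[str, str] = field(default_factory=dict)
    embedding: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.canonical_name:
            raise SchemaError("canonical_name must be non-empty")

    @property
    def key(self) -> tuple[str, str]:
        return (self.entity_type, self.canonical_name)


class Triple(NamedTuple):
    head: int
    relation: str
    tail: int


class KnowledgeGraph:
    """In-process typed triple store with schema validation.

    Node ids are stable integers assigned at insertion; all iteration orders
    are sorted for reproducibility.
    """

    def __init__(self, schema: EntitySchema | None = None):
        self.schema = schema if schema is not None else default_schema()
        self._nodes: dict[int, Node] = {}
        self._triples: set[Triple] = set()
        self._next_id = 0

    # -- construction ------------------------------------------------------

    def add_node(
        self,
        entity_type: str,
        canonical_name: str,
        attributes: Mapping[str, str] | None = None,
        embedding: np.ndarray | None = None,
        node_id: int | None = None,
    ) -> Node:
        attributes = dict(attributes or {})
        self.schema.validate_attributes(entity_type, attributes)
        if node_id is None:
            node_id = self._next_id
        elif node_id in self._nodes:
            raise SchemaError(f"node id {node_id} already present")
        self._next_id = max(self._next_id, node_id + 1)
        node = Node(node_id, entity_type, canonical_name, attributes, embedding)
        self._nodes[node_id] = node
        return node

    def add_triple(self, head: int, relation: str, tail: int) -> Triple:
        if head not in self._nodes or tail not in self._nodes:
            raise SchemaError(f"triple ({head}, {relation!r}, {tail}) has a missing endpoint")
        if head == tail:
            raise SchemaError("self-loops are not allowed by the schema")
        sig = (self._nodes[head].entity_type, relation, self._nodes[tail].entity_type)
        if sig not in self.schema.relation_types:
            raise SchemaError(f"typed signature {sig!r} not in schema")
        triple = Triple(head, relation, tail)
        self._triples.add(triple)
        return triple

    # -- access ------------------------------------------------------------

    @property
    def nodes(self) -> list[Node]:
        return [self._nodes[i] for i in sorted(self._nodes)]

    @property
    def triples(self) -> list[Triple]:
        return sorted(self._triples)

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    @property
    def n_triples(self) -> int:
        return len(self._triples)

    def node(self, node_id: int) -> Node:
        return self._nodes[node_id]

    def has_node(self, node_id: int) -> bool:
        return node_id in self._nodes

    def find_nodes(self, entity_type: str, canonical_name: str) -> list[Node]:
        """All nodes with the given (type, name) key, sorted by id."""
        return [
            n for n in self.nodes
            if n.entity_type == entity_type and n.canonical_name == canonical_name
        ]

    def nodes_of_type(self, *entity_types: str) -> list[Node]:
        wanted = set(entity_types)
        return [n for n in self.nodes if n.entity_type in wanted]

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty when valid)."""
        problems: list[str] = []
        for t in self.triples:
            if t.head not in self._nodes or t.tail not in self._nodes:
                problems.append(f"dangling triple {t}")
                continue
            sig = (self._nodes[t.head].entity_type, t.relation, self._nodes[t.tail].entity_type)
            if sig not in self.schema.relation_types:
                problems.append(f"triple {t} signature {sig} outside schema")
        return problems

    def copy(self) -> "KnowledgeGraph":
        out = KnowledgeGraph(self.schema)
        for n in self.nodes:
            emb = None if n.embedding is None else n.embedding.copy()
            out.add_node(n.entity_type, n.canonical_name, dict(n.attributes), emb, node_id=n.id)
        for t in self.triples:
            out.add_triple(*t)
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, KnowledgeGraph):
            return NotImplemented
        if self.schema != other.schema or set(self._triples) != set(other._triples):
            return False
        if sorted(self._nodes) != sorted(other._nodes):
            return False
        for i, node in self._nodes.items():
            o = other._nodes[i]
            if (node.entity_type, node.canonical_name, node.attributes) != (
                o.entity_type, o.canonical_name, o.attributes
            ):
                return False
            a, b = node.embedding, o.embedding
            if (a is None) != (b is None):
                return False
            if a is not None and not np.array_equal(a, b):
                return False
        return True


def fuse_graphs(graphs: Sequence[KnowledgeGraph]) -> KnowledgeGraph:
    """Merge graphs sharing one schema into a new graph.

    Nodes with equal (entity_type, canonical_name) collapse into one node;
    attribute maps are united with first-seen-wins conflict resolution (the
    discarded value is logged).  Triples are re-pointed to the merged ids and
    de-duplicated.  Inputs are not modified.
    """
    if not graphs:
        raise FusionError("nothing to fuse")
    schema = graphs[0].schema
    for g in graphs[1:]:
        if g.schema != schema:
            raise FusionError("all graphs must share one schema")

    out = KnowledgeGraph(schema)
    key_to_id: dict[tuple[str, str], int] = {}
    for g in graphs:
        remap: dict[int, int] = {}
        for node in g.nodes:
            if node.key in key_to_id:
                merged = out.node(key_to_id[node.key])
                for attr, value in node.attributes.items():
                    if attr in merged.attributes and merged.attributes[attr] != value:
                        logger.info(
                            "fuse: discarding conflicting value %r for %s.%s (kept %r)",
                            value, node.key, attr, merged.attributes[attr],
                        )
                    else:
                        merged.attributes.setdefault(attr, value)
                if merged.embedding is None and node.embedding is not None:
                    merged.embedding = node.embedding.copy()
            else:
                emb = None if node.embedding is None else node.embedding.copy()
                new = out.add_node(node.entity_type, node.canonical_name, dict(node.attributes), emb)
                key_to_id[node.key] = new.id
            remap[node.id] = key_to_id[node.key]
        for t in g.triples:
            head, tail = remap[t.head], remap[t.tail]
            if head != tail:
                out.add_triple(head, t.relation, tail)
    return out


def adjacency_list(
    kg: KnowledgeGraph,
    relations: Iterable[str] | None = None,
    directed: bool = False,
) -> dict[int, list[int]]:
    """Neighbor map A(v_i) = {v_j | (v_i, v_j) in R}.

    Edges are treated as undirected by default (the walk convention);
    neighbor lists are sorted and duplicate-free.
    """
    wanted = None if relations is None else set(relations)
    adj: dict[int, set[int]] = {n.id: set() for n in kg.nodes}
    for t in kg.triples:
        if wanted is not None and t.relation not in wanted:
            continue
        adj[t.head].add(t.tail)
        if not directed:
            adj[t.tail].add(t.head)
    return {i: sorted(neigh) for i, neigh in sorted(adj.items())}
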