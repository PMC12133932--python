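"""Graph I/O: JSON Lines, GraphML (via networkx), and node+edge CSV.

Embeddings are serialized as float32 value lists; write/read round-trips are
exact at float32 precision.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import networkx as nx
import numpy as np

from .errors import ParseError, SchemaError
from .kg_core import EntitySchema, KnowledgeGraph, default_schema

FORMATS = ("jsonl", "graphml", "csv")


def _embedding_to_list(emb: np.ndarray | None) -> list[float] | None:
    if emb is None:
        return None
    return [float(x) for x in np.asarray(emb, dtype=np.float32)]


def _embedding_from_list(values) -> np.ndarray | None:
    if values is None:
        return None
    return np.asarray(values, dtype=np.float32)


# ---------------------------------------------------------------------------
# JSONL: one record per line; node records then triple records.
# ---------------------------------------------------------------------------

def write_jsonl(kg: KnowledgeGraph, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for node in kg.nodes:
            rec = {
                "id": node.id,
                "type": node.entity_type,
                "name": node.canonical_name,
                "attributes": node.attributes,
            }
            emb = _embedding_to_list(node.embedding)
            if emb is not None:
                rec["embedding"] = emb
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")
        for t in kg.triples:
            fh.write(json.dumps({"head": t.head, "relation": t.relation, "tail": t.tail}) + "\n")


def read_jsonl(path: str | Path, schema: EntitySchema | None = None) -> KnowledgeGraph:
    kg = KnowledgeGraph(schema or default_schema())
    pending: list[tuple[int, dict]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ParseError(f"invalid JSON: {exc}", line=lineno) from exc
            if "relation" in rec:
                pending.append((lineno, rec))
            elif {"id", "type", "name"} <= rec.keys():
                try:
                    kg.add_node(
                        rec["type"], rec["name"], rec.get("attributes") or {},
                        _embedding_from_list(rec.get("embedding")), node_id=int(rec["id"]),
                    )
                except SchemaError as exc:
                    raise ParseError(str(exc), line=lineno) from exc
            else:
                raise ParseError("record is neither a node nor a triple", line=lineno)
    for lineno, rec in pending:
        try:
            kg.add_triple(int(rec["head"]), rec["relation"], int(rec["tail"]))
        except SchemaError as exc:
            raise ParseError(str(exc), line=lineno) from exc
    return kg


def read_triples_jsonl(path: str | Path, schema: EntitySchema | None = None) -> KnowledgeGraph:
    """Build a graph from a bare edge list ``{"head": name, "relation": r, "tail": name}``.

    Endpoint entity types are inferred from the relation's typed signature,
    which is unique per relation name in the default schema.
    """
    schema = schema or default_schema()
    kg = KnowledgeGraph(schema)
    ids: dict[tuple[str, str], int] = {}

    def _node(entity_type: str, name: str) -> int:
        key = (entity_type, name)
        if key not in ids:
            ids[key] = kg.add_node(entity_type, name).id
        return ids[key]

    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ParseError(f"invalid JSON: {exc}", line=lineno) from exc
            try:
                head_t, tail_t = schema.relation_signature(rec["relation"])
                kg.add_triple(
                    _node(head_t, rec["head"]), rec["relation"], _node(tail_t, rec["tail"])
                )
            except KeyError as exc:
                raise ParseError(f"missing field {exc}", line=lineno) from exc
            except SchemaError as exc:
                raise ParseError(str(exc), line=lineno) from exc
    return kg


# ---------------------------------------------------------------------------
# GraphML
# ---------------------------------------------------------------------------

def write_graphml(kg: KnowledgeGraph, path: str | Path) -> None:
    g = nx.MultiDiGraph()
    for node in kg.nodes:
        data = {"entity_type": node.entity_type, "name": node.canonical_name,
                "attributes": json.dumps(node.attributes, ensure_ascii=False)}
        emb = _embedding_to_list(node.embedding)
        if emb is not None:
            data["embedding"] = json.dumps(emb)
        g.add_node(node.id, **data)
    for t in kg.triples:
        g.add_edge(t.head, t.tail, relation=t.relation)
    nx.write_graphml(g, str(path))


def read_graphml(path: str | Path, schema: EntitySchema | None = None) -> KnowledgeGraph:
    g = nx.read_graphml(str(path))
    kg = KnowledgeGraph(schema or default_schema())
    for raw_id, data in sorted(g.nodes(data=True), key=lambda kv: int(kv[0])):
        kg.add_node(
            data["entity_type"], data["name"],
            json.loads(data.get("attributes", "{}")),
            _embedding_from_list(json.loads(data["embedding"])) if "embedding" in data else None,
            node_id=int(raw_id),
        )
    for u, v, data in g.edges(data=True):
        kg.add_triple(int(u), data["relation"], int(v))
    return kg


# ---------------------------------------------------------------------------
# node+edge CSV (graph-database bulk-import shape)
# ---------------------------------------------------------------------------

def _csv_paths(path: str | Path) -> tuple[Path, Path]:
    base = Path(path)
    if base.suffix == ".csv":
        base = base.with_suffix("")
    return base.with_suffix(".nodes.csv"), base.with_suffix(".edges.csv")


def write_csv(kg: KnowledgeGraph, path: str | Path) -> None:
    nodes_path, edges_path = _csv_paths(path)
    with open(nodes_path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["nodeId", "type", "name", "attributes", "embedding"])
        for node in kg.nodes:
            emb = _embedding_to_list(node.embedding)
            w.writerow([
                node.id, node.entity_type, node.canonical_name,
                json.dumps(node.attributes, ensure_ascii=False),
                "" if emb is None else json.dumps(emb),
            ])
    with open(edges_path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["startId", "relation", "endId"])
        for t in kg.triples:
            w.writerow([t.head, t.relation, t.tail])


def read_csv(path: str | Path, schema: EntitySchema | None = None) -> KnowledgeGraph:
    nodes_path, edges_path = _csv_paths(path)
    kg = KnowledgeGraph(schema or default_schema())
    with open(nodes_path, newline="", encoding="utf-8") as fh:
        for lineno, row in enumerate(csv.DictReader(fh), start=2):
            try:
                kg.add_node(
                    row["type"], row["name"], json.loads(row["attributes"] or "{}"),
                    _embedding_from_list(json.loads(row["embedding"])) if row["embedding"] else None,
                    node_id=int(row["nodeId"]),
                )
            except (KeyError, ValueError, SchemaError) as exc:
                raise ParseError(str(exc), line=lineno) from exc
    with open(edges_path, newline="", encoding="utf-8") as fh:
        for lineno, row in enumerate(csv.DictReader(fh), start=2):
            try:
                kg.add_triple(int(row["startId"]), row["relation"], int(row["endId"]))
            except (KeyError, ValueError, SchemaError) as exc:
                raise ParseError(str(exc), line=lineno) from exc
    return kg


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

_WRITERS = {"jsonl": write_jsonl, "graphml": write_graphml, "csv": write_csv}
_READERS = {"jsonl": read_jsonl, "graphml": read_graphml, "csv": read_csv}


def write_graph(kg: KnowledgeGraph, path: str | Path, format: str = "jsonl") -> None:
    if format not in _WRITERS:
        raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")
    _WRITERS[format](kg, path)


def read_graph(path: str | Path, format: str = "jsonl",
               schema: EntitySchema | None = None) -> KnowledgeGraph:
    if format not in _READERS:
        raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")
    return _READERS[format](path, schema)
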