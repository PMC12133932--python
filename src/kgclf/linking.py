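"""Combined entity linking: exact name match first, semantic-similarity
fallback second, then frequency-weighted aggregation of the linked nodes'
embeddings into a single knowledge vector."""

from __future__ import annotations

import zlib
from collections import Counter
from dataclasses import dataclass
from typing import Protocol, Sequence

import numpy as np

from .errors import ContractError, StateError
from .kg_core import KnowledgeGraph, Node

#: Entity types considered as linking candidates.
DEFAULT_CANDIDATE_TYPES = ("Symptoms", "Syndrome")

DEFAULT_TAU = 0.5
DEFAULT_DIMENSION = 384


class SentenceEmbedder(Protocol):
    """Deterministic text -> vector contract used by the semantic fallback."""

    dimension: int

    def encode(self, text: str) -> np.ndarray: ...


class HashingNgramEmbedder:
    """Deterministic character-n-gram hashing embedder.

    Hashes boundary-padded character n-grams into signed buckets and
    L2-normalizes; a stand-in for a pretrained sentence encoder that keeps
    string-similar surface forms close in cosine similarity.
    """

    def __init__(self, dimension: int = DEFAULT_DIMENSION, n: int = 3):
        if dimension < 1:
            raise ValueError("dimension must be >= 1")
        self.dimension = dimension
        self.n = n
        self.calls = 0  # instrumentation: exact-match precedence tests

    def encode(self, text: str) -> np.ndarray:
        self.calls += 1
        vec = np.zeros(self.dimension)
        padded = f"^{text}$"
        grams = [padded[i:i + self.n] for i in range(max(len(padded) - self.n + 1, 1))]
        for gram in grams:
            h = zlib.crc32(gram.encode("utf-8"))
            sign = 1.0 if (h >> 31) & 1 else -1.0
            vec[h % self.dimension] += sign
        norm = np.linalg.norm(vec)
        return vec / norm if norm > 0 else vec


@dataclass
class LinkResult:
    """Outcome of combined entity linking for one mention."""

    mention: str
    node: int | None
    method: str  # "exact" | "semantic" | "none"
    similarity: float | None = None
    frequency: int = 1

    def __post_init__(self) -> None:
        if self.method not in ("exact", "semantic", "none"):
            raise ValueError(f"unknown link method {self.method!r}")
        if self.method == "none" and self.node is not None:
            raise ValueError("method 'none' must carry no node")
        if self.frequency < 1:
            raise ValueError("frequency must be >= 1")


def _node_text(node: Node) -> str:
    """Name plus definition attribute, the text embedded for the fallback."""
    parts = [node.canonical_name]
    for attr, value in sorted(node.attributes.items()):
        if "definition" in attr.lower() and value:
            parts.append(value)
    return " ".join(parts)


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    return float(a @ b / denom) if denom > 0 else 0.0


def link_mention(
    mention: str,
    kg: KnowledgeGraph,
    embedder: SentenceEmbedder | None = None,
    tau: float = DEFAULT_TAU,
    candidate_types: Sequence[str] = DEFAULT_CANDIDATE_TYPES,
    semantic_fallback: bool = True,
) -> LinkResult:
    """Link one mention: hard name match first, semantic fallback second.

    The fallback is never invoked when an exact match exists.  Ties resolve
    to the higher similarity, then the lower node id.  ``tau=-1`` accepts the
    top-1 candidate unconditionally; ``semantic_fallback=False`` disables the
    fallback entirely.
    """
    if not mention:
        raise ValueError("mention must be non-empty")
    for etype in candidate_types:
        hits = kg.find_nodes(etype, mention)
        if hits:
            return LinkResult(mention, hits[0].id, "exact")
    if not semantic_fallback or embedder is None:
        return LinkResult(mention, None, "none")
    candidates = kg.nodes_of_type(*candidate_types)
    if not candidates:
        return LinkResult(mention, None, "none")
    query = np.asarray(embedder.encode(mention), dtype=float)
    if query.shape != (embedder.dimension,):
        raise ContractError(
            f"embedder returned shape {query.shape}, contract says ({embedder.dimension},)"
        )
    best: tuple[float, int] | None = None
    for node in candidates:  # sorted by id -> deterministic tie-break
        sim = _cosine(query, np.asarray(embedder.encode(_node_text(node)), dtype=float))
        if best is None or sim > best[0]:
            best = (sim, node.id)
    sim, node_id = best
    if sim >= tau:
        return LinkResult(mention, node_id, "semantic", similarity=sim)
    return LinkResult(mention, None, "none", similarity=sim)


def link_mentions(
    mentions: Sequence[str],
    kg: KnowledgeGraph,
    embedder: SentenceEmbedder | None = None,
    tau: float = DEFAULT_TAU,
    candidate_types: Sequence[str] = DEFAULT_CANDIDATE_TYPES,
    semantic_fallback: bool = True,
) -> list[LinkResult]:
    """Link all mentions of one record; frequencies count per-node resolutions."""
    links = [
        link_mention(m, kg, embedder, tau, candidate_types, semantic_fallback)
        for m in mentions
    ]
    counts = Counter(l.node for l in links if l.node is not None)
    for l in links:
        if l.node is not None:
            l.frequency = counts[l.node]
    return links


def aggregate_knowledge_embedding(
    links: Sequence[LinkResult],
    kg: KnowledgeGraph,
    dimension: int = DEFAULT_DIMENSION,
) -> np.ndarray:
    """Frequency-weighted mean of linked nodes' embedding vectors.

    V_kg = sum_i f_i V_i / sum_i f_i over distinct linked nodes, where f_i is
    the number of the record's mentions resolving to node i.  When no link
    succeeded the all-zero vector of ``dimension`` is returned.
    """
    counts = Counter(l.node for l in links if l.node is not None)
    if not counts:
        return np.zeros(dimension)
    total = 0.0
    acc: np.ndarray | None = None
    for node_id, freq in sorted(counts.items()):
        node = kg.node(node_id)
        if node.embedding is None:
            raise StateError(
                f"node {node_id} has no embedding; embed the graph before linking"
            )
        vec = np.asarray(node.embedding, dtype=float)
        acc = freq * vec if acc is None else acc + freq * vec
        total += freq
    return acc / total
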