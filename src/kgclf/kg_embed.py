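"""Graph representation learning: truncated random walks over the adjacency
list followed by skip-gram training with a full-softmax objective.

The skip-gram uses a single embedding table V; for a (center w, context u)
pair the objective is log P(u|w) = V_u.V_w - log sum_v exp(V_v.V_w).
Gradients are exact for the shared-table parameterization (including the
v = w term of the partition function).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.special import logsumexp, softmax

from .kg_core import KnowledgeGraph, adjacency_list


@dataclass(frozen=True)
class WalkConfig:
    """Random-walk parameters; ``walk_length`` is the maximum walk length T."""

    walk_length: int = 20
    walks_per_node: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.walk_length < 1:
            raise ValueError("walk_length must be >= 1")
        if self.walks_per_node < 1:
            raise ValueError("walks_per_node must be >= 1")


@dataclass(frozen=True)
class SkipGramConfig:
    dimension: int = 384
    window: int = 5
    epochs: int = 5
    learning_rate: float = 0.05
    batch_size: int = 64
    seed: int = 0
    #: "sgd" updates per mini-batch; "full" takes one full-batch step per epoch.
    mode: str = "sgd"

    def __post_init__(self) -> None:
        if self.dimension < 1:
            raise ValueError("dimension must be >= 1")
        if self.window < 1:
            raise ValueError("window must be >= 1")


@dataclass
class EmbeddingTable:
    """node-id -> fixed-dimension vector map."""

    dimension: int
    vectors: dict[int, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for nid, vec in self.vectors.items():
            vec = np.asarray(vec, dtype=np.float32)
            if vec.shape != (self.dimension,):
                raise ValueError(f"vector for node {nid} has shape {vec.shape}")
            if not np.all(np.isfinite(vec)):
                raise ValueError(f"vector for node {nid} has non-finite entries")
            self.vectors[nid] = vec

    def __contains__(self, node_id: int) -> bool:
        return node_id in self.vectors

    def __getitem__(self, node_id: int) -> np.ndarray:
        return self.vectors[node_id]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for nid in sorted(self.vectors):
                vals = "\t".join(repr(float(x)) for x in self.vectors[nid])
                fh.write(f"{nid}\t{vals}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "EmbeddingTable":
        vectors: dict[int, np.ndarray] = {}
        dim = None
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                vec = np.asarray([float(x) for x in parts[1:]], dtype=np.float32)
                dim = len(vec) if dim is None else dim
                vectors[int(parts[0])] = vec
        return cls(dim or 0, vectors)


def generate_walks(adj: Mapping[int, Sequence[int]], cfg: WalkConfig) -> list[list[int]]:
    """r truncated random walks per node; uniform neighbor choice; seeded.

    A walk stops early when the current node has no neighbors.
    """
    rng = np.random.default_rng(cfg.seed)
    walks: list[list[int]] = []
    for start in sorted(adj):
        for _ in range(cfg.walks_per_node):
            walk = [start]
            while len(walk) < cfg.walk_length:
                neighbors = adj.get(walk[-1], ())
                if not neighbors:
                    break
                walk.append(neighbors[rng.integers(len(neighbors))])
            walks.append(walk)
    return walks


def _walk_pairs(walks: Sequence[Sequence[int]], window: int,
                index: Mapping[int, int]) -> np.ndarray:
    """(center, context) index pairs within ``window`` positions in each walk."""
    pairs: list[tuple[int, int]] = []
    for walk in walks:
        for i, w in enumerate(walk):
            lo, hi = max(0, i - window), min(len(walk), i + window + 1)
            for j in range(lo, hi):
                if j != i:
                    pairs.append((index[w], index[walk[j]]))
    return np.asarray(pairs, dtype=np.int64).reshape(-1, 2)


def context_distribution(V: np.ndarray, w: int) -> np.ndarray:
    """P(.|w) under the full softmax; sums to one."""
    return softmax(V @ V[w])


def log_prob_and_grad(V: np.ndarray, w: int, u: int) -> tuple[float, np.ndarray]:
    """log P(u|w) and its exact gradient with respect to the shared table V."""
    scores = V @ V[w]
    logp = float(scores[u] - logsumexp(scores))
    p = softmax(scores)
    grad = -np.outer(p, V[w])          # -p_x * V_w for every row x
    grad[u] += V[w]
    grad[w] += V[u] - p @ V            # d/dV_w of V_u.V_w - log Z (v = w term
    return logp, grad                  # enters through the -p_x V_w row above)


def skipgram_objective(V: np.ndarray, pairs: np.ndarray) -> float:
    """Total log-likelihood sum over (center, context) pairs."""
    total = 0.0
    for w in np.unique(pairs[:, 0]):
        scores = V @ V[w]
        logz = logsumexp(scores)
        ctx = pairs[pairs[:, 0] == w, 1]
        total += float(np.sum(scores[ctx]) - len(ctx) * logz)
    return total


def _batch_gradient(V: np.ndarray, centers: np.ndarray, contexts: np.ndarray) -> np.ndarray:
    """Exact gradient of sum_j log P(u_j|w_j) over a batch, shared table."""
    scores = V[centers] @ V.T                      # (B, vocab)
    scores -= scores.max(axis=1, keepdims=True)
    P = np.exp(scores)
    P /= P.sum(axis=1, keepdims=True)
    grad = -P.T @ V[centers]                       # -sum_j p_j,x V_w_j
    np.add.at(grad, contexts, V[centers])
    np.add.at(grad, centers, V[contexts] - P @ V)
    return grad


def train_skipgram(walks: Sequence[Sequence[int]], cfg: SkipGramConfig) -> EmbeddingTable:
    """Skip-gram with full softmax over the walk corpus; seeded and exact-gradient.

    Every node appearing in the walks receives a vector of ``cfg.dimension``.
    """
    if not walks:
        raise ValueError("walks must be non-empty")
    vocab = sorted({n for walk in walks for n in walk})
    index = {n: i for i, n in enumerate(vocab)}
    rng = np.random.default_rng(cfg.seed)
    V = rng.uniform(-0.5, 0.5, size=(len(vocab), cfg.dimension)) / cfg.dimension
    pairs = _walk_pairs(walks, cfg.window, index)
    if len(pairs) == 0:
        # single-node walks only: vectors stay at initialization
        return EmbeddingTable(cfg.dimension,
                              {n: V[i].astype(np.float32) for n, i in index.items()})
    for _ in range(cfg.epochs):
        if cfg.mode == "full":
            V += cfg.learning_rate * _batch_gradient(V, pairs[:, 0], pairs[:, 1]) / len(pairs)
            continue
        order = rng.permutation(len(pairs))
        for lo in range(0, len(order), cfg.batch_size):
            batch = pairs[order[lo:lo + cfg.batch_size]]
            V += cfg.learning_rate * _batch_gradient(V, batch[:, 0], batch[:, 1]) / len(batch)
    return EmbeddingTable(cfg.dimension,
                          {n: V[i].astype(np.float32) for n, i in index.items()})


def embed_graph(
    kg: KnowledgeGraph,
    walk_cfg: WalkConfig | None = None,
    sg_cfg: SkipGramConfig | None = None,
    node_filter: Sequence[str] | None = None,
) -> KnowledgeGraph:
    """Attach trained vectors to node ``embedding`` attributes.

    ``node_filter`` restricts walks (and thus embedding) to a typed subgraph;
    other nodes are left untouched.
    """
    if kg.n_nodes == 0:
        raise ValueError("graph is empty")
    walk_cfg = walk_cfg or WalkConfig()
    sg_cfg = sg_cfg or SkipGramConfig()
    adj = adjacency_list(kg)
    if node_filter is not None:
        keep = {n.id for n in kg.nodes_of_type(*node_filter)}
        adj = {i: [j for j in neigh if j in keep] for i, neigh in adj.items() if i in keep}
    walks = generate_walks(adj, walk_cfg)
    table = train_skipgram(walks, sg_cfg)
    out = kg.copy()
    for node in out.nodes:
        if node.id in table:
            node.embedding = table[node.id].copy()
    return out
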