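"""Multiclass metrics (accuracy and macro precision/recall/F1) and experiment
harnesses: ablation over model variants and a KG-embedding-dimension sweep."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .kg_core import KnowledgeGraph
from .kg_embed import SkipGramConfig, WalkConfig, embed_graph
from .linking import (
    HashingNgramEmbedder,
    SentenceEmbedder,
    aggregate_knowledge_embedding,
    link_mentions,
)
from .model import EMRRecord, FusionModel, SmallTextEncoder, TrainConfig


@dataclass
class ConfusionCounts:
    """Per-class TP/FP/FN/TN tallies for a multiclass problem."""

    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    tn: np.ndarray
    n_classes: int
    total: int

    @classmethod
    def from_labels(cls, y_true: Sequence[int], y_pred: Sequence[int],
                    n_classes: int) -> "ConfusionCounts":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        if y_true.shape != y_pred.shape or y_true.size == 0:
            raise ValueError("y_true and y_pred must be equal-length and non-empty")
        for arr in (y_true, y_pred):
            if arr.min() < 0 or arr.max() >= n_classes:
                raise ValueError(f"labels must lie in [0, {n_classes})")
        tp = np.empty(n_classes, dtype=np.int64)
        fp = np.empty(n_classes, dtype=np.int64)
        fn = np.empty(n_classes, dtype=np.int64)
        for k in range(n_classes):
            tp[k] = int(np.sum((y_true == k) & (y_pred == k)))
            fp[k] = int(np.sum((y_true != k) & (y_pred == k)))
            fn[k] = int(np.sum((y_true == k) & (y_pred != k)))
        total = int(y_true.size)
        tn = total - tp - fp - fn
        return cls(tp, fp, fn, tn, n_classes, total)


@dataclass(frozen=True)
class MetricReport:
    acc: float
    macro_f1: float
    macro_precision: float
    macro_recall: float

    def __post_init__(self) -> None:
        for name in ("acc", "macro_f1", "macro_precision", "macro_recall"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")


def _safe_div(num: np.ndarray, den: np.ndarray, what: str) -> np.ndarray:
    out = np.zeros_like(num, dtype=float)
    mask = den > 0
    if not mask.all():
        warnings.warn(f"classes {np.flatnonzero(~mask).tolist()} have zero "
                      f"denominator for {what}; contributing 0", stacklevel=3)
    out[mask] = num[mask] / den[mask]
    return out


def compute_metrics(y_true: Sequence[int], y_pred: Sequence[int],
                    n_classes: int) -> MetricReport:
    """Accuracy plus macro-averaged precision/recall/F1.

    Accuracy is correct/total (the multiclass reduction of the one-vs-rest
    count formula).  Per-class precision, recall and F1 with a zero
    denominator contribute 0 to the macro average.
    """
    counts = ConfusionCounts.from_labels(y_true, y_pred, n_classes)
    precision = _safe_div(counts.tp, counts.tp + counts.fp, "precision")
    recall = _safe_div(counts.tp, counts.tp + counts.fn, "recall")
    f1 = _safe_div(2 * precision * recall, precision + recall, "f1")
    return MetricReport(
        acc=float(counts.tp.sum() / counts.total),
        macro_f1=float(f1.mean()),
        macro_precision=float(precision.mean()),
        macro_recall=float(recall.mean()),
    )


# ---------------------------------------------------------------------------
# experiment harnesses
# ---------------------------------------------------------------------------

@dataclass
class LabeledDataset:
    """Train/eval records plus per-record mention lists for linking."""

    train_records: list[EMRRecord]
    train_mentions: list[list[str]]
    eval_records: list[EMRRecord]
    eval_mentions: list[list[str]]
    n_classes: int


def compute_record_vectors(
    mentions_per_record: Sequence[Sequence[str]],
    kg: KnowledgeGraph,
    embedder: SentenceEmbedder | None,
    tau: float,
    dimension: int,
    semantic_fallback: bool = True,
) -> list[np.ndarray]:
    vecs = []
    for mentions in mentions_per_record:
        links = link_mentions(mentions, kg, embedder, tau,
                              semantic_fallback=semantic_fallback)
        vecs.append(aggregate_knowledge_embedding(links, kg, dimension))
    return vecs


def _train_and_score(
    data: LabeledDataset,
    train_vecs: Sequence[np.ndarray],
    eval_vecs: Sequence[np.ndarray],
    kg_dim: int,
    mode: str,
    fusion_method: str,
    train_cfg: TrainConfig,
    encoder_hidden: int,
) -> MetricReport:
    encoder = SmallTextEncoder(hidden_size=encoder_hidden, seed=train_cfg.seed)
    model = FusionModel(encoder, data.n_classes, kg_dim=kg_dim,
                        fusion_method=fusion_method, mode=mode, seed=train_cfg.seed)
    model.fit(data.train_records, train_vecs, train_cfg)
    preds = model.predict_many(data.eval_records, eval_vecs)
    truth = [r.label for r in data.eval_records]
    return compute_metrics(truth, preds, data.n_classes)


def run_ablation(
    data: LabeledDataset,
    kg: KnowledgeGraph,
    embedder: SentenceEmbedder | None = None,
    tau: float = 0.5,
    kg_dim: int = 384,
    fusion_method: str = "concat",
    train_cfg: TrainConfig | None = None,
    encoder_hidden: int = 64,
) -> pd.DataFrame:
    """Train and score the four model variants under identical seeds/splits.

    Variants: text_only (knowledge path removed), kg_only (text path
    removed), no_st (semantic fallback disabled; failed links yield the zero
    vector), and full.
    """
    if data.n_classes < 2:
        raise ValueError("need at least 2 classes")
    train_cfg = train_cfg or TrainConfig()
    # similarity embedder dimension is independent of the KG embedding dim
    embedder = embedder or HashingNgramEmbedder()
    full_train = compute_record_vectors(data.train_mentions, kg, embedder, tau, kg_dim)
    full_eval = compute_record_vectors(data.eval_mentions, kg, embedder, tau, kg_dim)
    nost_train = compute_record_vectors(data.train_mentions, kg, None, tau, kg_dim,
                                        semantic_fallback=False)
    nost_eval = compute_record_vectors(data.eval_mentions, kg, None, tau, kg_dim,
                                       semantic_fallback=False)
    zeros_train = [np.zeros(kg_dim) for _ in data.train_records]
    zeros_eval = [np.zeros(kg_dim) for _ in data.eval_records]

    rows = []
    configs = [
        ("text_only", "text_only", zeros_train, zeros_eval),
        ("kg_only", "kg_only", full_train, full_eval),
        ("no_st", "full", nost_train, nost_eval),
        ("full", "full", full_train, full_eval),
    ]
    for name, mode, tr, ev in configs:
        report = _train_and_score(data, tr, ev, kg_dim, mode, fusion_method,
                                  train_cfg, encoder_hidden)
        rows.append({"config": name, "acc": report.acc, "macro_f1": report.macro_f1,
                     "macro_precision": report.macro_precision,
                     "macro_recall": report.macro_recall, "seed": train_cfg.seed})
    return pd.DataFrame(rows)


def sweep_kg_dimension(
    data: LabeledDataset,
    kg: KnowledgeGraph,
    dims: Sequence[int] = (64, 128, 384, 768),
    tau: float = 0.5,
    walk_cfg: WalkConfig | None = None,
    sg_epochs: int = 3,
    train_cfg: TrainConfig | None = None,
    encoder_hidden: int = 64,
) -> pd.DataFrame:
    """Re-embed the graph at each dimension, retrain the full model, report."""
    if not dims:
        raise ValueError("dims must be non-empty")
    if any(d <= 0 for d in dims):
        raise ValueError("dimensions must be positive")
    train_cfg = train_cfg or TrainConfig()
    walk_cfg = walk_cfg or WalkConfig(seed=train_cfg.seed)
    rows = []
    for dim in dims:
        sg_cfg = SkipGramConfig(dimension=dim, epochs=sg_epochs, seed=train_cfg.seed)
        embedded = embed_graph(kg, walk_cfg, sg_cfg)
        embedder = HashingNgramEmbedder()
        train_vecs = compute_record_vectors(data.train_mentions, embedded, embedder, tau, dim)
        eval_vecs = compute_record_vectors(data.eval_mentions, embedded, embedder, tau, dim)
        report = _train_and_score(data, train_vecs, eval_vecs, dim, "full", "concat",
                                  train_cfg, encoder_hidden)
        rows.append({"dim": dim, "acc": report.acc, "macro_f1": report.macro_f1,
                     "macro_precision": report.macro_precision,
                     "macro_recall": report.macro_recall, "seed": train_cfg.seed})
    return pd.DataFrame(rows)
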