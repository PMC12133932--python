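"""Text representation and knowledge fusion classifier.

A record is formatted into a single string, encoded into a text vector, and
combined with the record's aggregated knowledge vector through a learned
projection plus one of three fusion methods (CONCAT default, AVG, WEIGHTED).
A linear head with softmax produces class probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np

from .errors import StateError
from .lstm import Adam

FUSION_METHODS = ("concat", "avg", "weighted")
MODES = ("full", "text_only", "kg_only")

UNK = "<unk>"


@dataclass
class EMRRecord:
    """One clinical record; ``label`` is the class id (training only)."""

    disease_name: str = ""
    chief_complaint: str = ""
    history: str = ""
    label: int | None = None

    def __post_init__(self) -> None:
        if not (self.disease_name or self.chief_complaint or self.history):
            raise ValueError("at least one text field must be non-empty")


def format_emr(record: EMRRecord) -> str:
    """Render a record as ``[CLS] disease, complaint [SEP] history [SEP]``."""
    return (
        f"[CLS] {record.disease_name}, {record.chief_complaint} "
        f"[SEP] {record.history} [SEP]"
    )


class TextEncoder(Protocol):
    hidden_size: int

    def encode(self, text: str) -> np.ndarray: ...


class SmallTextEncoder:
    """Trainable bag-of-embeddings encoder: mean-pooled token embeddings
    through one tanh dense layer.  Desk-scale stand-in for a pretrained
    transformer behind the same contract."""

    def __init__(self, hidden_size: int = 64, seed: int = 0):
        self.hidden_size = hidden_size
        self._seed = seed
        self.vocab: dict[str, int] | None = None
        self.Emb: np.ndarray | None = None
        self.W1: np.ndarray | None = None
        self.b1: np.ndarray | None = None

    def tokenize(self, text: str) -> list[str]:
        return text.split()

    def prepare(self, texts: Sequence[str]) -> None:
        """Build the vocabulary and initialize parameters (idempotent)."""
        if self.vocab is not None:
            return
        tokens = sorted({tok for t in texts for tok in self.tokenize(t)} - {UNK})
        self.vocab = {tok: i for i, tok in enumerate([UNK] + tokens)}
        rng = np.random.default_rng(self._seed)
        H = self.hidden_size
        self.Emb = rng.normal(0, 0.1, size=(len(self.vocab), H))
        self.W1 = rng.uniform(-1, 1, size=(H, H)) / np.sqrt(H)
        self.b1 = np.zeros(H)

    @property
    def params(self) -> dict[str, np.ndarray]:
        if self.vocab is None:
            raise StateError("encoder not prepared")
        return {"Emb": self.Emb, "W1": self.W1, "b1": self.b1}

    def forward(self, text: str, max_len: int | None = None):
        if self.vocab is None:
            raise StateError("encoder not prepared")
        tokens = self.tokenize(text)
        if max_len is not None:
            tokens = tokens[:max_len]
        ids = np.asarray([self.vocab.get(t, 0) for t in tokens], dtype=np.int64)
        x = self.Emb[ids].mean(axis=0) if len(ids) else np.zeros(self.hidden_size)
        h = np.tanh(self.W1 @ x + self.b1)
        return h, (ids, x, h)

    def backward(self, dh: np.ndarray, cache, grads: dict[str, np.ndarray]) -> None:
        ids, x, h = cache
        dpre = dh * (1.0 - h * h)
        grads["W1"] += np.outer(dpre, x)
        grads["b1"] += dpre
        if len(ids):
            dx = self.W1.T @ dpre / len(ids)
            np.add.at(grads["Emb"], ids, dx)

    def encode(self, text: str) -> np.ndarray:
        return self.forward(text)[0]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization defaults mirror the reference configuration (cross-entropy
    loss, AdamW, batch 16, lr 2e-5, weight decay 0.02, max seq length 128,
    10 epochs); the small test encoder is trained with a larger lr."""

    batch_size: int = 16
    learning_rate: float = 2e-5
    weight_decay: float = 0.02
    max_seq_length: int = 128
    epochs: int = 10
    seed: int = 0
    freeze_encoder: bool = False


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


class FusionModel:
    """Text-encoder backend + knowledge projection + fusion + label head.

    ``mode`` selects the ablation variant: "full" fuses both signals,
    "text_only" drops the knowledge path, "kg_only" drops the text path.
    """

    def __init__(
        self,
        encoder: TextEncoder,
        n_classes: int,
        kg_dim: int = 384,
        fusion_method: str = "concat",
        mode: str = "full",
        seed: int = 0,
    ):
        if fusion_method not in FUSION_METHODS:
            raise ValueError(f"fusion_method must be one of {FUSION_METHODS}")
        if mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if n_classes < 2:
            raise ValueError("need at least 2 classes")
        self.encoder = encoder
        self.n_classes = n_classes
        self.kg_dim = kg_dim
        self.fusion_method = fusion_method
        self.mode = mode
        hidden = encoder.hidden_size
        self.proj_dim = kg_dim if fusion_method == "concat" else hidden
        if mode == "text_only":
            self.fused_dim = hidden
        elif mode == "kg_only":
            self.fused_dim = self.proj_dim
        elif fusion_method == "concat":
            self.fused_dim = self.proj_dim + hidden
        else:
            self.fused_dim = hidden
        rng = np.random.default_rng(seed)
        self.P = rng.uniform(-1, 1, size=(self.proj_dim, kg_dim)) / np.sqrt(kg_dim)
        self.bP = np.zeros(self.proj_dim)
        #: raw non-negative fusion weights; normalized to sum 1 at use
        self.fusion_weights = np.array([0.5, 0.5])
        self.W2 = rng.uniform(-1, 1, size=(n_classes, self.fused_dim)) / np.sqrt(self.fused_dim)
        self.b2 = np.zeros(n_classes)
        self.fitted = False
        self.training_log: list[float] = []

    # -- fusion ------------------------------------------------------------

    def project(self, v_kg: np.ndarray) -> np.ndarray:
        v_kg = np.asarray(v_kg, dtype=float)
        if v_kg.shape != (self.kg_dim,):
            raise ValueError(f"v_kg has shape {v_kg.shape}, expected ({self.kg_dim},)")
        return self.P @ v_kg + self.bP

    def fuse(self, v_kg: np.ndarray, v_emrs: np.ndarray) -> np.ndarray:
        """Combine the projected knowledge vector with the text vector."""
        proj = self.project(v_kg)
        v_emrs = np.asarray(v_emrs, dtype=float)
        if v_emrs.shape != (self.encoder.hidden_size,):
            raise ValueError("v_emrs dimension mismatch")
        if self.fusion_method == "concat":
            return np.concatenate([proj, v_emrs])
        if self.fusion_method == "avg":
            return (proj + v_emrs) / 2.0
        w = self.fusion_weights
        alpha, beta = w / w.sum()
        return alpha * proj + beta * v_emrs

    # -- training ----------------------------------------------------------

    def _trainable_params(self, freeze_encoder: bool) -> dict[str, np.ndarray]:
        params: dict[str, np.ndarray] = {"W2": self.W2, "b2": self.b2}
        if self.mode != "text_only":
            params.update({"P": self.P, "bP": self.bP})
            if self.fusion_method == "weighted" and self.mode == "full":
                params["fw"] = self.fusion_weights
        if self.mode != "kg_only" and not freeze_encoder and hasattr(self.encoder, "params"):
            params.update({f"enc.{k}": v for k, v in self.encoder.params.items()})
        return params

    def _forward(self, record: EMRRecord, v_kg: np.ndarray, max_len: int | None):
        cache: dict = {}
        if self.mode != "kg_only":
            if hasattr(self.encoder, "forward"):
                v_emrs, cache["enc"] = self.encoder.forward(format_emr(record), max_len)
            else:
                v_emrs = np.asarray(self.encoder.encode(format_emr(record)), dtype=float)
                cache["enc"] = None
            cache["v_emrs"] = v_emrs
        if self.mode != "text_only":
            proj = self.project(np.asarray(v_kg, dtype=float))
            cache["proj"] = proj
            cache["v_kg"] = np.asarray(v_kg, dtype=float)
        if self.mode == "text_only":
            s = cache["v_emrs"]
        elif self.mode == "kg_only":
            s = cache["proj"]
        elif self.fusion_method == "concat":
            s = np.concatenate([cache["proj"], cache["v_emrs"]])
        elif self.fusion_method == "avg":
            s = (cache["proj"] + cache["v_emrs"]) / 2.0
        else:
            w = self.fusion_weights
            cache["alpha"] = w / w.sum()
            s = cache["alpha"][0] * cache["proj"] + cache["alpha"][1] * cache["v_emrs"]
        cache["s"] = s
        logits = self.W2 @ s + self.b2
        return logits, cache

    def _backward(self, dlogits: np.ndarray, cache: dict,
                  grads: dict[str, np.ndarray], freeze_encoder: bool) -> None:
        grads["W2"] += np.outer(dlogits, cache["s"])
        grads["b2"] += dlogits
        ds = self.W2.T @ dlogits
        hidden = self.encoder.hidden_size
        dproj = dv_emrs = None
        if self.mode == "text_only":
            dv_emrs = ds
        elif self.mode == "kg_only":
            dproj = ds
        elif self.fusion_method == "concat":
            dproj, dv_emrs = ds[:self.proj_dim], ds[self.proj_dim:]
        elif self.fusion_method == "avg":
            dproj = dv_emrs = ds / 2.0
        else:
            alpha = cache["alpha"]
            dproj = alpha[0] * ds
            dv_emrs = alpha[1] * ds
            if "fw" in grads:
                total = self.fusion_weights.sum()
                s = cache["s"]
                grads["fw"][0] += float(ds @ (cache["proj"] - s)) / total
                grads["fw"][1] += float(ds @ (cache["v_emrs"] - s)) / total
        if dproj is not None and "P" in grads:
            grads["P"] += np.outer(dproj, cache["v_kg"])
            grads["bP"] += dproj
        if dv_emrs is not None and not freeze_encoder and hasattr(self.encoder, "backward"):
            enc_grads = {k[4:]: v for k, v in grads.items() if k.startswith("enc.")}
            if enc_grads:
                self.encoder.backward(dv_emrs, cache["enc"], enc_grads)

    def fit(
        self,
        records: Sequence[EMRRecord],
        v_kgs: Sequence[np.ndarray],
        cfg: TrainConfig | None = None,
    ) -> "FusionModel":
        """Minimize cross-entropy of the softmax head with AdamW; seeded."""
        cfg = cfg or TrainConfig()
        if len(records) != len(v_kgs):
            raise ValueError("records and v_kgs must align")
        for rec, v in zip(records, v_kgs):
            if rec.label is None or not (0 <= rec.label < self.n_classes):
                raise ValueError(f"record label {rec.label!r} outside [0, {self.n_classes})")
            if v is None:
                raise StateError("record is missing its knowledge vector")
        if hasattr(self.encoder, "prepare") and self.mode != "kg_only":
            self.encoder.prepare([format_emr(r) for r in records])
        params = self._trainable_params(cfg.freeze_encoder)
        opt = Adam(params, lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
        rng = np.random.default_rng(cfg.seed)
        self.training_log = []
        for _ in range(cfg.epochs):
            order = rng.permutation(len(records))
            epoch_loss = 0.0
            for lo in range(0, len(order), cfg.batch_size):
                batch = order[lo:lo + cfg.batch_size]
                grads = {k: np.zeros_like(v) for k, v in params.items()}
                for idx in batch:
                    logits, cache = self._forward(records[idx], v_kgs[idx], cfg.max_seq_length)
                    probs = _softmax(logits)
                    epoch_loss -= float(np.log(max(probs[records[idx].label], 1e-300)))
                    dlogits = probs.copy()
                    dlogits[records[idx].label] -= 1.0
                    self._backward(dlogits / len(batch), cache, grads, cfg.freeze_encoder)
                opt.step(grads)
                if "fw" in params:
                    np.clip(self.fusion_weights, 1e-6, None, out=self.fusion_weights)
            self.training_log.append(epoch_loss / len(records))
        self.fitted = True
        return self

    # -- inference ---------------------------------------------------------

    def predict(self, record: EMRRecord, v_kg: np.ndarray) -> tuple[int, np.ndarray]:
        """(argmax label, probability vector); lowest-index tie-break."""
        if not self.fitted:
            raise StateError("model is not trained")
        logits, _ = self._forward(record, v_kg, None)
        probs = _softmax(logits)
        return int(np.argmax(probs)), probs

    def predict_many(self, records: Sequence[EMRRecord],
                     v_kgs: Sequence[np.ndarray]) -> np.ndarray:
        return np.asarray([self.predict(r, v)[0] for r, v in zip(records, v_kgs)])

    def accuracy(self, records: Sequence[EMRRecord],
                 v_kgs: Sequence[np.ndarray]) -> float:
        preds = self.predict_many(records, v_kgs)
        truth = np.asarray([r.label for r in records])
        return float(np.mean(preds == truth))
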