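"""Entity extraction: a BiLSTM-CRF sequence tagger for structured records and
a pluggable extractor contract with a deterministic gazetteer backend for
semi-structured text."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Protocol, Sequence

import numpy as np

from . import crf
from .errors import DataError, ExtractionError, SchemaError
from .kg_core import EntitySchema, default_schema
from .kg_normalize import AhoCorasick, leftmost_longest
from .lstm import Adam, BiLSTM

#: Mention kinds produced by the tagger, in BIO scheme.
ENTITY_KINDS = ("complaint", "symptom", "disease", "syndrome")

UNK = "<unk>"


def bio_labels(kinds: Sequence[str] = ENTITY_KINDS) -> list[str]:
    labels = ["O"]
    for kind in kinds:
        labels += [f"B-{kind}", f"I-{kind}"]
    return labels


def validate_bio(labels: Sequence[str]) -> None:
    """Raise DataError unless the tag sequence is BIO well-formed."""
    prev = "O"
    for tag in labels:
        if tag == "O":
            prev = tag
            continue
        if "-" not in tag:
            raise DataError(f"malformed tag {tag!r}")
        prefix, kind = tag.split("-", 1)
        if prefix not in ("B", "I"):
            raise DataError(f"malformed tag {tag!r}")
        if prefix == "I":
            if prev == "O" or prev.split("-", 1)[1] != kind:
                raise DataError(f"I-{kind} without preceding B-{kind}/I-{kind}")
        prev = tag


@dataclass
class TaggedSequence:
    """Parallel token and BIO-tag sequences."""

    tokens: list[str]
    labels: list[str]

    def __post_init__(self) -> None:
        if len(self.tokens) != len(self.labels):
            raise DataError("tokens and labels must have equal length")
        validate_bio(self.labels)


def bio_spans(labels: Sequence[str]) -> set[tuple[int, int, str]]:
    """Entity spans (start, end, kind) from a BIO tag sequence."""
    spans: set[tuple[int, int, str]] = set()
    start, kind = None, None
    for i, tag in enumerate(list(labels) + ["O"]):
        if tag.startswith("I-") and kind == tag[2:]:
            continue
        if start is not None:
            spans.add((start, i, kind))
            start, kind = None, None
        if tag.startswith("B-") or tag.startswith("I-"):
            start, kind = i, tag[2:]
    return spans


def entity_f1(gold: Sequence[TaggedSequence], predicted: Sequence[Sequence[str]]) -> float:
    """Micro-averaged entity-level F1 over exact span matches."""
    tp = fp = fn = 0
    for seq, pred in zip(gold, predicted):
        g = bio_spans(seq.labels)
        p = bio_spans(pred)
        tp += len(g & p)
        fp += len(p - g)
        fn += len(g - p)
    if tp == 0:
        return 0.0
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    return 2 * precision * recall / (precision + recall)


@dataclass(frozen=True)
class TaggerConfig:
    embedding_dim: int = 32
    hidden_dim: int = 64
    epochs: int = 20
    learning_rate: float = 1e-2
    seed: int = 0


class TaggerModel:
    """BiLSTM encoder with a CRF output layer over BIO tags."""

    def __init__(self, vocab: Sequence[str], labels: Sequence[str], cfg: TaggerConfig):
        self.cfg = cfg
        self.vocab = {tok: i for i, tok in enumerate([UNK] + sorted(set(vocab) - {UNK}))}
        self.labels = list(labels)
        self.label_index = {lab: i for i, lab in enumerate(self.labels)}
        rng = np.random.default_rng(cfg.seed)
        L = len(self.labels)
        self.E = rng.normal(0, 0.1, size=(len(self.vocab), cfg.embedding_dim))
        self.encoder = BiLSTM(cfg.embedding_dim, cfg.hidden_dim, rng)
        scale = 1.0 / np.sqrt(self.encoder.output_dim)
        self.W_out = rng.uniform(-scale, scale, size=(self.encoder.output_dim, L))
        self.b_out = np.zeros(L)
        self.transitions = np.zeros((L + 2, L + 2))

    @property
    def params(self) -> dict[str, np.ndarray]:
        out = {"E": self.E, "W_out": self.W_out, "b_out": self.b_out,
               "transitions": self.transitions}
        out.update({f"enc.{k}": v for k, v in self.encoder.params.items()})
        return out

    def _token_ids(self, tokens: Sequence[str]) -> np.ndarray:
        return np.asarray([self.vocab.get(t, self.vocab[UNK]) for t in tokens])

    def emissions(self, tokens: Sequence[str]):
        ids = self._token_ids(tokens)
        x = self.E[ids]
        h, cache = self.encoder.forward(x)
        return h @ self.W_out + self.b_out, (ids, h, cache)

    def sequence_loss_and_grads(self, seq: TaggedSequence):
        """Negative log-likelihood and gradient dict for one sequence."""
        em, (ids, h, cache) = self.emissions(seq.tokens)
        y = [self.label_index[lab] for lab in seq.labels]
        loglik, d_em, d_tr = crf.crf_log_likelihood_grad(em, self.transitions, y)
        d_em = -d_em  # minimize NLL
        grads: dict[str, np.ndarray] = {"transitions": -d_tr}
        grads["W_out"] = h.T @ d_em
        grads["b_out"] = d_em.sum(axis=0)
        dh = d_em @ self.W_out.T
        dx, enc_grads = self.encoder.backward(dh, cache)
        grads.update({f"enc.{k}": v for k, v in enc_grads.items()})
        dE = np.zeros_like(self.E)
        np.add.at(dE, ids, dx)
        grads["E"] = dE
        return -loglik, grads

    def decode(self, tokens: Sequence[str]) -> list[str]:
        em, _ = self.emissions(tokens)
        path = crf.viterbi_decode(em, self.transitions)
        return [self.labels[i] for i in path]


def train_tagger(corpus: Sequence[TaggedSequence], cfg: TaggerConfig | None = None,
                 log: list[float] | None = None) -> TaggerModel:
    """Train a BiLSTM-CRF on BIO-annotated sequences by stochastic gradient
    ascent on the CRF log-likelihood (Adam on the negated objective)."""
    if not corpus:
        raise ValueError("corpus must be non-empty")
    cfg = cfg or TaggerConfig()
    kinds = sorted({lab[2:] for seq in corpus for lab in seq.labels if lab != "O"})
    labels = bio_labels(kinds) if kinds else ["O"]
    label_set = set(labels)
    for seq in corpus:
        for lab in seq.labels:
            if lab not in label_set:
                raise DataError(f"label {lab!r} outside label set")
    vocab = [tok for seq in corpus for tok in seq.tokens]
    model = TaggerModel(vocab, labels, cfg)
    opt = Adam(model.params, lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)
    for _ in range(cfg.epochs):
        total = 0.0
        for idx in rng.permutation(len(corpus)):
            loss, grads = model.sequence_loss_and_grads(corpus[idx])
            opt.step(grads)
            total += loss
        if log is not None:
            log.append(total / len(corpus))
    return model


# ---------------------------------------------------------------------------
# Extractor contract for semi-structured text
# ---------------------------------------------------------------------------

@dataclass
class ExtractionResult:
    """Entities and relation triples extracted from one text unit.

    Triples are (symptom, relation, syndrome) tuples; relation names must be
    declared in the schema.
    """

    symptoms: list[str] = field(default_factory=list)
    syndromes: list[str] = field(default_factory=list)
    relations: list[tuple[str, str, str]] = field(default_factory=list)
    triples: list[tuple[str, str, str]] = field(default_factory=list)

    def validate(self, schema: EntitySchema | None = None) -> None:
        schema = schema or default_schema()
        known = set(self.symptoms) | set(self.syndromes)
        for sz, rel, sh in self.triples:
            if rel not in schema.relation_names:
                raise SchemaError(f"relation {rel!r} not declared in schema")
            if sz not in known or sh not in known:
                raise SchemaError(f"triple ({sz!r}, {rel!r}, {sh!r}) has unlisted entity")


class ExtractorBackend(Protocol):
    def extract(self, text: str) -> ExtractionResult: ...


class RuleBasedExtractor:
    """Deterministic gazetteer extractor.

    Matches gazetteer terms leftmost-longest and emits one
    (symptom, Has_symptom, syndrome) triple per co-occurring pair.  A pure
    function of (text, gazetteer).
    """

    def __init__(self, gazetteer: dict[str, str]):
        if not gazetteer:
            raise ExtractionError("empty gazetteer")
        self.gazetteer = dict(gazetteer)
        self._automaton = AhoCorasick(gazetteer)

    def extract(self, text: str) -> ExtractionResult:
        matches = leftmost_longest(self._automaton.iter_matches(text))
        symptoms: list[str] = []
        syndromes: list[str] = []
        for _, _, term in matches:
            kind = self.gazetteer[term]
            if kind == "Symptoms" and term not in symptoms:
                symptoms.append(term)
            elif kind == "Syndrome" and term not in syndromes:
                syndromes.append(term)
        triples = [(sz, "Has_symptom", sh) for sz in symptoms for sh in syndromes]
        return ExtractionResult(
            symptoms=symptoms, syndromes=syndromes,
            relations=list(triples), triples=list(triples),
        )


class PromptTemplateAdapter:
    """Adapter documenting the hosted-LLM extraction contract.

    The upstream design formats an instruction that lists the target entity
    categories, sends the text to a hosted model, and parses entities and
    relations from the reply.  This adapter accepts any callable with that
    behavior; no network backend is bundled.
    """

    PROMPT_TEMPLATE = (
        "Extract the symptom entities and syndrome entities from the text "
        "below and list the (symptom, relation, syndrome) triples.\n"
        "Categories: {categories}\nText: {text}"
    )

    def __init__(self, complete: Callable[[str], ExtractionResult] | None = None,
                 categories: Iterable[str] = ("symptom", "syndrome")):
        self._complete = complete
        self.categories = tuple(categories)

    def extract(self, text: str) -> ExtractionResult:
        if self._complete is None:
            raise ExtractionError("no completion backend configured")
        prompt = self.PROMPT_TEMPLATE.format(categories=", ".join(self.categories), text=text)
        return self._complete(prompt)


def extract_entities(text: str, backend: ExtractorBackend,
                     schema: EntitySchema | None = None) -> ExtractionResult:
    """Run a backend on one text unit and validate its output."""
    if not text:
        raise ValueError("text must be non-empty")
    try:
        result = backend.extract(text)
    except ExtractionError:
        raise
    except Exception as exc:  # backend diagnostics must surface
        raise ExtractionError(f"backend {type(backend).__name__} failed: {exc}") from exc
    result.validate(schema)
    return result
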