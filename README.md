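# kgclf

Knowledge-graph-augmented clinical text classification, built for syndrome
differentiation from electronic medical records. The pipeline:

1. **Graph construction** (`kgclf.kg_core`, `kgclf.kg_io`) — a typed,
   schema-validated triple store for a syndrome-centred clinical knowledge
   graph (11 entity types, 9 relation signatures), multi-source graph fusion,
   and JSONL / GraphML / bulk-import CSV round-tripping.
2. **Cleaning** (`kgclf.kg_normalize`) — regex span location, composite-label
   splitting on conjunction/disjunction connectives (bilingual defaults),
   dictionary normalization with a hand-built Aho-Corasick automaton
   (leftmost-longest), and duplicate-node merging.
3. **Graph embedding** (`kgclf.kg_embed`) — truncated random walks (default
   max length 20, 10 walks/node) plus skip-gram with an exact full-softmax
   objective and gradient, in NumPy.
4. **Entity extraction** (`kgclf.extraction`) — a BiLSTM-CRF BIO tagger with
   exact forward/Viterbi/forward-backward CRF primitives and handwritten
   backpropagation, plus a pluggable extractor contract with a deterministic
   gazetteer backend (the hosted-LLM route is an adapter stub).
5. **Entity linking** (`kgclf.linking`) — exact name match first, semantic
   cosine fallback second (pluggable sentence embedder; a deterministic
   character-n-gram hashing embedder is bundled), then frequency-weighted
   aggregation of linked-node vectors; failed linking yields the zero vector
   (default dimension 384).
6. **Fusion classifier** (`kgclf.model`) — records formatted as
   `[CLS] disease, complaint [SEP] history [SEP]`, a text-encoder contract
   (small trainable bag-of-embeddings encoder bundled for desk scale), a
   learned knowledge projection, CONCAT/AVG/WEIGHTED fusion, and a softmax
   head trained with AdamW (defaults: batch 16, lr 2e-5, weight decay 0.02,
   max seq length 128, 10 epochs).
7. **Evaluation** (`kgclf.evaluation`) — accuracy and macro
   precision/recall/F1, a four-variant ablation harness (text-only, KG-only,
   no-semantic-fallback, full), and a KG-dimension sweep.
8. **Synthetic fixtures** (`kgclf.synthdata`) — seeded generators for the
   graph, EMR corpora (synonym noise, class imbalance, symptom overlap), and
   BIO tagging corpora, with scenario presets (`clean`, `text-sufficient`,
   `synonym-heavy`, `complementary-signal`).

Everything numerical is NumPy/SciPy; no deep-learning framework is required.
All gradients (LSTM, CRF, skip-gram, fusion model) are exact and verified
against finite differences in the test suite.

## CLI

```bash
kgclf build-kg --in triples.jsonl --out kg.jsonl
kgclf clean --kg kg.jsonl --dict terms.csv --out kg.clean.jsonl --report report.jsonl
kgclf embed --kg kg.clean.jsonl --out kg.embedded.jsonl --dim 384 --walk-len 20 --seed 7
kgclf extract --gazetteer gaz.csv --in notes.jsonl --out triples.jsonl
kgclf link --kg kg.embedded.jsonl --in mentions.jsonl --tau 0.5 --out links.jsonl
kgclf simulate --preset complementary-signal --seed 7 --out fixtures/
kgclf ablate --preset complementary-signal --seed 7 --dim 64
kgclf sweep-dim --preset clean --dims 64,128,384,768
```

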