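"""Synthetic fixture generator: a syndrome-centred knowledge graph, EMR
corpora with surface variants / imbalance / cross-class symptom overlap, and
BIO-annotated tagging corpora.

Scenario presets back the ablation experiments:

- ``clean``: every mention exact-matches a graph node.
- ``text-sufficient``: the disease-name token alone determines the label.
- ``synonym-heavy``: all mentions are synonyms, evaluation uses held-out
  surface variants, and no text shortcut exists, so only semantic linking
  recovers the signal.
- ``complementary-signal``: text carries one factor of the label (the class
  group), the knowledge graph the other (which symptom set), so neither
  signal alone suffices.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .evaluation import LabeledDataset
from .extraction import TaggedSequence
from .kg_core import KnowledgeGraph, default_schema
from .kg_normalize import TermDictionary
from .model import EMRRecord

_SEVERITY = ("severe", "mild", "chronic")
_COMPLAINTS = (("persistent", "discomfort"), ("general", "malaise"), ("episodic", "unrest"))


@dataclass(frozen=True)
class SynthConfig:
    """Generator knobs; ``seed`` is mandatory and all outputs are seeded."""

    n_syndromes: int
    seed: int
    symptoms_per_syndrome: int = 4
    symptom_overlap_rate: float = 0.0
    synonym_rate: float = 0.0
    n_synonyms: int = 3
    records_per_class: int = 20
    imbalance_ratio: float | None = None
    min_class_size: int = 2
    noise_token_rate: float = 0.0
    mentions_per_record: tuple[int, int] = (2, 3)
    #: "disease_full" puts the label in the disease name; "disease_group"
    #: only the label's group (label // 2); "none" removes the shortcut.
    text_signal: str = "disease_full"
    #: "index": per-syndrome symptom sets with chain overlap;
    #: "parity": syndromes share a set by label parity (label % 2).
    symptom_set_key: str = "index"
    #: reserve the last synonym variant for evaluation records
    holdout_synonym: bool = False
    eval_records_per_class: int = 8

    def __post_init__(self) -> None:
        if self.n_syndromes < 2:
            raise ValueError("need at least 2 syndromes")
        for name in ("symptom_overlap_rate", "synonym_rate", "noise_token_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.text_signal not in ("disease_full", "disease_group", "none"):
            raise ValueError(f"unknown text_signal {self.text_signal!r}")
        if self.symptom_set_key not in ("index", "parity"):
            raise ValueError(f"unknown symptom_set_key {self.symptom_set_key!r}")


def _symptom_name(idx: int) -> str:
    return f"sx{idx:03d}"


def _synonym_name(symptom: str, variant: int) -> str:
    return f"{symptom}~{chr(ord('a') + variant)}"


def _syndrome_name(i: int) -> str:
    return f"synd{i:02d}"


def _symptom_sets(cfg: SynthConfig) -> list[list[str]]:
    k = cfg.symptoms_per_syndrome
    if cfg.symptom_set_key == "parity":
        base = [[_symptom_name(p * k + j) for j in range(k)] for p in range(2)]
        return [list(base[i % 2]) for i in range(cfg.n_syndromes)]
    n_shared = int(round(cfg.symptom_overlap_rate * k))
    sets: list[list[str]] = []
    counter = 0
    for i in range(cfg.n_syndromes):
        current: list[str] = []
        if i > 0 and n_shared:
            current.extend(sets[i - 1][:n_shared])
        while len(current) < k:
            current.append(_symptom_name(counter))
            counter += 1
        sets.append(current)
    return sets


def generate_kg(cfg: SynthConfig) -> tuple[KnowledgeGraph, TermDictionary, dict[str, str]]:
    """Syndrome-centred graph + symptom dictionary + gazetteer, seeded."""
    schema = default_schema()
    kg = KnowledgeGraph(schema)
    sets = _symptom_sets(cfg)
    symptom_ids: dict[str, int] = {}
    gazetteer: dict[str, str] = {}
    synonym_map: dict[str, str] = {}

    for i in range(cfg.n_syndromes):
        name = _syndrome_name(i)
        syndrome = kg.add_node("Syndrome", name, {
            "Syndrome_name": name,
            "Syndrome_English": f"pattern {i}",
            "Syndrome_PinYin": f"zheng{i}",
            "Syndrome_definition": f"disorder pattern number {i}",
        })
        gazetteer[name] = "Syndrome"
        for symptom in sets[i]:
            if symptom not in symptom_ids:
                node = kg.add_node("Symptoms", symptom, {
                    "TCM_symptom_name": symptom,
                    "Symptom_PinYin": symptom,
                })
                symptom_ids[symptom] = node.id
                gazetteer[symptom] = "Symptoms"
                for v in range(cfg.n_synonyms):
                    surface = _synonym_name(symptom, v)
                    synonym_map[surface] = symptom
                    gazetteer[surface] = "Symptoms"
            kg.add_triple(syndrome.id, "Has_symptom", symptom_ids[symptom])
        disease = kg.add_node("Disease", f"dis{i:02d}", {"name": f"dis{i:02d}"})
        kg.add_triple(syndrome.id, "Has_disease", disease.id)
        treatment = kg.add_node("Treatment", f"treat{i:02d}", {"name": f"treat{i:02d}"})
        kg.add_triple(syndrome.id, "Has_treatment", treatment.id)
        drug = kg.add_node("Drugs", f"drug{i:02d}", {"name": f"drug{i:02d}"})
        kg.add_triple(treatment.id, "Common pharmaceuticals", drug.id)
        flavor = kg.add_node("Flavor", f"flavor{i % 3}", {"name": f"flavor{i % 3}"})
        kg.add_triple(drug.id, "Has_flavor", flavor.id)
        form = kg.add_node("Form", f"form{i % 2}", {"name": f"form{i % 2}"})
        kg.add_triple(drug.id, "Dosage form", form.id)
        patients = kg.add_node("Patients", f"patients{i % 2}", {"name": f"patients{i % 2}"})
        kg.add_triple(disease.id, "Common patients", patients.id)
        dgroup = kg.add_node("Dgroup", f"dgroup{i % 2}", {"name": f"dgroup{i % 2}"})
        kg.add_triple(disease.id, "IspartofD", dgroup.id)
        fgroup = kg.add_node("Fgroup", f"fgroup{i % 2}", {"name": f"fgroup{i % 2}"})
        kg.add_triple(drug.id, "IspartofP", fgroup.id)
    kg.add_node("Herb", "herb00", {
        "Chinese_name": "herb00", "Pinyin_name": "herb00", "English_name": "herb zero",
        "Properties_Chinese": "warm", "Meridians_Chinese": "liver",
    })
    dictionary = TermDictionary(set(symptom_ids), synonym_map, domain="symptom")
    return kg, dictionary, gazetteer


def _class_sizes(cfg: SynthConfig, per_class: int) -> list[int]:
    if cfg.imbalance_ratio is None:
        return [per_class] * cfg.n_syndromes
    return [
        max(cfg.min_class_size, int(round(per_class * cfg.imbalance_ratio ** i)))
        for i in range(cfg.n_syndromes)
    ]


def _render_surface(symptom: str, cfg: SynthConfig, rng: np.random.Generator,
                    split: str) -> str:
    if cfg.synonym_rate == 0.0 or rng.random() >= cfg.synonym_rate:
        return symptom
    if cfg.holdout_synonym and cfg.n_synonyms >= 2:
        if split == "eval":
            variant = cfg.n_synonyms - 1
        else:
            variant = int(rng.integers(cfg.n_synonyms - 1))
    else:
        variant = int(rng.integers(cfg.n_synonyms))
    return _synonym_name(symptom, variant)


def _compose(parts: list[str]) -> str:
    if len(parts) == 1:
        return parts[0]
    return ", ".join(parts[:-1]) + " and " + parts[-1]


def generate_emrs(
    kg: KnowledgeGraph,
    cfg: SynthConfig,
    split: str = "train",
) -> tuple[list[EMRRecord], list[list[str]]]:
    """EMR corpus whose complaints mention sampled syndrome symptoms.

    Returns the records and, per record, the atomic mention surface forms
    (what span extraction over the complaint would produce).
    """
    if kg.n_nodes == 0:
        raise ValueError("graph is empty")
    syndromes = kg.nodes_of_type("Syndrome")
    by_syndrome: dict[int, list[str]] = {}
    for t in kg.triples:
        if t.relation == "Has_symptom":
            by_syndrome.setdefault(t.head, []).append(kg.node(t.tail).canonical_name)
    rng = np.random.default_rng([cfg.seed, 1 if split == "train" else 2])
    per_class = cfg.records_per_class if split == "train" else cfg.eval_records_per_class
    sizes = _class_sizes(cfg, per_class)
    records: list[EMRRecord] = []
    mentions: list[list[str]] = []
    lo, hi = cfg.mentions_per_record
    for label, syndrome in enumerate(syndromes):
        pool = sorted(by_syndrome.get(syndrome.id, []))
        for _ in range(sizes[label]):
            m = min(len(pool), int(rng.integers(lo, hi + 1)))
            chosen = [pool[j] for j in rng.choice(len(pool), size=m, replace=False)]
            surfaces = [_render_surface(s, cfg, rng, split) for s in chosen]
            complaint = _compose(surfaces)
            n_noise = rng.binomial(5, cfg.noise_token_rate)
            noise = " ".join(f"n{int(rng.integers(50))}" for _ in range(n_noise))
            history = f"onset {int(rng.integers(1, 30))} days ago {noise}".strip()
            if cfg.text_signal == "disease_full":
                disease = f"dis{label:02d}"
            elif cfg.text_signal == "disease_group":
                disease = f"grp{label // 2}"
            else:
                disease = "unspecified"
            records.append(EMRRecord(disease, complaint, history, label))
            mentions.append(surfaces)
    return records, mentions


def generate_tagging_corpus(
    kg: KnowledgeGraph,
    cfg: SynthConfig,
    n_sentences: int = 200,
) -> list[TaggedSequence]:
    """BIO-annotated sentences over symptom/disease/syndrome/complaint spans."""
    rng = np.random.default_rng([cfg.seed, 3])
    symptoms = sorted(n.canonical_name for n in kg.nodes_of_type("Symptoms"))
    syndromes = sorted(n.canonical_name for n in kg.nodes_of_type("Syndrome"))
    diseases = sorted(n.canonical_name for n in kg.nodes_of_type("Disease"))
    if not symptoms or not syndromes or not diseases:
        raise ValueError("graph lacks the node types needed for tagging fixtures")

    def symptom_span() -> tuple[list[str], list[str]]:
        name = symptoms[rng.integers(len(symptoms))]
        if rng.random() < 0.3:
            sev = _SEVERITY[rng.integers(len(_SEVERITY))]
            return [sev, name], ["B-symptom", "I-symptom"]
        return [name], ["B-symptom"]

    out: list[TaggedSequence] = []
    for _ in range(n_sentences):
        template = int(rng.integers(3))
        tokens: list[str] = []
        labels: list[str] = []
        if template == 0:
            s1t, s1l = symptom_span()
            s2t, s2l = symptom_span()
            tokens = ["patient", "reports"] + s1t + ["and"] + s2t
            labels = ["O", "O"] + s1l + ["O"] + s2l
        elif template == 1:
            phrase = _COMPLAINTS[rng.integers(len(_COMPLAINTS))]
            st, sl = symptom_span()
            tokens = ["chief", "complaint", "of"] + list(phrase) + ["with"] + st
            labels = ["O", "O", "O", "B-complaint", "I-complaint", "O"] + sl
        else:
            dis = diseases[rng.integers(len(diseases))]
            synd = syndromes[rng.integers(len(syndromes))]
            st, sl = symptom_span()
            tokens = ["diagnosis", dis, "with", "pattern", synd, "showing"] + st
            labels = ["O", "B-disease", "O", "O", "B-syndrome", "O"] + sl
        out.append(TaggedSequence(tokens, labels))
    return out


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

@dataclass
class PresetBundle:
    name: str
    config: SynthConfig
    kg: KnowledgeGraph
    dictionary: TermDictionary
    gazetteer: dict[str, str]
    dataset: LabeledDataset
    #: semantic-similarity acceptance threshold suited to the scenario
    tau: float


_PRESET_CONFIGS = {
    "clean": dict(n_syndromes=4, symptoms_per_syndrome=4),
    "text-sufficient": dict(n_syndromes=4, symptoms_per_syndrome=4,
                            synonym_rate=0.5, text_signal="disease_full"),
    "synonym-heavy": dict(n_syndromes=6, symptoms_per_syndrome=4,
                          synonym_rate=1.0, n_synonyms=4, holdout_synonym=True,
                          text_signal="none", noise_token_rate=0.3,
                          records_per_class=24),
    "complementary-signal": dict(n_syndromes=4, symptoms_per_syndrome=4,
                                 symptom_set_key="parity", synonym_rate=1.0,
                                 n_synonyms=4, holdout_synonym=True,
                                 text_signal="disease_group",
                                 records_per_class=24),
}

_PRESET_TAU = {"clean": 0.5, "text-sufficient": 0.2,
               "synonym-heavy": 0.2, "complementary-signal": 0.2}

PRESETS = tuple(_PRESET_CONFIGS)


def preset(name: str, seed: int) -> PresetBundle:
    """Build a named scenario: graph, dictionaries, and train/eval dataset."""
    if name not in _PRESET_CONFIGS:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESETS}")
    cfg = SynthConfig(seed=seed, **_PRESET_CONFIGS[name])
    kg, dictionary, gazetteer = generate_kg(cfg)
    train_records, train_mentions = generate_emrs(kg, cfg, split="train")
    eval_records, eval_mentions = generate_emrs(kg, cfg, split="eval")
    dataset = LabeledDataset(train_records, train_mentions,
                             eval_records, eval_mentions, cfg.n_syndromes)
    return PresetBundle(name, cfg, kg, dictionary, gazetteer, dataset,
                        tau=_PRESET_TAU[name])


def with_seed(bundle_cfg: SynthConfig, seed: int) -> SynthConfig:
    return replace(bundle_cfg, seed=seed)
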