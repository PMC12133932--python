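import numpy as np
import pytest

from kgclf.kg_core import KnowledgeGraph, default_schema


@pytest.fixture
def schema():
    return default_schema()


@pytest.fixture
def small_kg(schema):
    """Syndrome with two symptoms, a disease, and a treatment chain."""
    kg = KnowledgeGraph(schema)
    synd = kg.add_node("Syndrome", "pattern x", {"Syndrome_definition": "def x"})
    s1 = kg.add_node("Symptoms", "fatigue")
    s2 = kg.add_node("Symptoms", "insomnia")
    dis = kg.add_node("Disease", "flu")
    tr = kg.add_node("Treatment", "rest")
    kg.add_triple(synd.id, "Has_symptom", s1.id)
    kg.add_triple(synd.id, "Has_symptom", s2.id)
    kg.add_triple(synd.id, "Has_disease", dis.id)
    kg.add_triple(synd.id, "Has_treatment", tr.id)
    return kg


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
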