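import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kgclf.errors import ConfigurationError
from kgclf.kg_core import KnowledgeGraph
from kgclf.kg_normalize import (
    AhoCorasick,
    TermDictionary,
    leftmost_longest,
    locate_symptom_spans,
    merge_duplicate_nodes,
    normalize_term,
    split_composite_label,
)


def brute_force_matches(text, patterns):
    """All (start, end, pattern) occurrences by scanning every position."""
    out = []
    for pat in patterns:
        for i in range(len(text) - len(pat) + 1):
            if text[i:i + len(pat)] == pat:
                out.append((i, i + len(pat), pat))
    return sorted(out)


class TestAhoCorasick:
    def test_simple(self):
        ac = AhoCorasick(["he", "she", "his", "hers"])
        assert sorted(ac.iter_matches("ushers")) == [(1, 4, "she"), (2, 4, "he"),
                                                     (2, 6, "hers")]

    def test_empty_patterns_rejected(self):
        with pytest.raises(ConfigurationError):
            AhoCorasick([])

    @given(st.lists(st.text(alphabet="abc", min_size=1, max_size=4),
                    min_size=1, max_size=50),
           st.text(alphabet="abc", max_size=30))
    @settings(max_examples=300, deadline=None)
    def test_matches_equal_bruteforce(self, patterns, text):
        ac = AhoCorasick(patterns)
        assert sorted(ac.iter_matches(text)) == brute_force_matches(text, set(patterns))


class TestLocateSpans:
    def test_no_hit(self):
        assert locate_symptom_spans("nothing here", [r"zzz"]) == []

    def test_hit_at_start(self):
        assert locate_symptom_spans("fatigue always", [r"fatigue"]) == [(0, 7)]

    def test_invalid_pattern(self):
        with pytest.raises(ConfigurationError):
            locate_symptom_spans("x", [r"("])

    def test_overlap_matches_bruteforce_scan(self):
        text = "abcabcab"
        patterns = [r"abc", r"bca", r"abcab"]
        got = locate_symptom_spans(text, patterns)
        # oracle: all candidate spans at all positions, leftmost-longest greedy
        candidates = []
        import re
        for pat in patterns:
            rex = re.compile(pat)
            for pos in range(len(text)):
                m = rex.match(text, pos)
                if m and m.end() > m.start():
                    candidates.append((m.start(), m.end(), m.group()))
        expected = [(s, e) for s, e, _ in leftmost_longest(candidates)]
        assert got == expected
        assert got[0] == (0, 5)  # longest wins at position 0

    def test_spans_sorted_nonoverlapping(self):
        spans = locate_symptom_spans("ababab", [r"ab", r"ba"])
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2


class TestSplit:
    def test_no_connective(self):
        assert split_composite_label("fatigue") == ["fatigue"]

    def test_default_connectives(self):
        # oracle: naive delimiter split
        assert split_composite_label("fatigue and poor appetite") == \
            ["fatigue", "poor appetite"]

    def test_comma_enumeration(self):
        assert split_composite_label("a, b and c") == ["a", "b", "c"]

    def test_chinese_connectives(self):
        assert split_composite_label("头痛和乏力、失眠") == ["头痛", "乏力", "失眠"]

    def test_word_boundary_respected(self):
        # "sand" must not split on embedded "and"
        assert split_composite_label("sand") == ["sand"]

    def test_empty_label_rejected(self):
        with pytest.raises(ValueError):
            split_composite_label("   ")


@pytest.fixture
def tired_dict():
    return TermDictionary({"fatigue", "insomnia"},
                          {"tiredness": "fatigue", "sleeplessness": "insomnia"})


class TestNormalize:
    def test_canonical_is_identity(self, tired_dict):
        rep = normalize_term("fatigue", tired_dict)
        assert rep.output == "fatigue"
        assert rep.matched == [True]

    def test_synonym_replaced(self, tired_dict):
        rep = normalize_term("tiredness", tired_dict)
        assert rep.output == "fatigue"
        assert rep.matched == [True]
        assert rep.rule_trace == ["aho_corasick:tiredness->fatigue"]

    def test_unmatched_unchanged(self, tired_dict):
        rep = normalize_term("dizziness", tired_dict)
        assert rep.output == "dizziness"
        assert rep.matched == [False]

    def test_empty_dictionary_rejected(self):
        with pytest.raises(ConfigurationError):
            normalize_term("x", TermDictionary(set(), {}))

    def test_synonym_to_unknown_canonical_rejected(self):
        with pytest.raises(ConfigurationError):
            TermDictionary({"a"}, {"b": "c"})

    def test_agrees_with_bruteforce_scan_on_random_strings(self, tired_dict, rng):
        # oracle: leftmost-longest via brute-force all-position scan
        terms = sorted(tired_dict.canonical_terms | set(tired_dict.synonym_map))
        alphabet = list("abefgitu ")
        for _ in range(1000):
            n = rng.integers(0, 25)
            chars = [str(rng.choice(alphabet)) for _ in range(n)]
            if rng.random() < 0.5 and n > 0:
                pos = int(rng.integers(n))
                chars[pos:pos] = list(str(rng.choice(terms)))
            text = "".join(chars)
            matches = leftmost_longest(brute_force_matches(text, terms))
            out, cursor = [], 0
            for s, e, pat in matches:
                out.append(text[cursor:s])
                out.append(tired_dict.lookup(pat))
                cursor = e
            out.append(text[cursor:])
            assert normalize_term(text, tired_dict).output == "".join(out)

    @given(st.text(alphabet="abdefgintsu ", max_size=30))
    @settings(max_examples=200, deadline=None)
    def test_idempotent(self, text):
        d = TermDictionary({"fatigue", "insomnia"},
                           {"tiredness": "fatigue", "sleeplessness": "insomnia"})
        once = normalize_term(text, d).output
        assert normalize_term(once, d).output == once

    def test_from_csv(self, tmp_path):
        path = tmp_path / "terms.csv"
        path.write_text("surface,canonical,domain\n"
                        "fatigue,fatigue,symptom\n"
                        "tiredness,fatigue,symptom\n")
        d = TermDictionary.from_csv(path)
        assert d.lookup("tiredness") == "fatigue"
        assert d.domain == "symptom"


class TestMergeDuplicates:
    def _kg_with_dupes(self, schema):
        kg = KnowledgeGraph(schema)
        synd = kg.add_node("Syndrome", "s")
        a = kg.add_node("Symptoms", "tiredness")
        b = kg.add_node("Symptoms", "fatigue")
        dis = kg.add_node("Disease", "flu")
        kg.add_triple(synd.id, "Has_symptom", a.id)
        kg.add_triple(synd.id, "Has_symptom", b.id)
        kg.add_triple(synd.id, "Has_disease", dis.id)
        return kg

    def test_no_duplicates_is_identity(self, small_kg, tired_dict):
        out = merge_duplicate_nodes(small_kg, {"Symptoms": tired_dict})
        assert out.n_nodes == small_kg.n_nodes
        assert out.n_triples == small_kg.n_triples

    def test_synonym_nodes_merge(self, schema, tired_dict):
        kg = self._kg_with_dupes(schema)
        out = merge_duplicate_nodes(kg, {"Symptoms": tired_dict})
        assert out.n_nodes == kg.n_nodes - 1
        merged = out.find_nodes("Symptoms", "fatigue")
        assert len(merged) == 1
        # union of incident triples, deduplicated
        incident = [t for t in out.triples if merged[0].id in (t.head, t.tail)]
        assert len(incident) == 1

    def test_chain_of_three_merges_to_one(self, schema):
        d = TermDictionary({"fatigue"}, {"tiredness": "fatigue", "exhaustion": "fatigue"})
        kg = KnowledgeGraph(schema)
        synd = kg.add_node("Syndrome", "s")
        for name in ("fatigue", "tiredness", "exhaustion"):
            n = kg.add_node("Symptoms", name)
            kg.add_triple(synd.id, "Has_symptom", n.id)
        out = merge_duplicate_nodes(kg, {"Symptoms": d})
        assert len(out.nodes_of_type("Symptoms")) == 1
        assert out.n_triples == 1  # deduplicated union

    def test_never_increases_counts_and_keeps_relations(self, schema, tired_dict):
        kg = self._kg_with_dupes(schema)
        out = merge_duplicate_nodes(kg, {"Symptoms": tired_dict})
        assert out.n_nodes <= kg.n_nodes
        assert out.n_triples <= kg.n_triples
        # the Has_disease relation between distinct canonical nodes survives
        assert any(t.relation == "Has_disease" for t in out.triples)
        assert out.validate() == []
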