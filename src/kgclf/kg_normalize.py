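"""Cleaning pipeline: span location, composite-label splitting, dictionary
normalization with an Aho-Corasick automaton, and duplicate-node merging."""

from __future__ import annotations

import csv
import re
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import ConfigurationError
from .kg_core import KnowledgeGraph, fuse_graphs

#: Default conjunction/disjunction connectives used to split composite labels.
#: English connectives are matched as whole words; Chinese single-character
#: connectives and enumeration commas are matched anywhere.
DEFAULT_CONNECTIVES: tuple[str, ...] = (
    "and", "or", "with", ",", "，", "、", "和", "及", "并", "伴",
)


class AhoCorasick:
    """Multi-pattern string matcher (trie + failure links).

    ``iter_matches`` yields every occurrence of every pattern, including
    overlapping and nested ones; resolution policies are layered on top.
    """

    def __init__(self, patterns: Iterable[str]):
        patterns = [p for p in patterns if p]
        if not patterns:
            raise ConfigurationError("automaton needs at least one non-empty pattern")
        # trie as list of dicts: node -> {char: child}
        self._goto: list[dict[str, int]] = [{}]
        self._out: list[list[str]] = [[]]
        self._fail: list[int] = [0]
        for pat in sorted(set(patterns)):
            state = 0
            for ch in pat:
                nxt = self._goto[state].get(ch)
                if nxt is None:
                    self._goto.append({})
                    self._out.append([])
                    self._fail.append(0)
                    nxt = len(self._goto) - 1
                    self._goto[state][ch] = nxt
                state = nxt
            self._out[state].append(pat)
        # BFS to set failure links and merge outputs
        queue: deque[int] = deque()
        for child in self._goto[0].values():
            queue.append(child)
        while queue:
            state = queue.popleft()
            for ch, child in self._goto[state].items():
                queue.append(child)
                f = self._fail[state]
                while f and ch not in self._goto[f]:
                    f = self._fail[f]
                self._fail[child] = self._goto[f].get(ch, 0)
                if self._fail[child] == child:
                    self._fail[child] = 0
                self._out[child] = self._out[child] + self._out[self._fail[child]]

    def iter_matches(self, text: str):
        """Yield (start, end, pattern) for every pattern occurrence in text."""
        state = 0
        for i, ch in enumerate(text):
            while state and ch not in self._goto[state]:
                state = self._fail[state]
            state = self._goto[state].get(ch, 0)
            for pat in self._out[state]:
                yield (i - len(pat) + 1, i + 1, pat)


def leftmost_longest(matches: Iterable[tuple[int, int, str]]) -> list[tuple[int, int, str]]:
    """Resolve overlaps: earliest start wins, longest match at equal start."""
    chosen: list[tuple[int, int, str]] = []
    for start, end, pat in sorted(matches, key=lambda m: (m[0], -(m[1] - m[0]), m[2])):
        if not chosen or start >= chosen[-1][1]:
            chosen.append((start, end, pat))
    return chosen


@dataclass
class TermDictionary:
    """Canonical vocabulary plus surface-form synonym map for one domain."""

    canonical_terms: set[str]
    synonym_map: dict[str, str] = field(default_factory=dict)
    domain: str = "symptom"

    def __post_init__(self) -> None:
        for surface, canonical in self.synonym_map.items():
            if canonical not in self.canonical_terms:
                raise ConfigurationError(
                    f"synonym {surface!r} maps to unknown canonical {canonical!r}"
                )
            if surface in self.canonical_terms and surface != canonical:
                raise ConfigurationError(
                    f"surface {surface!r} is both canonical and a synonym of {canonical!r}"
                )
        self._automaton: AhoCorasick | None = None

    @classmethod
    def from_csv(cls, path: str | Path, domain: str | None = None) -> "TermDictionary":
        """Read a surface,canonical,domain CSV (header required)."""
        canonicals: set[str] = set()
        synonyms: dict[str, str] = {}
        domains: set[str] = set()
        with open(path, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                if domain is not None and row.get("domain") and row["domain"] != domain:
                    continue
                surface, canonical = row["surface"], row["canonical"]
                canonicals.add(canonical)
                if surface != canonical:
                    synonyms[surface] = canonical
                if row.get("domain"):
                    domains.add(row["domain"])
        return cls(canonicals, synonyms, domain or (domains.pop() if len(domains) == 1 else "symptom"))

    def lookup(self, surface: str) -> str | None:
        if surface in self.canonical_terms:
            return surface
        return self.synonym_map.get(surface)

    def automaton(self) -> AhoCorasick:
        if self._automaton is None:
            if not self.canonical_terms:
                raise ConfigurationError("empty dictionary")
            self._automaton = AhoCorasick(set(self.canonical_terms) | set(self.synonym_map))
        return self._automaton


@dataclass
class NormalizationReport:
    """Audit trail for one normalization call."""

    input_term: str
    output_terms: list[str]
    matched: list[bool]
    rule_trace: list[str]

    @property
    def output(self) -> str:
        return self.output_terms[0] if self.output_terms else ""


def locate_symptom_spans(text: str, patterns: Sequence[str]) -> list[tuple[int, int]]:
    """Locate pattern occurrences; half-open spans, longest-match resolution.

    Every start position is probed against every pattern so overlapping
    candidates are all considered before leftmost-longest resolution.
    """
    compiled = []
    for pat in patterns:
        try:
            compiled.append(re.compile(pat))
        except re.error as exc:
            raise ConfigurationError(f"invalid pattern {pat!r}: {exc}") from exc
    candidates: list[tuple[int, int, str]] = []
    for rex in compiled:
        for pos in range(len(text)):
            m = rex.match(text, pos)
            if m and m.end() > m.start():
                candidates.append((m.start(), m.end(), m.group()))
    return [(s, e) for s, e, _ in leftmost_longest(candidates)]


def split_composite_label(label: str, connectives: Sequence[str] | None = None) -> list[str]:
    """Split a composite label on conjunction/disjunction connectives."""
    if not label or not label.strip():
        raise ValueError("label must be non-empty")
    connectives = tuple(connectives) if connectives is not None else DEFAULT_CONNECTIVES
    parts_rx = []
    for conn in connectives:
        if re.fullmatch(r"[A-Za-z]+", conn):
            parts_rx.append(rf"\b{re.escape(conn)}\b")
        else:
            parts_rx.append(re.escape(conn))
    pieces = re.split("|".join(parts_rx), label) if parts_rx else [label]
    atoms = [p.strip() for p in pieces]
    return [a for a in atoms if a]


def normalize_term(term: str, dictionary: TermDictionary) -> NormalizationReport:
    """Replace dictionary synonyms in ``term`` by canonical forms.

    Uses leftmost-longest Aho-Corasick matching over canonicals + synonyms.
    Unmatched input is returned unchanged with matched=False.
    """
    if not dictionary.canonical_terms:
        raise ConfigurationError("empty dictionary")
    if not term:
        return NormalizationReport(term, [], [], [])
    matches = leftmost_longest(dictionary.automaton().iter_matches(term))
    trace: list[str] = []
    out: list[str] = []
    cursor = 0
    any_match = False
    for start, end, pat in matches:
        out.append(term[cursor:start])
        canonical = dictionary.lookup(pat)
        out.append(canonical)
        any_match = True
        if canonical != pat:
            trace.append(f"aho_corasick:{pat}->{canonical}")
        else:
            trace.append(f"aho_corasick:{pat}=canonical")
        cursor = end
    out.append(term[cursor:])
    result = "".join(out)
    return NormalizationReport(term, [result], [any_match], trace)


def merge_duplicate_nodes(
    kg: KnowledgeGraph,
    dicts: Mapping[str, TermDictionary],
) -> KnowledgeGraph:
    """Normalize Symptoms/Syndrome names and merge nodes sharing (type, name).

    ``dicts`` maps entity type -> TermDictionary.  Triples are re-pointed to
    the merged nodes; node and triple counts never increase.
    """
    renamed = kg.copy()
    for node in renamed.nodes:
        d = dicts.get(node.entity_type)
        if d is not None:
            report = normalize_term(node.canonical_name, d)
            if report.output and report.output != node.canonical_name:
                node.canonical_name = report.output
    # fusion of a single graph merges equal (type, name) keys
    return fuse_graphs([renamed])
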