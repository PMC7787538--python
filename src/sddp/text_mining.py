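"""Literature mining of marker–disease associations.

Implements the strict, sentence-structure-aware extraction stage: term
mentions are located by longest-match dictionary lookup on a POST
(:mod:`sddp.post`); two mentions are *semantically related* unless an
exclusion rule fires; per-pair co-occurrence counts across the corpus
are turned into a z-score against the independence expectation, and a
pair is reported only when the z-score and the document support both
clear their thresholds.

Two strict rules are hardwired:

* **pronoun rule** — a pronoun is replaced by the closest terms of the
  preceding independent clause, so terms linked through a pronoun count
  as co-occurring (:func:`resolve_pronouns`);
* **preposition-modifier rule** — mentions in distinct independent
  clauses joined by "whereas"/"while"/"but" are unrelated.

Further rules register through the ``extra_rules`` plugin hook: any
callable ``rule(tree, mention_a, mention_b) -> bool`` returning True
*excludes* the pair.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

from .post import (
    DEFAULT_COORDINATORS,
    DEFAULT_PRONOUNS,
    Constituent,
    ConstituentTree,
    copy_tree,
    innermost_clause,
    load_post,
    post_from_text,
    tokenize,
)

__all__ = [
    "TermDictionary",
    "TermMention",
    "PairStatistics",
    "Publication",
    "ExtractionConfig",
    "load_post",
    "resolve_pronouns",
    "find_mentions",
    "related_pairs",
    "mention_pair_related",
    "pair_zscore",
    "extract_markers",
]

logger = logging.getLogger(__name__)

TERM_TYPES = ("marker", "disease")

#: Exclusion-rule plugin: return True to declare the mention pair unrelated.
ExclusionRule = Callable[[ConstituentTree, "TermMention", "TermMention"], bool]


@dataclass(frozen=True)
class TermEntry:
    id: str
    type: str
    surface_forms: tuple[str, ...]

    def __post_init__(self):
        if self.type not in TERM_TYPES:
            raise ValueError(f"term type must be one of {TERM_TYPES}: {self.type!r}")
        if not self.surface_forms:
            raise ValueError(f"term {self.id!r} has no surface forms")


class TermDictionary:
    """Canonical-id → typed term entries with case-insensitive lookup."""

    def __init__(self, entries: Iterable[TermEntry]):
        self.entries: dict[str, TermEntry] = {}
        for entry in entries:
            if entry.id in self.entries:
                raise ValueError(f"duplicate term id {entry.id!r}")
            self.entries[entry.id] = entry
        # token-tuple index for longest-match scanning
        self._index: dict[tuple[str, ...], str] = {}
        self._max_len = 0
        for entry in self.entries.values():
            for form in entry.surface_forms:
                key = tuple(t.lower() for t in tokenize(form))
                if not key:
                    raise ValueError(f"empty surface form for {entry.id!r}")
                if key in self._index and self._index[key] != entry.id:
                    logger.warning(
                        "surface form %r maps to both %s and %s; keeping %s",
                        form, self._index[key], entry.id, self._index[key])
                    continue
                self._index[key] = entry.id
                self._max_len = max(self._max_len, len(key))

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, term_id: str) -> TermEntry:
        return self.entries[term_id]

    def type_of(self, term_id: str) -> str:
        return self.entries[term_id].type

    def ids(self, type: str | None = None) -> list[str]:
        return sorted(e.id for e in self.entries.values()
                      if type is None or e.type == type)

    def scan(self, tokens: Sequence[str]) -> list[tuple[int, int, str]]:
        """Greedy left-to-right longest-match over lowercased tokens.

        Returns (start, end, term_id) triples with 0-based half-open spans.
        """
        low = [t.lower() for t in tokens]
        out: list[tuple[int, int, str]] = []
        i = 0
        n = len(low)
        while i < n:
            hit = None
            for length in range(min(self._max_len, n - i), 0, -1):
                key = tuple(low[i:i + length])
                if key in self._index:
                    hit = (i, i + length, self._index[key])
                    break
            if hit:
                out.append(hit)
                i = hit[1]
            else:
                i += 1
        return out


@dataclass(frozen=True)
class TermMention:
    """A located dictionary term (or pronoun-borne antecedent) in a sentence."""

    id: str
    type: str
    start: int
    end: int
    sentence_index: int = 0
    path: tuple[int, ...] = ()
    via_pronoun: bool = False


@dataclass
class PairStatistics:
    """Corpus-level co-occurrence counts for one unordered term pair."""

    pair: tuple[str, str]
    n_related: int
    n_a: int
    n_b: int
    n_sentences: int
    n_docs_related: int
    z: float = 0.0

    def validate(self) -> None:
        if not (0 <= self.n_related <= min(self.n_a, self.n_b) <= self.n_sentences):
            raise ValueError(f"inconsistent counts for {self.pair}")


@dataclass
class Publication:
    """One abstract: raw sentences plus their POSTs."""

    pmid: str
    sentences: list[ConstituentTree]
    raw: list[str] = field(default_factory=list)


@dataclass
class ExtractionConfig:
    z_min: float = 1.96
    min_docs: int = 3
    coordinators: frozenset[str] = DEFAULT_COORDINATORS
    pronouns: frozenset[str] = DEFAULT_PRONOUNS
    unit: str = "sentence"  # or "abstract"
    extra_rules: tuple[ExclusionRule, ...] = ()

    def __post_init__(self):
        if self.unit not in ("sentence", "abstract"):
            raise ValueError(f"unit must be 'sentence' or 'abstract': {self.unit!r}")


# ---------------------------------------------------------------------------
# pronoun resolution

def resolve_pronouns(
    tree: ConstituentTree,
    dictionary: TermDictionary,
    pronouns: frozenset[str] = DEFAULT_PRONOUNS,
) -> ConstituentTree:
    """Annotate pronoun leaves with the closest preceding-clause terms.

    For each pronoun token, the predecessor independent clause is the
    independent clause ending nearest before the pronoun; within it the
    dictionary mentions with the smallest token distance from mention
    end to the pronoun are taken as antecedents (ties keep all).  Tree
    shape is unchanged; pronouns with no resolvable antecedent are left
    unannotated with a logged warning.
    """
    out = copy_tree(tree)
    tokens = out.tokens()
    clauses = [c for c in out.root.walk() if c.label == "independent-clause"]
    hits = dictionary.scan(tokens)

    for leaf in out.leaves():
        if leaf.text is None or leaf.text.lower() not in pronouns:
            continue
        # predecessor independent clause: ends closest before the pronoun,
        # excluding any clause containing the pronoun itself
        candidates = [c for c in clauses
                      if c.end <= leaf.start
                      and not (c.start <= leaf.start < c.end)]
        if not candidates:
            logger.warning("pronoun %r at token %d has no predecessor "
                           "independent clause", leaf.text, leaf.start)
            continue
        clause = max(candidates, key=lambda c: (c.end, c.start))
        in_clause = [(s, e, tid) for s, e, tid in hits
                     if clause.start <= s and e <= clause.end]
        if not in_clause:
            logger.warning("pronoun %r at token %d: predecessor clause has "
                           "no dictionary terms", leaf.text, leaf.start)
            continue
        best = min(leaf.start - e for _, e, _ in in_clause)
        ante = sorted({tid for _, e, tid in in_clause if leaf.start - e == best})
        leaf.antecedents = tuple(ante)
    return out


# ---------------------------------------------------------------------------
# mentions and relatedness

def _constituent_path(tree: ConstituentTree, start: int, end: int) -> tuple[int, ...]:
    """Child-index path from root to the smallest constituent covering the span."""
    path: list[int] = []
    node = tree.root
    while True:
        for i, child in enumerate(node.children):
            if not child.is_token and child.start <= start and end <= child.end:
                path.append(i)
                node = child
                break
        else:
            return tuple(path)


def find_mentions(
    tree: ConstituentTree,
    dictionary: TermDictionary,
    sentence_index: int = 0,
) -> list[TermMention]:
    """Dictionary mentions in a POST, including pronoun-borne antecedents."""
    if len(dictionary) == 0:
        raise ValueError("empty term dictionary")
    tokens = tree.tokens()
    mentions = [
        TermMention(tid, dictionary.type_of(tid), s, e, sentence_index,
                    _constituent_path(tree, s, e))
        for s, e, tid in dictionary.scan(tokens)
    ]
    for leaf in tree.leaves():
        for tid in leaf.antecedents:
            if tid in dictionary:
                mentions.append(TermMention(
                    tid, dictionary.type_of(tid), leaf.start, leaf.end,
                    sentence_index, _constituent_path(tree, leaf.start, leaf.end),
                    via_pronoun=True))
    mentions.sort(key=lambda m: (m.start, m.end, m.id))
    return mentions


def preposition_modifier_rule(
    coordinators: frozenset[str] = DEFAULT_COORDINATORS,
) -> ExclusionRule:
    """Exclusion rule: distinct independent clauses joined by a coordinator."""

    def rule(tree: ConstituentTree, a: TermMention, b: TermMention) -> bool:
        ca = innermost_clause(tree, a.start, a.end)
        cb = innermost_clause(tree, b.start, b.end)
        if ca is None or cb is None or ca is cb:
            return False
        if not (ca.end <= cb.start or cb.end <= ca.start):
            return False  # nested clauses are not "distinct"
        first, second = (ca, cb) if ca.end <= cb.start else (cb, ca)
        between = tree.tokens()[first.end:second.start]
        return any(tok.lower() in coordinators for tok in between)

    return rule


def mention_pair_related(
    tree: ConstituentTree,
    a: TermMention,
    b: TermMention,
    coordinators: frozenset[str] = DEFAULT_COORDINATORS,
    extra_rules: Sequence[ExclusionRule] = (),
) -> bool:
    """True unless an exclusion rule declares the two mentions unrelated.

    A mention is always related to itself.
    """
    if a is b or (a.start, a.end, a.id) == (b.start, b.end, b.id):
        return True
    rules: list[ExclusionRule] = [preposition_modifier_rule(coordinators)]
    rules.extend(extra_rules)
    return not any(rule(tree, a, b) for rule in rules)


def related_pairs(
    tree: ConstituentTree,
    dictionary: TermDictionary,
    coordinators: frozenset[str] = DEFAULT_COORDINATORS,
    extra_rules: Sequence[ExclusionRule] = (),
) -> set[tuple[str, str]]:
    """Unordered id pairs judged semantically related in the sentence.

    A pair of distinct ids is related iff some mention of one is related
    to some mention of the other.  Pronoun annotations count as mentions
    of their antecedent terms.
    """
    mentions = find_mentions(tree, dictionary)
    out: set[tuple[str, str]] = set()
    for i, a in enumerate(mentions):
        for b in mentions[i + 1:]:
            if a.id == b.id:
                continue
            key = (min(a.id, b.id), max(a.id, b.id))
            if key in out:
                continue
            if mention_pair_related(tree, a, b, coordinators, extra_rules):
                out.add(key)
    return out


# ---------------------------------------------------------------------------
# association statistics

def pair_zscore(stats: PairStatistics) -> float:
    """One-sample binomial z-score against the independence expectation.

    With marginal sentence probabilities ``n_a/N`` and ``n_b/N`` the
    expected number of co-occurring sentences under independence is
    ``E = N * (n_a/N) * (n_b/N)``; the statistic is
    ``(n_related - E) / sqrt(E * (1 - p))``.
    """
    n = stats.n_sentences
    if n <= 0 or stats.n_a <= 0 or stats.n_b <= 0:
        raise ValueError("pair_zscore requires n_sentences, n_a, n_b > 0")
    stats.validate()
    expected = stats.n_a * stats.n_b / n
    p = expected / n
    if expected == 0:
        return 0.0
    denom = math.sqrt(expected * (1.0 - p))
    if denom == 0:
        return 0.0
    return (stats.n_related - expected) / denom


def extract_markers(
    corpus: Iterable[Publication],
    dictionary: TermDictionary,
    disease_id: str,
    config: ExtractionConfig | None = None,
) -> list[tuple[str, PairStatistics]]:
    """Markers significantly related to ``disease_id`` across the corpus.

    Keeps pairs with ``z >= z_min`` and related co-occurrence in at
    least ``min_docs`` distinct publications; ordered by z descending,
    then marker id ascending.  Invariant under publication order.
    """
    config = config or ExtractionConfig()
    if disease_id not in dictionary:
        raise ValueError(f"disease id {disease_id!r} not in dictionary")
    if dictionary.type_of(disease_id) != "disease":
        raise ValueError(f"{disease_id!r} is not a disease term")

    n_units = 0
    term_units: dict[str, int] = {}
    related_units: dict[str, int] = {}
    related_docs: dict[str, set[str]] = {}

    for pub in corpus:
        doc_present: set[str] = set()
        doc_related: set[str] = set()
        for idx, tree in enumerate(pub.sentences):
            resolved = resolve_pronouns(tree, dictionary, config.pronouns)
            mentions = find_mentions(resolved, dictionary, idx)
            present = {m.id for m in mentions}
            pairs = related_pairs(resolved, dictionary,
                                  config.coordinators, config.extra_rules)
            markers_here = {
                a if b == disease_id else b
                for a, b in pairs
                if disease_id in (a, b)
                and dictionary.type_of(a if b == disease_id else b) == "marker"
            }
            if config.unit == "sentence":
                n_units += 1
                for tid in present:
                    term_units[tid] = term_units.get(tid, 0) + 1
                for m in markers_here:
                    related_units[m] = related_units.get(m, 0) + 1
            doc_present |= present
            doc_related |= markers_here
            for m in markers_here:
                related_docs.setdefault(m, set()).add(pub.pmid)
        if config.unit == "abstract":
            n_units += 1
            for tid in doc_present:
                term_units[tid] = term_units.get(tid, 0) + 1
            for m in doc_related:
                related_units[m] = related_units.get(m, 0) + 1

    n_disease = term_units.get(disease_id, 0)
    results: list[tuple[str, PairStatistics]] = []
    if n_disease == 0 or n_units == 0:
        return results
    for marker, n_rel in related_units.items():
        stats = PairStatistics(
            pair=(marker, disease_id),
            n_related=n_rel,
            n_a=term_units.get(marker, 0),
            n_b=n_disease,
            n_sentences=n_units,
            n_docs_related=len(related_docs.get(marker, ())),
        )
        stats.z = pair_zscore(stats)
        if stats.z >= config.z_min and stats.n_docs_related >= config.min_docs:
            results.append((marker, stats))
    results.sort(key=lambda item: (-item[1].z, item[0]))
    return results
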