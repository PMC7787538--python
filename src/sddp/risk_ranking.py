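"""Dominance ranking of pathway combinations — the risk indicator.

Each combination of molecular pathways gets a per-publication
co-occurrence weight; combination c_i *beats* c_j when its weight
exceeds c_j's in more publications than the reverse.  The dominance
score of a combination is beats minus losses over all pairwise
comparisons (a Copeland-style score), and the risk indicator assigned
to an individual is the competition rank (ties share a rank, the
following ranks are skipped) of the individual's inferred combination.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations as _itercombs
from typing import Iterable, Mapping, Sequence

import numpy as np

from .text_mining import (
    ExtractionConfig,
    Publication,
    TermDictionary,
    find_mentions,
    mention_pair_related,
    resolve_pronouns,
)

__all__ = [
    "Combination",
    "CombinationWeights",
    "DominanceResult",
    "enumerate_combinations",
    "combination_weights",
    "pairwise_outcome",
    "dominance_scores",
    "risk_indicator",
]


@dataclass(frozen=True)
class Combination:
    id: str
    pathways: frozenset[str]

    def __post_init__(self):
        if not self.pathways:
            raise ValueError(f"combination {self.id!r} is empty")


@dataclass
class CombinationWeights:
    """Per-publication co-occurrence weight matrix, publications × combinations."""

    combinations: list[Combination]
    publications: list[str]
    W: np.ndarray

    def __post_init__(self):
        self.W = np.asarray(self.W)
        if self.W.shape != (len(self.publications), len(self.combinations)):
            raise ValueError("weight matrix shape does not match labels")
        if not np.issubdtype(self.W.dtype, np.integer):
            if not np.all(self.W == self.W.astype(int)):
                raise ValueError("weights must be integers")
            self.W = self.W.astype(int)
        if (self.W < 0).any():
            raise ValueError("weights must be non-negative")
        ids = [c.id for c in self.combinations]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate combination ids")

    def index(self, cid: str) -> int:
        for i, c in enumerate(self.combinations):
            if c.id == cid:
                return i
        raise ValueError(f"unknown combination {cid!r}")

    def column(self, cid: str) -> np.ndarray:
        return self.W[:, self.index(cid)]


@dataclass
class DominanceResult:
    """Pairwise beats matrix, Copeland scores, and competition ranks."""

    combinations: list[str]
    beats: np.ndarray   # entries in {+1, 0, -1}; beats[i, j] = outcome of c_i vs c_j
    scores: np.ndarray  # beats minus losses per combination
    ranks: np.ndarray   # 1 + number of strictly better scores

    def index(self, cid: str) -> int:
        try:
            return self.combinations.index(cid)
        except ValueError:
            raise ValueError(f"unknown combination {cid!r}") from None

    def score(self, cid: str) -> int:
        return int(self.scores[self.index(cid)])

    def rank(self, cid: str) -> int:
        return int(self.ranks[self.index(cid)])


def enumerate_combinations(
    pathway_ids: Iterable[str],
    max_size: int = 3,
    include: Iterable[frozenset[str]] = (),
) -> list[Combination]:
    """All pathway subsets up to ``max_size`` (plus any in ``include``).

    Ids run c1, c2, … over subsets ordered by size then lexicographic
    member tuple, so the enumeration is deterministic.
    """
    ids = sorted(set(pathway_ids))
    subsets: list[tuple[str, ...]] = []
    for size in range(1, max_size + 1):
        subsets.extend(_itercombs(ids, size))
    seen = {frozenset(s) for s in subsets}
    for extra in include:
        fs = frozenset(extra)
        if fs and fs not in seen:
            subsets.append(tuple(sorted(fs)))
            seen.add(fs)
    return [Combination(f"c{i}", frozenset(s))
            for i, s in enumerate(subsets, start=1)]


def combination_weights(
    corpus: Iterable[Publication],
    dictionary: TermDictionary,
    pathway_markers: Mapping[str, Iterable[str]],
    combinations: Sequence[Combination],
    config: ExtractionConfig | None = None,
) -> CombinationWeights:
    """Count, per publication, the sentences jointly supporting each combination.

    A sentence supports combination c when at least one marker term of
    every member pathway occurs in it and all such marker mentions are
    pairwise semantically related (same strict rules as the extractor).
    """
    config = config or ExtractionConfig()
    marker_sets = {pid: frozenset(ms) for pid, ms in pathway_markers.items()}
    for comb in combinations:
        unknown = comb.pathways - marker_sets.keys()
        if unknown:
            raise ValueError(
                f"combination {comb.id!r} references unknown pathway "
                f"{sorted(unknown)[0]!r}")

    pubs = list(corpus)
    W = np.zeros((len(pubs), len(combinations)), dtype=int)
    for p_idx, pub in enumerate(pubs):
        for tree in pub.sentences:
            resolved = resolve_pronouns(tree, dictionary, config.pronouns)
            mentions = find_mentions(resolved, dictionary)
            marker_mentions = [m for m in mentions if m.type == "marker"]
            if not marker_mentions:
                continue
            present = {m.id for m in marker_mentions}
            for c_idx, comb in enumerate(combinations):
                if not all(marker_sets[pid] & present for pid in comb.pathways):
                    continue
                relevant_ids = frozenset().union(
                    *(marker_sets[pid] for pid in comb.pathways))
                involved = [m for m in marker_mentions if m.id in relevant_ids]
                ok = all(
                    mention_pair_related(resolved, a, b,
                                         config.coordinators, config.extra_rules)
                    for i, a in enumerate(involved) for b in involved[i + 1:])
                if ok:
                    W[p_idx, c_idx] += 1
    return CombinationWeights(list(combinations), [p.pmid for p in pubs], W)


def pairwise_outcome(w_i: Sequence[int], w_j: Sequence[int]) -> int:
    """+1 if c_i out-weighs c_j in more publications than the reverse, −1
    if fewer, 0 on balance."""
    a = np.asarray(w_i)
    b = np.asarray(w_j)
    if a.shape != b.shape:
        raise ValueError("weight columns must have equal length")
    wins = int(np.sum(a > b))
    losses = int(np.sum(b > a))
    return (wins > losses) - (wins < losses)


def dominance_scores(weights: CombinationWeights) -> DominanceResult:
    """Beats matrix, Copeland scores, and competition ranks for all combinations."""
    n = len(weights.combinations)
    if n < 1:
        raise ValueError("need at least one combination")
    beats = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            out = pairwise_outcome(weights.W[:, i], weights.W[:, j])
            beats[i, j] = out
            beats[j, i] = -out
    scores = (np.maximum(beats, 0).sum(axis=1)
              - np.maximum(-beats, 0).sum(axis=1))
    ranks = np.array([1 + int(np.sum(scores > s)) for s in scores], dtype=int)
    return DominanceResult(
        combinations=[c.id for c in weights.combinations],
        beats=beats, scores=scores, ranks=ranks)


def risk_indicator(result: DominanceResult, combination_id: str) -> int:
    """The dominance rank of the individual's combination."""
    return result.rank(combination_id)
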