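"""Seed-reproducible synthetic corpora, networks and pathway sets.

Every stage of the pipeline is testable offline against known ground
truth: the corpus generator plants marker–disease associations in
single-clause sentences (with pronoun-linked and two-marker joint
variants), scatters decoy co-occurrences across "whereas"-split
clauses, and adds independence-level noise so the z-score null is
exact; the network generator produces a random interaction graph plus
overlapping pathway molecule sets with designated markers.  Generated
sentences carry their own POST bracketings, so no external parser is
involved anywhere.

Also houses the extraction quality metrics (precision / recall /
F-value) and the packaged worked-example fixtures (the two-clause
example sentence and the 3-publication × 10-combination weight matrix
with its expected dominance scores and ranks).
"""
from __future__ import annotations

import random
import string
from dataclasses import dataclass, field
from typing import NamedTuple

import networkx as nx
import numpy as np

from .pathway_model import Pathway
from .post import ConstituentTree, load_post
from .text_mining import Publication, TermDictionary, TermEntry
from .risk_ranking import Combination, CombinationWeights

__all__ = [
    "GeneratorConfig", "PlantedPair", "CorpusTruth", "EvaluationCounts",
    "gen_corpus", "gen_network_and_pathways", "score_extraction",
    "load_worked_examples", "nested_example", "WorkedExamples",
]


class PlantedPair(NamedTuple):
    marker: str
    disease: str
    prob: float  # per-document probability of a planted related sentence


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic study.

    The defaults describe a small literature-mining study: 200
    abstracts of 3–6 background sentences each, a 24-marker / 2-disease
    vocabulary with 12 planted associations realised in roughly one in
    six abstracts, a quarter of background sentences split by a
    coordinator (decoys), pronoun-linked and joint two-marker restates
    of planted pairs, and background term mentions dropped in under
    independence so unplanted pairs sit at the z-score null.
    """

    seed: int = 1
    n_publications: int = 200
    sentences_per_abstract: tuple[int, int] = (3, 6)
    n_markers: int = 24
    n_diseases: int = 2
    planted: tuple[PlantedPair, ...] | None = None
    n_planted: int = 12
    planted_prob: float = 0.16
    noise_marker_rate: float = 0.4
    noise_disease_rate: float = 0.3
    whereas_fraction: float = 0.25
    pronoun_fraction: float = 0.2
    joint_fraction: float = 0.15
    # network / pathway side
    network_size: int = 60
    edge_prob: float = 0.15
    n_pathways: int = 4
    pathway_size: int = 10
    overlap_fraction: float = 0.3
    markers_per_pathway: int = 2

    def __post_init__(self):
        for name in ("planted_prob", "noise_marker_rate", "noise_disease_rate",
                     "whereas_fraction", "pronoun_fraction", "joint_fraction",
                     "edge_prob", "overlap_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_publications", "n_markers", "n_diseases",
                     "network_size", "n_pathways", "pathway_size",
                     "markers_per_pathway"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.sentences_per_abstract
        if not (0 < lo <= hi):
            raise ValueError("sentences_per_abstract must be a positive range")

    @property
    def marker_ids(self) -> list[str]:
        return [f"MRK{i:02d}" for i in range(1, self.n_markers + 1)]

    @property
    def disease_ids(self) -> list[str]:
        return [f"DIS{i:02d}" for i in range(1, self.n_diseases + 1)]

    def build_dictionary(self) -> TermDictionary:
        entries = [TermEntry(m, "marker", (m, f"{m} protein"))
                   for m in self.marker_ids]
        entries += [TermEntry(d, "disease", (d, f"{d} syndrome"))
                    for d in self.disease_ids]
        return TermDictionary(entries)

    def planted_pairs(self) -> tuple[PlantedPair, ...]:
        if self.planted is not None:
            return self.planted
        if self.n_planted > self.n_markers:
            raise ValueError("more planted pairs than marker vocabulary")
        diseases = self.disease_ids
        return tuple(
            PlantedPair(f"MRK{i:02d}", diseases[(i - 1) % len(diseases)],
                        self.planted_prob)
            for i in range(1, self.n_planted + 1))


@dataclass
class CorpusTruth:
    """Ground truth emitted alongside a generated corpus."""

    planted: frozenset[tuple[str, str]]
    sentence_pairs: dict[tuple[str, int], frozenset[tuple[str, str]]]
    dictionary: TermDictionary


def _pair(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


# --- sentence templates: (raw text, bracketed POST, true related pairs) ----

def _planted_sentence(rng: random.Random, m: str, d: str):
    variants = (
        (f"{m} is significantly associated with {d} in patients",
         f"(S (NP {m}) (VP is significantly associated with (NP {d}) in patients))"),
        (f"elevated {m} levels correlate with {d}",
         f"(S (NP elevated {m} levels) (VP correlate with (NP {d})))"),
    )
    raw, post = variants[rng.randrange(len(variants))]
    return raw, post, {_pair(m, d)}


def _joint_sentence(m1: str, m2: str, d: str):
    raw = f"{m1} and {m2} are jointly linked to {d}"
    post = (f"(S (NP (UCP {m1} and {m2})) "
            f"(VP are jointly linked to (NP {d})))")
    return raw, post, {_pair(m1, m2), _pair(m1, d), _pair(m2, d)}


def _decoy_sentence(m: str, d: str):
    raw = f"{m} regulates cellular signalling , whereas {d} involves impaired homeostasis"
    post = (f"(POST (S (NP {m}) (VP regulates cellular signalling)) , whereas "
            f"(S (NP {d}) (VP involves impaired homeostasis)))")
    return raw, post, set()


def _pronoun_sentence(m: str, d: str):
    raw = f"{m} is frequently overexpressed , which contributes to {d}"
    post = (f"(POST (S (NP {m}) (VP is frequently overexpressed)) , "
            f"(S (WHNP which) (VP contributes to (NP {d}))))")
    return raw, post, {_pair(m, d)}


def _noise_sentence(terms: list[str]):
    if not terms:
        raw = "this study examined expression patterns in tissue samples"
        post = "(S (NP this study) (VP examined expression patterns in tissue samples))"
        return raw, post, set()
    if len(terms) == 1:
        t = terms[0]
        raw = f"this study examined {t} in tissue samples"
        post = f"(S (NP this study) (VP examined (NP {t}) in tissue samples))"
        return raw, post, set()
    t1, t2 = terms[:2]
    raw = f"this study examined {t1} and {t2} in tissue samples"
    post = (f"(S (NP this study) (VP examined (UCP {t1} and {t2}) "
            f"in tissue samples))")
    return raw, post, {_pair(t1, t2)}


def gen_corpus(config: GeneratorConfig) -> tuple[list[Publication], CorpusTruth]:
    """Generate a corpus of abstracts with per-sentence ground truth.

    Pure function of the config (including its seed): identical configs
    give byte-identical corpora.  Every planted pair is guaranteed to
    appear in at least one related sentence (a top-up abstract is
    appended in the rare case sampling missed one).
    """
    if config.n_markers == 0 or config.n_diseases == 0:
        raise ValueError("empty vocabularies")
    rng = random.Random(config.seed)
    dictionary = config.build_dictionary()
    markers = config.marker_ids
    diseases = config.disease_ids
    planted = config.planted_pairs()
    by_disease: dict[str, list[str]] = {}
    for p in planted:
        by_disease.setdefault(p.disease, []).append(p.marker)

    publications: list[Publication] = []
    sentence_pairs: dict[tuple[str, int], frozenset] = {}
    realised: set[tuple[str, str]] = set()

    def build_abstract(pmid: str, sentences: list[tuple[str, str, set]]):
        raws, trees = [], []
        for idx, (raw, post, pairs) in enumerate(sentences):
            raws.append(raw)
            trees.append(load_post(post))
            sentence_pairs[(pmid, idx)] = frozenset(pairs)
        publications.append(Publication(pmid=pmid, sentences=trees, raw=raws))

    for i in range(config.n_publications):
        pmid = str(10_000_000 + i)
        sentences: list[tuple[str, str, set]] = []
        planted_here = [p for p in planted if rng.random() < p.prob]
        for p in planted_here:
            sentences.append(_planted_sentence(rng, p.marker, p.disease))
            realised.add((p.marker, p.disease))
        if planted_here and rng.random() < config.pronoun_fraction:
            p = rng.choice(planted_here)
            sentences.append(_pronoun_sentence(p.marker, p.disease))
        n_base = rng.randint(*config.sentences_per_abstract)
        for _ in range(n_base):
            r = rng.random()
            if r < config.whereas_fraction:
                sentences.append(_decoy_sentence(
                    rng.choice(markers), rng.choice(diseases)))
            elif r < config.whereas_fraction + config.joint_fraction and planted:
                p = planted[rng.randrange(len(planted))]
                partners = [m for m in by_disease[p.disease] if m != p.marker]
                if partners:
                    m2 = rng.choice(partners)
                    sentences.append(_joint_sentence(p.marker, m2, p.disease))
                    realised.add((p.marker, p.disease))
                    realised.add((m2, p.disease))
                else:
                    sentences.append(_planted_sentence(rng, p.marker, p.disease))
                    realised.add((p.marker, p.disease))
            else:
                terms = []
                if rng.random() < config.noise_marker_rate:
                    terms.append(rng.choice(markers))
                if rng.random() < config.noise_disease_rate:
                    terms.append(rng.choice(diseases))
                sentences.append(_noise_sentence(terms))
        rng.shuffle(sentences)
        build_abstract(pmid, sentences)

    missing = [(p.marker, p.disease) for p in planted
               if (p.marker, p.disease) not in realised]
    if missing:
        build_abstract("99999999",
                       [_planted_sentence(rng, m, d) for m, d in missing])

    truth = CorpusTruth(
        planted=frozenset((p.marker, p.disease) for p in planted),
        sentence_pairs=sentence_pairs,
        dictionary=dictionary,
    )
    return publications, truth


def gen_network_and_pathways(
    config: GeneratorConfig,
) -> tuple[nx.Graph, list[Pathway]]:
    """Random interaction network plus overlapping pathway molecule sets.

    The first ``n_markers`` network nodes carry the marker-term names,
    so marker molecules line up with the corpus vocabulary.  Pathways
    are laid out as a chain in which consecutive pathways share
    ``round(overlap_fraction * pathway_size)`` molecules; each pathway
    gets ``markers_per_pathway`` distinct marker molecules.
    """
    cfg = config
    if cfg.n_markers > cfg.network_size:
        raise ValueError("marker vocabulary larger than the network")
    need_markers = cfg.n_pathways * cfg.markers_per_pathway
    if need_markers > cfg.n_markers:
        raise ValueError("not enough marker molecules for all pathways")

    rng = random.Random(cfg.seed + 10_007)
    names = cfg.marker_ids + [
        f"MOL{i:03d}" for i in range(1, cfg.network_size - cfg.n_markers + 1)]
    g = nx.gnp_random_graph(cfg.network_size, cfg.edge_prob,
                            seed=cfg.seed + 20_011)
    network = nx.relabel_nodes(g, dict(enumerate(names)))

    k_shared = round(cfg.overlap_fraction * cfg.pathway_size)
    fill_pool = [n for n in names if n.startswith("MOL")]
    rng.shuffle(fill_pool)
    marker_pool = list(cfg.marker_ids)
    rng.shuffle(marker_pool)

    def draw(pool: list[str], k: int) -> list[str]:
        if len(pool) < k:
            raise ValueError(
                "overlap fraction infeasible for the requested sizes: "
                "molecule pool exhausted")
        return [pool.pop() for _ in range(k)]

    shared_blocks = [draw(fill_pool, k_shared) for _ in range(cfg.n_pathways - 1)]
    pathways: list[Pathway] = []
    letters = string.ascii_uppercase
    for i in range(cfg.n_pathways):
        markers = draw(marker_pool, cfg.markers_per_pathway)
        molecules = set(markers)
        if i > 0:
            molecules |= set(shared_blocks[i - 1])
        if i < cfg.n_pathways - 1:
            molecules |= set(shared_blocks[i])
        n_fill = cfg.pathway_size - len(molecules)
        if n_fill < 0:
            raise ValueError(
                "overlap fraction infeasible for the requested sizes: "
                "shared blocks exceed the pathway size")
        molecules |= set(draw(fill_pool, n_fill))
        pid = f"MP_{letters[i % 26]}{'' if i < 26 else i // 26}"
        pathways.append(Pathway(pid, frozenset(molecules), frozenset(markers)))
    return network, pathways


def nested_example() -> tuple[nx.Graph, Pathway, Pathway]:
    """Hand-constructed nested pathway pair with a known hierarchy arrow.

    Pathway MP_A's molecules are a subset of MP_B's, and MP_A's marker
    sits deeper in MP_B's tree, so the MPIN arrow runs from MP_B to
    MP_A (MP_A more specific): the lowest common molecule M1 has level
    1 in MP_A's forest and level 2 in MP_B's.
    """
    network = nx.Graph()
    network.add_edges_from([("MM_A", "M1"), ("MM_B", "M2"), ("M2", "M1")])
    a = Pathway("MP_A", frozenset({"MM_A", "M1"}), frozenset({"MM_A"}))
    b = Pathway("MP_B", frozenset({"MM_A", "MM_B", "M1", "M2"}),
                frozenset({"MM_B"}))
    return network, a, b


# ---------------------------------------------------------------------------
# evaluation metrics

@dataclass
class EvaluationCounts:
    """TP/FP/FN counts with precision, recall and F-value.

    ``precision = TP/(TP+FP)``, ``recall = TP/(TP+FN)``,
    ``f_value = 2*P*R/(P+R)``; denominators of zero yield 0.0 and the
    affected metric names are listed in ``undefined``.
    """

    tp: int
    fp: int
    fn: int
    precision: float = field(init=False)
    recall: float = field(init=False)
    f_value: float = field(init=False)
    undefined: tuple[str, ...] = field(init=False)

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")
        undef = []
        if self.tp + self.fp > 0:
            self.precision = self.tp / (self.tp + self.fp)
        else:
            self.precision, undef = 0.0, undef + ["precision"]
        if self.tp + self.fn > 0:
            self.recall = self.tp / (self.tp + self.fn)
        else:
            self.recall, undef = 0.0, undef + ["recall"]
        if self.precision + self.recall > 0:
            self.f_value = (2 * self.precision * self.recall
                            / (self.precision + self.recall))
        else:
            self.f_value, undef = 0.0, undef + ["f_value"]
        self.undefined = tuple(undef)


def score_extraction(predicted, truth) -> EvaluationCounts:
    """Compare predicted against true association pairs."""
    predicted = {tuple(sorted(p)) for p in predicted}
    truth = {tuple(sorted(p)) for p in truth}
    tp = len(predicted & truth)
    return EvaluationCounts(tp=tp, fp=len(predicted) - tp, fn=len(truth) - tp)


# ---------------------------------------------------------------------------
# worked-example fixtures

EXAMPLE_SENTENCE = ("In some studies, SLC6A2 and SLC6A4 are linked, whereas "
                    "susceptibility to OCD was linked to G1287A and 5-HIT")

EXAMPLE_SENTENCE_POST = (
    "(POST (S (PP In some studies) , (NP (UCP SLC6A2 and SLC6A4)) "
    "(VP are linked)) , whereas "
    "(S (NP susceptibility to (NP OCD)) "
    "(VP was linked to (UCP G1287A and 5-HIT))))"
)

_EXAMPLE_TERMS = (
    TermEntry("SLC6A2", "marker", ("SLC6A2",)),
    TermEntry("SLC6A4", "marker", ("SLC6A4",)),
    TermEntry("G1287A", "marker", ("G1287A",)),
    TermEntry("5-HIT", "marker", ("5-HIT",)),
    TermEntry("OCD", "disease", ("OCD",)),
)

# 3 publications × 10 combinations joint co-occurrence counts
WEIGHT_MATRIX = np.array([
    [3, 0, 0, 0, 7, 0, 3, 6, 3, 0],
    [0, 3, 7, 3, 0, 0, 0, 3, 0, 4],
    [3, 3, 5, 0, 0, 6, 0, 0, 4, 0],
])

EXPECTED_SCORES = (0, 1, 8, -6, -1, -1, -6, 4, 3, -2)
EXPECTED_RANKS = (5, 4, 1, 9, 6, 6, 9, 2, 3, 8)


@dataclass
class WorkedExamples:
    sentence: str
    sentence_post: str
    sentence_tree: ConstituentTree
    dictionary: TermDictionary
    expected_related: frozenset[tuple[str, str]]
    expected_unrelated: frozenset[tuple[str, str]]
    weights: CombinationWeights
    expected_scores: dict[str, int]
    expected_ranks: dict[str, int]


def load_worked_examples() -> WorkedExamples:
    """Packaged fixtures for the two in-text worked examples.

    The two-clause example sentence with its POST and expected
    relatedness partition, and the 10-combination weight matrix with
    the dominance scores and risk-indicator ranks it must produce.
    The combinations' pathway compositions are not part of the fixture;
    placeholder singletons stand in, as ranking depends on the weights
    only.
    """
    related = frozenset({
        _pair("SLC6A2", "SLC6A4"),
        _pair("OCD", "G1287A"),
        _pair("OCD", "5-HIT"),
        _pair("G1287A", "5-HIT"),
    })
    unrelated = frozenset(
        _pair(a, b)
        for a in ("SLC6A2", "SLC6A4")
        for b in ("OCD", "G1287A", "5-HIT"))
    combos = [Combination(f"c{i}", frozenset({f"MP{i}"})) for i in range(1, 11)]
    weights = CombinationWeights(
        combinations=combos,
        publications=["p1", "p2", "p3"],
        W=WEIGHT_MATRIX.copy(),
    )
    return WorkedExamples(
        sentence=EXAMPLE_SENTENCE,
        sentence_post=EXAMPLE_SENTENCE_POST,
        sentence_tree=load_post(EXAMPLE_SENTENCE_POST),
        dictionary=TermDictionary(_EXAMPLE_TERMS),
        expected_related=related,
        expected_unrelated=unrelated,
        weights=weights,
        expected_scores={f"c{i}": s for i, s in enumerate(EXPECTED_SCORES, 1)},
        expected_ranks={f"c{i}": r for i, r in enumerate(EXPECTED_RANKS, 1)},
    )
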