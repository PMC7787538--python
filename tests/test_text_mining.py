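"""Strict relatedness rules, pronoun resolution, z-scores, extraction."""
import math
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sddp.post import load_post
from sddp.synthetic import GeneratorConfig, gen_corpus
from sddp.text_mining import (
    ExtractionConfig,
    PairStatistics,
    Publication,
    TermDictionary,
    TermEntry,
    extract_markers,
    find_mentions,
    pair_zscore,
    related_pairs,
    resolve_pronouns,
)

MARKERS = [TermEntry("TP53", "marker", ("TP53",)),
           TermEntry("BRCA1", "marker", ("BRCA1",)),
           TermEntry("IL6", "marker", ("IL6",))]
DISEASES = [TermEntry("sarcoma", "disease", ("sarcoma",)),
            TermEntry("breast cancer", "disease", ("breast cancer",))]
DICT = TermDictionary(MARKERS + DISEASES)


def pub(pmid, *posts):
    return Publication(pmid, [load_post(p) for p in posts])


# ---------------------------------------------------------------------------
# mentions and pronouns

def test_longest_match_multiword_term():
    tree = load_post("(S (NP BRCA1) (VP drives (NP breast cancer) progression))")
    ids = [m.id for m in find_mentions(tree, DICT)]
    assert ids == ["BRCA1", "breast cancer"]


def test_pronoun_annotated_with_closest_preceding_clause_term():
    tree = load_post(
        "(POST (S (NP TP53) (VP is mutated)) , "
        "(S (WHNP which) (VP elevates risk of (NP sarcoma))))")
    resolved = resolve_pronouns(tree, DICT)
    pronoun = [l for l in resolved.leaves() if l.text == "which"][0]
    assert pronoun.antecedents == ("TP53",)
    # the antecedent becomes a co-occurring mention inside the second clause
    mentions = find_mentions(resolved, DICT)
    via = [m for m in mentions if m.via_pronoun]
    assert [(m.id, m.start) for m in via] == [("TP53", pronoun.start)]
    assert related_pairs(resolved, DICT) == {("TP53", "sarcoma")}


def test_pronoun_resolution_identity_without_pronouns():
    tree = load_post("(S (NP TP53) (VP suppresses (NP sarcoma)))")
    resolved = resolve_pronouns(tree, DICT)
    assert resolved.tokens() == tree.tokens()
    assert all(not l.antecedents for l in resolved.leaves())


def test_sentence_initial_pronoun_left_unannotated(caplog):
    tree = load_post("(S (NP It) (VP is unclear))")
    with caplog.at_level("WARNING"):
        resolved = resolve_pronouns(tree, DICT)
    assert all(not l.antecedents for l in resolved.leaves())
    assert "no predecessor" in caplog.text


# ---------------------------------------------------------------------------
# relatedness

def test_single_clause_pair_is_related():
    tree = load_post("(S (NP BRCA1) (VP is associated with (NP breast cancer)))")
    assert related_pairs(tree, DICT) == {("BRCA1", "breast cancer")}


def test_example_sentence_partition(worked):
    pairs = related_pairs(worked.sentence_tree, worked.dictionary)
    assert pairs == worked.expected_related
    assert not pairs & worked.expected_unrelated


def test_relatedness_needs_both_distinct_clauses_and_coordinator():
    # two clauses joined by a plain comma: still related
    tree = load_post("(POST (S (NP TP53) (VP is mutated)) , "
                     "(S (NP sarcoma) (VP progresses)))")
    assert related_pairs(tree, DICT) == {("TP53", "sarcoma")}


def test_removing_coordinator_grows_related_set():
    with_c = load_post("(POST (S (NP TP53) (VP is mutated)) , whereas "
                       "(S (NP sarcoma) (VP progresses)))")
    without = load_post("(POST (S (NP TP53) (VP is mutated)) , "
                        "(S (NP sarcoma) (VP progresses)))")
    assert related_pairs(with_c, DICT) <= related_pairs(without, DICT)
    assert related_pairs(with_c, DICT) == set()


def test_empty_dictionary_is_an_error():
    tree = load_post("(S (NP TP53))")
    with pytest.raises(ValueError):
        related_pairs(tree, TermDictionary([]))


def _oracle_related(tree, a, b):
    """Independent hand application of the preposition-modifier rule."""
    def innermost_ic(start, end):
        best = None
        for node in tree.root.walk():
            if (node.label == "independent-clause"
                    and node.start <= start and end <= node.end):
                if best is None or node.end - node.start <= best.end - best.start:
                    best = node
        return best

    ca, cb = innermost_ic(a.start, a.end), innermost_ic(b.start, b.end)
    if ca is None or cb is None or ca is cb:
        return True
    if not (ca.end <= cb.start or cb.end <= ca.start):
        return True
    lo = min(ca.end, cb.end)
    hi = max(ca.start, cb.start)
    toks = tree.tokens()[lo:hi]
    return not any(t.lower() in {"whereas", "while", "but"} for t in toks)


def test_related_pairs_match_mention_pair_oracle_on_generated_sentences():
    corpus, truth = gen_corpus(GeneratorConfig(seed=3, n_publications=5))
    dictionary = truth.dictionary
    trees = [resolve_pronouns(t, dictionary)
             for p in corpus for t in p.sentences][:20]
    assert len(trees) == 20
    for tree in trees:
        mentions = find_mentions(tree, dictionary)
        expected = set()
        for i, a in enumerate(mentions):
            for b in mentions[i + 1:]:
                if a.id != b.id and _oracle_related(tree, a, b):
                    expected.add(tuple(sorted((a.id, b.id))))
        assert related_pairs(tree, dictionary) == expected


def test_related_pairs_symmetry_and_generator_truth():
    corpus, truth = gen_corpus(GeneratorConfig(seed=5, n_publications=10))
    for p in corpus:
        for idx, tree in enumerate(p.sentences):
            resolved = resolve_pronouns(tree, truth.dictionary)
            pairs = related_pairs(resolved, truth.dictionary)
            assert all(a <= b for a, b in pairs)  # canonical unordered form
            assert pairs == set(truth.sentence_pairs[(p.pmid, idx)])


# ---------------------------------------------------------------------------
# z-score

def test_zscore_closed_form_values():
    base = dict(pair=("a", "b"), n_a=100, n_b=100, n_sentences=1000,
                n_docs_related=1)
    assert pair_zscore(PairStatistics(n_related=10, **base)) == pytest.approx(0.0)
    assert pair_zscore(PairStatistics(n_related=30, **base)) == pytest.approx(
        20 / math.sqrt(10 * 0.99))
    assert pair_zscore(PairStatistics(n_related=0, **base)) == pytest.approx(
        -10 / math.sqrt(10 * 0.99))


def test_zscore_rejects_zero_marginals():
    with pytest.raises(ValueError):
        pair_zscore(PairStatistics(("a", "b"), 0, 0, 5, 10, 0))


@settings(derandomize=True, max_examples=200)
@given(n=st.integers(2, 500), data=st.data())
def test_zscore_sign_matches_excess_over_expectation(n, data):
    n_a = data.draw(st.integers(1, n))
    n_b = data.draw(st.integers(1, n))
    n_rel = data.draw(st.integers(0, min(n_a, n_b)))
    stats = PairStatistics(("a", "b"), n_rel, n_a, n_b, n, 0)
    expected = n_a * n_b / n
    z = pair_zscore(stats)
    if n_a == n and n_b == n:
        assert z == 0.0  # degenerate p = 1
    else:
        assert (z > 0) == (n_rel > expected)
        assert (z < 0) == (n_rel < expected)


# ---------------------------------------------------------------------------
# corpus-level extraction

REL = "(S (NP {m}) (VP is associated with (NP {d})))"
BARE = "(S (NP {t}) (VP was measured))"
FILLER = "(S (NP the cohort) (VP was followed up))"


def _mini_corpus():
    pubs = []
    for i in range(6):
        posts = [REL.format(m="TP53", d="sarcoma"), BARE.format(t="BRCA1"),
                 FILLER]
        pubs.append(pub(f"p{i}", *posts))
    # background sentences without the disease
    pubs.append(pub("p6", BARE.format(t="IL6"), BARE.format(t="TP53")))
    return pubs


def test_extract_markers_reports_planted_pair_first():
    out = extract_markers(_mini_corpus(), DICT, "sarcoma",
                          ExtractionConfig(min_docs=3))
    assert [m for m, _ in out] == ["TP53"]
    stats = out[0][1]
    assert stats.n_related == 6 and stats.n_docs_related == 6
    assert stats.z >= 1.96


def test_extract_markers_document_support_boundary():
    # strongly related pair (z well above threshold) in only 2 documents
    pubs = [pub(f"p{i}", REL.format(m="TP53", d="sarcoma"),
                REL.format(m="TP53", d="sarcoma"),
                FILLER, FILLER, FILLER, FILLER)
            for i in range(2)]
    cfg = ExtractionConfig(min_docs=3)
    assert extract_markers(pubs, DICT, "sarcoma", cfg) == []
    cfg2 = ExtractionConfig(min_docs=2)
    assert [m for m, _ in extract_markers(pubs, DICT, "sarcoma", cfg2)] == ["TP53"]


def test_extract_markers_empty_without_disease_mentions():
    pubs = [pub("p0", BARE.format(t="TP53"))]
    assert extract_markers(pubs, DICT, "sarcoma", ExtractionConfig()) == []


def test_extract_markers_unknown_disease_errors():
    with pytest.raises(ValueError):
        extract_markers([], DICT, "nonexistent")
    with pytest.raises(ValueError):
        extract_markers([], DICT, "TP53")  # marker, not disease


def test_extract_markers_invariant_under_publication_order():
    pubs = _mini_corpus()
    cfg = ExtractionConfig(min_docs=2)
    forward = extract_markers(pubs, DICT, "sarcoma", cfg)
    backward = extract_markers(list(reversed(pubs)), DICT, "sarcoma", cfg)
    assert [(m, s.n_related, s.z) for m, s in forward] == \
           [(m, s.n_related, s.z) for m, s in backward]
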