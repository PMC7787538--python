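# Methods

This note records the models implemented in `sddp`, the conventions
chosen where the procedure admits more than one reading, and what the
synthetic study does and does not establish.

## Problem setting

A *traceable biomarker* (molecular marker, MM) is a measurable molecule
whose abnormal detection indicates disruption of a disease-associated
*molecular pathway* (MP). For a disease with pathway set S, an
individual's screening detects markers for only a subset S′ of
pathways. The system infers the undetected deficient pathways
S′′ ⊆ S − S′ from the hierarchy of pathway interrelationships, and
converts the combined combination S′ ∪ S′′ into a *risk indicator*: the
dominance rank of that combination among all pathway combinations,
scored by their co-occurrence support in the literature.

## Information extraction

Sentences are represented as Part-Of-Sentence Trees (POSTs): ordered
rooted trees over independent clauses, adverbial/conjoint clauses,
compound units, units, groups, and token leaves. Parsing is consumed,
not performed — the library ingests Penn-style bracketed parses (labels
map onto the POST kinds; unmappable labels collapse to `unit`) or falls
back to a deliberately simple clause splitter for raw text. This keeps
every test deterministic and the package free of model-sized NLP
dependencies.

Two strict relatedness rules are hardwired:

* **Pronoun rule.** Each pronoun (`whom, which, it, who, that`;
  configurable) is annotated with the *closest* dictionary terms of the
  nearest preceding independent clause (distance = tokens from term end
  to the pronoun; ties keep all). Annotated pronouns count as mentions
  of their antecedents, so a term linked through a pronoun co-occurs in
  the pronoun's clause. Pronouns without a resolvable antecedent are
  left alone and logged.
* **Preposition-modifier rule.** Mentions in two *distinct* independent
  clauses joined by a coordinator (`whereas, while, but`; configurable)
  are unrelated. "Joined by" is operationalised as: a coordinator token
  lies in the token gap between the two clause spans. Nested clauses are
  not distinct.

Additional exclusion rules plug in as predicates over (tree, mention,
mention); the shipped rule set is deliberately limited to the two above.

### Association statistic

For terms a, b with sentence counts n_a, n_b out of N corpus sentences,
the expected number of co-occurring sentences under independence is
E = n_a·n_b/N, and

    z = (n_related − E) / sqrt(E·(1 − p)),   p = E/N,

the one-sample binomial z-score against the independence expectation.
A marker–disease pair is reported when z ≥ z_min (default 1.96) **and**
its related co-occurrences span at least `min_docs` distinct
publications (default 3). Both thresholds are configurable; the
sentence is the default co-occurrence unit (`unit="abstract"` switches
to per-abstract bags). Output order is z descending, marker id
ascending, so results are invariant under publication order.

## Pathway modelling

A **Molecular Characteristic Tree (MCT)** is the single-parent
shortest-path spanning tree of the pathway-induced interaction
subnetwork, rooted at one marker: node depths equal breadth-first
distances from the root; where several neighbours preserve the shortest
path, the parent is drawn uniformly at random from the run's seed
(`deterministic=True` substitutes the lexicographically smallest for
bit-exact runs). Depth maps are therefore seed-independent; only parent
choices vary. One MCT per marker makes a pathway's forest; molecules
unreachable from every marker are excluded and logged.

The **MP Interrelationships Network (MPIN)** links two pathways
whenever their molecule sets intersect. The *hierarchical level* of a
molecule in a pathway is its minimum depth over that pathway's forest.
Conventions adopted where the construction is under-determined:

* **Lowest common molecule.** Among shared molecules reachable in both
  forests, the one minimising x̄ + ȳ (closest to both marker roots);
  ties go to the lexicographically smallest id. "Lowest" is read as
  *nearest the roots*; levels count from 0 at the root.
* **Direction.** x̄ < ȳ draws the arrow from y to x and makes x the
  more specific pathway; x̄ = ȳ (and the no-reachable-shared-molecule
  case) leaves the edge undirected, carrying no hierarchy claim.

## Rule composition and inference

Specification rules are propositional implications over pathway atoms.
From the MPIN, each arrow general → specific emits, under the default
**generalize** policy, the rule `specific → general`: a deficiency in
the specific pathway implies one in its more general relative, since
the shared molecule lies in both. This direction is a documented
package convention — hand-curated rule bases for a real disease may
encode either direction; `specialize` reverses it and `conjunctive`
adds `g1 ∧ … ∧ gk → s` for a specific pathway with several incoming
arrows. Rules can equally be loaded from a one-rule-per-line DSL
(`Ri: EXPR -> EXPR`, `& | !` at standard precedence, `∧ ∨ ¬ →`
aliases, `#` comments, errors with line and caret).

**Forward chaining.** The contract is classical entailment: given rule
base Σ and detected atoms D, the inferred set is
{a ∉ D : Σ ∪ D ⊨ a}. The engine saturates the CNF clause space
breadth-first with binary resolution under forward subsumption, which
is complete for unit consequences (subsumption theorem) and terminates
on the finite clause space; a derived empty clause flags the rule base
inconsistent (warning raised, every atom reported). Detected atoms
outside the rule base are carried through unchanged.

Every resolvent becomes a numbered trace step. Steps are named after
the classical rule they instantiate — modus ponens (unit satisfying a
whole single-atom antecedent), modus tollens, hypothetical syllogism
(implication chaining), disjunctive syllogism — with generic
"resolution" otherwise; clause forms of multi-clause rules enter as
steps justified by the source rule id. Clauses are rendered in
implication normal form (negative literals as a conjunctive antecedent)
for readability. `explain` extracts and renumbers the minimal
supporting sub-derivation of one inferred atom. The "addition" and
"conjunction" rule names never arise in machine traces: conjunctive
antecedents are discharged literal-by-literal at the clause level,
which keeps saturation finite without any ad-hoc restriction on
formula growth.

## Risk indicator

Combination weights: W[p][c] counts the sentences of publication p in
which at least one marker term of *every* member pathway of c occurs
and all such marker mentions are pairwise semantically related (the
extractor's rules, applied mention-by-mention). A precomputed weight
matrix can be loaded instead, which is how the packaged worked example
is driven. Combination universes are enumerated up to a configurable
size (default 3) or supplied explicitly.

Combination c_i beats c_j when W[·][i] > W[·][j] in more publications
than the reverse; only `>` comparisons are used, so any per-publication
strictly increasing reweighting leaves all outcomes unchanged. The
dominance score is beats minus losses (a Copeland-style score; the
beats matrix is antisymmetric and scores sum to zero), and the risk
indicator is the competition rank
rank_i = 1 + #{j : score_j > score_i} — tied scores share a rank and
the following ranks are skipped, the only scheme consistent with the
worked example's printed rank row.

## Synthetic study design

The generator emulates the system's literature input at desk scale.
Defaults (chosen once as a realistic small study, before any test was
run, and not revisited): 200 abstracts of 3–6 background sentences; a
24-marker / 2-disease vocabulary; 12 planted marker–disease pairs each
realised in a given abstract with probability 0.16 (≈2 planted
sentences per abstract); 20% of abstracts with planted content restate
one pair through a pronoun-linked clause pair; background sentences are
coordinator-split decoys with probability 0.25 (marker and disease in
opposite clauses — co-occurrence without relatedness), joint two-marker
restatements with probability 0.15, and otherwise noise sentences that
include a random marker with probability 0.4 and a random disease with
probability 0.3, *independently*, so unplanted pairs sit exactly at the
z-score null. Decoys inflate term marginals without adding related
counts, pushing unplanted markers below the null; planted pairs land at
z ≈ 4–7. Every sentence is emitted with its own POST bracketing, and
the per-sentence related-pair ground truth is recorded from the
construction, not recomputed.

On the network side, a G(n, p) interaction graph (60 nodes, edge
probability 0.15) carries the marker names on its first nodes so corpus
and pathway marker vocabularies coincide; pathways (4 × 10 molecules,
2 markers each) form a chain in which consecutive pathways share
round(0.3 × 10) = 3 molecules.

What passing the synthetic tests shows: the extraction rules, the
statistic, and every downstream stage behave correctly on inputs whose
ground truth is known exactly. What it does not show: performance on
real abstracts — real syntax is harder than the templates, dictionary
coverage is imperfect, and real co-occurrence violates independence in
both directions. The generator is a correctness instrument, not a
benchmark.

## Evaluation metrics

Precision = TP/(TP+FP), Recall = TP/(TP+FN),
F = 2·P·R/(P+R); undefined denominators yield 0.0 with the affected
metric named in an `undefined` flag rather than silently.

## Numerical and degenerate-input choices

* E is computed as `n_a*n_b/n` before deriving p, so the z-score is
  exactly 0 when n_related equals the expectation in integer cases.
* p = 1 (both terms in every sentence) makes the z denominator 0; the
  statistic returns 0 rather than dividing.
* Empty dictionaries, unknown disease/pathway/combination ids, markers
  missing from the network, and malformed files raise errors naming the
  offending entity, file, line and field.
* All writers are atomic: output appears under its final name only on
  success, otherwise a `.partial` file marks the aborted write.
* All randomness (MCT parent ties, generators) flows from explicit
  integer seeds; the pipeline manifest records the seed used.

## Known limitations

* Only the two strict rules above are hardwired; richer rule
  catalogues are domain-specific, and the plugin hook exists precisely
  so users can register their own exclusion rules without the package
  guessing their content.
* The MPIN→rules direction and the "lowest common molecule" tie-breaks
  are documented conventions of this package (see above); other
  hierarchy readings are defensible.
* The combination-weight counting rule (joint related sentence counts)
  is the package's definition consistent with the extractor's
  semantics; the worked example is reproduced from its printed weight
  matrix, which bypasses that definition.
* Trace step names describe resolution instances; a human-written proof
  might choose different (equally valid) classical rule applications.
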