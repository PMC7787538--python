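# sddp — Susceptibility Degree to a Disease Predictor

`sddp` estimates an individual's degree of future susceptibility to a
disease from the few molecular pathways their screening has actually
flagged. It is written for computational biologists working at the
interface of literature mining and pathway analysis, and it chains four
stages:

1. **Information extraction.** Marker–disease associations are mined
   from abstracts under *strict* sentence-structure rules: sentences
   are constituent trees (POSTs), pronouns are replaced by the closest
   terms of the preceding independent clause, and term pairs split
   across independent clauses joined by *whereas/while/but* are
   discarded. Surviving pair counts are filtered by a binomial z-score
   against the independence expectation,
   `z = (n_related − E)/√(E(1−p))` with `E = n_a·n_b/N`, plus a
   minimum-document-support cut.
2. **Pathway modelling.** Each pathway's interaction subnetwork is
   collapsed into Molecular Characteristic Trees (MCTs) — single-parent
   shortest-path trees rooted at the pathway's markers — and pathways
   sharing molecules are wired into the MP Interrelationships Network
   (MPIN), whose arrows point from general to more specific pathways
   according to the level of the lowest common molecule.
3. **Logic inference.** The MPIN hierarchy (or a user rule file) is
   compiled to propositional specification rules; forward chaining by
   breadth-first resolution derives every pathway entailed by the
   individual's detected pathways, with a numbered proof trace (modus
   ponens, modus tollens, hypothetical syllogism, …) for each
   inferred pathway.
4. **Risk indicator.** Pathway combinations are scored by pairwise
   dominance over per-publication co-occurrence weights — `c_i` beats
   `c_j` if it out-weighs it in more publications — a Copeland-style
   score (beats − losses), and the individual's combination receives
   its competition rank (ties share a rank; following ranks skip) as
   the risk indicator.

A seed-reproducible synthetic-data module generates corpora, networks
and pathway sets with exact ground truth, so the whole pipeline is
testable without any downloads.

## Worked example

The packaged fixtures carry the two in-text worked examples: the
two-clause sentence and the 3-publication × 10-combination
co-occurrence weight matrix.

```python
from sddp import (load_worked_examples, related_pairs,
                  dominance_scores, risk_indicator)

ex = load_worked_examples()
print(sorted(related_pairs(ex.sentence_tree, ex.dictionary)))
res = dominance_scores(ex.weights)
for cid, s, r in zip(res.combinations, res.scores, res.ranks):
    print(f"{cid:>4}  score {int(s):+d}  rank {int(r)}")
print("risk indicator for c9:", risk_indicator(res, "c9"))
```

prints

```
[('5-HIT', 'G1287A'), ('5-HIT', 'OCD'), ('G1287A', 'OCD'), ('SLC6A2', 'SLC6A4')]
  c1  score +0  rank 5
  c2  score +1  rank 4
  c3  score +8  rank 1
  c4  score -6  rank 9
  c5  score -1  rank 6
  c6  score -1  rank 6
  c7  score -6  rank 9
  c8  score +4  rank 2
  c9  score +3  rank 3
 c10  score -2  rank 8
risk indicator for c9: 3
```

Reading it: in the example sentence the four within-clause term pairs
are related while all six pairs straddling the "whereas" are excluded;
on the weight matrix, combination c3 dominates every comparison it can
win (score +8, rank 1), the two combinations tied at −1 share rank 6 so
the next score lands at rank 8, and an individual whose inferred
pathway combination is c9 gets risk indicator 3.

## Command line

Every stage is also a subcommand of `sddp`:

```sh
sddp simulate corpus  --seed 1 --out data/   # synthetic abstracts + dictionary
sddp simulate network --seed 1 --out data/   # interaction net + pathways + detected markers
sddp extract --corpus data/corpus.jsonl --dict data/dictionary.tsv \
             --disease DIS01 --z-min 1.96 --min-docs 3 --out assoc.tsv
sddp build-mpin --network data/network.sif --pathways data/pathways.tsv \
             --seed 1 --out mpin.tsv
sddp rules --mpin mpin.tsv --policy generalize --out rules.rules
sddp infer --rules rules.rules --detected pathways.txt --out inference.json
sddp rank --weights weights.tsv --out ranking.tsv
sddp indicate --rank ranking.tsv --combination c9
sddp run-all --config pipeline.cfg          # all seven stages + manifest
```

Formats are plain text throughout: JSONL or MEDLINE corpora, 4-column
TSV dictionaries, SIF/TSV networks, TSV pathway membership, a small
rule DSL (`R1: MP_A & MP_B -> MP_C`), and TSV weight matrices.

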