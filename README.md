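# medcat-discovery

Category discovery in POS-tagged biomedical corpora.

Large literature databases discuss far more kinds of entities — infections,
inhibitors, receptors, assays — than any manually curated ontology keeps up
with. This package implements two independent, corpus-driven routes to
candidate *semantic categories* (nouns that name a class of things), plus
the machinery to compare their outputs:

1. **A statistical headword filter.** Normalize every noun (lowercase,
   singularize) and keep a noun *w* when it is (i) tagged as a noun in more
   than *D* distinct documents, (ii) a *stand-alone* noun — not adjacent to
   another noun or adjective, a determiner being permitted — in at least
   *S* documents, and (iii) the headword of at least *H* distinct multiword
   phrases from a curated lexicon. Raising *H* through 10/50/100 gives a
   nested family of noun sets (the FHN-style sets).

2. **Alignment-based hypernym pattern induction.** Starting from
   narrower/broader seed term pairs (UMLS-style), every sentence containing
   a pair becomes a template `w_1 … w_k X w_l … w_m Y w_n … w_r` with the
   first-occurring term replaced by `X` and the second by `Y`. Templates
   are embedded as multisets of ordered word-pair features; each induction
   round samples a query template, ranks the whole collection by cosine
   similarity, cuts the ranking at the largest score drop-off
   `N = argmax_{50 ≤ i < 300} [Score(i) − Score(i+1)]` (rejecting the query
   when the drop-off is below 0.01), samples five templates from the bottom
   half of the retained set, keeps the word-order features present in more
   than 80 % of the retained set, strips each sampled template to the
   surviving tokens, and takes the column consensus of a token-level
   progressive multiple sequence alignment. Rounds emit patterns such as
   `X and other Y`; repeated rounds rank patterns by how often they are
   generated.

Induced (or curated, 40 ship with the package) patterns are then **matched
against the corpus**: wherever the literal tokens occur flanked by noun
phrases, the X-side phrase is harvested as an instance and the Y-side
phrase as a category (roles reverse for `such as`). Grouping by the
normalized category headword yields categories with subcategory phrases,
instances, and support counts. Finally, the **overlap** of the two noun
sets is scored with a one-sided hypergeometric tail in log space:
`−log10 P[X ≥ k]` for intersection *k* over an explicit universe.

A seeded synthetic-corpus generator with planted patterns and categories
makes the whole pipeline testable end to end without any external data.

## Worked example

```python
from medcat.corpus_io import parse_pattern
from medcat.pattern_application import harvest_matches, aggregate
from medcat.pattern_induction import (
    make_templates, reduce_template, align_and_consensus,
)
from medcat.synthetic_fixtures import (
    table2_fixture, WORKED_EXAMPLE_FEATURES, propranolol_fixture,
)

# pattern induction, end game: five retrieved sentences -> one pattern
sentences, pairs = table2_fixture()
reduced = [
    reduce_template(make_templates(s, [p])[0], WORKED_EXAMPLE_FEATURES)
    for s, p in zip(sentences, pairs)
]
print(align_and_consensus(reduced))     # X and other Y

# pattern application on one sentence
(match,) = harvest_matches([propranolol_fixture()],
                           [parse_pattern("X and other Y")])
print(match.instance, "|", match.category_phrase, "|", match.category_headword)
# propranolol | beta blockers | blocker
```

The first block reproduces the induction endgame: five sentences like
*"Effects of anticoagulants and other drugs."* all reduce to
`X and other Y` once only the high-frequency word-order features
(`X and; X other; and other; and Y; other Y`) are kept, and the alignment
consensus returns that pattern. The second block shows application: in
*"The unique action of propranolol and other beta blockers …"* the pattern
identifies *beta blockers* as a candidate category (headword *blocker*
after normalization) with *propranolol* as an instance.

The command-line interface exposes the same pipeline as `medcat stat`,
`medcat induce`, `medcat apply`, `medcat compare` and `medcat synth`; every
run writes a manifest JSON (inputs, digests, seed, counters) beside its
output.

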