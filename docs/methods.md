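# Methods

This note documents the models and procedures the package implements, the
parameters that matter, the numerical choices made where the published
procedure leaves room, and what the synthetic-data tests do and do not
demonstrate.

## Corpus model

The unit of input is a POS-tagged sentence: one sentence per line,
whitespace-separated `surface/TAG` tokens. The **last** slash separates
surface from tag, so surfaces containing `/` survive. Tags are opaque
strings; downstream logic only consults three *tag classes* — noun-like,
adjective-like, determiner-like — through a configurable prefix table whose
defaults follow the MedPost tagset (`NN*`, `JJ*`, `DD`/`DB`). All matching
is case-insensitive after lowercasing; original surfaces are kept for
reporting. Document identity is taken as given (an optional
`doc_id<TAB>…` line dialect); the package does not decide what a
"document" is.

Noun normalization is a deterministic rule cascade — an
irregular/invariant table of ~70 forms biased toward Greek/Latin biomedical
plurals (analyses→analysis, bacteria→bacterium, viruses→virus,
species→species), then `-ies→-y`, a guarded `-es` strip, and a final `-s`
strip with `-ss/-us/-is` guards. It is idempotent and auditable; it is not
a lemmatizer, and unknown irregulars pass through lowercased. This is a
deliberate trade of coverage for reproducibility.

## Statistical category extraction

A noun is a candidate category when all three hold:

1. tagged as a noun in **more than** `min_doc_freq` distinct documents
   (strict inequality; default 10,000 — the scale of a full literature
   database);
2. **stand-alone** — neither neighbour is a noun or adjective; a preceding
   determiner is explicitly fine, and punctuation or anything non-nominal
   does not block — in **at least** `min_standalone_doc_freq` documents
   (default 1,000);
3. the headword (final non-determiner token, normalized) of **at least**
   `min_headword_phrases` distinct phrases of a curated multiword lexicon
   (defaults 10/50/100 give the nested set family).

Counting is per distinct document, never per token occurrence. The filter
is antitone in every threshold, which the test suite checks as a property
(the 100/50/100 sets nest).

## Pattern induction

Templates, features and the retrieval loop are described in the README.
Choices the published procedure leaves open, and what this package does:

- **Feature weights.** Features are counted (multiset) and cosine is taken
  over raw counts. Binary weighting is a one-line change but counts are
  the simplest scheme consistent with cosine ranking.
- **Within-segment pairs.** Ordered pairs are taken with `i < j` in every
  segment (prefix, mid, suffix); self-pairs are excluded. This matches the
  worked example, where the mid segment `and other` contributes exactly
  `and other` and no `and and` / `other other`.
- **The query stays in the ranking**, at rank 1 with score 1, so the
  retained set R always contains the query's own structure.
- **Drop-off cut.** `N = argmax_{50 ≤ i < 300} Δ_i`, `Δ_i = Score(i) −
  Score(i+1)` over 1-based ranks, ties to the smallest rank; the query is
  rejected when `Δ_N < 0.01` and a rejection does not consume an
  iteration (a cap of `100 × iterations` rejections turns a degenerate
  score landscape into an error instead of a livelock). Ranking uses a
  stable sort so tied scores order deterministically.
- **Sampling ranks** are `floor(jN/10)` for `j ∈ {5,…,9}` (1-based), which
  stays within the bottom half of R for every `N ≥ 50`.
- **Feature filter.** "Relative frequency above 0.8" is strict (>),
  computed as *presence* over all N templates of R; the orientation
  feature is always dropped.
- **Alignment.** Tokens are aligned with Needleman–Wunsch (match +1,
  mismatch −1, gap −1, all configurable) and a progressive MSA: seed with
  the most similar pair, then greedily add the remaining sequence most
  similar to any aligned one; sequence-to-group scoring counts a column as
  a match when *any* non-gap member equals the token. Consensus keeps
  columns where at least `consensus_min` (default 1.0, i.e. unanimity —
  consistent with the worked example) of all sequences carry the identical
  token, gaps counting against. A consensus that is not a well-formed
  pattern (one X, one Y, X first) is discarded for that round.
- **Multiple seed-pair occurrences** in one sentence each contribute their
  own template (every non-overlapping occurrence combination); one
  template contributes one vector.

`induce()` is fully reproducible given `rng_seed` and returns unique
patterns sorted by times generated, then lexicographically.

## Pattern application

Noun phrases follow the regular grammar `determiner? (adjective|noun)*
noun` over tag classes, chunked greedily left-to-right (trailing
adjectives are excluded; the span ends at its last noun). A pattern
matches where its literal tokens occur contiguously with an NP immediately
left-adjacent at X (maximal span ending there) and an NP immediately
right-adjacent at Y (maximal span starting there). Only the adjacent
conjunct is captured — `A, B, and other Y` contributes only B — a known
fidelity limit. Determiners are stripped from reported NP text; adjectival
modifiers are retained because they define subcategories (*viral*
infections). For every pattern except `such as` the X-side NP is the
instance and the Y-side NP the category; `such as` swaps the roles
(categories *such as* instances). Support counts matches (a sentence
matching twice counts twice). Aggregation groups by normalized category
headword so *infections*/*infection* merge, and orders records by support
then headword for determinism.

## Overlap significance

`overlap()` reports the intersection count, the percentage of A found in B
(rounded half-up to the nearest integer), and `−log10` of the one-sided
hypergeometric upper tail `P[X ≥ k]` for drawing `|A|` items from a
universe containing `|B|` marked items, evaluated via `scipy`'s log-space
survival function so tails far below float underflow remain finite. The
universe size is a **required** argument: the published analysis this
mirrors does not state its universe, so the package never defaults one
silently, and the package makes no claim of reproducing any published
`−log10 p` values — only the percentage arithmetic is checked.

## Synthetic data: what it emulates and what it does not

The generator emits documents of tagged sentences in three kinds:
*pattern sentences* (a planted pattern instantiated around a sampled
instance/category pair, with 0–3 non-nominal noise tokens on each side),
*stand-alone sentences* (`the <category> <verb> …`), and *noise sentences*
(4–8 words from a 300-word Zipf-weighted pseudo-word vocabulary with mixed
noun/adjective/verb tags). Defaults, chosen once as the study conditions
for all tests: 1,000 documents × 5 sentences; pattern-sentence fraction
0.5; planted patterns `X is a Y` and `X such as Y` with equal weight
(≈1,250 supporting sentences each); 6 categories × 12 instances × 8
modifiers; modifier probability 0.5; sentence-final period probability
0.5. The period probability is deliberately below 1: sentence-final
punctuation after Y is a word-order feature like any other, and a corpus
in which *every* template carries `(Y, .)` would legitimately pull the
period into every induced pattern; mixed title-style lines (the
worked-example fixtures themselves include one) keep that feature below
the 0.8 filter. `such as` sentences use the plural category surface and
the seed-pair list includes both singular and plural broader terms,
exercising normalization at the application stage.

The ground-truth ledger (triples, per-pattern and per-headword support,
per-noun document statistics) is recorded at emission time and the test
suite verifies it equals an independent recount of the emitted corpus.
Recovery tests (both planted patterns within 200 accepted rounds;
harvested categories exactly the planted headwords at support ≥ 50;
statistical categories exactly the planted ones at thresholds 50/20/3,
calibrated to the generator's scale) run at 5,000 sentences over three
seeds.

What passing does **not** show: real corpora have richer syntax (relative
clauses, coordination, abbreviations), tagger errors, and far heavier-tailed
template similarity landscapes; the drop-off cut and the 0.8 filter are
exercised here on a clean cluster structure, so recovery on synthetic data
is a correctness check of the machinery, not an estimate of precision or
recall on real text. Absolute published counts (thousands of qualifying
nouns, 850 raw induced patterns) require the full database and are out of
scope by design.

## Problem sizes

Tests and the acceptance script use 5,000-sentence corpora (≈2,500
templates), 200 accepted induction rounds, and three seeds — sizes at
which every stage's behaviour is already asymptotic in the properties
checked (cluster structure above the 300-rank window, supports an order of
magnitude above thresholds) while the full suite runs in seconds.
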