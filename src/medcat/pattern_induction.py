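"""Alignment-based induction of hypernymy patterns.

Given a tagged corpus and a list of narrower/broader seed pairs, every
sentence containing both terms of a pair is turned into a *template*: the
first-occurring term becomes the placeholder X, the second Y, and the
remaining words split into a prefix (before X), a mid segment (between X and
Y) and a suffix (after Y).  Each template is represented by a sparse vector
of ordered word-pair features, and repeated rounds of

    sample a query template -> rank all templates by cosine similarity ->
    cut the ranking at the largest score drop-off within ranks [n_min, n_max)
    -> sample 5 templates from the bottom half of the retained set ->
    keep features shared by > 80% of the retained set -> strip each of the 5
    templates down to tokens participating in a kept feature -> token-level
    progressive multiple sequence alignment -> column consensus

emit candidate patterns such as ``X and other Y``.  Patterns are
deduplicated and ranked by how often the procedure generated them.

Feature weights are raw occurrence counts and the query's own vector stays
in the ranking (rank 1, score 1); both choices are configurable.
"""

from __future__ import annotations

import random
from collections import Counter
from dataclasses import dataclass, field
from math import floor, sqrt
from typing import Iterable, Sequence

import numpy as np
from scipy import sparse

from medcat.corpus_io import (
    PLACEHOLDER_X,
    PLACEHOLDER_Y,
    Pattern,
    SeedPair,
    TaggedSentence,
)

__all__ = [
    "ORIENT_NARROWER_FIRST",
    "ORIENT_BROADER_FIRST",
    "TemplateSentence",
    "FeatureVector",
    "RetrievalResult",
    "InductionConfig",
    "make_templates",
    "templates_from_corpus",
    "extract_features",
    "cosine",
    "TemplateIndex",
    "rank_and_cut",
    "sample_ranks",
    "select_sample",
    "filter_features",
    "reduce_template",
    "align_pair",
    "align_and_consensus",
    "induce",
    "InductionError",
]

# orientation labels: which member of the seed pair occurs first (= becomes X)
ORIENT_NARROWER_FIRST = "NX_BY"
ORIENT_BROADER_FIRST = "BX_NY"


class InductionError(RuntimeError):
    pass


@dataclass
class TemplateSentence:
    """A sentence with one seed-pair occurrence replaced by X and Y.

    Tokens are lowercased surfaces.  ``prefix + [X] + mid + [Y] + suffix``
    reproduces the source sentence with the pair's terms excised.
    """

    prefix: tuple[str, ...]
    mid: tuple[str, ...]
    suffix: tuple[str, ...]
    orientation: str
    source_sentence_id: str = ""
    source_pair: SeedPair | None = None

    def full_tokens(self) -> list[str]:
        return [
            *self.prefix,
            PLACEHOLDER_X,
            *self.mid,
            PLACEHOLDER_Y,
            *self.suffix,
        ]


@dataclass
class FeatureVector:
    """Multiset of ordered-pair features with its Euclidean norm."""

    counts: dict[tuple[str, str], int]
    norm: float = field(init=False)

    def __post_init__(self) -> None:
        self.norm = sqrt(sum(c * c for c in self.counts.values()))


@dataclass
class RetrievalResult:
    """A ranked retrieval with its drop-off cut.

    ``order[r]`` is the collection index at 1-based rank ``r + 1``;
    ``scores`` is sorted non-increasing; ``deltas[i]`` is
    Score(i+1) - Score(i+2).  ``n_cut`` is the accepted depth N.
    """

    order: np.ndarray
    scores: np.ndarray
    n_cut: int

    @property
    def top_indices(self) -> np.ndarray:
        """Collection indices of the retained set R (top N)."""
        return self.order[: self.n_cut]

    @property
    def deltas(self) -> np.ndarray:
        return self.scores[:-1] - self.scores[1:]


@dataclass(frozen=True)
class InductionConfig:
    n_min: int = 50
    n_max: int = 300  # exclusive upper bound on the cut rank
    drop_off_min: float = 0.01
    feature_rel_freq: float = 0.8
    iterations: int = 5_000
    rng_seed: int = 0
    msa_match: float = 1.0
    msa_mismatch: float = -1.0
    msa_gap: float = -1.0
    consensus_min: float = 1.0
    max_rejections_factor: int = 100

    def __post_init__(self) -> None:
        if not 0 < self.feature_rel_freq <= 1:
            raise ValueError("feature_rel_freq must be in (0, 1]")
        if self.n_min >= self.n_max:
            raise ValueError("n_min must be < n_max")
        if self.n_min < 10:
            raise ValueError("n_min must be >= 10 (5 sample ranks need N/10 >= 1)")


# ---------------------------------------------------------------------------
# templating


def _find_occurrences(haystack: Sequence[str], needle: Sequence[str]) -> list[tuple[int, int]]:
    """All (start, end) spans where ``needle`` occurs as a contiguous
    subsequence of ``haystack``."""
    n = len(needle)
    if n == 0:
        return []
    return [
        (i, i + n)
        for i in range(len(haystack) - n + 1)
        if list(haystack[i : i + n]) == list(needle)
    ]


def make_templates(
    sentence: TaggedSentence, pairs: Iterable[SeedPair]
) -> list[TemplateSentence]:
    """All templates a sentence yields for the given seed pairs.

    Both terms must occur as contiguous token subsequences
    (case-insensitive).  Every non-overlapping combination of one
    narrower-term occurrence and one broader-term occurrence yields one
    template; X always marks the first-occurring term.
    """
    words = sentence.lower_surfaces()
    templates: list[TemplateSentence] = []
    for pair in pairs:
        n_occ = _find_occurrences(words, pair.narrower.split())
        if not n_occ:
            continue
        b_occ = _find_occurrences(words, pair.broader.split())
        for ns, ne in n_occ:
            for bs, be in b_occ:
                if ne <= bs:  # narrower first
                    x_span, y_span = (ns, ne), (bs, be)
                    orientation = ORIENT_NARROWER_FIRST
                elif be <= ns:  # broader first
                    x_span, y_span = (bs, be), (ns, ne)
                    orientation = ORIENT_BROADER_FIRST
                else:  # overlapping occurrences
                    continue
                templates.append(
                    TemplateSentence(
                        prefix=tuple(words[: x_span[0]]),
                        mid=tuple(words[x_span[1] : y_span[0]]),
                        suffix=tuple(words[y_span[1] :]),
                        orientation=orientation,
                        source_sentence_id=sentence.sentence_id,
                        source_pair=pair,
                    )
                )
    return templates


def templates_from_corpus(
    corpus: Iterable[TaggedSentence], pairs: Sequence[SeedPair]
) -> list[TemplateSentence]:
    """Collect templates for the whole corpus, indexing pairs by their first
    narrower word to avoid scanning every pair against every sentence."""
    by_first_word: dict[str, list[SeedPair]] = {}
    for pair in pairs:
        by_first_word.setdefault(pair.narrower.split()[0], []).append(pair)
    templates: list[TemplateSentence] = []
    for sentence in corpus:
        candidates: list[SeedPair] = []
        seen: set[SeedPair] = set()
        for word in set(sentence.lower_surfaces()):
            for pair in by_first_word.get(word, ()):
                if pair not in seen:
                    seen.add(pair)
                    candidates.append(pair)
        if candidates:
            templates.extend(make_templates(sentence, candidates))
    return templates


# ---------------------------------------------------------------------------
# features


def extract_features(template: TemplateSentence) -> FeatureVector:
    """Ordered-pair features of a template (a counted multiset):

    - word pairs (w_i, w_j), i < j, within the prefix, within the mid
      segment, and within the suffix;
    - (w_i, X) for prefix words; (X, w_i) and (w_i, Y) for mid words;
      (Y, w_i) for suffix words;
    - one orientation feature (NX, BY) or (BX, NY).
    """
    counts: Counter[tuple[str, str]] = Counter()
    for seg in (template.prefix, template.mid, template.suffix):
        for i in range(len(seg)):
            for j in range(i + 1, len(seg)):
                counts[(seg[i], seg[j])] += 1
    for w in template.prefix:
        counts[(w, PLACEHOLDER_X)] += 1
    for w in template.mid:
        counts[(PLACEHOLDER_X, w)] += 1
        counts[(w, PLACEHOLDER_Y)] += 1
    for w in template.suffix:
        counts[(PLACEHOLDER_Y, w)] += 1
    if template.orientation == ORIENT_NARROWER_FIRST:
        counts[("NX", "BY")] += 1
    else:
        counts[("BX", "NY")] += 1
    return FeatureVector(counts=dict(counts))


_ORIENTATION_FEATURES = frozenset({("NX", "BY"), ("BX", "NY")})


def cosine(v1: FeatureVector, v2: FeatureVector) -> float:
    """Cosine similarity between two feature multisets."""
    if v1.norm == 0 or v2.norm == 0:
        raise ValueError("cosine undefined for zero-norm feature vector")
    if len(v2.counts) < len(v1.counts):
        v1, v2 = v2, v1
    dot = sum(c * v2.counts.get(f, 0) for f, c in v1.counts.items())
    return dot / (v1.norm * v2.norm)


class TemplateIndex:
    """Sparse row-normalized feature matrix over a template collection, for
    fast cosine ranking of every template against a query."""

    def __init__(self, vectors: Sequence[FeatureVector]):
        self.vectors = list(vectors)
        vocab: dict[tuple[str, str], int] = {}
        rows, cols, data = [], [], []
        for r, vec in enumerate(self.vectors):
            for feat, count in vec.counts.items():
                c = vocab.setdefault(feat, len(vocab))
                rows.append(r)
                cols.append(c)
                data.append(float(count))
        self.vocab = vocab
        matrix = sparse.csr_matrix(
            (data, (rows, cols)), shape=(len(self.vectors), max(len(vocab), 1))
        )
        norms = np.sqrt(np.asarray(matrix.multiply(matrix).sum(axis=1)).ravel())
        norms[norms == 0] = 1.0
        self.matrix = sparse.diags(1.0 / norms) @ matrix

    def scores_for(self, query_index: int) -> np.ndarray:
        return self.matrix @ self.matrix[query_index].T.toarray().ravel()

    def scores_for_vector(self, query: FeatureVector) -> np.ndarray:
        if query.norm == 0:
            raise ValueError("cosine undefined for zero-norm feature vector")
        col = np.zeros(self.matrix.shape[1])
        for feat, count in query.counts.items():
            c = self.vocab.get(feat)
            if c is not None:
                col[c] = count / query.norm
        return self.matrix @ col


def _cut_ranking(scores_sorted: np.ndarray, config: InductionConfig) -> int | None:
    """The drop-off cut N = argmax_{n_min <= i < n_max} Score(i)-Score(i+1)
    (1-based ranks, ties to the smallest i), or None when the largest gap is
    below ``drop_off_min`` (reject the query)."""
    i = np.arange(config.n_min, config.n_max)  # candidate 1-based ranks
    deltas = scores_sorted[i - 1] - scores_sorted[i]
    best = int(np.argmax(deltas))  # np.argmax takes the first maximum
    if deltas[best] < config.drop_off_min:
        return None
    return config.n_min + best


def rank_and_cut(
    query: FeatureVector | int,
    collection: Sequence[FeatureVector],
    config: InductionConfig,
    *,
    index: TemplateIndex | None = None,
) -> RetrievalResult | None:
    """Rank the collection by cosine to the query and cut at the largest
    drop-off within ranks [n_min, n_max).

    ``query`` is either a FeatureVector or an index into the collection (the
    query's own vector then occupies rank 1 with score 1).  Returns None
    when the query is rejected (no drop-off >= ``drop_off_min``).
    """
    if len(collection) < config.n_max:
        raise ValueError(
            f"collection of {len(collection)} templates is smaller than "
            f"n_max={config.n_max}; the drop-off range cannot be evaluated"
        )
    if index is None:
        index = TemplateIndex(collection)
    if isinstance(query, (int, np.integer)):
        scores = index.scores_for(int(query))
    else:
        scores = index.scores_for_vector(query)
    # stable sort for determinism under tied scores
    order = np.argsort(-scores, kind="stable")
    scores_sorted = scores[order]
    n_cut = _cut_ranking(scores_sorted, config)
    if n_cut is None:
        return None
    return RetrievalResult(order=order, scores=scores_sorted, n_cut=n_cut)


def sample_ranks(n_cut: int) -> list[int]:
    """The five 1-based ranks floor(j*N/10), j in 5..9, spread over the
    bottom half of the retained set."""
    return [floor(j * n_cut / 10) for j in range(5, 10)]


def select_sample(result: RetrievalResult) -> list[int]:
    """Collection indices of the five sampled templates."""
    return [int(result.order[r - 1]) for r in sample_ranks(result.n_cut)]


def filter_features(
    vectors: Sequence[FeatureVector], rel_freq: float = 0.8
) -> set[tuple[str, str]]:
    """Word-order features present in strictly more than ``rel_freq`` of the
    retained templates.  Orientation features are always dropped."""
    presence: Counter[tuple[str, str]] = Counter()
    for vec in vectors:
        presence.update(set(vec.counts))
    n = len(vectors)
    return {
        feat
        for feat, k in presence.items()
        if feat not in _ORIENTATION_FEATURES and k / n > rel_freq
    }


def reduce_template(
    template: TemplateSentence, selected: set[tuple[str, str]]
) -> list[str]:
    """Strip a template to X, Y and the words occurring in at least one
    selected feature, preserving order."""
    keep = {w for feat in selected for w in feat}
    out: list[str] = []
    for tok in template.full_tokens():
        if tok in (PLACEHOLDER_X, PLACEHOLDER_Y) or tok in keep:
            out.append(tok)
    return out


# ---------------------------------------------------------------------------
# token-level multiple sequence alignment

GAP = None  # gap marker inside alignment columns


def align_pair(
    a: Sequence[str],
    b: Sequence[str],
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -1.0,
) -> float:
    """Needleman-Wunsch global alignment score over token sequences."""
    la, lb = len(a), len(b)
    prev = [j * gap for j in range(lb + 1)]
    for i in range(1, la + 1):
        cur = [i * gap] + [0.0] * lb
        for j in range(1, lb + 1):
            sub = match if a[i - 1] == b[j - 1] else mismatch
            cur[j] = max(prev[j - 1] + sub, prev[j] + gap, cur[j - 1] + gap)
        prev = cur
    return prev[lb]


def _align_seq_to_group(
    group: list[list[str | None]],
    seq: Sequence[str],
    match: float,
    mismatch: float,
    gap: float,
) -> list[list[str | None]]:
    """Globally align one sequence to an aligned group of columns.  A column
    matches a token when any non-gap member equals it."""
    cols = list(zip(*group)) if group else []
    lc, ls = len(cols), len(seq)
    score = np.empty((lc + 1, ls + 1))
    move = np.zeros((lc + 1, ls + 1), dtype=np.int8)  # 0 diag, 1 up, 2 left
    score[:, 0] = np.arange(lc + 1) * gap
    score[0, :] = np.arange(ls + 1) * gap
    move[1:, 0] = 1
    move[0, 1:] = 2
    for i in range(1, lc + 1):
        col = cols[i - 1]
        for j in range(1, ls + 1):
            sub = match if any(m == seq[j - 1] for m in col if m is not None) else mismatch
            best = score[i - 1, j - 1] + sub
            mv = 0
            up = score[i - 1, j] + gap
            if up > best:
                best, mv = up, 1
            left = score[i, j - 1] + gap
            if left > best:
                best, mv = left, 2
            score[i, j] = best
            move[i, j] = mv
    # traceback
    k = len(group)
    new_rows: list[list[str | None]] = [[] for _ in range(k + 1)]
    i, j = lc, ls
    while i > 0 or j > 0:
        mv = move[i, j]
        if mv == 0:
            for r in range(k):
                new_rows[r].append(group[r][i - 1])
            new_rows[k].append(seq[j - 1])
            i, j = i - 1, j - 1
        elif mv == 1:
            for r in range(k):
                new_rows[r].append(group[r][i - 1])
            new_rows[k].append(GAP)
            i -= 1
        else:
            for r in range(k):
                new_rows[r].append(GAP)
            new_rows[k].append(seq[j - 1])
            j -= 1
    return [row[::-1] for row in new_rows]


def align_and_consensus(
    sequences: Sequence[Sequence[str]], config: InductionConfig | None = None
) -> Pattern | None:
    """Progressive token MSA followed by column consensus.

    Sequences join the alignment in order of decreasing pairwise similarity
    (Clustal-style guide heuristic).  The consensus keeps columns where at
    least ``consensus_min`` of all sequences carry the identical token
    (gaps count against).  Returns None when the consensus is not a valid
    pattern (missing X or Y, duplicates, or Y before X).
    """
    if config is None:
        config = InductionConfig()
    seqs = [list(s) for s in sequences]
    if len(seqs) < 2:
        raise ValueError("alignment needs at least 2 sequences")
    if any(not s for s in seqs):
        raise ValueError("alignment sequences must be non-empty")

    m, mm, g = config.msa_match, config.msa_mismatch, config.msa_gap
    n = len(seqs)
    pair_scores = {
        (i, j): align_pair(seqs[i], seqs[j], m, mm, g)
        for i in range(n)
        for j in range(i + 1, n)
    }
    # seed the group with the most similar pair, then greedily add the
    # remaining sequence most similar to any aligned one
    (i0, j0), _ = max(pair_scores.items(), key=lambda kv: (kv[1], (-kv[0][0], -kv[0][1])))
    group = _align_seq_to_group([[t for t in seqs[i0]]], seqs[j0], m, mm, g)
    aligned = [i0, j0]
    remaining = [i for i in range(n) if i not in aligned]
    while remaining:
        def affinity(i: int) -> float:
            return max(
                pair_scores[(min(i, a), max(i, a))] for a in aligned
            )
        nxt = max(remaining, key=lambda i: (affinity(i), -i))
        group = _align_seq_to_group(group, seqs[nxt], m, mm, g)
        aligned.append(nxt)
        remaining.remove(nxt)

    consensus: list[str] = []
    for col in zip(*group):
        tokens = [t for t in col if t is not GAP]
        if not tokens:
            continue
        top, k = Counter(tokens).most_common(1)[0]
        if k / n >= config.consensus_min:
            consensus.append(top)
    try:
        return Pattern(tokens=tuple(consensus))
    except ValueError:
        return None


# ---------------------------------------------------------------------------
# the induction loop


def induce(
    corpus: Iterable[TaggedSentence] | Sequence[TemplateSentence],
    pairs: Sequence[SeedPair] | None,
    config: InductionConfig,
) -> list[tuple[Pattern, int]]:
    """Run the full induction procedure for ``config.iterations`` accepted
    rounds and return unique patterns with how often each was generated,
    sorted by count (descending) then pattern text.

    ``corpus`` may be a sentence iterable (with ``pairs``) or an already
    templated collection (``pairs=None``).  Rejected queries (no adequate
    score drop-off) do not count toward ``iterations``; a cap of
    ``max_rejections_factor * iterations`` rejections guards against
    degenerate score landscapes.
    """
    if pairs is None:
        templates = list(corpus)  # type: ignore[arg-type]
    else:
        templates = templates_from_corpus(corpus, pairs)  # type: ignore[arg-type]
    if config.iterations == 0:
        return []
    if len(templates) < config.n_max:
        raise ValueError(
            f"only {len(templates)} templates derived; need at least "
            f"n_max={config.n_max} to evaluate the drop-off range"
        )
    vectors = [extract_features(t) for t in templates]
    index = TemplateIndex(vectors)
    rng = random.Random(config.rng_seed)
    counter: Counter[tuple[str, ...]] = Counter()
    accepted = 0
    rejections = 0
    max_rejections = config.max_rejections_factor * config.iterations
    while accepted < config.iterations:
        q = rng.randrange(len(templates))
        result = rank_and_cut(q, vectors, config, index=index)
        if result is None:
            rejections += 1
            if rejections > max_rejections:
                raise InductionError(
                    f"no query accepted within {max_rejections} rejections; "
                    f"score drop-offs stay below {config.drop_off_min} in "
                    f"ranks [{config.n_min}, {config.n_max}) — the template "
                    "collection may be too homogeneous"
                )
            continue
        accepted += 1
        retained = [vectors[i] for i in result.top_indices]
        selected = filter_features(retained, config.feature_rel_freq)
        reduced = [
            reduce_template(templates[i], selected) for i in select_sample(result)
        ]
        pattern = align_and_consensus(reduced, config)
        if pattern is not None:
            counter[pattern.tokens] += 1
    ranked = sorted(
        counter.items(), key=lambda kv: (-kv[1], " ".join(kv[0]))
    )
    return [(Pattern(tokens=toks), count) for toks, count in ranked]
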