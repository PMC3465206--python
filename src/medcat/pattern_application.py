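"""Applying hypernymy patterns to a tagged corpus to harvest categories.

A pattern ``X <literal words> Y`` matches a sentence when its literal tokens
occur contiguously (case-insensitive) with a noun phrase immediately
left-adjacent at the X slot and a noun phrase immediately right-adjacent at
the Y slot.  Noun phrases follow the regular grammar
``determiner? (adjective|noun)* noun`` over tag classes.

For every pattern except ``such as`` the X-side phrase is the instance
(hyponym) and the Y-side phrase the category (hypernym); ``such as``
reverses the roles ("categories such as instance").  Matches are aggregated
by the normalized headword of the category phrase; phrases sharing a
headword become its subcategories and the X-side phrases its instances.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

from medcat._normalize import normalize_noun
from medcat.corpus_io import (
    MEDPOST_TAG_CLASSES,
    Pattern,
    TagClasses,
    TaggedSentence,
)

__all__ = [
    "NounPhraseSpan",
    "PatternMatch",
    "CategoryRecord",
    "chunk_noun_phrases",
    "match_pattern",
    "harvest_matches",
    "aggregate",
    "is_such_as",
]


@dataclass(frozen=True)
class NounPhraseSpan:
    """A noun-phrase token span (0-based, half-open) within a sentence.

    ``text`` is the lowercased surface with any leading determiner stripped;
    ``headword`` the normalized final token.
    """

    start: int
    end: int
    text: str
    headword: str


@dataclass(frozen=True)
class PatternMatch:
    """One pattern match with hyponym direction already resolved."""

    sentence_id: str
    pattern: str
    instance: str
    category_phrase: str
    category_headword: str


@dataclass
class CategoryRecord:
    """A harvested category: headword, support, subcategory phrases and the
    instances attached to each subcategory."""

    headword: str
    support: int
    subcategories: dict[str, int] = field(default_factory=dict)
    instances: dict[str, list[tuple[str, int]]] = field(default_factory=dict)


def _np_span_at(
    sentence: TaggedSentence,
    start: int,
    tag_classes: TagClasses,
) -> NounPhraseSpan | None:
    """Maximal NP starting at ``start``: optional determiner, then a run of
    adjectives/nouns, ending at the last noun of the run."""
    tokens = sentence.tokens
    n = len(tokens)
    if start >= n:
        return None
    k = start
    has_det = tag_classes.is_determiner(tokens[k].tag)
    if has_det:
        k += 1
    last_noun = None
    while k < n and (
        tag_classes.is_noun(tokens[k].tag) or tag_classes.is_adjective(tokens[k].tag)
    ):
        if tag_classes.is_noun(tokens[k].tag):
            last_noun = k
        k += 1
    if last_noun is None:
        return None
    return _make_span(sentence, start, last_noun + 1, tag_classes)


def _make_span(
    sentence: TaggedSentence, start: int, end: int, tag_classes: TagClasses
) -> NounPhraseSpan:
    content = sentence.tokens[start:end]
    if tag_classes.is_determiner(content[0].tag) and len(content) > 1:
        content = content[1:]
    return NounPhraseSpan(
        start=start,
        end=end,
        text=" ".join(t.surface.lower() for t in content),
        headword=normalize_noun(content[-1].surface),
    )


def chunk_noun_phrases(
    sentence: TaggedSentence, tag_classes: TagClasses = MEDPOST_TAG_CLASSES
) -> list[NounPhraseSpan]:
    """Maximal, non-overlapping noun-phrase spans, scanning left to right."""
    spans: list[NounPhraseSpan] = []
    tokens = sentence.tokens
    i = 0
    while i < len(tokens):
        tag = tokens[i].tag
        if (
            tag_classes.is_determiner(tag)
            or tag_classes.is_adjective(tag)
            or tag_classes.is_noun(tag)
        ):
            span = _np_span_at(sentence, i, tag_classes)
            if span is not None:
                spans.append(span)
                i = span.end
                continue
            # a det/adj run without a noun: skip past it
            j = i + (1 if tag_classes.is_determiner(tag) else 0)
            while j < len(tokens) and tag_classes.is_adjective(tokens[j].tag):
                j += 1
            i = max(j, i + 1)
        else:
            i += 1
    return spans


def _np_ending_at(
    sentence: TaggedSentence, end: int, tag_classes: TagClasses
) -> NounPhraseSpan | None:
    """Maximal NP whose final token is at position ``end - 1``."""
    tokens = sentence.tokens
    if end <= 0 or not tag_classes.is_noun(tokens[end - 1].tag):
        return None
    k = end - 1
    while k > 0 and (
        tag_classes.is_noun(tokens[k - 1].tag)
        or tag_classes.is_adjective(tokens[k - 1].tag)
    ):
        k -= 1
    if k > 0 and tag_classes.is_determiner(tokens[k - 1].tag):
        k -= 1
    return _make_span(sentence, k, end, tag_classes)


def match_pattern(
    sentence: TaggedSentence,
    pattern: Pattern,
    tag_classes: TagClasses = MEDPOST_TAG_CLASSES,
) -> list[tuple[NounPhraseSpan, NounPhraseSpan]]:
    """All (X-side NP, Y-side NP) matches of a pattern in a sentence.

    Literal prefix/mid/suffix tokens must match contiguously around the two
    adjacent noun phrases.  Roles (instance vs. category) are *not* resolved
    here; see :func:`harvest_matches`.
    """
    words = sentence.lower_surfaces()
    pre, mid, suf = pattern.prefix, pattern.mid, pattern.suffix
    lm = len(mid)
    out: list[tuple[NounPhraseSpan, NounPhraseSpan]] = []
    for m_start in range(len(words) - lm + 1):
        if tuple(words[m_start : m_start + lm]) != mid:
            continue
        x_np = _np_ending_at(sentence, m_start, tag_classes)
        if x_np is None:
            continue
        if pre:
            ps = x_np.start - len(pre)
            if ps < 0 or tuple(words[ps : x_np.start]) != pre:
                continue
        y_np = _np_span_at(sentence, m_start + lm, tag_classes)
        if y_np is None:
            continue
        if suf and tuple(words[y_np.end : y_np.end + len(suf)]) != suf:
            continue
        out.append((x_np, y_np))
    return out


def is_such_as(pattern: Pattern) -> bool:
    """Whether the pattern carries the role-reversing 'such as' string."""
    toks = [t.lower() for t in pattern.tokens]
    return any(
        toks[i] == "such" and toks[i + 1] == "as" for i in range(len(toks) - 1)
    )


def harvest_matches(
    corpus: Iterable[TaggedSentence],
    patterns: Sequence[Pattern],
    tag_classes: TagClasses = MEDPOST_TAG_CLASSES,
) -> Iterator[PatternMatch]:
    """Stream every pattern match in the corpus with instance/category roles
    resolved (X side is the instance except for 'such as' patterns)."""
    for sentence in corpus:
        for pattern in patterns:
            for x_np, y_np in match_pattern(sentence, pattern, tag_classes):
                if is_such_as(pattern):
                    inst, cat = y_np, x_np
                else:
                    inst, cat = x_np, y_np
                yield PatternMatch(
                    sentence_id=sentence.sentence_id,
                    pattern=str(pattern),
                    instance=inst.text,
                    category_phrase=cat.text,
                    category_headword=cat.headword,
                )


def aggregate(
    matches: Iterable[PatternMatch], min_support: int = 50
) -> list[CategoryRecord]:
    """Group matches by category headword and keep headwords supported by at
    least ``min_support`` matches.

    Records are ordered by support (descending) then headword; subcategory
    and instance maps are ordered by count (descending) then text.
    """
    support: dict[str, int] = defaultdict(int)
    subcats: dict[str, dict[str, int]] = defaultdict(lambda: defaultdict(int))
    inst: dict[str, dict[str, dict[str, int]]] = defaultdict(
        lambda: defaultdict(lambda: defaultdict(int))
    )
    for m in matches:
        head = m.category_headword
        support[head] += 1
        subcats[head][m.category_phrase] += 1
        inst[head][m.instance][m.category_phrase] += 1

    records: list[CategoryRecord] = []
    for head in sorted(support, key=lambda h: (-support[h], h)):
        if support[head] < min_support:
            continue
        sub = dict(
            sorted(subcats[head].items(), key=lambda kv: (-kv[1], kv[0]))
        )
        instances = {
            phrase: sorted(by_sub.items(), key=lambda kv: (-kv[1], kv[0]))
            for phrase, by_sub in inst[head].items()
        }
        instances = dict(
            sorted(
                instances.items(),
                key=lambda kv: (-sum(c for _, c in kv[1]), kv[0]),
            )
        )
        records.append(
            CategoryRecord(
                headword=head,
                support=support[head],
                subcategories=sub,
                instances=instances,
            )
        )
    return records
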