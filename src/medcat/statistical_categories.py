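"""Statistical extraction of candidate category nouns from a tagged corpus.

A noun qualifies as a candidate category when it is

1. frequent — tagged as a noun in more than ``min_doc_freq`` distinct
   documents;
2. meaningful on its own — occurs as a *stand-alone* noun (not adjacent to
   another noun or adjective; a determiner is permitted) in at least
   ``min_standalone_doc_freq`` distinct documents;
3. productive — the headword of at least ``min_headword_phrases`` distinct
   multiword phrases from a curated lexicon.

The intersections of the three criteria at headword cutoffs 10/50/100 form a
nested family of noun sets (FHN-style sets); ``extract_fhn`` computes any
member given thresholds.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping

from medcat._normalize import normalize_noun
from medcat.corpus_io import (
    MEDPOST_TAG_CLASSES,
    PhraseLexicon,
    TagClasses,
    TaggedSentence,
    _DETERMINER_WORDS,
)

__all__ = [
    "normalize_noun",
    "NounStats",
    "ThresholdConfigStat",
    "is_standalone",
    "count_noun_stats",
    "headword_counts",
    "phrase_headword",
    "compute_noun_stats",
    "extract_fhn",
]


@dataclass
class NounStats:
    """Per-noun corpus and lexicon statistics."""

    noun: str
    doc_freq: int = 0
    standalone_doc_freq: int = 0
    headword_phrase_count: int = 0


@dataclass(frozen=True)
class ThresholdConfigStat:
    """Criterion thresholds.  Criterion 1 is strict ("more than"), criteria
    2-3 are inclusive ("at least")."""

    min_doc_freq: int = 10_000
    min_standalone_doc_freq: int = 1_000
    min_headword_phrases: int = 50

    def __post_init__(self) -> None:
        for name in (
            "min_doc_freq",
            "min_standalone_doc_freq",
            "min_headword_phrases",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


def is_standalone(
    sentence: TaggedSentence,
    position: int,
    tag_classes: TagClasses = MEDPOST_TAG_CLASSES,
) -> bool:
    """Whether the noun at ``position`` is a stand-alone occurrence.

    A stand-alone noun is not part of a longer noun phrase: its neighbours
    are neither nouns nor adjectives (a preceding determiner is fine, and
    punctuation or anything else non-nominal does not block).
    """
    if not 0 <= position < len(sentence.tokens):
        raise IndexError(
            f"position {position} out of range for sentence "
            f"{sentence.sentence_id!r} of length {len(sentence.tokens)}"
        )

    def blocking(tag: str) -> bool:
        return tag_classes.is_noun(tag) or tag_classes.is_adjective(tag)

    if position > 0 and blocking(sentence.tokens[position - 1].tag):
        return False
    if position + 1 < len(sentence.tokens) and blocking(
        sentence.tokens[position + 1].tag
    ):
        return False
    return True


def count_noun_stats(
    corpus: Iterable[TaggedSentence],
    tag_classes: TagClasses = MEDPOST_TAG_CLASSES,
) -> dict[str, NounStats]:
    """Count, per normalized noun, the number of distinct documents with any
    noun-tagged occurrence and with at least one stand-alone occurrence.

    Each document contributes at most once per noun per statistic regardless
    of how many times the noun occurs in it.
    """
    doc_sets: dict[str, set[str]] = defaultdict(set)
    standalone_doc_sets: dict[str, set[str]] = defaultdict(set)
    for sentence in corpus:
        for i, token in enumerate(sentence.tokens):
            if not tag_classes.is_noun(token.tag):
                continue
            noun = normalize_noun(token.surface)
            doc_sets[noun].add(sentence.doc_id)
            if is_standalone(sentence, i, tag_classes):
                standalone_doc_sets[noun].add(sentence.doc_id)
    return {
        noun: NounStats(
            noun=noun,
            doc_freq=len(docs),
            standalone_doc_freq=len(standalone_doc_sets.get(noun, ())),
        )
        for noun, docs in doc_sets.items()
    }


def phrase_headword(phrase: str) -> str:
    """The normalized final non-determiner token of a phrase."""
    words = [w for w in phrase.lower().split() if w not in _DETERMINER_WORDS]
    if not words:
        raise ValueError(f"phrase {phrase!r} has no non-determiner token")
    return normalize_noun(words[-1])


def headword_counts(lexicon: PhraseLexicon) -> dict[str, int]:
    """Number of distinct lexicon phrases per normalized headword."""
    counts: dict[str, int] = defaultdict(int)
    for phrase in lexicon.phrases:
        counts[phrase_headword(phrase)] += 1
    return dict(counts)


def compute_noun_stats(
    corpus: Iterable[TaggedSentence],
    lexicon: PhraseLexicon,
    tag_classes: TagClasses = MEDPOST_TAG_CLASSES,
) -> dict[str, NounStats]:
    """Corpus counts merged with lexicon headword counts (nouns that only
    appear as lexicon headwords get zero corpus counts)."""
    stats = count_noun_stats(corpus, tag_classes)
    for noun, count in headword_counts(lexicon).items():
        stats.setdefault(noun, NounStats(noun=noun)).headword_phrase_count = count
    return stats


def extract_fhn(
    stats: Mapping[str, NounStats], config: ThresholdConfigStat
) -> set[str]:
    """Nouns satisfying all three criteria at the configured thresholds.

    Antitone in every threshold: raising any threshold never adds a noun,
    hence the 100/50/10 headword cutoffs nest.
    """
    return {
        noun
        for noun, s in stats.items()
        if s.doc_freq > config.min_doc_freq
        and s.standalone_doc_freq >= config.min_standalone_doc_freq
        and s.headword_phrase_count >= config.min_headword_phrases
    }
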