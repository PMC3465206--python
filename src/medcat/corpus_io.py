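"""Data model and readers/writers for tagged corpora, phrase lists, seed pairs
and hypernymy patterns.

The corpus dialect is one sentence per line, whitespace-separated
``surface/TAG`` tokens with a MedPost-style tagset.  The *last* ``/`` on a
token separates surface from tag, so surfaces containing ``/`` (chemical
names, fractions) survive a round trip.  Tags are consumed opaquely; only
three tag classes matter downstream (noun-like, adjective-like,
determiner-like) and the mapping is configurable with MedPost defaults.

All text comparison downstream is case-insensitive; original surfaces are
retained on the token objects for reporting.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence, Union

__all__ = [
    "CorpusFormatError",
    "TagClasses",
    "MEDPOST_TAG_CLASSES",
    "TaggedToken",
    "TaggedSentence",
    "PhraseLexicon",
    "SeedPair",
    "Pattern",
    "read_tagged_corpus",
    "write_tagged_corpus",
    "read_phrase_lexicon",
    "write_phrase_lexicon",
    "read_seed_pairs",
    "write_seed_pairs",
    "read_patterns",
    "write_patterns",
    "parse_pattern",
    "load_packaged_patterns",
]

PathLike = Union[str, Path]


class CorpusFormatError(ValueError):
    """A malformed input file; the message names the offending line/token."""


@dataclass(frozen=True)
class TagClasses:
    """Prefix-based mapping from an opaque tagset to the three tag classes
    the pipeline cares about.

    Defaults follow MedPost: nouns ``NN``/``NNS``/``NNP``, adjectives
    ``JJ``/``JJR``/``JJT``, determiners ``DD`` (and predeterminer ``DB``).
    """

    noun_prefixes: tuple[str, ...] = ("NN",)
    adjective_prefixes: tuple[str, ...] = ("JJ",)
    determiner_prefixes: tuple[str, ...] = ("DD", "DB")

    def is_noun(self, tag: str) -> bool:
        return tag.startswith(self.noun_prefixes)

    def is_adjective(self, tag: str) -> bool:
        return tag.startswith(self.adjective_prefixes)

    def is_determiner(self, tag: str) -> bool:
        return tag.startswith(self.determiner_prefixes)


MEDPOST_TAG_CLASSES = TagClasses()

#: words treated as determiners in untagged phrase lists
_DETERMINER_WORDS = frozenset(
    {"the", "a", "an", "this", "that", "these", "those", "some", "any", "each"}
)


@dataclass
class TaggedToken:
    surface: str
    tag: str

    def __post_init__(self) -> None:
        if not self.surface:
            raise ValueError("token surface must be non-empty")
        if not self.tag:
            raise ValueError(f"token {self.surface!r} has an empty tag")

    @property
    def lower(self) -> str:
        return self.surface.lower()

    @property
    def normalized(self) -> str:
        """Lowercased, singularized form (computed lazily)."""
        from medcat._normalize import normalize_noun

        return normalize_noun(self.surface)


@dataclass
class TaggedSentence:
    """An ordered sequence of tagged tokens with sentence/document identity."""

    tokens: list[TaggedToken]
    sentence_id: str = ""
    doc_id: str = ""

    def __len__(self) -> int:
        return len(self.tokens)

    def __iter__(self) -> Iterator[TaggedToken]:
        return iter(self.tokens)

    def surfaces(self) -> list[str]:
        return [t.surface for t in self.tokens]

    def lower_surfaces(self) -> list[str]:
        return [t.surface.lower() for t in self.tokens]


@dataclass
class PhraseLexicon:
    """A set of lowercased multiword phrases (>= 2 non-determiner tokens)."""

    phrases: set[str] = field(default_factory=set)

    def __len__(self) -> int:
        return len(self.phrases)

    def __contains__(self, phrase: str) -> bool:
        return phrase.lower() in self.phrases

    def add(self, phrase: str) -> None:
        phrase = " ".join(phrase.lower().split())
        content = [w for w in phrase.split() if w not in _DETERMINER_WORDS]
        if len(content) < 2:
            raise ValueError(
                f"phrase {phrase!r} has fewer than 2 non-determiner tokens"
            )
        self.phrases.add(phrase)


@dataclass(frozen=True)
class SeedPair:
    """A narrower/broader term pair (stand-in for hyponym/hypernym)."""

    narrower: str
    broader: str

    def __post_init__(self) -> None:
        if not self.narrower or not self.broader:
            raise ValueError("seed pair terms must be non-empty")
        if self.narrower == self.broader:
            raise ValueError(f"seed pair terms are identical: {self.narrower!r}")


PLACEHOLDER_X = "X"
PLACEHOLDER_Y = "Y"


@dataclass
class Pattern:
    """A lexical hypernymy pattern: literal tokens around one X and one Y,
    X before Y (e.g. ``X and other Y``)."""

    tokens: tuple[str, ...]
    support: int = 0

    def __post_init__(self) -> None:
        self.tokens = tuple(self.tokens)
        xs = [i for i, t in enumerate(self.tokens) if t == PLACEHOLDER_X]
        ys = [i for i, t in enumerate(self.tokens) if t == PLACEHOLDER_Y]
        text = " ".join(self.tokens)
        if len(xs) != 1 or len(ys) != 1:
            raise ValueError(
                f"pattern {text!r} must contain exactly one X and one Y"
            )
        if xs[0] > ys[0]:
            raise ValueError(f"pattern {text!r} has Y before X")

    def __str__(self) -> str:
        return " ".join(self.tokens)

    @property
    def x_index(self) -> int:
        return self.tokens.index(PLACEHOLDER_X)

    @property
    def y_index(self) -> int:
        return self.tokens.index(PLACEHOLDER_Y)

    @property
    def prefix(self) -> tuple[str, ...]:
        """Literal tokens before X (lowercased)."""
        return tuple(t.lower() for t in self.tokens[: self.x_index])

    @property
    def mid(self) -> tuple[str, ...]:
        """Literal tokens between X and Y (lowercased)."""
        return tuple(
            t.lower() for t in self.tokens[self.x_index + 1 : self.y_index]
        )

    @property
    def suffix(self) -> tuple[str, ...]:
        """Literal tokens after Y (lowercased)."""
        return tuple(t.lower() for t in self.tokens[self.y_index + 1 :])


# ---------------------------------------------------------------------------
# readers / writers


def _open_maybe(path_or_handle, mode: str = "r") -> tuple[IO[str], bool]:
    if hasattr(path_or_handle, "read") or hasattr(path_or_handle, "write"):
        return path_or_handle, False
    return open(path_or_handle, mode, encoding="utf-8"), True


def parse_tagged_line(line: str, lineno: int = 0) -> list[TaggedToken]:
    tokens: list[TaggedToken] = []
    for raw in line.split():
        sep = raw.rfind("/")
        if sep <= 0 or sep == len(raw) - 1:
            raise CorpusFormatError(
                f"line {lineno}: malformed token {raw!r} (expected surface/TAG)"
            )
        tokens.append(TaggedToken(surface=raw[:sep], tag=raw[sep + 1 :]))
    return tokens


def read_tagged_corpus(
    path: PathLike | IO[str], *, with_doc_ids: bool = False
) -> Iterator[TaggedSentence]:
    """Stream sentences from a one-sentence-per-line tagged corpus.

    With ``with_doc_ids=True`` each line is ``doc_id<TAB>token/TAG ...``;
    otherwise every line is its own document (``doc_id == sentence_id``).
    Memory use is bounded by one sentence.
    """
    handle, owned = _open_maybe(path)
    try:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            sid = f"line:{lineno}"
            doc_id = sid
            if with_doc_ids:
                if "\t" not in line:
                    raise CorpusFormatError(
                        f"line {lineno}: expected 'doc_id<TAB>tokens' dialect"
                    )
                doc_id, line = line.split("\t", 1)
            if not line.strip():
                continue
            yield TaggedSentence(
                tokens=parse_tagged_line(line, lineno),
                sentence_id=sid,
                doc_id=doc_id,
            )
    finally:
        if owned:
            handle.close()


def write_tagged_corpus(
    sentences: Iterable[TaggedSentence],
    path: PathLike | IO[str],
    *,
    with_doc_ids: bool = False,
) -> None:
    handle, owned = _open_maybe(path, "w")
    try:
        for sent in sentences:
            body = " ".join(f"{t.surface}/{t.tag}" for t in sent.tokens)
            if with_doc_ids:
                handle.write(f"{sent.doc_id}\t{body}\n")
            else:
                handle.write(body + "\n")
    finally:
        if owned:
            handle.close()


def read_phrase_lexicon(path: PathLike | IO[str]) -> PhraseLexicon:
    """Read a one-phrase-per-line multiword lexicon (lowercased, deduped)."""
    lex = PhraseLexicon()
    handle, owned = _open_maybe(path)
    try:
        for lineno, line in enumerate(handle, start=1):
            phrase = line.strip()
            if not phrase:
                continue
            try:
                lex.add(phrase)
            except ValueError as exc:
                raise CorpusFormatError(f"line {lineno}: {exc}") from exc
    finally:
        if owned:
            handle.close()
    return lex


def write_phrase_lexicon(lexicon: PhraseLexicon, path: PathLike | IO[str]) -> None:
    handle, owned = _open_maybe(path, "w")
    try:
        for phrase in sorted(lexicon.phrases):
            handle.write(phrase + "\n")
    finally:
        if owned:
            handle.close()


def read_seed_pairs(path: PathLike | IO[str]) -> list[SeedPair]:
    """Read narrower<TAB>broader pairs; lowercased, deduplicated preserving
    first-occurrence order."""
    pairs: list[SeedPair] = []
    seen: set[SeedPair] = set()
    handle, owned = _open_maybe(path)
    try:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 2 or not cols[0].strip() or not cols[1].strip():
                raise CorpusFormatError(
                    f"row {lineno}: expected 2 tab-separated columns, "
                    f"got {line.rstrip()!r}"
                )
            pair = SeedPair(
                narrower=" ".join(cols[0].lower().split()),
                broader=" ".join(cols[1].lower().split()),
            )
            if pair not in seen:
                seen.add(pair)
                pairs.append(pair)
    finally:
        if owned:
            handle.close()
    return pairs


def write_seed_pairs(pairs: Iterable[SeedPair], path: PathLike | IO[str]) -> None:
    handle, owned = _open_maybe(path, "w")
    try:
        for pair in pairs:
            handle.write(f"{pair.narrower}\t{pair.broader}\n")
    finally:
        if owned:
            handle.close()


def parse_pattern(text: str, lineno: int = 0) -> Pattern:
    tokens = tuple(text.split())
    try:
        return Pattern(tokens=tokens)
    except ValueError as exc:
        raise CorpusFormatError(f"line {lineno}: {exc}") from exc


def read_patterns(path: PathLike | IO[str]) -> list[Pattern]:
    """Read one pattern per line; placeholders are bare uppercase X and Y."""
    patterns: list[Pattern] = []
    handle, owned = _open_maybe(path)
    try:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            patterns.append(parse_pattern(line.strip(), lineno))
    finally:
        if owned:
            handle.close()
    return patterns


def write_patterns(patterns: Iterable[Pattern], path: PathLike | IO[str]) -> None:
    handle, owned = _open_maybe(path, "w")
    try:
        for pattern in patterns:
            handle.write(str(pattern) + "\n")
    finally:
        if owned:
            handle.close()


def load_packaged_patterns() -> list[Pattern]:
    """The 40 curated hypernymy patterns shipped as a package resource."""
    from importlib.resources import files

    text = files("medcat").joinpath("resources/curated_patterns.txt").read_text(
        encoding="utf-8"
    )
    return read_patterns(io.StringIO(text))
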