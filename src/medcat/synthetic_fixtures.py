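"""Seeded synthetic corpora with planted category structure, plus the small
worked-example fixtures used throughout the documentation and tests.

The generator emits a POS-tagged corpus in which a configurable fraction of
sentences instantiate a planted hypernymy pattern around a sampled
(instance, category-phrase) pair, e.g.::

    tuberculosis/NN is/VBZ a/DD chronic/JJ infection/NN ./.
    infections/NNS such/II as/II malaria/NN

The remaining sentences are either stand-alone mentions of a category noun
(exercising the stand-alone criterion) or noise drawn from a Zipf-like
unigram model over pseudo-words, so cosine retrieval faces realistic
near-duplicates.  Alongside the corpus the generator returns a ground-truth
ledger: every planted (pattern, instance, category) triple, per-pattern and
per-category support, and per-noun document statistics, all recomputable by
brute force from the emitted sentences.

Sentence-final periods are emitted with probability ``period_prob`` < 1
(mirroring title-style corpus lines that end without punctuation); a corpus
in which *every* template shares the ``(Y, .)`` feature would otherwise pull
the period into every induced pattern.
"""

from __future__ import annotations

import random
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable

from medcat.corpus_io import (
    MEDPOST_TAG_CLASSES,
    Pattern,
    PhraseLexicon,
    SeedPair,
    TaggedSentence,
    TaggedToken,
)

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "default_vocabulary",
    "generate_corpus",
    "table2_fixture",
    "quinoprotein_fixture",
    "propranolol_fixture",
    "WORKED_EXAMPLE_FEATURES",
]


def default_vocabulary() -> dict[str, list[str]]:
    """Six planted categories with a dozen single-token instances each."""
    return {
        "infection": [
            "tuberculosis", "malaria", "influenza", "syphilis",
            "toxoplasmosis", "candidiasis", "aspergillosis", "pneumonia",
            "cholera", "dengue", "hepatitis", "mucormycosis",
        ],
        "enzyme": [
            "trypsin", "pepsin", "lipase", "amylase", "catalase",
            "lysozyme", "kinase", "phosphatase", "protease", "ligase",
            "helicase", "polymerase",
        ],
        "inhibitor": [
            "captopril", "enalapril", "aspirin", "warfarin", "statins",
            "ritonavir", "imatinib", "allopurinol", "omeprazole",
            "sildenafil", "bortezomib", "methotrexate",
        ],
        "disease": [
            "diabetes", "asthma", "lupus", "gout", "epilepsy",
            "psoriasis", "sarcoidosis", "scleroderma", "fibromyalgia",
            "endometriosis", "hemophilia", "amyloidosis",
        ],
        "receptor": [
            "cd4", "cd8", "trka", "egfr", "her2", "gpr55",
            "cxcr4", "nmda", "ampa", "ryr1", "trpv1", "pparg",
        ],
        "hormone": [
            "insulin", "cortisol", "melatonin", "thyroxine", "leptin",
            "ghrelin", "oxytocin", "prolactin", "aldosterone",
            "estradiol", "glucagon", "adrenaline",
        ],
    }


_MODIFIERS = (
    "viral", "chronic", "bacterial", "acute", "fungal",
    "severe", "recurrent", "systemic",
)

_SYLLABLES = (
    "ba", "cro", "din", "fex", "gal", "hem", "jun", "kor",
    "lam", "mek", "nor", "pil", "qua", "rev", "sul", "tor",
)


def _noise_vocab(size: int) -> list[str]:
    words = []
    i = 0
    while len(words) < size:
        a = _SYLLABLES[i % 16]
        b = _SYLLABLES[(i // 16) % 16]
        c = _SYLLABLES[(i // 256) % 16]
        words.append(a + b + c)
        i += 1
    return words


@dataclass
class GeneratorConfig:
    n_documents: int = 1_000
    sentences_per_doc: int = 5
    vocabulary: dict[str, list[str]] = field(default_factory=default_vocabulary)
    planted_patterns: list[Pattern] = field(
        default_factory=lambda: [
            Pattern(tokens=("X", "is", "a", "Y")),
            Pattern(tokens=("X", "such", "as", "Y")),
        ]
    )
    pattern_weights: list[float] | None = None
    pattern_sentence_fraction: float = 0.5
    standalone_sentence_fraction: float = 0.25
    modifier_prob: float = 0.5
    period_prob: float = 0.5
    noise_vocab_size: int = 300
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "pattern_sentence_fraction",
            "standalone_sentence_fraction",
            "modifier_prob",
            "period_prob",
        ):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if not self.vocabulary:
            raise ValueError("vocabulary must be non-empty")
        if any(not v for v in self.vocabulary.values()):
            raise ValueError("every category needs at least one instance")


@dataclass
class GroundTruth:
    """What the generator planted, in the vocabulary of the harvest stages."""

    #: (pattern text, instance text, category phrase text) per pattern sentence
    triples: list[tuple[str, str, str]] = field(default_factory=list)
    pattern_support: dict[str, int] = field(default_factory=dict)
    #: matches per normalized category headword
    category_support: dict[str, int] = field(default_factory=dict)
    categories: set[str] = field(default_factory=set)
    seed_pairs: list[SeedPair] = field(default_factory=list)
    lexicon: PhraseLexicon = field(default_factory=PhraseLexicon)
    noun_doc_freq: dict[str, int] = field(default_factory=dict)
    noun_standalone_doc_freq: dict[str, int] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "triples": [list(t) for t in self.triples],
            "pattern_support": dict(self.pattern_support),
            "category_support": dict(self.category_support),
            "categories": sorted(self.categories),
            "seed_pairs": [[p.narrower, p.broader] for p in self.seed_pairs],
            "lexicon": sorted(self.lexicon.phrases),
            "noun_doc_freq": dict(self.noun_doc_freq),
            "noun_standalone_doc_freq": dict(self.noun_standalone_doc_freq),
        }


_NONNOMINAL_TAGS = ("VVZ", "II", "RR", "CS")


def _plural(word: str) -> str:
    return word if word.endswith("s") else word + "s"


def generate_corpus(
    config: GeneratorConfig,
) -> tuple[list[TaggedSentence], GroundTruth]:
    """Emit a tagged corpus with planted pattern structure and its ground
    truth.  Byte-identical output for equal configs (seed included)."""
    from medcat._normalize import normalize_noun

    rng = random.Random(config.rng_seed)
    noise_words = _noise_vocab(config.noise_vocab_size)
    noise_weights = [1.0 / (r + 1) for r in range(len(noise_words))]
    # fixed per-word noise tags; ~2/5 of the noise vocabulary is nominal
    noise_tags = {
        w: ("NN", "JJ", "VVZ", "II", "RR")[i % 5]
        for i, w in enumerate(noise_words)
    }
    nonnominal_noise = [w for w in noise_words if noise_tags[w] in _NONNOMINAL_TAGS]
    nonnominal_weights = [
        1.0 / (noise_words.index(w) + 1) for w in nonnominal_noise
    ]

    categories = list(config.vocabulary)
    patterns = list(config.planted_patterns)
    weights = config.pattern_weights or [1.0] * len(patterns)

    truth = GroundTruth(categories={normalize_noun(c) for c in categories})
    for cat in categories:
        for mod in _MODIFIERS:
            truth.lexicon.add(f"{mod} {cat}")
        for inst in config.vocabulary[cat]:
            truth.seed_pairs.append(SeedPair(narrower=inst, broader=cat))
            if _plural(cat) != cat:
                truth.seed_pairs.append(
                    SeedPair(narrower=inst, broader=_plural(cat))
                )

    def noise_run(k: int, nominal_ok: bool) -> list[TaggedToken]:
        if nominal_ok:
            words = rng.choices(noise_words, weights=noise_weights, k=k)
        else:
            words = rng.choices(
                nonnominal_noise, weights=nonnominal_weights, k=k
            )
        return [TaggedToken(surface=w, tag=noise_tags[w]) for w in words]

    pattern_support: dict[str, int] = defaultdict(int)
    category_support: dict[str, int] = defaultdict(int)
    doc_sets: dict[str, set[str]] = defaultdict(set)
    standalone_doc_sets: dict[str, set[str]] = defaultdict(set)

    def build_pattern_sentence() -> TaggedSentence:
        pat = rng.choices(patterns, weights=weights, k=1)[0]
        cat = rng.choice(categories)
        inst = rng.choice(config.vocabulary[cat])
        mod = rng.random() < config.modifier_prob
        modifier = rng.choice(_MODIFIERS) if mod else None
        tokens: list[TaggedToken] = list(noise_run(rng.randint(0, 3), False))
        if pat.tokens == ("X", "such", "as", "Y"):
            cat_surface = _plural(cat)
            phrase_tokens = []
            if modifier:
                phrase_tokens.append(TaggedToken(modifier, "JJ"))
            phrase_tokens.append(TaggedToken(cat_surface, "NNS"))
            tokens += phrase_tokens
            tokens += [TaggedToken("such", "II"), TaggedToken("as", "II")]
            tokens.append(TaggedToken(inst, "NN"))
            phrase_text = (f"{modifier} " if modifier else "") + cat_surface
        else:  # X <mid literals> Y
            tokens.append(TaggedToken(inst, "NN"))
            for lit in pat.mid:
                tag = "DD" if lit in ("a", "an", "the") else "VVZ"
                tokens.append(TaggedToken(lit, tag))
            if modifier:
                tokens.append(TaggedToken(modifier, "JJ"))
            tokens.append(TaggedToken(cat, "NN"))
            phrase_text = (f"{modifier} " if modifier else "") + cat
        tokens += noise_run(rng.randint(0, 3), False)
        if rng.random() < config.period_prob:
            tokens.append(TaggedToken(".", "."))
        truth.triples.append((str(pat), inst, phrase_text))
        pattern_support[str(pat)] += 1
        category_support[normalize_noun(cat)] += 1
        return TaggedSentence(tokens=tokens)

    def build_standalone_sentence() -> TaggedSentence:
        cat = rng.choice(categories)
        tokens = [
            TaggedToken("the", "DD"),
            TaggedToken(cat, "NN"),
            TaggedToken(rng.choices(nonnominal_noise, nonnominal_weights, k=1)[0], "VVZ"),
        ]
        tokens += noise_run(rng.randint(0, 2), False)
        if rng.random() < config.period_prob:
            tokens.append(TaggedToken(".", "."))
        return TaggedSentence(tokens=tokens)

    def build_noise_sentence() -> TaggedSentence:
        tokens = noise_run(rng.randint(4, 8), True)
        if rng.random() < config.period_prob:
            tokens.append(TaggedToken(".", "."))
        return TaggedSentence(tokens=tokens)

    sentences: list[TaggedSentence] = []
    line = 0
    for d in range(config.n_documents):
        doc_id = f"doc:{d + 1}"
        for _ in range(config.sentences_per_doc):
            line += 1
            u = rng.random()
            if u < config.pattern_sentence_fraction:
                sent = build_pattern_sentence()
            elif u < config.pattern_sentence_fraction + (
                1 - config.pattern_sentence_fraction
            ) * config.standalone_sentence_fraction:
                sent = build_standalone_sentence()
            else:
                sent = build_noise_sentence()
            sent.sentence_id = f"line:{line}"
            sent.doc_id = doc_id
            sentences.append(sent)
            # ground-truth noun statistics (inline recount at emission time)
            tags = [t.tag for t in sent.tokens]
            for i, tok in enumerate(sent.tokens):
                if not MEDPOST_TAG_CLASSES.is_noun(tok.tag):
                    continue
                noun = normalize_noun(tok.surface)
                doc_sets[noun].add(doc_id)
                prev_blocks = i > 0 and (
                    MEDPOST_TAG_CLASSES.is_noun(tags[i - 1])
                    or MEDPOST_TAG_CLASSES.is_adjective(tags[i - 1])
                )
                next_blocks = i + 1 < len(tags) and (
                    MEDPOST_TAG_CLASSES.is_noun(tags[i + 1])
                    or MEDPOST_TAG_CLASSES.is_adjective(tags[i + 1])
                )
                if not prev_blocks and not next_blocks:
                    standalone_doc_sets[noun].add(doc_id)

    truth.pattern_support = dict(pattern_support)
    truth.category_support = dict(category_support)
    truth.noun_doc_freq = {n: len(s) for n, s in doc_sets.items()}
    truth.noun_standalone_doc_freq = {
        n: len(s) for n, s in standalone_doc_sets.items()
    }
    return sentences, truth


# ---------------------------------------------------------------------------
# in-paper fixtures


def _sent(spec: str, sid: str) -> TaggedSentence:
    tokens = [
        TaggedToken(surface=tok.rsplit("/", 1)[0], tag=tok.rsplit("/", 1)[1])
        for tok in spec.split()
    ]
    return TaggedSentence(tokens=tokens, sentence_id=sid, doc_id=sid)


def table2_fixture() -> tuple[list[TaggedSentence], list[SeedPair]]:
    """The five worked-example sentences with their narrower/broader pairs.

    Reducing their templates with :data:`WORKED_EXAMPLE_FEATURES` and taking
    the alignment consensus yields the pattern ``X and other Y``.
    """
    sentences = [
        _sent("Spouse/NN abuse/NN and/CC other/JJ domestic/JJ violence/NN ./.", "t2:1"),
        _sent("Effects/NNS of/II anticoagulants/NNS and/CC other/JJ drugs/NNS ./.", "t2:2"),
        _sent("Epidemiology/NN of/II rabies/NN virus/NN and/CC other/JJ lyssaviruses/NNS", "t2:3"),
        _sent("Biosynthesis/NN of/II Cholesterol/NN and/CC Other/JJ Sterols/NNS ./.", "t2:4"),
        _sent("Alcohol/NN and/CC other/JJ drug/NN dependencies/NNS ./.", "t2:5"),
    ]
    pairs = [
        SeedPair(narrower="spouse abuse", broader="domestic violence"),
        SeedPair(narrower="anticoagulants", broader="drugs"),
        SeedPair(narrower="rabies virus", broader="lyssaviruses"),
        SeedPair(narrower="cholesterol", broader="sterols"),
        SeedPair(narrower="alcohol", broader="drug"),
    ]
    return sentences, pairs


#: the word-order features surviving the 0.8 relative-frequency filter in the
#: worked example: "X and; X other; and other; and Y; other Y"
WORKED_EXAMPLE_FEATURES: set[tuple[str, str]] = {
    ("X", "and"),
    ("X", "other"),
    ("and", "other"),
    ("and", "Y"),
    ("other", "Y"),
}


def quinoprotein_fixture() -> tuple[TaggedSentence, SeedPair]:
    """The worked example's query sentence with its bacteria/organisms pair."""
    sentence = _sent(
        "Quinoproteins/NNS are/VBR a/DD big/JJ class/NN of/II oxyreductive/JJ "
        "agents/NNS occurring/VVG in/II bacteria/NN and/CC other/JJ "
        "organisms/NNS ./.",
        "q:1",
    )
    return sentence, SeedPair(narrower="bacteria", broader="organisms")


def propranolol_fixture() -> TaggedSentence:
    """The pattern-application example sentence: applying ``X and other Y``
    yields instance *propranolol* and category phrase *beta blockers*."""
    return _sent(
        "The/DD unique/JJ action/NN of/II propranolol/NN and/CC other/JJ "
        "beta/NN blockers/NNS in/II lowering/VVG raised/VVN arterial/JJ "
        "pressure/NN is/VBZ discussed/VVN ./.",
        "p:1",
    )
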