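import random

import pytest

from medcat.corpus_io import TaggedSentence, TaggedToken


def make_sentence(spec: str, sid: str = "s:1", doc_id: str = "") -> TaggedSentence:
    """Build a sentence from 'surface/TAG surface/TAG ...' shorthand."""
    tokens = [
        TaggedToken(surface=t.rsplit("/", 1)[0], tag=t.rsplit("/", 1)[1])
        for t in spec.split()
    ]
    return TaggedSentence(tokens=tokens, sentence_id=sid, doc_id=doc_id or sid)


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20120)


@pytest.fixture
def small_corpus() -> list[TaggedSentence]:
    """Three documents with known noun placements."""
    return [
        make_sentence("the/DD infection/NN was/VBD treated/VVN ./.", "s1", "d1"),
        make_sentence("viral/JJ infection/NN persists/VVZ ./.", "s2", "d1"),
        make_sentence("infection/NN and/CC inflammation/NN ./.", "s3", "d2"),
        make_sentence("western/JJ blot/NN analysis/NN ./.", "s4", "d2"),
        make_sentence("the/DD blot/NN faded/VVD ./.", "s5", "d3"),
        make_sentence("infections/NNS are/VBR common/JJ ./.", "s6", "d3"),
    ]
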