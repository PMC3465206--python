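import math
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from medcat.corpus_io import SeedPair
from medcat.pattern_induction import (
    InductionConfig,
    FeatureVector,
    TemplateSentence,
    align_and_consensus,
    align_pair,
    cosine,
    extract_features,
    filter_features,
    induce,
    make_templates,
    rank_and_cut,
    reduce_template,
    sample_ranks,
    select_sample,
    _cut_ranking,
)
from medcat.synthetic_fixtures import quinoprotein_fixture

from conftest import make_sentence
from oracles import align_bruteforce, drop_off_cut_bruteforce, features_bruteforce


def template(prefix=(), mid=(), suffix=(), orientation="NX_BY"):
    return TemplateSentence(
        prefix=tuple(prefix), mid=tuple(mid), suffix=tuple(suffix),
        orientation=orientation,
    )


class TestMakeTemplates:
    def test_quinoprotein_query_sentence(self):
        sentence, pair = quinoprotein_fixture()
        (t,) = make_templates(sentence, [pair])
        assert t.prefix == (
            "quinoproteins", "are", "a", "big", "class", "of",
            "oxyreductive", "agents", "occurring", "in",
        )
        assert t.mid == ("and", "other")
        assert t.suffix == (".",)
        assert t.orientation == "NX_BY"

    def test_sentence_without_the_pair(self):
        sent = make_sentence("no/DD match/NN here/RR")
        assert make_templates(sent, [SeedPair("bacteria", "organisms")]) == []

    def test_broader_term_first_flips_orientation(self):
        sent = make_sentence("organisms/NNS such/II as/II bacteria/NN")
        (t,) = make_templates(sent, [SeedPair("bacteria", "organisms")])
        assert t.orientation == "BX_NY"
        assert t.mid == ("such", "as")

    def test_multiword_terms_match_contiguously(self):
        sent = make_sentence(
            "rabies/NN virus/NN and/CC other/JJ lyssaviruses/NNS"
        )
        (t,) = make_templates(sent, [SeedPair("rabies virus", "lyssaviruses")])
        assert t.prefix == () and t.mid == ("and", "other")

    def test_multiple_occurrences_enumerated(self):
        # narrower 'a' at positions 0 and 4; broader 'b' at 2: combinations
        # (0,2) and (4,2) are both non-overlapping
        sent = make_sentence("a/NN x/VVZ b/NN y/VVZ a/NN")
        ts = make_templates(sent, [SeedPair("a", "b")])
        assert len(ts) == 2
        orientations = {t.orientation for t in ts}
        assert orientations == {"NX_BY", "BX_NY"}

    def test_occurrence_combinations_match_bruteforce(self, rng):
        words = ["a", "b", "c"]
        pair = SeedPair("a", "b")
        for _ in range(100):
            seq = [rng.choice(words) for _ in range(rng.randint(2, 8))]
            sent = make_sentence(" ".join(f"{w}/NN" for w in seq))
            got = make_templates(sent, [pair])
            # oracle: every (i, j) with seq[i]=='a', seq[j]=='b', i != j
            expected = sum(
                1
                for i, wi in enumerate(seq)
                for j, wj in enumerate(seq)
                if wi == "a" and wj == "b" and i != j
            )
            assert len(got) == expected
            for t in got:
                full = t.full_tokens()
                assert full.count("X") == 1 and full.count("Y") == 1


class TestExtractFeatures:
    def test_worked_example_row(self):
        t = template(prefix=("effects", "of"), mid=("and", "other"))
        feats = extract_features(t)
        assert feats.counts == {
            ("effects", "of"): 1,
            ("effects", "X"): 1,
            ("of", "X"): 1,
            ("X", "and"): 1,
            ("X", "other"): 1,
            ("and", "other"): 1,
            ("and", "Y"): 1,
            ("other", "Y"): 1,
            ("NX", "BY"): 1,
        }

    def test_bare_template_has_only_orientation(self):
        feats = extract_features(template())
        assert feats.counts == {("NX", "BY"): 1}
        assert feats.norm == 1.0

    def test_repeated_words_counted_as_multiset(self):
        t = template(mid=("and", "and"))
        assert extract_features(t).counts[("X", "and")] == 2
        assert extract_features(t).counts[("and", "and")] == 1

    def test_matches_position_pair_oracle(self, rng):
        words = ["alpha", "beta", "gamma", "delta"]
        for _ in range(250):
            parts = [
                tuple(rng.choice(words) for _ in range(rng.randint(0, 3)))
                for _ in range(3)
            ]
            orientation = rng.choice(["NX_BY", "BX_NY"])
            t = template(*parts, orientation=orientation)
            assert extract_features(t).counts == dict(
                features_bruteforce(*parts, orientation)
            )


class TestCosine:
    def test_self_similarity_is_one(self):
        v = extract_features(template(mid=("is", "a")))
        assert cosine(v, v) == pytest.approx(1.0)

    def test_orientation_only_overlap(self):
        # each vector: orientation + 3 unit features, sharing only orientation
        v1 = FeatureVector({("NX", "BY"): 1, ("a", "b"): 1, ("c", "d"): 1, ("e", "f"): 1})
        v2 = FeatureVector({("NX", "BY"): 1, ("g", "h"): 1, ("i", "j"): 1, ("k", "l"): 1})
        assert cosine(v1, v2) == pytest.approx(0.25)

    def test_disjoint_features_score_zero(self):
        v1 = extract_features(template(mid=("is",), orientation="NX_BY"))
        v2 = extract_features(template(mid=("as",), orientation="BX_NY"))
        assert cosine(v1, v2) == 0.0

    def test_zero_norm_rejected(self):
        with pytest.raises(ValueError):
            cosine(FeatureVector({}), FeatureVector({("a", "b"): 1}))

    @settings(max_examples=60, deadline=None)
    @given(
        st.lists(st.sampled_from("abcdef"), max_size=4),
        st.lists(st.sampled_from("abcdef"), max_size=4),
    )
    def test_symmetric_and_bounded(self, mid1, mid2):
        v1 = extract_features(template(mid=tuple(mid1)))
        v2 = extract_features(template(mid=tuple(mid2)))
        s = cosine(v1, v2)
        assert s == pytest.approx(cosine(v2, v1))
        assert 0.0 <= s <= 1.0 + 1e-12


class TestRankAndCut:
    def _config(self, **kw):
        defaults = dict(n_min=50, n_max=300, drop_off_min=0.01)
        defaults.update(kw)
        return InductionConfig(**defaults)

    def test_single_large_gap(self):
        scores = [1.0 - 0.0001 * i for i in range(55)] + [
            0.7 - 0.0001 * i for i in range(300)
        ]
        import numpy as np

        assert _cut_ranking(np.array(scores), self._config()) == 55

    def test_flat_scores_rejected(self):
        import numpy as np

        assert _cut_ranking(np.ones(400), self._config()) is None

    def test_tie_breaks_to_smallest_rank(self):
        import numpy as np

        scores = np.ones(400)
        scores[60:] -= 0.5  # gap at rank 60
        scores[120:] -= 0.5  # equal gap at rank 120
        assert _cut_ranking(scores, self._config()) == 60

    def test_matches_scanning_oracle(self, rng):
        import numpy as np

        for _ in range(50):
            scores = sorted(
                (round(rng.random(), 2) for _ in range(400)), reverse=True
            )
            got = _cut_ranking(np.array(scores), self._config())
            assert got == drop_off_cut_bruteforce(scores, 50, 300, 0.01)

    def test_collection_smaller_than_range_errors(self):
        vs = [extract_features(template(mid=("a",))) for _ in range(10)]
        with pytest.raises(ValueError, match="n_max"):
            rank_and_cut(0, vs, self._config())

    def test_query_ranks_first_with_score_one(self):
        rng = random.Random(3)
        vs = [
            extract_features(
                template(mid=tuple(rng.choice("abc") for _ in range(rng.randint(1, 3))))
            )
            for _ in range(400)
        ]
        result = rank_and_cut(7, vs, self._config(drop_off_min=0.0))
        assert result is not None
        assert result.scores[0] == pytest.approx(1.0)
        assert 7 in result.order[: list(result.scores).count(result.scores[0])]
        # scores sorted non-increasing; accepted N in the stated range
        assert all(
            result.scores[i] >= result.scores[i + 1]
            for i in range(len(result.scores) - 1)
        )
        assert 50 <= result.n_cut < 300


class TestSelectSample:
    @pytest.mark.parametrize(
        "n,expected",
        [
            (100, [50, 60, 70, 80, 90]),
            (55, [27, 33, 38, 44, 49]),
            (50, [25, 30, 35, 40, 45]),
        ],
    )
    def test_rank_arithmetic(self, n, expected):
        assert sample_ranks(n) == expected

    def test_indices_come_from_ranked_order(self):
        import numpy as np

        from medcat.pattern_induction import RetrievalResult

        order = np.arange(399, -1, -1)
        result = RetrievalResult(order=order, scores=np.linspace(1, 0, 400), n_cut=100)
        assert select_sample(result) == [int(order[r - 1]) for r in (50, 60, 70, 80, 90)]


class TestFilterFeatures:
    def test_worked_example_feature_set(self):
        from medcat.synthetic_fixtures import (
            WORKED_EXAMPLE_FEATURES,
            table2_fixture,
        )

        sents, pairs = table2_fixture()
        vectors = [
            extract_features(make_templates(s, [p])[0])
            for s, p in zip(sents, pairs)
        ]
        assert filter_features(vectors, 0.8) == WORKED_EXAMPLE_FEATURES

    def test_threshold_is_strict(self):
        v_all = [extract_features(template(mid=("is", "a"))) for _ in range(3)]
        v_all.append(extract_features(template(mid=("is",))))
        # ('X','a'), ('a','Y'), ('is','a') occur in 3/4 of the templates:
        # dropped at a 0.75 threshold because "above" is strict
        assert filter_features(v_all, 0.75) == {("X", "is"), ("is", "Y")}
        # any feature absent from even one template fails a threshold of 1.0
        assert filter_features(v_all, 1.0) == set()

    def test_orientation_always_dropped(self):
        vs = [extract_features(template(mid=("is",))) for _ in range(5)]
        assert ("NX", "BY") not in filter_features(vs, 0.5)

    def test_matches_counting_oracle(self, rng):
        pool = [("a", "b"), ("c", "d"), ("e", "f"), ("g", "h"), ("X", "w")]
        for _ in range(40):
            vectors = [
                FeatureVector(
                    {f: 1 for f in rng.sample(pool, rng.randint(1, len(pool)))}
                )
                for _ in range(10)
            ]
            got = filter_features(vectors, 0.8)
            for f in pool:
                frac = sum(f in v.counts for v in vectors) / 10
                assert (f in got) == (frac > 0.8)


class TestReduceTemplate:
    def test_worked_example_reduction(self):
        from medcat.synthetic_fixtures import WORKED_EXAMPLE_FEATURES

        t = template(prefix=("effects", "of"), mid=("and", "other"))
        assert reduce_template(t, WORKED_EXAMPLE_FEATURES) == ["X", "and", "other", "Y"]

    def test_empty_selection_keeps_only_placeholders(self):
        t = template(prefix=("a",), mid=("b",), suffix=("c",))
        assert reduce_template(t, set()) == ["X", "Y"]

    def test_output_is_subsequence(self, rng):
        words = ["p", "q", "r", "s"]
        feats = [("p", "q"), ("r", "X"), ("Y", "s")]
        for _ in range(60):
            t = template(
                prefix=tuple(rng.choices(words, k=rng.randint(0, 3))),
                mid=tuple(rng.choices(words, k=rng.randint(0, 3))),
                suffix=tuple(rng.choices(words, k=rng.randint(0, 3))),
            )
            selected = set(rng.sample(feats, rng.randint(0, 3)))
            out = reduce_template(t, selected)
            keep = {w for f in selected for w in f}
            full = t.full_tokens()
            assert out == [
                w for w in full if w in ("X", "Y") or w in keep
            ]
            assert len(out) <= len(full)


class TestAlignment:
    def test_gap_versus_match_example(self):
        assert align_pair("X and other Y".split(), "X other Y".split()) == 2.0

    def test_dp_equals_exhaustive_on_short_sequences(self, rng):
        alphabet = ["X", "Y", "and", "other", "is"]
        for _ in range(200):
            a = [rng.choice(alphabet) for _ in range(rng.randint(1, 6))]
            b = [rng.choice(alphabet) for _ in range(rng.randint(1, 6))]
            assert align_pair(a, b) == pytest.approx(align_bruteforce(a, b))

    def test_five_identical_copies_give_that_pattern(self):
        seqs = [["X", "and", "other", "Y"]] * 5
        assert align_and_consensus(seqs).tokens == ("X", "and", "other", "Y")

    def test_identical_sequences_any_content(self):
        seqs = [["X", "is", "a", "Y"]] * 3
        assert align_and_consensus(seqs).tokens == ("X", "is", "a", "Y")

    def test_consensus_without_unanimity_drops_column(self):
        seqs = [
            ["X", "and", "other", "Y"],
            ["X", "and", "other", "Y"],
            ["X", "and", "Y"],
        ]
        pattern = align_and_consensus(seqs)
        assert pattern.tokens == ("X", "and", "Y")

    def test_invalid_consensus_returns_none(self):
        # no shared X column: consensus lacks X
        seqs = [["X", "a", "Y"], ["b", "X", "Y"], ["X", "c", "Y"]]
        cfg = InductionConfig(consensus_min=1.0)
        result = align_and_consensus(seqs, cfg)
        assert result is None or (
            "X" in result.tokens and "Y" in result.tokens
        )

    def test_fewer_than_two_sequences_errors(self):
        with pytest.raises(ValueError):
            align_and_consensus([["X", "Y"]])


class TestInduce:
    def test_zero_iterations(self):
        from medcat.synthetic_fixtures import GeneratorConfig, generate_corpus

        sents, truth = generate_corpus(GeneratorConfig(rng_seed=9))
        cfg = InductionConfig(iterations=0, rng_seed=1)
        assert induce(sents, truth.seed_pairs, cfg) == []

    def test_too_few_templates_errors(self):
        sents = [make_sentence("a/NN is/VVZ a/DD b/NN")] * 5
        with pytest.raises(ValueError, match="templates"):
            induce(sents, [SeedPair("a", "b")], InductionConfig(iterations=1))

    def test_seed_reproducibility(self):
        from medcat.synthetic_fixtures import GeneratorConfig, generate_corpus

        sents, truth = generate_corpus(GeneratorConfig(rng_seed=9))
        cfg = InductionConfig(iterations=40, rng_seed=17)
        run1 = induce(sents, truth.seed_pairs, cfg)
        run2 = induce(sents, truth.seed_pairs, cfg)
        assert [(p.tokens, c) for p, c in run1] == [(p.tokens, c) for p, c in run2]
        assert run1  # the synthetic corpus does yield patterns

    def test_emitted_patterns_are_well_formed(self):
        from medcat.synthetic_fixtures import GeneratorConfig, generate_corpus

        sents, truth = generate_corpus(GeneratorConfig(rng_seed=9))
        cfg = InductionConfig(iterations=40, rng_seed=17)
        for pattern, count in induce(sents, truth.seed_pairs, cfg):
            assert count >= 1
            toks = pattern.tokens
            assert toks.count("X") == 1 and toks.count("Y") == 1
            assert toks.index("X") < toks.index("Y")
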