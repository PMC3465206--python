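"""Independent brute-force oracles used to cross-check the implementation.

Each function here re-derives a quantity from first principles (exhaustive
enumeration, rational arithmetic, regular-expression matching) without
sharing code with the package.
"""

from __future__ import annotations

import itertools
import re
from collections import Counter, defaultdict
from fractions import Fraction
from math import comb


def features_bruteforce(
    prefix: tuple[str, ...],
    mid: tuple[str, ...],
    suffix: tuple[str, ...],
    orientation: str,
) -> Counter:
    """Enumerate ordered-pair features by classifying every position pair of
    the full token sequence prefix + [X] + mid + [Y] + suffix."""
    seq = list(prefix) + ["X"] + list(mid) + ["Y"] + list(suffix)
    x = len(prefix)
    y = x + 1 + len(mid)
    feats: Counter = Counter()
    for p, q in itertools.combinations(range(len(seq)), 2):
        if q < x or (x < p and q < y) or y < p:
            feats[(seq[p], seq[q])] += 1  # within one segment
        elif q == x or p == x and q < y or (x < p < y and q == y) or p == y:
            feats[(seq[p], seq[q])] += 1  # pair with adjacent placeholder
    feats[("NX", "BY") if orientation == "NX_BY" else ("BX", "NY")] += 1
    return feats


def chunk_bruteforce(tag_classes_string: str) -> list[tuple[int, int]]:
    """NP spans over a tag-class string ('d' determiner, 'j' adjective,
    'n' noun, 'o' other) via a leftmost-greedy regular expression."""
    return [m.span() for m in re.finditer(r"d?[jn]*n", tag_classes_string)]


def align_bruteforce(
    a: list[str], b: list[str], match: float = 1.0, mismatch: float = -1.0,
    gap: float = -1.0,
) -> float:
    """Optimal global alignment score by enumerating every monotone matching
    between the two sequences (feasible for lengths <= 6)."""
    best = gap * (len(a) + len(b))  # align nothing
    ia, ib = range(len(a)), range(len(b))
    for m in range(1, min(len(a), len(b)) + 1):
        for pa in itertools.combinations(ia, m):
            for pb in itertools.combinations(ib, m):
                score = sum(
                    match if a[i] == b[j] else mismatch for i, j in zip(pa, pb)
                ) + gap * (len(a) - m + len(b) - m)
                best = max(best, score)
    return best


def hypergeom_tail_exact(
    intersection: int, universe: int, size_b: int, size_a: int
) -> Fraction:
    """P[overlap >= intersection] by exact rational tail summation."""
    total = comb(universe, size_a)
    upper = min(size_a, size_b)
    return Fraction(
        sum(
            comb(size_b, k) * comb(universe - size_b, size_a - k)
            for k in range(intersection, upper + 1)
        ),
        total,
    )


def aggregate_bruteforce(
    matches: list[tuple[str, str, str]], min_support: int
) -> dict[str, dict]:
    """Independent group-by over (instance, category_phrase, headword)
    triples: support, subcategory counts, instance-by-subcategory counts."""
    out: dict[str, dict] = {}
    by_head: dict[str, list[tuple[str, str]]] = defaultdict(list)
    for inst, phrase, head in matches:
        by_head[head].append((inst, phrase))
    for head, rows in by_head.items():
        if len(rows) < min_support:
            continue
        out[head] = {
            "support": len(rows),
            "subcategories": dict(Counter(p for _, p in rows)),
            "instances": {
                inst: dict(
                    Counter(p for i2, p in rows if i2 == inst)
                )
                for inst in {i for i, _ in rows}
            },
        }
    return out


def noun_doc_counts_bruteforce(
    docs: dict[str, list[list[tuple[str, str]]]],
) -> tuple[dict[str, int], dict[str, int]]:
    """Per-noun document frequencies recounted document by document.

    ``docs`` maps doc_id -> sentences -> list of (lowercased-normalized
    word, tag class in {'n','j','d','o'}).
    """
    doc_freq: Counter = Counter()
    standalone: Counter = Counter()
    for sentences in docs.values():
        nouns: set[str] = set()
        alone: set[str] = set()
        for sent in sentences:
            for i, (word, cls) in enumerate(sent):
                if cls != "n":
                    continue
                nouns.add(word)
                prev_ok = i == 0 or sent[i - 1][1] not in ("n", "j")
                next_ok = i == len(sent) - 1 or sent[i + 1][1] not in ("n", "j")
                if prev_ok and next_ok:
                    alone.add(word)
        for w in nouns:
            doc_freq[w] += 1
        for w in alone:
            standalone[w] += 1
    return dict(doc_freq), dict(standalone)


def drop_off_cut_bruteforce(
    scores_sorted: list[float], n_min: int, n_max: int, drop_off_min: float
) -> int | None:
    """Largest-gap cut by direct scanning (1-based ranks, first maximum)."""
    best_i, best_delta = None, None
    for i in range(n_min, n_max):
        delta = scores_sorted[i - 1] - scores_sorted[i]
        if best_delta is None or delta > best_delta:
            best_i, best_delta = i, delta
    if best_delta is None or best_delta < drop_off_min:
        return None
    return best_i
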