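"""Overlap statistics between two noun sets.

Reports the intersection count, the percentage of set A found in set B
(rounded to the nearest integer percent), and the significance of the
overlap as -log10 of a one-sided hypergeometric upper-tail probability
P[overlap >= observed] given an explicit universe size.  The tail is
evaluated in log space so astronomically small p-values survive.

The universe is a required parameter: overlap significance is meaningless
without stating the population the two sets were drawn from.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Collection

from scipy import stats

__all__ = ["OverlapReport", "overlap", "overlap_counts"]


@dataclass(frozen=True)
class OverlapReport:
    size_a: int
    size_b: int
    intersection_count: int
    percentage_of_a: int
    neg_log10_p: float


def overlap_counts(
    size_a: int, size_b: int, intersection: int, universe_size: int
) -> OverlapReport:
    """Overlap report from pre-computed counts.

    ``percentage_of_a`` is 100 * intersection / size_a rounded half-up to
    the nearest integer.  ``neg_log10_p`` is the hypergeometric upper tail
    P[X >= intersection] for drawing ``size_a`` items out of a universe
    containing ``size_b`` marked items, in -log10 units.
    """
    if size_a < 1:
        raise ValueError("set A must be non-empty")
    if intersection > min(size_a, size_b):
        raise ValueError("intersection exceeds a set size")
    union_lower_bound = size_a + size_b - intersection
    if universe_size < union_lower_bound:
        raise ValueError(
            f"universe size {universe_size} is smaller than the union "
            f"(at least {union_lower_bound})"
        )
    pct = math.floor(100 * intersection / size_a + 0.5)
    if intersection == 0:
        neg_log10_p = 0.0
    else:
        log_sf = stats.hypergeom.logsf(
            intersection - 1, universe_size, size_b, size_a
        )
        neg_log10_p = -log_sf / math.log(10)
    return OverlapReport(
        size_a=size_a,
        size_b=size_b,
        intersection_count=intersection,
        percentage_of_a=pct,
        neg_log10_p=float(neg_log10_p),
    )


def overlap(
    set_a: Collection[str], set_b: Collection[str], universe_size: int
) -> OverlapReport:
    """Overlap report between two noun sets over an explicit universe."""
    a, b = set(set_a), set(set_b)
    return overlap_counts(len(a), len(b), len(a & b), universe_size)
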