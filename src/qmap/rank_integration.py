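"""Rank mutant pairs per screen and combine rankings across screens.

Raw interaction scores from different platforms are not on a common scale,
so integration is done on ranks: each screen ranks its shared mutant pairs
by evidence for interaction (rank 1 = strongest), and per-pair ranks are
combined with one of four aggregation functions - minimum, maximum,
product (the rank product of meta-analysis) and Borda count (the sum of
ranks). Aggregation depends only on the rank order, so it is invariant to
any strictly monotone transform of the underlying scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ValidationError
from .interaction_scoring import ScoreMatrix

AGGREGATION_METHODS = ("minimum", "maximum", "product", "borda")


@dataclass
class RankedPairs:
    """Average-tie ranks over a list of pairs for one screen and direction.

    ``direction='positive'`` ranks descending by score (most positive pair
    gets rank 1); ``'negative'`` ascending. Ranks sum to N(N+1)/2.
    """

    pairs: list[tuple[str, str]]
    ranks: np.ndarray
    direction: str
    source: str = ""

    def __post_init__(self) -> None:
        self.ranks = np.asarray(self.ranks, dtype=float)
        if len(self.pairs) != self.ranks.size:
            raise ValidationError("pairs and ranks must be aligned")
        if self.direction not in ("positive", "negative"):
            raise ValidationError(
                f"direction must be 'positive' or 'negative', got {self.direction!r}"
            )


@dataclass
class AggregatedRanking:
    """Combined ranking over pairs present in all input screens.

    ``final_order`` sorts pairs ascending by aggregate value (strongest
    combined evidence first), ties broken by pair identifier.
    """

    pairs: list[tuple[str, str]]
    aggregate_values: np.ndarray
    method: str
    final_order: list[int]

    def ordered_pairs(self) -> list[tuple[str, str]]:
        return [self.pairs[i] for i in self.final_order]


def rank_pairs(sm: ScoreMatrix, pairs: list[tuple[str, str]],
               direction: str = "positive") -> RankedPairs:
    """Rank the given (query, array) pairs by their score in ``sm``.

    Ties get average ranks; pairs with undefined scores are dropped (the
    returned object covers only defined pairs, in request order).
    """
    if not pairs:
        raise ValidationError("empty pair list")
    if direction not in ("positive", "negative"):
        raise ValidationError(
            f"direction must be 'positive' or 'negative', got {direction!r}"
        )
    qidx = {g: i for i, g in enumerate(sm.query_ids)}
    aidx = {g: i for i, g in enumerate(sm.array_ids)}
    vals = []
    kept = []
    for (q, a) in pairs:
        if q not in qidx or a not in aidx:
            raise ValidationError(f"pair ({q!r}, {a!r}) not present in score matrix")
        v = sm.scores[qidx[q], aidx[a]]
        if np.isnan(v):
            continue
        vals.append(float(v))
        kept.append((q, a))
    if not kept:
        raise ValidationError("no defined scores among the requested pairs")
    arr = np.asarray(vals)
    ranks = stats.rankdata(-arr if direction == "positive" else arr, method="average")
    return RankedPairs(pairs=kept, ranks=ranks, direction=direction, source=sm.name)


def aggregate_ranks(rankings: list[RankedPairs], method: str) -> AggregatedRanking:
    """Combine two or more rankings of the same direction.

    Only pairs ranked in every input are aggregated; each input's ranks are
    first re-ranked within that common intersection (preserving order and
    ties) so that all screens share one rank scale regardless of how many
    pairs each ranked originally. The aggregate per pair is the minimum,
    maximum, product or sum (Borda count) of its per-screen ranks; the
    final order is ascending by aggregate, ties broken lexicographically by
    pair identifier for determinism.
    """
    if len(rankings) < 2:
        raise ValidationError("need at least two rankings to aggregate")
    if method not in AGGREGATION_METHODS:
        raise ValidationError(
            f"unknown aggregation method {method!r}; expected one of {AGGREGATION_METHODS}"
        )
    directions = {r.direction for r in rankings}
    if len(directions) != 1:
        raise ValidationError(f"direction mismatch across rankings: {directions}")
    common = set(rankings[0].pairs)
    for r in rankings[1:]:
        common &= set(r.pairs)
    if not common:
        raise ValidationError("rankings share no common pairs")
    pairs = sorted(common)
    rank_columns = []
    for r in rankings:
        pos = {p: i for i, p in enumerate(r.pairs)}
        sub = np.array([r.ranks[pos[p]] for p in pairs])
        rank_columns.append(stats.rankdata(sub, method="average"))
    R = np.column_stack(rank_columns)
    if method == "minimum":
        agg = R.min(axis=1)
    elif method == "maximum":
        agg = R.max(axis=1)
    elif method == "product":
        agg = R.prod(axis=1)
    else:  # borda
        agg = R.sum(axis=1)
    final_order = sorted(range(len(pairs)), key=lambda i: (agg[i], pairs[i]))
    return AggregatedRanking(pairs=pairs, aggregate_values=agg, method=method,
                             final_order=final_order)
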