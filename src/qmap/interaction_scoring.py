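"""Residual interaction scores from a fitness matrix and a QMA fit.

The interaction score of a mutant pair (a, b) is the residual
s_ab = w_ab - s(x_a, y_b) under a chosen null/scoring function s. A large
positive score is evidence for an alleviating (positive) interaction, a
large negative score for an aggravating (negative) one, with synthetic
lethality (w_ab = 0) the extreme negative case; scores near zero mark
non-interacting pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .fitness_io import FitnessMatrix
from .qma_core import (POSITIVITY_FLOOR, SingleMutantEstimates,
                       expected_fitness, qma_estimate)

SCORING_FUNCTIONS = ("product", "minimum", "maximum", "scaled_epistasis")


@dataclass
class ScoreMatrix:
    """Signed residual interaction scores aligned with a fitness matrix.

    A score is defined only where the fitness value and both single-mutant
    estimates are defined. ``provenance`` records the QMA parameters used.
    """

    query_ids: list[str]
    array_ids: list[str]
    scores: np.ndarray
    null_fn: str = "product"
    name: str = ""
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.query_ids), len(self.array_ids)):
            raise ValidationError(
                f"score shape {self.scores.shape} does not match id lists"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.scores.shape

    def score_at(self, query: str, array: str) -> float:
        a = self.query_ids.index(query)
        b = self.array_ids.index(array)
        return float(self.scores[a, b])


def score_interactions(fm: FitnessMatrix, est: SingleMutantEstimates,
                       null_fn: str = "product") -> ScoreMatrix:
    """Compute s_ab = w_ab - s(x_a, y_b) for every defined cell.

    For ``null_fn="scaled_epistasis"`` the product residual is normalised by
    a sign-dependent distance: above the null expectation it is divided by
    |min(x_a, y_b) - x_a*y_b| (distance to the masking bound), below it by
    x_a*y_b (distance to lethality), the denominator floored at 1e-8. This
    maps residuals onto a comparable [-1, ~1] epistasis scale.
    """
    if est.x.shape[0] != fm.shape[0] or est.y.shape[0] != fm.shape[1]:
        raise ValidationError(
            f"estimate lengths ({est.x.shape[0]}, {est.y.shape[0]}) do not "
            f"match matrix shape {fm.shape}"
        )
    if null_fn not in SCORING_FUNCTIONS:
        raise ValidationError(
            f"unknown scoring function {null_fn!r}; expected one of {SCORING_FUNCTIONS}"
        )
    with np.errstate(invalid="ignore"):
        if null_fn == "scaled_epistasis":
            expected = expected_fitness(est, "product")
            resid = fm.values - expected
            minimum = np.minimum(est.x[:, None], est.y[None, :])
            denom = np.where(resid >= 0, np.abs(minimum - expected), expected)
            denom = np.maximum(denom, POSITIVITY_FLOOR)
            scores = resid / denom
        else:
            scores = fm.values - expected_fitness(est, null_fn)
    return ScoreMatrix(
        query_ids=list(fm.query_ids), array_ids=list(fm.array_ids),
        scores=scores, null_fn=null_fn, name=fm.name,
        provenance={"p": est.p, "q": est.q, "iterations": est.iterations_run,
                    "null_fn": null_fn},
    )


def median_baseline_score(fm: FitnessMatrix, min_obs: int = 5) -> ScoreMatrix:
    """The median-baseline score: single-pass QMA with p = q = 0.5 and the
    product scoring function.

    Definitionally equal, cell for cell, to
    ``score_interactions(fm, qma_estimate(fm, 0.5, 0.5, max_iter=1), "product")``.
    """
    est = qma_estimate(fm, p=0.5, q=0.5, max_iter=1, min_obs=min_obs)
    return score_interactions(fm, est, "product")


def call_extremes(sm: ScoreMatrix, tail_fraction: float = 0.03,
                  combined: bool = False,
                  ) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Call candidate interactions in the extreme tails of the score
    distribution.

    Returns ``(positive_calls, negative_calls)``: pairs at or above the
    (1 - tail_fraction) quantile and at or below the tail_fraction quantile
    of all defined scores. With ``combined=True`` the fraction is split
    across both tails (tail_fraction/2 each) instead of applied per tail.
    Pairs exactly at a quantile boundary are included in the tail; in the
    degenerate all-equal case both tails are empty.
    """
    pos_mask, neg_mask = extreme_tail_masks(sm.scores, tail_fraction, combined)
    pos = [(sm.query_ids[a], sm.array_ids[b]) for a, b in np.argwhere(pos_mask)]
    neg = [(sm.query_ids[a], sm.array_ids[b]) for a, b in np.argwhere(neg_mask)]
    return pos, neg


def extreme_tail_masks(scores: np.ndarray, tail_fraction: float,
                       combined: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Boolean masks of the upper and lower extreme tails of ``scores``.

    Implements the tail rule of :func:`call_extremes` on a bare array:
    upper tail = scores at/above the (1 - f) quantile of defined values
    (and strictly above the lower threshold, which empties both tails in
    the degenerate all-equal case); lower tail mirrored.
    """
    scores = np.asarray(scores, dtype=float)
    if not (0.0 < tail_fraction < 0.5):
        raise ValidationError(
            f"tail_fraction must lie strictly between 0 and 0.5; got {tail_fraction}"
        )
    defined = ~np.isnan(scores)
    if not np.any(defined):
        raise ValidationError("no defined scores to call extremes on")
    f = tail_fraction / 2 if combined else tail_fraction
    vals = scores[defined]
    lo = np.quantile(vals, f)
    hi = np.quantile(vals, 1.0 - f)
    with np.errstate(invalid="ignore"):
        pos_mask = defined & (scores >= hi) & (scores > lo)
        neg_mask = defined & (scores <= lo) & (scores < hi)
    return pos_mask, neg_mask
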