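"""Pairwise comparison of two screens over their shared mutant pairs.

Screens from different platforms cover different query x array universes;
all comparisons here are restricted to the pairs measured (with a defined
value) in both. The module provides the intersection machinery, overall
Pearson/Spearman agreement, the extreme-tail prediction AUC (how well one
screen's scores predict the other's most extreme pairs), and the grid-wise
hypergeometric enrichment of reference interactions in a rank-rank scatter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ValidationError
from .interaction_scoring import ScoreMatrix, extreme_tail_masks
from .roc_evaluation import roc_curve

logger = logging.getLogger(__name__)

P_CLAMP_LO = 1e-100
P_CLAMP_HI = 0.99


def _values_of(mat) -> np.ndarray:
    v = getattr(mat, "scores", None)
    return v if v is not None else mat.values


@dataclass
class PairIntersection:
    """Shared (query, array) pairs of two matrices with values from both."""

    shared_query_ids: list[str]
    shared_array_ids: list[str]
    pairs: list[tuple[str, str]]
    a_values: np.ndarray
    b_values: np.ndarray

    @property
    def size(self) -> int:
        return len(self.pairs)


def intersect_datasets(a, b, allow_transpose: bool = False) -> PairIntersection:
    """Match cells of two matrices by (query, array) identifiers.

    A pair contributes when its value is defined in both matrices. With
    ``allow_transpose`` (for symmetric screens) a pair (q, r) in ``a`` also
    matches (r, q) in ``b``; if both orientations are defined in ``b`` their
    values are averaged, consistent with the duplicate-mean rule. An empty
    intersection is returned (and logged), not raised.
    """
    av, bv = _values_of(a), _values_of(b)
    b_qidx = {g: i for i, g in enumerate(b.query_ids)}
    b_aidx = {g: i for i, g in enumerate(b.array_ids)}

    def b_lookup(q: str, r: str) -> float:
        vals = []
        if q in b_qidx and r in b_aidx:
            v = bv[b_qidx[q], b_aidx[r]]
            if not np.isnan(v):
                vals.append(v)
        if allow_transpose and r in b_qidx and q in b_aidx:
            v = bv[b_qidx[r], b_aidx[q]]
            if not np.isnan(v):
                vals.append(v)
        return float(np.mean(vals)) if vals else np.nan

    pairs: list[tuple[str, str]] = []
    a_vals: list[float] = []
    b_vals: list[float] = []
    for i, q in enumerate(a.query_ids):
        for j, r in enumerate(a.array_ids):
            if np.isnan(av[i, j]):
                continue
            w = b_lookup(q, r)
            if np.isnan(w):
                continue
            pairs.append((q, r))
            a_vals.append(float(av[i, j]))
            b_vals.append(w)
    shared_q = sorted({p[0] for p in pairs})
    shared_a = sorted({p[1] for p in pairs})
    if not pairs:
        logger.info("empty intersection between %r and %r",
                    getattr(a, "name", "?"), getattr(b, "name", "?"))
    return PairIntersection(shared_query_ids=shared_q, shared_array_ids=shared_a,
                            pairs=pairs, a_values=np.asarray(a_vals),
                            b_values=np.asarray(b_vals))


def correlations(a_values, b_values) -> tuple[float, float]:
    """Pearson and Spearman correlation over complete cases.

    Spearman uses average ranks for ties. Returns ``(nan, nan)`` (flagged by
    NaN, not an exception) with fewer than 3 complete pairs or zero
    variance in either vector.
    """
    a = np.asarray(a_values, dtype=float)
    b = np.asarray(b_values, dtype=float)
    ok = ~np.isnan(a) & ~np.isnan(b)
    a, b = a[ok], b[ok]
    if a.size < 3 or np.ptp(a) == 0 or np.ptp(b) == 0:
        return (np.nan, np.nan)
    pearson = float(stats.pearsonr(a, b).statistic)
    spearman = float(stats.spearmanr(a, b).statistic)
    return (pearson, spearman)


def extreme_agreement_auc(reference: ScoreMatrix, predictor: ScoreMatrix,
                          pairs: PairIntersection | None = None,
                          tail_fraction: float = 0.03,
                          tail: str = "positive",
                          allow_transpose: bool = False) -> float:
    """AUC for predicting the reference screen's extreme-tail pairs from the
    predictor screen's scores, over the shared pairs.

    ``pairs`` must have been built with the reference as the first matrix
    (``intersect_datasets(reference, predictor)``); it is computed here when
    omitted. Labels mark membership of each shared pair in the reference's
    extreme ``tail`` (same tail rule as
    :func:`~qmap.interaction_scoring.call_extremes`, applied to the
    shared-pair reference values); scores are the predictor's values,
    negated for the negative tail so that higher still means stronger.
    Returns NaN if the tail is empty or covers everything.
    """
    if pairs is None:
        pairs = intersect_datasets(reference, predictor, allow_transpose)
    if tail not in ("positive", "negative"):
        raise ValidationError(f"tail must be 'positive' or 'negative', got {tail!r}")
    pos_mask, neg_mask = extreme_tail_masks(pairs.a_values, tail_fraction)
    labels = pos_mask if tail == "positive" else neg_mask
    if labels.sum() == 0 or labels.all():
        return np.nan
    scores = pairs.b_values if tail == "positive" else -pairs.b_values
    return roc_curve(scores, labels).auc


def hypergeom_upper(K: int, M: int, t: int, found: int) -> float:
    """Upper-tail hypergeometric probability P(X >= found) for drawing t
    pairs from K of which M are class interactions, clamped to
    [1e-100, 0.99].
    """
    if not (0 <= M <= K):
        raise ValidationError(f"need 0 <= M <= K; got M={M}, K={K}")
    if not (0 <= found <= t <= K):
        raise ValidationError(f"need 0 <= found <= t <= K; got found={found}, t={t}, K={K}")
    p = float(stats.hypergeom.sf(found - 1, K, M, t))
    return float(np.clip(p, P_CLAMP_LO, P_CLAMP_HI))


@dataclass
class EnrichmentGrid:
    """Grid-wise enrichment of reference interactions in a rank-rank scatter.

    Each axis of the scatter (rank in screen a vs rank in screen b) is cut
    into ``grid_dim`` equal-count bins; per cell, an upper-tail
    hypergeometric p-value is computed for each interaction class.
    """

    grid_dim: int
    a_bounds: np.ndarray
    b_bounds: np.ndarray
    counts: np.ndarray
    positive_found: np.ndarray
    negative_found: np.ndarray
    positive_p: np.ndarray
    negative_p: np.ndarray


def _equal_count_bins(ranks: np.ndarray, grid_dim: int) -> tuple[np.ndarray, np.ndarray]:
    bounds = np.quantile(ranks, np.arange(1, grid_dim) / grid_dim)
    # side="left": a value equal to a boundary goes to the lower bin
    bins = np.searchsorted(bounds, ranks, side="left")
    return bins, bounds


def enrichment_grid(a_ranks, b_ranks, positive_labels, negative_labels,
                    grid_dim: int = 6) -> EnrichmentGrid:
    """Hypergeometric enrichment of positive and negative interactions per
    cell of a ``grid_dim`` x ``grid_dim`` rank-rank grid.

    Bins are equal-count along each rank axis (ties at a boundary fall to
    the lower bin). Per cell, K = total pairs, M = class total, t = cell
    size, found = class count in the cell.
    """
    a = np.asarray(a_ranks, dtype=float)
    b = np.asarray(b_ranks, dtype=float)
    pos = np.asarray(positive_labels, dtype=bool)
    neg = np.asarray(negative_labels, dtype=bool)
    if not (a.size == b.size == pos.size == neg.size):
        raise ValidationError("rank and label vectors must be aligned")
    if grid_dim < 2:
        raise ValidationError("grid_dim must be >= 2")
    if a.size < grid_dim ** 2:
        raise ValidationError(
            f"need at least grid_dim^2 = {grid_dim ** 2} pairs, got {a.size}"
        )
    a_bins, a_bounds = _equal_count_bins(a, grid_dim)
    b_bins, b_bounds = _equal_count_bins(b, grid_dim)
    K = a.size
    M_pos, M_neg = int(pos.sum()), int(neg.sum())
    shape = (grid_dim, grid_dim)
    counts = np.zeros(shape, dtype=int)
    found_pos = np.zeros(shape, dtype=int)
    found_neg = np.zeros(shape, dtype=int)
    p_pos = np.empty(shape)
    p_neg = np.empty(shape)
    for i in range(grid_dim):
        for j in range(grid_dim):
            cell = (a_bins == i) & (b_bins == j)
            t = int(cell.sum())
            mp, mn = int(pos[cell].sum()), int(neg[cell].sum())
            counts[i, j] = t
            found_pos[i, j] = mp
            found_neg[i, j] = mn
            p_pos[i, j] = hypergeom_upper(K, M_pos, t, mp)
            p_neg[i, j] = hypergeom_upper(K, M_neg, t, mn)
    return EnrichmentGrid(grid_dim=grid_dim, a_bounds=a_bounds, b_bounds=b_bounds,
                          counts=counts, positive_found=found_pos,
                          negative_found=found_neg, positive_p=p_pos,
                          negative_p=p_neg)
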