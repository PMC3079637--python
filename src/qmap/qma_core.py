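"""Quantile-based rank-one multiplicative matrix approximation (QMA).

Most mutant pairs in a large-scale screen do not interact, so the
double-mutant fitness matrix W is approximately rank one under the
multiplicative null model of epistasis, w_ab = w_a * w_b. QMA exploits this
to recover single-mutant fitness vectors x (queries, rows) and y (arrays,
columns) directly from W, without separate single-mutant growth experiments:
row and column quantiles are computed alternately, in the spirit of Tukey's
median polish but multiplicative and with arbitrary quantile levels p and q
instead of medians. Quantiles are robust to the minority of genuinely
interacting cells, which appear as outliers relative to the rank-one bulk.

Gauge convention: the decomposition is identifiable only up to x -> c*x,
y -> y/c. Here x is anchored in fitness units by its initialisation from raw
row quantiles of W, and y is estimated from ratio quantiles w_ab / x_a, which
places it in fitness units as well (median-normalised screens have
single-mutant fitness near 1). No post-hoc rescaling is applied. Note the
orientation: x is indexed by rows (query strains) and y by columns (array
strains) throughout this package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EstimationError, ValidationError
from .fitness_io import FitnessMatrix

#: Denominators below this are excluded from ratio quantiles; estimates that
#: come out below it (all-lethal rows/columns) are raised to it.
POSITIVITY_FLOOR = 1e-8

NULL_FUNCTIONS = ("product", "minimum", "maximum", "scaled_epistasis_base")


@dataclass
class SingleMutantEstimates:
    """Estimated single-mutant fitness vectors from a QMA fit.

    ``x`` has one entry per query strain (row), ``y`` one per array strain
    (column); entries are NaN where fewer than ``min_obs`` observations
    supported the estimate. ``p`` and ``q`` are the row/column quantile
    levels used; ``iterations_run`` counts full (y, x) alternations.
    """

    x: np.ndarray
    y: np.ndarray
    p: float
    q: float
    iterations_run: int = 0

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        for vec, label in ((self.x, "x"), (self.y, "y")):
            if np.any(vec[~np.isnan(vec)] < 0):
                raise ValidationError(f"{label} contains negative fitness estimates")


def _quantile(values: np.ndarray, level: float, axis: int) -> np.ndarray:
    """Linear-interpolation ("type 7") quantile over present entries."""
    with np.errstate(all="ignore"):
        counts = np.sum(~np.isnan(values), axis=axis)
        out = np.full(counts.shape, np.nan)
        ok = counts > 0
        if np.any(ok):
            sub = np.take(values, np.nonzero(ok)[0], axis=1 - axis)
            out[ok] = np.nanquantile(sub, level, axis=axis, method="linear")
        return out


def qma_estimate(fm: FitnessMatrix, p: float = 0.5, q: float = 0.5,
                 max_iter: int = 20, tol: float = 1e-6,
                 min_obs: int = 5) -> SingleMutantEstimates:
    """Fit the rank-one multiplicative model W ~ x (outer) y by alternating
    row p-quantiles and column q-quantiles.

    Parameters
    ----------
    p, q
        Quantile levels in [0, 1] for the row (query) and column (array)
        updates. The default 0.5/0.5 is the median baseline.
    max_iter
        Maximum number of full alternations (y-update then x-update); at
        least one alternation is always performed.
    tol
        Convergence threshold on the maximum relative change of the
        concatenated (x, y) between alternations.
    min_obs
        Rows or columns with fewer usable observations than this get an
        undefined (NaN) estimate; scores depending on them stay undefined.

    Notes
    -----
    Update scheme: x is initialised as the row p-quantiles of W; then
    y_b <- q-quantile over rows a of w_ab / x_a (denominators below the
    positivity floor are skipped) and x_a <- p-quantile over columns b of
    w_ab / y_b, repeated until converged. A strictly positive rank-one
    matrix is a fixed point after the first alternation, for any (p, q).
    """
    if not (0.0 <= p <= 1.0 and 0.0 <= q <= 1.0):
        raise ValidationError(f"quantile levels must lie in [0, 1]; got p={p}, q={q}")
    if max_iter < 1:
        raise ValidationError("max_iter must be >= 1")
    if min_obs < 1:
        raise ValidationError("min_obs must be >= 1")
    W = fm.values
    if not np.any(~np.isnan(W)):
        raise EstimationError("cannot approximate an all-missing matrix")

    present = ~np.isnan(W)
    x = _quantile(W, p, axis=1)
    x[present.sum(axis=1) < min_obs] = np.nan
    x = _apply_floor(x)
    y = np.full(W.shape[1], np.nan)

    iterations = 0
    for _ in range(max_iter):
        x_old, y_old = x, y
        denom_x = np.where(np.isnan(x) | (x < POSITIVITY_FLOOR), np.nan, x)
        ratios = W / denom_x[:, None]
        y = _quantile(ratios, q, axis=0)
        y[np.sum(~np.isnan(ratios), axis=0) < min_obs] = np.nan
        y = _apply_floor(y)

        denom_y = np.where(np.isnan(y) | (y < POSITIVITY_FLOOR), np.nan, y)
        ratios = W / denom_y[None, :]
        x = _quantile(ratios, p, axis=1)
        x[np.sum(~np.isnan(ratios), axis=1) < min_obs] = np.nan
        x = _apply_floor(x)

        iterations += 1
        if _max_relative_change(x_old, x) < tol and _max_relative_change(y_old, y) < tol:
            break

    return SingleMutantEstimates(x=x, y=y, p=p, q=q, iterations_run=iterations)


def _apply_floor(vec: np.ndarray) -> np.ndarray:
    defined = ~np.isnan(vec)
    vec[defined & (vec < POSITIVITY_FLOOR)] = POSITIVITY_FLOOR
    return vec


def _max_relative_change(old: np.ndarray, new: np.ndarray) -> float:
    both = ~np.isnan(old) & ~np.isnan(new)
    if not np.any(both):
        return np.inf
    denom = np.maximum(np.abs(old[both]), POSITIVITY_FLOOR)
    return float(np.max(np.abs(new[both] - old[both]) / denom))


def expected_fitness(est: SingleMutantEstimates, null_fn: str = "product") -> np.ndarray:
    """Expected neutral double-mutant fitness s(x_a, y_b) for every cell.

    ``null_fn`` is one of ``product`` (the multiplicative null, and the base
    for scaled epistasis, alias ``scaled_epistasis_base``), ``minimum`` or
    ``maximum``. Cells where either estimate is undefined are NaN.
    """
    x, y = est.x[:, None], est.y[None, :]
    if null_fn in ("product", "scaled_epistasis_base"):
        return x * y
    if null_fn == "minimum":
        return np.minimum(x, y)
    if null_fn == "maximum":
        return np.maximum(x, y)
    raise ValidationError(
        f"unknown scoring function {null_fn!r}; expected one of {NULL_FUNCTIONS}"
    )
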