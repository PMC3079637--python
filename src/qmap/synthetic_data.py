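"""Synthetic double-mutant fitness screens with known ground truth.

The generator produces screens whose non-interacting bulk follows the
multiplicative null exactly: single-mutant fitness vectors x and y are
drawn from a truncated normal centred at 1 (median-normalised screens have
median fitness near unity), and the baseline matrix is their outer
product. A small fraction of cells (~3% combined by default, matching the
interaction-rate estimate from unbiased screens) is planted as genuine
interactions by multiplying the cell by an alleviation factor gamma > 1
(positive) or an aggravation factor gamma < 1 (negative), with a share of
the negatives set to exact 0 (synthetic lethality). Measurement error is
multiplicative log-normal noise, applied per cell; missingness is MCAR;
a fraction of strains can be duplicated (same identifier, independent
noise) to exercise the duplicate-merging path.

What this emulates - and what it does not: real screens additionally carry
plate/batch spatial effects, same-chromosome linkage artifacts and
strain-specific biases, which the source platforms remove upstream. Tests
passing on these screens therefore validate the scoring machinery, not
robustness to those artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ValidationError
from .fitness_io import FitnessMatrix


@dataclass
class ScreenParams:
    """Generation parameters for one synthetic screen.

    Defaults give a 200 x 100 screen with single-mutant fitness
    ~ TruncNormal(1.0, 0.15) on [0.05, 1.5], 1.5% planted positive and
    1.5% planted negative interactions (3% combined), alleviation factors
    U(1.4, 2.5), aggravation factors U(0, 0.6) with 10% of negatives
    lethal, 10% log-scale multiplicative noise, 5% missing cells and 5%
    duplicated strains.
    """

    m: int = 200
    n: int = 100
    fitness_mean: float = 1.0
    fitness_sd: float = 0.15
    fitness_bounds: tuple[float, float] = (0.05, 1.5)
    rho_pos: float = 0.015
    rho_neg: float = 0.015
    gamma_pos_range: tuple[float, float] = (1.4, 2.5)
    gamma_neg_range: tuple[float, float] = (0.0, 0.6)
    lethal_fraction: float = 0.1
    noise_sd: float = 0.1
    missing_fraction: float = 0.05
    duplicate_fraction: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.m < 1 or self.n < 1:
            raise ValidationError("dimensions must be positive")
        if not (0 <= self.rho_pos and 0 <= self.rho_neg
                and self.rho_pos + self.rho_neg < 0.5):
            raise ValidationError("need rho_pos, rho_neg >= 0 and rho_pos + rho_neg < 0.5")
        for rng_name in ("fitness_bounds", "gamma_pos_range", "gamma_neg_range"):
            lo, hi = getattr(self, rng_name)
            if lo > hi:
                raise ValidationError(f"{rng_name} must be ordered, got ({lo}, {hi})")
        if self.gamma_pos_range[0] <= 1.0:
            raise ValidationError("gamma_pos_range must lie above 1 (alleviation)")
        if not (0 <= self.gamma_neg_range[0] and self.gamma_neg_range[1] < 1.0):
            raise ValidationError("gamma_neg_range must lie in [0, 1) (aggravation)")
        for frac_name in ("lethal_fraction", "missing_fraction", "duplicate_fraction"):
            v = getattr(self, frac_name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{frac_name} must lie in [0, 1], got {v}")
        if self.noise_sd < 0 or self.fitness_sd < 0:
            raise ValidationError("standard deviations must be non-negative")


@dataclass
class SyntheticScreen:
    """A generated screen with its ground truth.

    ``fm`` may contain duplicated strains (repeated identifiers appended
    after the unique block); ``true_x``, ``true_y`` and the planted-pair
    masks refer to the m x n unique-strain grid, which is exactly what
    ``merge_duplicates(fm)`` aligns back to.
    """

    fm: FitnessMatrix
    true_x: np.ndarray
    true_y: np.ndarray
    pos_mask: np.ndarray
    neg_mask: np.ndarray
    params: ScreenParams


def _truncated_normal(rng: np.random.Generator, size: int, mean: float,
                      sd: float, bounds: tuple[float, float]) -> np.ndarray:
    """Rejection-sampled truncated normal (bounds are far from degenerate
    for realistic parameters, so this converges in a few rounds)."""
    lo, hi = bounds
    if sd == 0:
        return np.full(size, np.clip(mean, lo, hi))
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=2 * (size - filled))
        draw = draw[(draw >= lo) & (draw <= hi)][: size - filled]
        out[filled:filled + draw.size] = draw
        filled += draw.size
    return out


def _plant_interactions(rng: np.random.Generator, params: ScreenParams,
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Choose disjoint planted cells and their gamma factors (1 elsewhere)."""
    m, n = params.m, params.n
    cells = rng.permutation(m * n)
    k_pos = int(round(params.rho_pos * m * n))
    k_neg = int(round(params.rho_neg * m * n))
    pos_mask = np.zeros(m * n, dtype=bool)
    neg_mask = np.zeros(m * n, dtype=bool)
    pos_mask[cells[:k_pos]] = True
    neg_mask[cells[k_pos:k_pos + k_neg]] = True
    gamma = np.ones(m * n)
    gamma[pos_mask] = rng.uniform(*params.gamma_pos_range, size=k_pos)
    gamma[neg_mask] = rng.uniform(*params.gamma_neg_range, size=k_neg)
    lethal = np.zeros(m * n, dtype=bool)
    neg_cells = cells[k_pos:k_pos + k_neg]
    n_lethal = int(round(params.lethal_fraction * k_neg))
    lethal[neg_cells[:n_lethal]] = True
    gamma[lethal] = 0.0
    shape = (m, n)
    return (pos_mask.reshape(shape), neg_mask.reshape(shape),
            gamma.reshape(shape), lethal.reshape(shape))


def _observe(clean: np.ndarray, params: ScreenParams,
             rng: np.random.Generator, name: str) -> FitnessMatrix:
    """Apply duplication, noise and missingness to the clean planted matrix."""
    m, n = params.m, params.n
    query_ids = [f"Q{a:04d}" for a in range(m)]
    array_ids = [f"A{b:04d}" for b in range(n)]
    n_dup_rows = int(round(params.duplicate_fraction * m))
    n_dup_cols = int(round(params.duplicate_fraction * n))
    dup_rows = rng.choice(m, size=n_dup_rows, replace=False) if n_dup_rows else np.array([], dtype=int)
    dup_cols = rng.choice(n, size=n_dup_cols, replace=False) if n_dup_cols else np.array([], dtype=int)
    values = clean
    if n_dup_rows:
        values = np.vstack([values, values[dup_rows]])
        query_ids = query_ids + [query_ids[i] for i in dup_rows]
    if n_dup_cols:
        values = np.hstack([values, values[:, dup_cols]])
        array_ids = array_ids + [array_ids[j] for j in dup_cols]
    if params.noise_sd > 0:
        values = values * np.exp(rng.normal(0.0, params.noise_sd, size=values.shape))
    else:
        values = values.copy()
    values = np.clip(values, 0.0, None)
    if params.missing_fraction > 0:
        miss = rng.random(values.shape) < params.missing_fraction
        values[miss] = np.nan
    return FitnessMatrix(query_ids=query_ids, array_ids=array_ids,
                         values=values, name=name)


def simulate_screen(params: ScreenParams | None = None, **overrides) -> SyntheticScreen:
    """Generate one synthetic screen, fully reproducible from
    ``params.seed``.

    Keyword overrides are applied on top of ``params`` (or the defaults),
    e.g. ``simulate_screen(seed=7, noise_sd=0.0)``.
    """
    params = replace(params or ScreenParams(), **overrides)
    params.validate()
    root = np.random.SeedSequence(params.seed)
    truth_rng, plant_rng, obs_rng = (np.random.default_rng(s) for s in root.spawn(3))
    return _simulate(params, truth_rng, plant_rng, obs_rng, name=f"synthetic-{params.seed}")


def _simulate(params: ScreenParams, truth_rng, plant_rng, obs_rng,
              name: str) -> SyntheticScreen:
    true_x = _truncated_normal(truth_rng, params.m, params.fitness_mean,
                               params.fitness_sd, params.fitness_bounds)
    true_y = _truncated_normal(truth_rng, params.n, params.fitness_mean,
                               params.fitness_sd, params.fitness_bounds)
    pos_mask, neg_mask, gamma, _ = _plant_interactions(plant_rng, params)
    clean = np.outer(true_x, true_y) * gamma
    fm = _observe(clean, params, obs_rng, name)
    return SyntheticScreen(fm=fm, true_x=true_x, true_y=true_y,
                           pos_mask=pos_mask, neg_mask=neg_mask, params=params)


def simulate_replicate_pair(params: ScreenParams | None = None,
                            shared_truth_seed: int = 0,
                            noise_seeds: tuple[int, int] = (1, 2),
                            **overrides) -> tuple[SyntheticScreen, SyntheticScreen]:
    """Two screens of the same underlying biology: shared true_x, true_y
    and planted masks; independent noise, missingness and duplicates.

    Emulates two platforms assaying the same mutant collections, for
    testing rank-aggregation integration.
    """
    params = replace(params or ScreenParams(), **overrides)
    params.validate()
    screens = []
    for k, nseed in enumerate(noise_seeds):
        truth_rng, plant_rng = (np.random.default_rng(s)
                                for s in np.random.SeedSequence(shared_truth_seed).spawn(2))
        obs_rng = np.random.default_rng(np.random.SeedSequence(nseed))
        screens.append(_simulate(params, truth_rng, plant_rng, obs_rng,
                                 name=f"replicate-{shared_truth_seed}-{k}"))
    return screens[0], screens[1]
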