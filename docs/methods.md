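# Methods

## Model

A double-mutant fitness matrix **W** (rows = *m* query strains, columns =
*n* array strains) is modelled as rank one under the multiplicative null of
epistasis: for non-interacting mutations, `w_ab = x_a · y_b`, where `x` and
`y` are the single-mutant fitness effects of the query and array strains.
Interactions are the residuals `s_ab = w_ab − s(x_a, y_b)` for a chosen
scoring function `s`; with the product function this is the classical
multiplicative deviation. The assumption that makes estimation possible is
sparsity of interactions: the large majority of cells follow the null, so
robust (quantile-based) summaries of rows and columns recover `x` and `y`
even though every observed entry is a double mutant.

A note on orientation: `x` is indexed by rows (query strains) and `y` by
columns (array strains) everywhere in this package. For symmetric screens
the two coincide in interpretation; for asymmetric ones the two sides are
genuinely different strain collections and the labels matter.

## Estimation (QMA)

`qma_estimate` initialises `x_a` as the *p*-quantile of the present values
of row *a*, then alternates

* `y_b ← q`-quantile over rows *a* of `w_ab / x_a`
* `x_a ← p`-quantile over columns *b* of `w_ab / y_b`

until the maximum relative change of the concatenated `(x, y)` falls below
`tol` or `max_iter` alternations have run (at least one always runs). Any
strictly positive rank-one matrix is a fixed point after the first
alternation, for every `(p, q)` — the basis of the exactness tests.

**Gauge.** The decomposition is identifiable only up to `x → c·x`,
`y → y/c`, and the minimum/maximum scoring functions are gauge-dependent.
The gauge is fixed by the initialisation: `x` is anchored in fitness units
by the raw row quantiles of **W**, and `y`, estimated from ratios
`w_ab / x_a`, lands in fitness units as well (screens normalised to median
fitness ≈ 1 give single-mutant effects near 1). No post-hoc rescaling is
applied; a 1×1 matrix `[[0.7]]` yields `x = [0.7]`, `y = [1.0]`.

**Numerical choices.**

* Quantiles use linear interpolation between order statistics (numpy's
  default "linear"/type-7 convention), pinned so tests are bit-stable. Any
  interpolation convention satisfies the method's invariants.
* Quantiles are taken over present (non-missing) entries only. Rows or
  columns with fewer than `min_obs` usable observations (default 5) get
  undefined estimates, and every score depending on them stays undefined —
  quantiles of tiny samples are too unstable to trust.
* Positivity floor 1e-8: denominators below the floor are excluded from
  ratio quantiles, and an estimate that comes out below the floor (an
  all-lethal row, say) is raised to it, so lethal queries cannot produce
  divisions by zero.
* Defaults `p = q = 0.5` reproduce the median baseline
  (`median_baseline_score` ≡ one-pass QMA at the medians + product
  scoring). Per-dataset tuned quantile levels are deliberately left to the
  caller as configuration; `max_iter = 20`, `tol = 1e-6`.

## Scoring

`score_interactions` supports product, minimum, maximum and scaled
epistasis. Scaled epistasis divides the product residual by a
sign-dependent normaliser: `|min(x_a, y_b) − x_a·y_b|` above the null
(distance to the masking bound) and `x_a·y_b` below it (distance to
lethality, so a synthetic-lethal cell scores exactly −1), floored at 1e-8.
This is a convention of this package — the normalisation places residuals
on a comparable epistasis scale but its exact form is not canonical.

`call_extremes` returns the pairs at or beyond the `tail_fraction`
quantiles of the defined scores (default 0.03 per tail, matching the
~3% interaction-rate estimate from unbiased screens; 0.01/0.05 are the
usual sensitivity settings). Boundary ties are included; in the degenerate
all-equal case both tails are empty. A `combined` switch splits the
fraction across the two tails instead, since "extreme 3%" can be read
either way.

## Reference classes

Edge lists are treated as unordered gene pairs: an edge A–B labels both
(A,B) and (B,A) wherever addressable. Default category mapping: positive =
{Positive Genetic, Phenotypic Suppression}; negative = {Negative Genetic,
Synthetic Growth Defect, Synthetic Lethality / Synthetic Lethal, Phenotypic
Enhancement}; matching is case-insensitive after trimming because exports
vary in casing, and both lethality spellings occur in the wild. Pairs
annotated in both classes are ambiguous and excluded from both matrices;
self pairs are always excluded (the diagonal measures a single mutant, not
an interaction); explicit exclusion lists (e.g. interactions derived from
the screens under evaluation) are also unordered.

## Comparison and enrichment

Screens are compared over shared (query, array) pairs with defined values
in both. For symmetric screens, transposed matching can be enabled; when
both orientations exist in the partner screen their values are averaged,
consistent with the duplicate-mean rule (duplicate rows/columns are merged
by the mean over present values before scoring — fitness 0 is a biological
value, lethality, never treated as missing).

The enrichment grid cuts a rank–rank scatter into `grid_dim` (default 6)
equal-count bins per axis — equal-count rather than equal-width, because
the scatter axes are ranks; ties at a boundary fall to the lower bin. Per
cell an upper-tail hypergeometric p-value is computed per interaction class
(`K` = all pairs, `M` = class total, `t` = cell size, `found` = class count
in the cell) and clamped to [1e-100, 0.99].

## Ranking and integration

Pairs are ranked per screen by their score (rank 1 = strongest evidence;
descending for positive interactions, ascending for negative), average
ranks on ties. Aggregation across screens uses minimum, maximum, product
(rank product) or Borda count (sum). Ranks are recomputed within the
common pair intersection before aggregating so all screens share one rank
scale — Borda sums over rankings of different lengths would not be
comparable. Final order is ascending by aggregate value with a
lexicographic pair-id tie-break for reproducible output.

## Evaluation

ROC curves collapse tied scores into single thresholds (diagonal
segments); the trapezoidal AUC then equals the Mann–Whitney statistic with
ties counted ½, which the tests verify by brute-force pair counting.
Partial AUC integrates the curve over FPR ∈ [0, r] (linear interpolation
at r) and divides by r; at the default r = 0.1 a random ranking scores
0.05. Early sensitivity is the TPR of the step curve at the largest
achieved FPR ≤ the cut (default 0.01), without interpolation — with fewer
than ~100 negatives the cut may be unreachable and the value falls back to
the TPR at FPR 0, a conservative choice.

## Synthetic screens

The generator draws `x` and `y` from a normal distribution with mean 1.0
and sd 0.15, truncated to [0.05, 1.5] — median-normalised screens have
single-mutant fitness concentrated near 1 — and sets the baseline to their
outer product, so unplanted noiseless cells satisfy the null exactly.
Planted interactions (default 1.5% positive + 1.5% negative of cells,
matching the ~3% empirical interaction rate) multiply the cell by
γ ~ U(1.4, 2.5) (alleviation) or γ ~ U(0, 0.6) (aggravation), with 10% of
negatives set to exact 0 (synthetic lethality). Measurement error is
multiplicative log-normal (`exp(N(0, 0.1))` by default), which keeps values
non-negative and the product model exact in log-expectation; missingness is
5% MCAR; 5% of strains are duplicated with independent noise to exercise
the merging path. One root seed drives separate generators for truth,
planting and observation, so replicate pairs can share biology (truth and
planted masks) while drawing noise independently.

What the generator does **not** emulate: plate/batch spatial effects,
same-chromosome linkage artifacts, and strain-specific biases — these are
removed upstream in the source screening pipelines. Tests passing on
synthetic screens therefore validate the scoring and integration machinery
under the stated noise model, not robustness to raw-screen artifacts. The
true noise magnitude of real screens is not pinned anywhere; the default
0.1 was chosen once to make the recovery and detection properties
discriminating (detection is near-ceiling at this level; raising
`noise_sd` to ~0.3 degrades it smoothly).

## Problem sizes used in the checks

The shipped checks run at desk scale, chosen as the smallest sizes at
which the Monte-Carlo properties are stable: random-classifier calibration
uses 1 000 replicates of 2 000 pairs with 100 positives; recovery and
detection use the default 200 × 100 screen; the integration benchmark
averages 50 replicate screen pairs in the test suite (10 in the acceptance
script) with a 0.01 allowance on the compared means. Exhaustive oracles
(hypergeometric draws, Mann–Whitney counting) cover K ≤ 12 and up to 500
points respectively.

## Known limitations

* Alternating quantile updates have no general convergence guarantee; on
  noisy data the iteration can hover above `tol` until `max_iter` — the
  estimates are stable in practice, but `iterations_run` should be
  inspected when in doubt.
* The minimum/maximum scoring functions inherit the gauge convention;
  comparing them across screens with very different normalisations is not
  meaningful without re-anchoring.
* No higher-rank approximation, no additive (log-scale) null variant, no
  alias resolution for gene identifiers (exact, case-sensitive systematic
  names only), no modelling of spatial or linkage artifacts.
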