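import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import qmap
from qmap.dataset_comparison import (P_CLAMP_HI, P_CLAMP_LO, correlations,
                                     enrichment_grid, extreme_agreement_auc,
                                     hypergeom_upper, intersect_datasets)
from qmap.errors import ValidationError


def _sm(scores, qids=None, aids=None, name=""):
    scores = np.asarray(scores, dtype=float)
    m, n = scores.shape
    return qmap.ScoreMatrix(qids or [f"q{i}" for i in range(m)],
                            aids or [f"a{j}" for j in range(n)], scores,
                            name=name)


class TestIntersectDatasets:
    def test_counts_shared_defined_cells(self):
        a = _sm(np.arange(9.0).reshape(3, 3))
        b = _sm([[1.0, 2.0], [3.0, 4.0]], qids=["q0", "q1"], aids=["a0", "a1"])
        inter = intersect_datasets(a, b)
        assert inter.size == 4
        assert set(inter.pairs) == {("q0", "a0"), ("q0", "a1"),
                                    ("q1", "a0"), ("q1", "a1")}

    def test_missing_cells_do_not_pair(self):
        a = _sm([[1.0, np.nan], [2.0, 3.0]])
        b = _sm([[5.0, 6.0], [np.nan, 7.0]])
        inter = intersect_datasets(a, b)
        assert set(inter.pairs) == {("q0", "a0"), ("q1", "a1")}

    def test_disjoint_id_sets_empty(self):
        a = _sm([[1.0]], qids=["x"], aids=["y"])
        b = _sm([[1.0]], qids=["u"], aids=["v"])
        assert intersect_datasets(a, b).size == 0

    def test_transpose_matching_and_orientation_averaging(self):
        a = _sm([[1.0]], qids=["gA"], aids=["gB"])
        # b holds only the flipped orientation
        b_flipped = _sm([[5.0]], qids=["gB"], aids=["gA"])
        assert intersect_datasets(a, b_flipped).size == 0
        inter = intersect_datasets(a, b_flipped, allow_transpose=True)
        assert inter.pairs == [("gA", "gB")] and inter.b_values[0] == 5.0
        # b holds both orientations: averaged
        b_both = _sm([[np.nan, 3.0], [7.0, np.nan]],
                     qids=["gA", "gB"], aids=["gA", "gB"])
        inter = intersect_datasets(a, b_both, allow_transpose=True)
        assert inter.b_values[0] == pytest.approx(5.0)


class TestCorrelations:
    def test_affine_transform_perfect(self):
        a = np.array([0.1, 0.5, 0.9, 1.3])
        pearson, spearman = correlations(a, 2 * a + 1)
        assert pearson == pytest.approx(1.0) and spearman == pytest.approx(1.0)

    def test_monotone_transform_spearman_only(self):
        a = np.array([0.0, 1.0, 2.0, 5.0])
        pearson, spearman = correlations(a, np.exp(a))
        assert spearman == pytest.approx(1.0) and pearson < 1.0

    def test_hand_spearman(self):
        _, spearman = correlations([1, 2, 3], [3, 1, 2])
        assert spearman == pytest.approx(-0.5)

    @pytest.mark.parametrize("a,b", [
        ([1.0, 2.0], [2.0, 1.0]),          # too few pairs
        ([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]),  # zero variance
    ])
    def test_undefined_cases_flagged_not_raised(self, a, b):
        pearson, spearman = correlations(a, b)
        assert math.isnan(pearson) and math.isnan(spearman)

    def test_incomplete_cases_dropped(self):
        a = [1.0, 2.0, np.nan, 3.0, 4.0]
        b = [2.0, 4.0, 9.0, 6.0, 8.0]
        pearson, _ = correlations(a, b)
        assert pearson == pytest.approx(1.0)


class TestExtremeAgreementAUC:
    def _pair(self, ref_vals, pred_vals):
        ref = _sm(np.asarray(ref_vals, float).reshape(1, -1))
        pred = _sm(np.asarray(pred_vals, float).reshape(1, -1))
        return ref, pred, intersect_datasets(ref, pred)

    def test_self_prediction_is_perfect(self):
        vals = np.linspace(-1, 1, 100)
        ref, pred, inter = self._pair(vals, vals)
        assert extreme_agreement_auc(ref, pred, inter, 0.03, "positive") == 1.0
        assert extreme_agreement_auc(ref, pred, inter, 0.03, "negative") == 1.0

    def test_permuted_predictor_near_chance(self):
        rng = np.random.default_rng(0)
        vals = np.linspace(-1, 1, 500)
        aucs = [extreme_agreement_auc(*self._pair(vals, rng.permutation(vals)),
                                      0.03, "positive") for _ in range(40)]
        assert abs(np.mean(aucs) - 0.5) < 0.05

    def test_equals_brute_force_concordance_count(self):
        ref_vals = np.array([0.0, 1.0, 2.0, 3.0, 9.0, 8.0, -1.0, 0.5, 0.2, 4.0])
        pred_vals = np.array([0.3, 0.1, 2.0, 0.2, 5.0, 1.0, 0.0, 0.4, 0.6, 3.0])
        ref, pred, inter = self._pair(ref_vals, pred_vals)
        auc = extreme_agreement_auc(ref, pred, inter, 0.25, "positive")
        # labels: top-25% tail of the reference (hand check: 9.0, 8.0, 4.0)
        labels = ref_vals >= np.quantile(ref_vals, 0.75)
        conc = sum((pred_vals[i] > pred_vals[j]) + 0.5 * (pred_vals[i] == pred_vals[j])
                   for i in np.nonzero(labels)[0] for j in np.nonzero(~labels)[0])
        assert auc == pytest.approx(conc / (labels.sum() * (~labels).sum()))

    def test_invariant_to_monotone_predictor_transform(self):
        rng = np.random.default_rng(1)
        ref_vals = rng.normal(size=200)
        pred_vals = rng.normal(size=200)
        ref, pred, inter = self._pair(ref_vals, pred_vals)
        base = extreme_agreement_auc(ref, pred, inter, 0.05, "positive")
        ref2, pred2, inter2 = self._pair(ref_vals, np.exp(3 * pred_vals))
        assert extreme_agreement_auc(ref2, pred2, inter2, 0.05, "positive") \
            == pytest.approx(base)


class TestHypergeomUpper:
    def test_found_zero_clamps_to_ceiling(self):
        assert hypergeom_upper(10, 4, 3, 0) == P_CLAMP_HI

    def test_exact_enumeration_example(self):
        # P(X >= 2) = [C(4,2)C(6,1) + C(4,3)C(6,0)] / C(10,3) = 40/120
        assert hypergeom_upper(10, 4, 3, 2) == pytest.approx(1 / 3)

    def test_tiny_p_clamps_to_floor(self):
        assert hypergeom_upper(10 ** 6, 500, 500, 500) == P_CLAMP_LO

    @pytest.mark.parametrize("args", [(5, 6, 2, 1), (5, 3, 6, 1), (5, 3, 2, 3)])
    def test_invalid_arguments_rejected(self, args):
        with pytest.raises(ValidationError):
            hypergeom_upper(*args)

    def test_matches_exhaustive_draw_enumeration_small_K(self):
        # spot-check against enumerating all C(K, t) draws (full sweep of
        # K <= 12 lives in the acceptance suite)
        for K, M, t in [(7, 3, 4), (9, 5, 3), (12, 6, 6)]:
            items = [1] * M + [0] * (K - M)
            draws = list(itertools.combinations(items, t))
            for found in range(t + 1):
                exact = sum(sum(d) >= found for d in draws) / len(draws)
                clamped = min(max(exact, P_CLAMP_LO), P_CLAMP_HI)
                assert hypergeom_upper(K, M, t, found) == pytest.approx(clamped)


class TestEnrichmentGrid:
    def test_counts_conservation_on_random_input(self):
        rng = np.random.default_rng(2)
        n = 300
        a = stats.rankdata(rng.normal(size=n))
        b = stats.rankdata(rng.normal(size=n))
        pos = rng.random(n) < 0.05
        neg = (~pos) & (rng.random(n) < 0.05)
        g = enrichment_grid(a, b, pos, neg, grid_dim=6)
        assert g.counts.sum() == n
        assert g.positive_found.sum() == pos.sum()
        assert g.negative_found.sum() == neg.sum()
        assert np.all((g.positive_p >= P_CLAMP_LO) & (g.positive_p <= P_CLAMP_HI))

    def test_fully_packed_corner_cell_matches_direct_formula(self):
        # 2x2 grid, 16 pairs: the top-right cell holds the 8 pairs above the
        # median on both axes, and all 4 positives are among them
        a = np.arange(1.0, 17.0)
        b = np.arange(1.0, 17.0)
        pos = a > 12
        g = enrichment_grid(a, b, pos, np.zeros(16, bool), grid_dim=2)
        assert g.counts[1, 1] == 8 and g.positive_found[1, 1] == 4
        assert g.positive_p[1, 1] == pytest.approx(hypergeom_upper(16, 4, 8, 4))
        # other cells hold no positives -> clamped to the ceiling
        assert g.positive_p[0, 0] == P_CLAMP_HI

    def test_null_labels_p_values_near_ceiling(self):
        rng = np.random.default_rng(3)
        n = 3600
        a = stats.rankdata(rng.normal(size=n))
        b = stats.rankdata(rng.normal(size=n))
        pos = np.zeros(n, bool)
        pos[rng.choice(n, 60, replace=False)] = True
        g = enrichment_grid(a, b, pos, np.zeros(n, bool), grid_dim=6)
        # with uniformly scattered labels most cells show no enrichment
        assert np.median(g.positive_p) > 0.1

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValidationError, match="grid_dim"):
            enrichment_grid(np.arange(10.0), np.arange(10.0),
                            np.zeros(10, bool), np.zeros(10, bool), grid_dim=6)

    def test_boundary_ties_fall_to_lower_bin(self):
        ranks = np.array([1.0, 2.0, 2.0, 4.0])
        g = enrichment_grid(ranks, ranks, np.array([1, 0, 0, 0], bool),
                            np.zeros(4, bool), grid_dim=2)
        # the tied rank-2 values sit exactly at the median boundary -> lower bin
        assert g.counts[0, 0] == 3 and g.counts[1, 1] == 1
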