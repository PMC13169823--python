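"""AUC estimation, DeLong inference, cutoff selection, rank correlation."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import ocmbtriage as ot
from ocmbtriage.roc import operating_point

# ---------------------------------------------------------------------------
# Deterministic score fixture cross-checked against R pROC (DeLong method);
# the expected numbers below were computed with pROC's ci.auc / roc.test and
# frozen.  Synthetic data, not patient data.
# ---------------------------------------------------------------------------
NEG_A = [0.45949, 0.053586, -0.874452, 0.288246, -0.501468, 0.792636, -0.390478,
         1.276096, -0.030761, -0.007101, -0.243321, 0.440514, -0.56852, -1.654866,
         0.798432, -1.510022, 0.837025, 0.058804]
POS_A = [0.345634, 3.684562, 2.678212, 0.328409, 1.150956, 2.683181, -0.094525,
         2.903642, 1.278818, 1.735064, 0.046747, 1.310558, 1.343994, 0.501421,
         2.452163, -0.704443, -0.570935, 1.036572, 1.328849, 3.405802, 1.916005,
         1.120165]
SCORES_B = [1.146137, 0.127416, -0.643252, -0.624073, 0.387882, -0.850853, -0.745041,
            2.141915, -1.70868, -1.167374, 0.542282, -1.179162, -0.709016, -1.057791,
            1.138902, -0.896933, 1.122005, 0.777034, 0.185041, 2.02448, 1.239293,
            1.588951, -0.259775, 0.690706, -1.734678, 1.773821, 0.048622, 0.887408,
            0.186792, 2.411933, 0.876593, -0.196779, 1.096783, 0.485873, -0.044446,
            -0.366294, 1.263657, 1.175824, -0.436809, 0.784173]
LABELS_AB = [0] * 18 + [1] * 22
SCORES_A = NEG_A + POS_A

PROC_AUC_A = 0.8257575758
PROC_SE_A = 0.066630120762
PROC_CI_A = (0.6951649388, 0.9563502127)
PROC_PAIRED_Z = 1.4084784431
PROC_PAIRED_P = 0.1589894458


def brute_force_auc(pos, neg):
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


scores = st.lists(st.integers(min_value=-5, max_value=5), min_size=1, max_size=25)


class TestEmpiricalAuc:
    @pytest.mark.parametrize(
        "pos, neg, expected",
        [([2, 3], [1], 1.0), ([1, 2], [1, 3], 0.375), ([1, 2, 2], [1, 2, 2], 0.5)],
    )
    def test_examples(self, pos, neg, expected):
        assert ot.empirical_auc(pos, neg) == pytest.approx(expected, abs=1e-15)

    def test_empty_class_rejected(self):
        with pytest.raises(ot.InsufficientDataError):
            ot.empirical_auc([], [1.0])

    @given(scores, scores)
    def test_matches_pairwise_oracle(self, pos, neg):
        assert ot.empirical_auc(pos, neg) == pytest.approx(
            brute_force_auc(pos, neg), abs=1e-12
        )

    @given(scores, scores)
    def test_complement_identity(self, pos, neg):
        assert ot.empirical_auc(pos, neg) + ot.empirical_auc(neg, pos) == pytest.approx(
            1.0, abs=1e-12
        )

    @given(scores, scores)
    def test_invariant_under_monotone_transform(self, pos, neg):
        f = lambda xs: [math.exp(0.3 * x) + x for x in xs]
        assert ot.empirical_auc(f(pos), f(neg)) == pytest.approx(
            ot.empirical_auc(pos, neg), abs=1e-12
        )


class TestRocCurve:
    def test_perfect_classifier(self):
        curve = ot.roc_curve([1, 2, 3, 4], [0, 0, 1, 1])
        assert curve.auc() == pytest.approx(1.0)
        # passes through (spec=1, sens=1)
        assert any(
            s == 1.0 and sp == 1.0 for s, sp in zip(curve.sensitivity, curve.specificity)
        )

    def test_monotone_and_endpoints(self):
        rng = np.random.default_rng(0)
        curve = ot.roc_curve(rng.normal(size=40), rng.integers(0, 2, 40))
        assert np.all(np.diff(curve.sensitivity) >= 0)
        assert np.all(np.diff(curve.specificity) <= 0)
        assert (curve.sensitivity[0], curve.specificity[0]) == (0.0, 1.0)
        assert (curve.sensitivity[-1], curve.specificity[-1]) == (1.0, 0.0)
        assert math.isinf(curve.thresholds[0])

    def test_trapezoid_equals_mann_whitney(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = int(rng.integers(5, 60))
            scores = np.round(rng.normal(size=n), 1)  # ties likely
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            curve = ot.roc_curve(scores, labels)
            assert curve.auc() == pytest.approx(
                ot.empirical_auc(scores[labels == 1], scores[labels == 0]), abs=1e-12
            )

    def test_shuffled_labels_center_on_half(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=50)
        aucs = []
        for _ in range(300):
            labels = np.zeros(50, dtype=int)
            labels[:20] = 1
            rng.shuffle(labels)
            aucs.append(ot.roc_curve(scores, labels).auc())
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.03)

    def test_single_class_rejected(self):
        with pytest.raises(ot.InsufficientDataError):
            ot.roc_curve([1, 2, 3], [1, 1, 1])


class TestDelongCi:
    def test_matches_proc_oracle(self):
        est = ot.delong_ci(POS_A, NEG_A)
        assert est.auc == pytest.approx(PROC_AUC_A, abs=1e-9)
        assert est.se == pytest.approx(PROC_SE_A, abs=1e-9)
        assert est.ci_low == pytest.approx(PROC_CI_A[0], abs=1e-9)
        assert est.ci_high == pytest.approx(PROC_CI_A[1], abs=1e-9)

    def test_perfect_separation_boundary(self):
        est = ot.delong_ci(np.arange(10, 20), np.arange(0, 10))
        assert est.auc == 1.0
        assert est.ci_high == 1.0

    def test_all_tied_scores_degenerate(self):
        est = ot.delong_ci([1.0, 1.0, 1.0], [1.0, 1.0])
        assert est.se == 0.0
        assert est.degenerate

    def test_doubling_observations_shrinks_se(self):
        est1 = ot.delong_ci(POS_A, NEG_A)
        est2 = ot.delong_ci(POS_A * 2, NEG_A * 2)
        assert est2.auc == pytest.approx(est1.auc, abs=1e-12)
        assert est2.se < est1.se

    def test_coverage_of_true_binormal_auc(self):
        """Nominal 95 % DeLong CI covers the true AUC 0.71 at n=54/43."""
        delta = ot.calibrate_delta(0.71, 1.0, 1.0)
        rng = np.random.default_rng(42)
        hits = 0
        reps = 2000
        for _ in range(reps):
            est = ot.delong_ci(rng.normal(delta, 1.0, 54), rng.normal(0.0, 1.0, 43))
            hits += est.ci_low <= 0.71 <= est.ci_high
        assert 0.92 <= hits / reps <= 0.97


class TestDelongPairedTest:
    def test_identical_scores(self):
        res = ot.delong_paired_test(SCORES_A, SCORES_A, LABELS_AB)
        assert res.statistic == 0.0
        assert res.pvalue == 1.0

    def test_matches_proc_oracle(self):
        res = ot.delong_paired_test(SCORES_A, SCORES_B, LABELS_AB)
        assert res.statistic == pytest.approx(PROC_PAIRED_Z, abs=1e-9)
        assert res.pvalue == pytest.approx(PROC_PAIRED_P, abs=1e-9)
        assert res.auc_a == pytest.approx(PROC_AUC_A, abs=1e-9)

    def test_antisymmetric_in_arguments(self):
        fwd = ot.delong_paired_test(SCORES_A, SCORES_B, LABELS_AB)
        rev = ot.delong_paired_test(SCORES_B, SCORES_A, LABELS_AB)
        assert rev.statistic == pytest.approx(-fwd.statistic, abs=1e-12)
        assert rev.pvalue == pytest.approx(fwd.pvalue, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ot.InvalidValueError):
            ot.delong_paired_test([1, 2], [1, 2, 3], [0, 1])


class TestSelectCutoff:
    def test_bruteforce_enumeration_case(self):
        """Integers: negatives 1..20, positives 15..34, floor 0.85.

        Exhaustive enumeration of all operating points shows the
        highest-sensitivity threshold with specificity strictly above 0.85 is
        19 (sens 16/20, spec 18/20).
        """
        scores = list(range(1, 21)) + list(range(15, 35))
        labels = [0] * 20 + [1] * 20
        curve = ot.roc_curve(scores, labels)
        cutoff = ot.select_cutoff(curve, 0.85)
        assert cutoff == 19.0
        sens, spec = operating_point(curve, cutoff)
        assert (sens, spec) == (16 / 20, 18 / 20)

    def test_perfect_separation_tie_break_highest_threshold(self):
        curve = ot.roc_curve([1, 2, 3, 4], [0, 0, 1, 1])
        # (sens 1, spec 1) only at threshold 3, the lowest positive score
        assert ot.select_cutoff(curve, 0.85) == 3.0

    def test_impossible_constraint(self):
        curve = ot.roc_curve([1, 2, 2, 3], [0, 1, 0, 1])
        with pytest.raises(ot.NoFeasibleCutoffError):
            ot.select_cutoff(curve, 1.0)

    def test_snap_rounds_up_to_grid(self):
        neg = [0.05, 0.08, 0.10, 0.12, 0.14]
        pos = [0.17, 0.22, 0.31, 0.44, 0.52]
        curve = ot.roc_curve(neg + pos, [0] * 5 + [1] * 5)
        raw = ot.select_cutoff(curve, 0.85)
        assert raw == pytest.approx(0.17)
        snapped = ot.select_cutoff(curve, 0.85, snap_grid=0.05)
        assert snapped == pytest.approx(0.20)
        _, spec = operating_point(curve, snapped)
        assert spec > 0.85

    def test_snap_keeps_on_grid_value(self):
        neg = [0.1, 0.1, 0.15]
        pos = [0.2, 0.3, 0.4]
        curve = ot.roc_curve(neg + pos, [0, 0, 0, 1, 1, 1])
        assert ot.select_cutoff(curve, 0.85, snap_grid=0.05) == pytest.approx(0.20)

    def test_constraint_always_satisfied_post_hoc(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            n = int(rng.integers(10, 80))
            scores = np.round(rng.normal(1.0, 1.0, n), 1)
            labels = np.r_[np.ones(n // 2, int), np.zeros(n - n // 2, int)]
            rng.shuffle(labels)
            curve = ot.roc_curve(scores, labels)
            try:
                cutoff = ot.select_cutoff(curve, 0.85, snap_grid=0.05)
            except ot.NoFeasibleCutoffError:
                continue
            _, spec = operating_point(curve, cutoff)
            assert spec > 0.85


class TestRankCorrelation:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ([1, 2, 3, 4], [10, 20, 30, 40], 1.0),
            ([1, 2, 3, 4], [4, 3, 2, 1], -1.0),
            ([1, 2, 3, 4], [2, 1, 4, 3], 0.6),  # 1 - 6*4/(4*15)
        ],
    )
    def test_examples(self, x, y, expected):
        assert ot.rank_correlation(x, y).correlation == pytest.approx(expected)

    def test_constant_vector_undefined(self):
        with pytest.raises(ot.UndefinedCorrelationError):
            ot.rank_correlation([1, 1, 1], [1, 2, 3])

    def test_too_short_rejected(self):
        with pytest.raises(ot.InsufficientDataError):
            ot.rank_correlation([1, 2], [3, 4])
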