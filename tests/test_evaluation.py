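"""Metrics and statistics: balanced accuracy, certainty curve and AUC,
regression through the origin, distance contrast, corrected t-test."""

import numpy as np
import pytest
from scipy import stats

from spectvote.conclusiveness import build_grid
from spectvote.evaluation import (
    CertaintyCurve,
    ConfusionCounts,
    balanced_accuracy,
    build_certainty_curve,
    certainty_auc,
    distance_by_consistency,
    nadeau_bengio_ttest,
    regression_through_origin,
)


class TestBalancedAccuracy:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            (ConfusionCounts(10, 0, 10, 0), 100.0),
            (ConfusionCounts(10, 0, 0, 10), 50.0),  # all-positive classifier
            (ConfusionCounts(8, 2, 6, 4), 70.0),
        ],
    )
    def test_values(self, counts, expected):
        assert balanced_accuracy(counts) == pytest.approx(expected)

    def test_single_class_undefined(self):
        assert balanced_accuracy(ConfusionCounts(5, 1, 0, 0)) is None

    def test_invariant_to_duplication(self):
        c1 = ConfusionCounts(8, 2, 6, 4)
        c2 = ConfusionCounts(16, 4, 12, 8)
        assert balanced_accuracy(c1) == balanced_accuracy(c2)


class TestCertaintyCurve:
    def test_toy_hand_enumeration(self):
        # 6 cases; sigmoids and majority labels chosen so one error sits
        # near the threshold and is swallowed by the widest interval
        sig = np.array([0.05, 0.1, 0.45, 0.55, 0.9, 0.95])
        lab = np.array([0, 0, 1, 0, 1, 1])  # 0.45->1 and 0.55->0 are errors
        grid = build_grid(np.array([0.4, 0.45, 0.55, 0.6, 0.1, 0.9]), targets=(1 / 3,))
        curve = build_certainty_curve(sig, lab, grid)
        # interval from validation: k = 1 per side -> bounds (0.425, 0.575)
        pts = dict((round(x, 6), (y, z)) for x, y, z in curve.points)
        # overall point: sens=2/3, spec=2/3 -> 66.67
        assert pts[0.0][0] == pytest.approx(200 / 3, abs=1e-6)
        # with the two boundary errors inconclusive: certain cases perfect
        assert pts[round(2 / 6, 6)][0] == pytest.approx(100.0)
        assert pts[round(2 / 6, 6)][1] == pytest.approx(0.0)

    def test_empty_grid_gives_overall_point(self):
        sig = np.array([0.1, 0.9])
        lab = np.array([0, 1])
        grid = build_grid(np.array([0.1, 0.9] * 50), targets=(0.002,))  # k=0
        curve = build_certainty_curve(sig, lab, grid)
        assert curve.points[0] == (0.0, 100.0, None)

    def test_label_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            build_certainty_curve([0.5], [1, 0], build_grid([0.5]))


class TestCertaintyAUC:
    def test_constant_100(self):
        curve = CertaintyCurve([(0.0, 100.0, None), (0.12, 100.0, None)])
        assert certainty_auc(curve) == pytest.approx(100.0)

    def test_constant_90(self):
        curve = CertaintyCurve([(0.0, 90.0, None), (0.12, 90.0, None)])
        assert certainty_auc(curve) == pytest.approx(90.0)

    def test_two_point_trapezoid(self):
        curve = CertaintyCurve([(0.002, 90.0, None), (0.10, 100.0, None)])
        assert certainty_auc(curve) == pytest.approx(95.0)

    def test_collinear_point_insertion_invariant(self):
        base = CertaintyCurve([(0.002, 90.0, None), (0.10, 100.0, None)])
        dense = CertaintyCurve(
            [(0.002, 90.0, None), (0.051, 95.0, None), (0.10, 100.0, None)]
        )
        assert certainty_auc(dense) == pytest.approx(certainty_auc(base))

    def test_needs_two_defined_points(self):
        with pytest.raises(ValueError):
            certainty_auc(CertaintyCurve([(0.05, 95.0, None)]))

    def test_gaps_are_skipped_not_zeroed(self):
        curve = CertaintyCurve(
            [(0.002, 90.0, None), (0.05, None, 50.0), (0.10, 100.0, None)]
        )
        assert certainty_auc(curve) == pytest.approx(95.0)


class TestRegressionThroughOrigin:
    def test_identity_slope(self):
        x = np.linspace(0.002, 0.1, 50)
        assert regression_through_origin(x, x) == pytest.approx(1.0)

    def test_known_slope(self):
        x = np.linspace(0.002, 0.1, 50)
        assert regression_through_origin(x, 1.5 * x) == pytest.approx(1.5)

    def test_zero_observed(self):
        x = np.linspace(0.002, 0.1, 50)
        assert regression_through_origin(x, np.zeros_like(x)) == 0.0

    def test_all_zero_targets_rejected(self):
        with pytest.raises(ValueError):
            regression_through_origin([0.0, 0.0], [0.1, 0.2])


class TestDistanceByConsistency:
    def test_hand_values(self):
        table = distance_by_consistency(
            [0.9, 0.1, 0.55], [True, True, False]
        ).set_index("group")
        assert table.loc["consistent", "mean_distance"] == pytest.approx(0.4)
        assert table.loc["discrepant", "mean_distance"] == pytest.approx(0.05)

    def test_all_at_threshold(self):
        table = distance_by_consistency([0.5, 0.5], [True, False])
        assert (table.mean_distance == 0).all()

    def test_empty_group_absent(self):
        table = distance_by_consistency([0.7, 0.2], [True, True])
        assert list(table.group) == ["consistent"]


class TestNadeauBengio:
    def test_hand_computed_statistic(self):
        d = np.arange(1.0, 11.0)
        cmp = nadeau_bengio_ttest(d, rho=1 / 3)
        expected_t = 5.5 / np.sqrt((0.1 + 1 / 3) * np.var(d, ddof=1))
        assert cmp.t_corrected == pytest.approx(expected_t, rel=1e-12)
        assert cmp.t_corrected == pytest.approx(2.759, abs=2e-3)
        assert cmp.df == 9
        assert cmp.p_two_sided == pytest.approx(
            2 * stats.t.sf(expected_t, 9), rel=1e-12
        )

    def test_rho_to_zero_recovers_classical_paired_t(self):
        rng = np.random.default_rng(0)
        d = rng.normal(0.3, 1.0, size=12)
        classical = stats.ttest_1samp(d, 0.0)
        cmp = nadeau_bengio_ttest(d, rho=1e-12)
        assert cmp.t_corrected == pytest.approx(classical.statistic, rel=1e-5)

    def test_correction_never_increases_significance(self):
        rng = np.random.default_rng(1)
        d = rng.normal(0.5, 1.0, size=10)
        corrected = nadeau_bengio_ttest(d, rho=1 / 3)
        classical = stats.ttest_1samp(d, 0.0)
        assert corrected.p_two_sided >= classical.pvalue

    def test_antisymmetry(self):
        d = np.array([0.5, 1.0, -0.2, 0.8])
        a = nadeau_bengio_ttest(d, rho=1 / 3)
        b = nadeau_bengio_ttest(-d, rho=1 / 3)
        assert a.t_corrected == pytest.approx(-b.t_corrected)
        assert a.p_two_sided == pytest.approx(b.p_two_sided)

    def test_zero_variance_degenerate(self):
        allzero = nadeau_bengio_ttest(np.zeros(5))
        assert allzero.t_corrected == 0.0 and allzero.p_two_sided == 1.0
        with pytest.warns(UserWarning):
            shifted = nadeau_bengio_ttest(np.full(5, 2.0))
        assert shifted.p_two_sided == 0.0

    def test_too_few_realizations_rejected(self):
        with pytest.raises(ValueError):
            nadeau_bengio_ttest([1.0])
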