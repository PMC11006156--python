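import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import rocreport as rr
from rocreport.errors import DegenerateDataError, InfeasibleConstraintError
from oracles import best_chi2, best_topleft, best_youden
from test_roc import dataset_strategy


def toy_curve(points):
    """ROCCurve from explicit (threshold, sens, spec) triples."""
    t, s, p = map(np.array, zip(*points))
    return rr.ROCCurve(
        thresholds=t, sensitivities=s, specificities=p,
        direction=rr.GREATER, auc=0.5, auc_ci_lower=0.0, auc_ci_upper=1.0,
        ci_level=0.95, n_positive=10, n_negative=10,
    )


class TestYouden:
    def test_perfect_separation(self, perfect_data):
        c = rr.build_roc(perfect_data)
        y = rr.youden(c)
        assert y.criterion_value == pytest.approx(1.0)
        assert y.threshold == pytest.approx(2.5)  # separating midpoint

    def test_identical_classes_j_zero(self, identical_data):
        y = rr.youden(rr.build_roc(identical_data))
        assert y.criterion_value == pytest.approx(0.0)

    def test_j_range(self, nafld_cohort):
        y = rr.youden(rr.build_roc(nafld_cohort))
        assert -1.0 <= y.criterion_value <= 1.0

    def test_optimum_dominates_all_candidates(self, nafld_cohort):
        c = rr.build_roc(nafld_cohort)
        y = rr.youden(c)
        j = c.sensitivities + c.specificities - 1.0
        assert y.criterion_value >= j.max() - 1e-15

    def test_smallest_threshold_wins_ties(self):
        # two separated clusters: every midpoint in the gap gives J=1,
        # but distinct values make only one midpoint; craft a real tie
        # instead with a flat J region.
        d = rr.from_arrays([1, 2, 5, 6], [0, 0, 1, 1])
        c = rr.build_roc(d)
        j = c.sensitivities + c.specificities - 1.0
        ties = c.thresholds[j == j.max()]
        assert rr.youden(c).threshold == ties.min()


class TestClosestTopleft:
    def test_perfect_separation_d_zero(self, perfect_data):
        r = rr.closest_topleft(rr.build_roc(perfect_data))
        assert r.criterion_value == pytest.approx(0.0)

    def test_single_informative_point(self):
        c = toy_curve([(-np.inf, 1.0, 0.0), (0.0, 0.8, 0.7), (np.inf, 0.0, 1.0)])
        r = rr.closest_topleft(c)
        assert r.threshold == 0.0
        assert r.criterion_value == pytest.approx(0.04 + 0.09)

    def test_identical_classes_chance_line(self, identical_data):
        r = rr.closest_topleft(rr.build_roc(identical_data))
        assert r.criterion_value == pytest.approx(0.5)


class TestConstrainedMax:
    def test_perfect_separation(self, perfect_data):
        c = rr.build_roc(perfect_data)
        r = rr.constrained_max(c, "specificity", 0.9)
        assert r.criterion_value == pytest.approx(1.0)  # sens
        assert r.specificity >= 0.9

    def test_enumeration_specificity_bound(self):
        c = toy_curve([
            (1, 1.0, 0.0), (2, 0.9, 0.5), (3, 0.6, 0.8),
            (4, 0.2, 0.95), (5, 0.0, 1.0),
        ])
        r = rr.constrained_max(c, "specificity", 0.7)
        assert (r.sensitivity, r.specificity) == (0.6, 0.8)
        assert r.constraint == ("specificity", 0.7)

    def test_enumeration_sensitivity_bounds(self):
        c = toy_curve([
            (1, 1.0, 0.0), (2, 0.9, 0.5), (3, 0.6, 0.8),
            (4, 0.2, 0.95), (5, 0.0, 1.0),
        ])
        assert rr.constrained_max(c, "sensitivity", 0.95).sensitivity == 1.0
        r = rr.constrained_max(c, "sensitivity", 0.85)
        assert (r.sensitivity, r.specificity) == (0.9, 0.5)

    def test_infeasible_constraint(self):
        c = toy_curve([(1, 1.0, 0.0), (2, 0.5, 0.5)])
        with pytest.raises(InfeasibleConstraintError):
            rr.constrained_max(c, "specificity", 0.9)

    def test_bad_bound_rejected(self, perfect_data):
        c = rr.build_roc(perfect_data)
        with pytest.raises(ValueError):
            rr.constrained_max(c, "specificity", 0.0)


class TestMinPvalue:
    def test_hand_computed_diagonal_table(self):
        # positives {5,6}, negatives {1,2}: a separating cut puts all four
        # counts on the diagonal; chi-square = n = 4
        d = rr.from_arrays([5, 6, 1, 2], [1, 1, 0, 0])
        r = rr.min_pvalue(d)
        assert r.criterion_value == pytest.approx(4.0)
        assert r.p_value == pytest.approx(stats.chi2.sf(4.0, 1))
        assert 2 < r.threshold < 5

    def test_identical_classes_zero_statistic(self, identical_data):
        r = rr.min_pvalue(identical_data)
        assert r.criterion_value == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)

    def test_random_sample_matches_bruteforce(self):
        rng = np.random.default_rng(42)
        d = rr.from_arrays(
            np.concatenate([rng.normal(1, 1, 20), rng.normal(0, 1, 20)]).round(2),
            np.concatenate([np.ones(20, int), np.zeros(20, int)]),
        )
        r = rr.min_pvalue(d)
        c_o, stat_o, ties = best_chi2(d.positives, d.negatives)
        assert any(r.threshold == pytest.approx(c) for c in ties)
        assert r.criterion_value == pytest.approx(stat_o)

    def test_constant_marker_rejected(self):
        d = rr.from_arrays([2.0, 2.0, 2.0, 2.0], [1, 1, 0, 0])
        with pytest.raises(DegenerateDataError):
            rr.min_pvalue(d)

    def test_type_one_error_inflation_under_null(self):
        """Selecting the cutoff that minimizes p inflates the Type I error:
        under the null the nominal-0.05 rejection rate is well above 0.05.
        This documents known behaviour; it is not a correctness failure."""
        rng = np.random.default_rng(123)
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            x = rng.normal(0, 1, 50)
            d = rr.from_arrays(x, np.repeat([1, 0], 25))
            if rr.min_pvalue(d).p_value < 0.05:
                rejections += 1
        assert rejections / n_rep > 0.05


class TestBiomarkerOriented:
    def test_mean_median(self):
        d = rr.from_arrays([1, 2, 3, 4, 5], [1, 1, 1, 0, 0])
        assert rr.biomarker_oriented(d, "mean").threshold == pytest.approx(3.0)
        assert rr.biomarker_oriented(d, "median").threshold == pytest.approx(3.0)

    def test_mode_most_frequent(self):
        d = rr.from_arrays([1, 1, 2, 9], [1, 1, 0, 0])
        assert rr.biomarker_oriented(d, "mode").threshold == 1.0

    def test_mode_tie_takes_smallest(self):
        assert rr.marker_mode(np.array([1.0, 1.0, 5.0, 5.0, 3.0])) == 1.0

    def test_mode_continuous_histogram_peak(self):
        rng = np.random.default_rng(9)
        x = rng.normal(50, 5, 500)
        assert np.unique(x).size == x.size  # all distinct
        edges = np.histogram_bin_edges(x, bins="fd")
        hist, edges = np.histogram(x, bins=edges)
        k = int(np.argmax(hist))
        expected = (edges[k] + edges[k + 1]) / 2
        assert rr.marker_mode(x) == pytest.approx(expected)

    def test_constant_marker_mode(self):
        assert rr.marker_mode(np.array([2.0, 2.0, 2.0])) == 2.0

    def test_unknown_statistic(self, perfect_data):
        with pytest.raises(ValueError):
            rr.biomarker_oriented(perfect_data, "midhinge")


class TestManual:
    def test_passthrough(self, nafld_cohort):
        r = rr.manual_cutoff(nafld_cohort, 45.326)
        assert r.method == "manual" and r.threshold == 45.326

    def test_threshold_below_all_values(self, nafld_cohort):
        cm = rr.confusion_at(nafld_cohort, nafld_cohort.marker.min() - 1)
        assert cm.sensitivity == 1.0 and cm.specificity == 0.0

    def test_threshold_above_all_values(self, nafld_cohort):
        cm = rr.confusion_at(nafld_cohort, nafld_cohort.marker.max() + 1)
        assert cm.sensitivity == 0.0 and cm.specificity == 1.0

    def test_non_finite_rejected(self, nafld_cohort):
        with pytest.raises(ValueError):
            rr.manual_cutoff(nafld_cohort, np.inf)


class TestOracleProperties:
    @given(dataset_strategy())
    def test_youden_and_topleft_match_enumeration(self, data):
        c = rr.build_roc(data, direction=rr.GREATER)
        y = rr.youden(c)
        cy, jy = best_youden(data.positives, data.negatives)
        assert y.threshold == pytest.approx(cy)
        assert y.criterion_value == pytest.approx(jy, abs=1e-12)
        t = rr.closest_topleft(c)
        ct, dt = best_topleft(data.positives, data.negatives)
        assert t.threshold == pytest.approx(ct)
        assert t.criterion_value == pytest.approx(dt, abs=1e-12)

    @given(dataset_strategy())
    def test_selected_threshold_in_candidate_set(self, data):
        c = rr.build_roc(data, direction=rr.GREATER)
        cand = set(c.thresholds.tolist())
        assert rr.youden(c).threshold in cand
        assert rr.closest_topleft(c).threshold in cand

    def test_monotone_transform_equivariance(self, nafld_cohort):
        """A strictly increasing remap of the marker moves the selected
        cutoff into the image of the original inter-value gap."""
        c1 = rr.build_roc(nafld_cohort, direction=rr.GREATER)
        y1 = rr.youden(c1)
        f = lambda v: v ** 3 / 1000.0  # strictly increasing on positives
        warped = rr.from_arrays(f(nafld_cohort.marker), nafld_cohort.outcome)
        c2 = rr.build_roc(warped, direction=rr.GREATER)
        y2 = rr.youden(c2)
        x = np.sort(nafld_cohort.marker)
        lo = x[x < y1.threshold].max()
        hi = x[x > y1.threshold].min()
        assert f(lo) < y2.threshold < f(hi)
        # and identical operating characteristics
        assert (y1.sensitivity, y1.specificity) == (y2.sensitivity, y2.specificity)
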