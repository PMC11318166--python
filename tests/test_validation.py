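import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chematlas import (
    RegionSelection,
    binary_cross_entropy,
    classification_metrics,
    clip_color_range,
    confusion_counts,
    kde_curves,
    loss_vector,
    region_report,
    roc_auc,
    select_region,
)


class TestBinaryCrossEntropy:
    @pytest.mark.parametrize(
        "y, p, expected",
        [
            (1, 1.0, 0.0),                      # confident correct (up to the clamp)
            (0, 0.0, 0.0),
            (1, 0.5, math.log(2)),              # maximal uncertainty
            (0, 0.177, -math.log(0.823)),       # a 17.7% activity call on an inactive
        ],
    )
    def test_closed_forms(self, y, p, expected):
        assert binary_cross_entropy(y, p) == pytest.approx(expected, abs=1e-6)

    def test_exact_closed_forms_at_high_precision(self):
        assert binary_cross_entropy(1, 0.5) == pytest.approx(math.log(2), abs=1e-10)
        assert binary_cross_entropy(0, 0.177) == pytest.approx(-math.log(0.823), abs=1e-10)

    def test_matches_high_precision_evaluation(self):
        """Float formula agrees with 30-digit symbolic evaluation on random pairs."""
        import sympy

        rng = np.random.default_rng(13)
        ps = rng.uniform(1e-6, 1 - 1e-6, 1000)
        ys = rng.integers(0, 2, 1000)
        for y, p in zip(ys, ps):
            exact = -(
                int(y) * sympy.log(sympy.Float(p, 30))
                + (1 - int(y)) * sympy.log(1 - sympy.Float(p, 30))
            )
            assert binary_cross_entropy(int(y), float(p)) == pytest.approx(
                float(exact.evalf(30)), rel=1e-10, abs=1e-12
            )

    def test_wrong_confident_prediction_is_finite_and_large(self):
        loss = binary_cross_entropy(1, 0.0)
        assert np.isfinite(loss) and loss > 10

    @pytest.mark.parametrize("p", [-0.1, 1.1])
    def test_probability_out_of_range_fatal(self, p):
        with pytest.raises(ValueError):
            binary_cross_entropy(1, p)

    @settings(deadline=None, derandomize=True)
    @given(
        st.floats(min_value=0.0, max_value=0.999),
        st.floats(min_value=1e-6, max_value=0.001),
    )
    def test_strictly_decreasing_in_p_for_active(self, p, delta):
        if p + delta <= 1.0:
            assert binary_cross_entropy(1, p + delta) < binary_cross_entropy(1, p)


class TestRegionSelection:
    def test_universal_rectangle_selects_all(self):
        xy = np.random.default_rng(0).normal(size=(30, 2))
        reg = RegionSelection.rectangle(-100, 100, -100, 100)
        assert len(select_region(xy, reg)) == 30

    def test_remote_rectangle_selects_none(self):
        xy = np.zeros((5, 2))
        reg = RegionSelection.rectangle(10, 11, 10, 11)
        assert len(select_region(xy, reg)) == 0

    def test_unit_square_polygon(self):
        reg = RegionSelection.polygon([(0, 0), (1, 0), (1, 1), (0, 1)])
        xy = np.array([[0.5, 0.5], [2.0, 2.0], [0.0, 0.0]])
        assert list(select_region(xy, reg)) == [0, 2]  # boundary inclusive

    def test_rectangle_boundary_inclusive(self):
        reg = RegionSelection.rectangle(0, 1, 0, 1)
        assert list(select_region(np.array([[0.0, 1.0]]), reg)) == [0]

    def test_polygon_needs_three_vertices(self):
        with pytest.raises(ValueError):
            RegionSelection.polygon([(0, 0), (1, 1)])

    @settings(deadline=None, derandomize=True)
    @given(st.floats(min_value=0.1, max_value=5.0), st.floats(min_value=0.0, max_value=3.0))
    def test_nested_regions_monotone(self, half_width, extra):
        xy = np.random.default_rng(1).normal(size=(50, 2))
        inner = RegionSelection.rectangle(-half_width, half_width, -half_width, half_width)
        outer = RegionSelection.rectangle(
            -half_width - extra, half_width + extra, -half_width - extra, half_width + extra
        )
        assert len(select_region(xy, inner)) <= len(select_region(xy, outer))


class TestConfusionCounts:
    def test_simple(self):
        assert confusion_counts([1, 0], [0.9, 0.1]) == (1, 0, 1, 0)

    def test_threshold_boundary_is_positive(self):
        assert confusion_counts([1], [0.5]) == (1, 0, 0, 0)

    def test_matches_per_element_loop(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, 50)
        p = rng.random(50)
        tp = fp = tn = fn = 0
        for yi, pi in zip(y, p):
            pred = pi >= 0.5
            if pred and yi == 1:
                tp += 1
            elif pred:
                fp += 1
            elif yi == 0:
                tn += 1
            else:
                fn += 1
        assert confusion_counts(y, p) == (tp, fp, tn, fn)

    def test_length_mismatch_fatal(self):
        with pytest.raises(ValueError):
            confusion_counts([1, 0], [0.5])


def oracle_metrics(tp, fp, tn, fn):
    """Definition-level brute-force metrics with None for 0/0."""
    def div(a, b):
        return a / b if b else None

    n = tp + fp + tn + fn
    sens = div(tp, tp + fn)
    spec = div(tn, tn + fp)
    out = {
        "sensitivity": sens,
        "specificity": spec,
        "accuracy": div(tp + tn, n),
        "balanced_accuracy": (sens + spec) / 2 if sens is not None and spec is not None else None,
        "f1": div(2 * tp, 2 * tp + fp + fn),
    }
    den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    out["mcc"] = (tp * tn - fp * fn) / den if den else 0.0
    return out


class TestClassificationMetrics:
    def test_perfect_classifier(self):
        m = classification_metrics((50, 0, 50, 0))
        assert m.sensitivity == m.specificity == m.accuracy == 1.0
        assert m.balanced_accuracy == m.f1 == m.mcc == 1.0

    def test_worked_example(self):
        m = classification_metrics((6, 2, 3, 1))
        assert m.sensitivity == pytest.approx(6 / 7)
        assert m.specificity == pytest.approx(3 / 5)
        assert m.accuracy == pytest.approx(9 / 12)
        assert m.mcc == pytest.approx((18 - 2) / math.sqrt(8 * 7 * 5 * 4))

    def test_worked_example_against_sklearn(self):
        from sklearn.metrics import f1_score, matthews_corrcoef

        y = [1] * 6 + [0] * 2 + [0] * 3 + [1] * 1
        pred = [1] * 6 + [1] * 2 + [0] * 3 + [0] * 1
        m = classification_metrics((6, 2, 3, 1))
        assert m.mcc == pytest.approx(matthews_corrcoef(y, pred), abs=1e-12)
        assert m.f1 == pytest.approx(f1_score(y, pred), abs=1e-12)

    def test_undefined_marker_for_degenerate(self):
        m = classification_metrics((3, 0, 0, 2))  # no negatives in the region
        assert m.specificity is None
        assert "specificity_undefined" in m.flags
        assert m.balanced_accuracy is None
        assert m.sensitivity == pytest.approx(0.6)

    def test_mcc_zero_denominator_convention(self):
        m = classification_metrics((2, 0, 0, 0))
        assert m.mcc == 0.0
        assert "mcc_zero_denominator" in m.flags

    def test_exhaustive_against_brute_force(self):
        """All confusion tables with n <= 12 match the definition-level oracle."""
        for tp, fp, tn, fn in itertools.product(range(13), repeat=4):
            if not 1 <= tp + fp + tn + fn <= 12:
                continue
            m = classification_metrics((tp, fp, tn, fn))
            expected = oracle_metrics(tp, fp, tn, fn)
            for name, want in expected.items():
                got = getattr(m, name)
                if want is None:
                    assert got is None, (tp, fp, tn, fn, name)
                else:
                    assert got == pytest.approx(want, abs=1e-12), (tp, fp, tn, fn, name)


def oracle_auc_pairwise(y, p):
    """AUC as the tie-corrected probability that a positive outscores a negative."""
    pos = p[y == 1]
    neg = p[y == 0]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        _, auc = roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert auc == 1.0

    def test_enumerated_example(self):
        # pairs: (.8,.6)+ (.8,.2)+ (.4,.6)- (.4,.2)+  -> 3/4 concordant
        _, auc = roc_auc([1, 1, 0, 0], [0.8, 0.4, 0.6, 0.2])
        assert auc == pytest.approx(0.75)

    def test_all_ties_give_half(self):
        _, auc = roc_auc([1, 0, 1, 0], [0.5, 0.5, 0.5, 0.5])
        assert auc == pytest.approx(0.5)

    def test_single_class_undefined(self):
        curve, auc = roc_auc([1, 1, 1], [0.2, 0.5, 0.9])
        assert auc is None
        assert curve.empty

    def test_curve_endpoints(self):
        curve, _ = roc_auc([0, 1, 0, 1], [0.3, 0.6, 0.5, 0.9])
        assert (curve.iloc[0].fpr, curve.iloc[0].tpr) == (0.0, 0.0)
        assert (curve.iloc[-1].fpr, curve.iloc[-1].tpr) == (1.0, 1.0)

    def test_trapezoid_equals_pairwise_enumeration(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            n = rng.integers(4, 40)
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                y[0] = 1 - y[0]
            p = np.round(rng.random(n), 1)  # coarse grid forces ties
            _, auc = roc_auc(y, p)
            assert auc == pytest.approx(oracle_auc_pairwise(y, p), abs=1e-10)

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(4)
        for _ in range(20):
            y = rng.integers(0, 2, 30)
            if y.min() == y.max():
                y[0] = 1 - y[0]
            p = rng.random(30)
            _, auc = roc_auc(y, p)
            assert auc == pytest.approx(roc_auc_score(y, p), abs=1e-12)


class TestKdeCurves:
    def test_single_location_peaks_there(self):
        curves = kde_curves(np.full(10, 0.5), np.zeros(10, dtype=int))
        d0 = curves["density_class0"].to_numpy()
        assert curves["grid"].iloc[int(np.argmax(d0))] == pytest.approx(0.5, abs=0.01)

    def test_two_groups_give_bimodal_density(self):
        p = np.concatenate([np.random.default_rng(5).normal(0.2, 0.02, 50),
                            np.random.default_rng(6).normal(0.8, 0.02, 50)])
        p = np.clip(p, 0, 1)
        curves = kde_curves(p, np.zeros(100, dtype=int))
        d = curves["density_class0"].to_numpy()
        interior_maxima = [
            i for i in range(1, len(d) - 1) if d[i] > d[i - 1] and d[i] >= d[i + 1] and d[i] > 0.5
        ]
        assert len(interior_maxima) >= 2

    def test_nonnegative_everywhere(self):
        rng = np.random.default_rng(7)
        curves = kde_curves(rng.random(40), rng.integers(0, 2, 40))
        assert (curves[["density_class0", "density_class1"]] >= 0).all().all()

    def test_density_integrates_to_one(self):
        # interior data so boundary truncation is negligible
        rng = np.random.default_rng(8)
        p = np.clip(rng.normal(0.5, 0.05, 200), 0, 1)
        curves = kde_curves(p, np.zeros(200, dtype=int))
        integral = np.trapezoid(curves["density_class0"], curves["grid"])
        assert integral == pytest.approx(1.0, abs=0.05)

    def test_singleton_class_handled(self):
        curves = kde_curves(np.array([0.4]), np.array([1]))
        d1 = curves["density_class1"].to_numpy()
        assert np.all(np.isfinite(d1)) and d1.max() > 0


class TestClipColorRange:
    def test_endpoints_and_midpoint(self):
        out = clip_color_range(np.array([2.0, 4.0, 3.0]), 2.0, 4.0)
        assert np.allclose(out, [0.0, 1.0, 0.5])

    def test_clamping(self):
        out = clip_color_range(np.array([-10.0, 10.0]), 0.0, 1.0)
        assert np.allclose(out, [0.0, 1.0])

    def test_invalid_range_fatal(self):
        with pytest.raises(ValueError):
            clip_color_range(np.array([1.0]), 2.0, 2.0)


class TestRegionReport:
    def _data(self, n=60, seed=9):
        rng = np.random.default_rng(seed)
        xy = rng.normal(size=(n, 2))
        y = rng.integers(0, 2, n)
        p = np.clip(0.6 * y + 0.2 * rng.random(n), 0, 1)
        return xy, y, p

    def test_whole_plane_reproduces_global(self):
        xy, y, p = self._data()
        bbox = RegionSelection.rectangle(
            xy[:, 0].min(), xy[:, 0].max(), xy[:, 1].min(), xy[:, 1].max()
        )
        global_rep = region_report(xy, y, p, region=None)
        boxed = region_report(xy, y, p, region=bbox)
        assert boxed.to_dict() == global_rep.to_dict()

    def test_confidently_correct_region(self):
        xy = np.array([[0.0, 0], [0.1, 0], [5, 5], [5.1, 5]])
        y = np.array([1, 0, 1, 0])
        p = np.array([0.99, 0.01, 0.2, 0.8])  # left cluster correct, right wrong
        rep = region_report(xy, y, p, region=RegionSelection.rectangle(-1, 1, -1, 1))
        assert rep.metrics.accuracy == 1.0
        assert rep.mean_loss < 0.02

    def test_empty_region_reports_n_zero(self):
        xy, y, p = self._data()
        rep = region_report(xy, y, p, region=RegionSelection.rectangle(99, 100, 99, 100))
        assert rep.metrics.n == 0
        assert rep.metrics.sensitivity is None
        assert rep.mean_loss is None
        assert "empty_region" in rep.metrics.flags

    def test_loss_vector_matches_scalar(self):
        y = np.array([0, 1, 1, 0])
        p = np.array([0.1, 0.9, 0.2, 0.8])
        expected = [binary_cross_entropy(int(yi), float(pi)) for yi, pi in zip(y, p)]
        assert np.allclose(loss_vector(y, p), expected, atol=1e-12)
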