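"""Diagnostic-accuracy primitives: confusion metrics, kappa, ROC/AUC, chi-squared."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats
from sklearn.metrics import cohen_kappa_score, roc_auc_score

from pednutriscreen.diagnostics import (
    ConfusionMatrix,
    ROCPoint,
    auc_trapezoid,
    cohen_kappa,
    confusion_matrix,
    diagnostic_metrics,
    pearson_chi_squared,
    roc_curve,
    round_half_away,
    select_cutoff_max_youden,
)
from pednutriscreen.errors import ComputationError, InputError

# confusion matrix of the reconstructed validation cohort at cut-off 2
CM_STUDY = ConfusionMatrix(tp=248, fp=103, fn=24, tn=750)


class TestConfusionMatrix:
    def test_perfect_pair(self):
        cm = confusion_matrix([True, False], [True, False])
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (1, 0, 0, 1)

    def test_all_false_positive(self):
        cm = confusion_matrix([True, True], [False, False])
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (0, 2, 0, 0)

    def test_length_mismatch_and_empty_rejected(self):
        with pytest.raises(InputError):
            confusion_matrix([True], [True, False])
        with pytest.raises(InputError):
            confusion_matrix([], [])

    def test_negative_count_rejected(self):
        with pytest.raises(InputError):
            ConfusionMatrix(tp=-1, fp=0, fn=0, tn=2)


class TestDiagnosticMetrics:
    def test_study_confusion_matrix(self):
        m = diagnostic_metrics(CM_STUDY)
        assert m.sensitivity == pytest.approx(0.912, abs=5e-4)
        assert m.specificity == pytest.approx(0.879, abs=5e-4)
        assert m.ppv == pytest.approx(0.707, abs=5e-4)
        assert m.npv == pytest.approx(0.969, abs=5e-4)
        assert m.youden == pytest.approx(0.791, abs=5e-4)

    def test_perfect_classifier(self):
        m = diagnostic_metrics(ConfusionMatrix(10, 0, 0, 10))
        assert (m.sensitivity, m.specificity, m.ppv, m.npv, m.youden) == \
            (1.0, 1.0, 1.0, 1.0, 1.0)

    def test_degenerate_denominators_are_undefined_not_zero(self):
        m = diagnostic_metrics(ConfusionMatrix(0, 0, 5, 5))
        assert m.sensitivity == 0.0
        assert m.ppv is None

    @given(tp=st.integers(0, 50), fp=st.integers(0, 50),
           fn=st.integers(0, 50), tn=st.integers(0, 50))
    def test_youden_identity(self, tp, fp, fn, tn):
        if tp + fn == 0 or tn + fp == 0:
            return
        m = diagnostic_metrics(ConfusionMatrix(tp, fp, fn, tn))
        assert m.youden == m.sensitivity + m.specificity - 1.0


class TestCohenKappa:
    def test_study_value(self):
        assert cohen_kappa(CM_STUDY) == pytest.approx(0.720, abs=5e-4)

    def test_perfect_agreement(self):
        assert cohen_kappa(ConfusionMatrix(10, 0, 0, 10)) == pytest.approx(1.0)

    def test_chance_agreement(self):
        assert cohen_kappa(ConfusionMatrix(25, 25, 25, 25)) == pytest.approx(0.0)

    def test_pe_one_is_undefined(self):
        with pytest.raises(ComputationError):
            cohen_kappa(ConfusionMatrix(5, 0, 0, 0))

    @given(tp=st.integers(0, 30), fp=st.integers(0, 30),
           fn=st.integers(0, 30), tn=st.integers(0, 30))
    def test_matches_sklearn_and_bounds(self, tp, fp, fn, tn):
        cm = np.array([[tp, fp], [fn, tn]])
        if cm.sum() == 0:
            return
        pred = np.repeat([1, 1, 0, 0], [tp, fp, fn, tn])
        ref = np.repeat([1, 0, 1, 0], [tp, fp, fn, tn])
        p_e = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / cm.sum() ** 2
        if p_e == 1.0:
            return
        kappa = cohen_kappa(ConfusionMatrix(tp, fp, fn, tn))
        assert kappa == pytest.approx(
            cohen_kappa_score(ref, pred), abs=1e-12)
        p_o = (tp + tn) / cm.sum()
        assert kappa <= p_o + 1e-12 <= 1 + 1e-12
        both_classes = (tp + fn) > 0 and (fp + tn) > 0
        if both_classes:
            assert (kappa == pytest.approx(1.0)) == (fp == 0 and fn == 0)


class TestRocCurve:
    def test_single_class_reference_rejected(self):
        with pytest.raises(InputError):
            roc_curve([1, 2, 3], [True, True, True])

    def test_threshold_below_min_is_all_positive(self):
        pts = roc_curve([0, 1], [False, True], candidate_thresholds=[-1.0])
        p = [q for q in pts if q.threshold == -1.0][0]
        assert (p.false_positive_rate, p.sensitivity) == (1.0, 1.0)

    def test_threshold_above_max_is_all_negative(self):
        pts = roc_curve([0, 1], [False, True], candidate_thresholds=[5.0])
        p = [q for q in pts if q.threshold == 5.0][0]
        assert (p.false_positive_rate, p.sensitivity) == (0.0, 0.0)

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(7)
        scores = rng.integers(0, 7, size=300)
        ref = rng.random(300) < 0.3
        ref[0], ref[1] = True, False
        pts = roc_curve(scores, ref)
        sens = [p.sensitivity for p in pts]
        fpr = [p.false_positive_rate for p in pts]
        assert sens == sorted(sens, reverse=True)
        assert fpr == sorted(fpr, reverse=True)


class TestAucTrapezoid:
    def test_perfect_separation(self):
        pts = roc_curve([0, 0, 1, 1], [False, False, True, True])
        assert auc_trapezoid(pts) == pytest.approx(1.0)

    def test_identical_distributions(self):
        pts = roc_curve([0, 1, 0, 1], [False, False, True, True])
        assert auc_trapezoid(pts) == pytest.approx(0.5)

    def test_label_swap_with_score_negation_invariance(self):
        rng = np.random.default_rng(11)
        scores = rng.integers(0, 7, 200).astype(float)
        ref = rng.random(200) < 0.4
        ref[:2] = [True, False]
        a = auc_trapezoid(roc_curve(scores, ref))
        thresholds = sorted(set(-s + 0.5 for s in range(0, 8)))
        b = auc_trapezoid(roc_curve(-scores, ~ref, thresholds))
        assert 0.0 <= a <= 1.0
        assert a == pytest.approx(b, abs=1e-12)

    def test_matches_sklearn_on_integer_scores(self):
        # half-integer thresholds hit every step of the empirical ROC, so the
        # trapezoid equals the rank-based AUC
        rng = np.random.default_rng(3)
        scores = rng.integers(0, 7, 500).astype(float)
        ref = rng.random(500) < 0.35
        ref[:2] = [True, False]
        mine = auc_trapezoid(roc_curve(scores, ref))
        assert mine == pytest.approx(roc_auc_score(ref, scores), abs=1e-12)


class TestSelectCutoff:
    def test_tie_breaks_toward_higher_specificity(self):
        pts = [
            ROCPoint(threshold=1.5, sensitivity=0.9, false_positive_rate=0.3),
            ROCPoint(threshold=2.5, sensitivity=0.7, false_positive_rate=0.1),
        ]
        cut, youden = select_cutoff_max_youden(pts)
        assert cut == 3 and youden == pytest.approx(0.6)

    def test_single_interior_point(self):
        pts = [ROCPoint(threshold=0.5, sensitivity=0.8, false_positive_rate=0.2)]
        assert select_cutoff_max_youden(pts) == (1, pytest.approx(0.6))

    def test_endpoints_never_selected(self):
        pts = [
            ROCPoint(threshold=-0.5, sensitivity=1.0, false_positive_rate=1.0),
            ROCPoint(threshold=0.5, sensitivity=0.6, false_positive_rate=0.2),
            ROCPoint(threshold=6.5, sensitivity=0.0, false_positive_rate=0.0),
        ]
        assert select_cutoff_max_youden(pts)[0] == 1


class TestPearsonChiSquared:
    @pytest.mark.parametrize("table,statistic,df", [
        ([[118, 75], [233, 699]], 97.286, 1),
        ([[13, 522], [209, 181], [129, 71]], 400.694, 2),
        ([[187, 241, 176, 170], [211, 79, 27, 34]], 144.933, 3),
    ])
    def test_group_contrast_tables(self, table, statistic, df):
        r = pearson_chi_squared(table)
        assert round_half_away(r.statistic, 3) == pytest.approx(statistic)
        assert r.df == df
        assert r.p_value < 0.01

    def test_proportional_rows_give_zero(self):
        r = pearson_chi_squared([[10, 10], [20, 20]])
        assert r.statistic == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)

    def test_zero_expected_cell_names_the_cell(self):
        with pytest.raises(ComputationError, match=r"\(.*1.*\)"):
            pearson_chi_squared([[1, 0], [2, 0]])

    def test_yates_correction_matches_scipy(self):
        table = [[12, 5], [7, 19]]
        mine = pearson_chi_squared(table, yates=True)
        ref = stats.chi2_contingency(np.array(table), correction=True)
        assert mine.statistic == pytest.approx(ref.statistic, abs=1e-12)

    @given(st.lists(st.lists(st.integers(0, 40), min_size=2, max_size=4),
                    min_size=2, max_size=4).filter(
                        lambda rows: len({len(r) for r in rows}) == 1))
    def test_agrees_with_brute_force_and_scipy(self, rows):
        obs = np.array(rows, dtype=float)
        if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
            return
        r = pearson_chi_squared(rows)
        # cell-by-cell brute force
        total = obs.sum()
        stat = 0.0
        for i in range(obs.shape[0]):
            for j in range(obs.shape[1]):
                e = obs[i].sum() * obs[:, j].sum() / total
                stat += (obs[i, j] - e) ** 2 / e
        assert r.statistic == pytest.approx(stat, abs=1e-9)
        ref = stats.chi2_contingency(obs, correction=False)
        assert r.statistic == pytest.approx(ref.statistic, abs=1e-9)
        assert r.p_value == pytest.approx(ref.pvalue, abs=1e-9)


@pytest.mark.parametrize("x,nd,expected", [
    (0.7915, 3, 0.792), (-0.1235, 3, -0.124), (97.2865, 3, 97.287),
    (91.15, 1, 91.2), (2.5, 0, 3.0),
])
def test_round_half_away_from_zero(x, nd, expected):
    assert round_half_away(x, nd) == expected
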