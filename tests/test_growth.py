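"""LMS growth-reference engine: transform, interpolation, indicator sets."""

import io
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pednutriscreen.cohort import synthetic_lms_table
from pednutriscreen.errors import (
    ConfigurationError,
    DomainError,
    FormatError,
    OutOfRangeError,
    ValidityError,
)
from pednutriscreen.growth import (
    AxisKind,
    GrowthReference,
    Indicator,
    ReferenceLibrary,
    Sex,
    compute_bmi,
    days_to_months,
    interpolated_lms,
    lms_inverse,
    lms_zscore,
    load_growth_reference,
    zscore_set,
)
from pednutriscreen.screening import SubjectRecord


def _table(text):
    return io.StringIO(text)


class TestLoadGrowthReference:
    def test_minimal_two_row_table(self):
        ref = load_growth_reference(
            _table("age_months,L,M,S\n0,1,3.3,0.12\n1,1,4.3,0.12\n"),
            Indicator.WFA, Sex.MALE)
        assert len(ref.axis) == 2
        assert ref.axis_kind is AxisKind.AGE_MONTHS
        assert ref.sex is Sex.MALE

    def test_tab_delimited_and_axis_kind_from_header(self):
        ref = load_growth_reference(
            _table("height_cm\tL\tM\tS\n50\t1\t3.4\t0.1\n60\t1\t5.7\t0.1\n"),
            Indicator.WFH, Sex.FEMALE)
        assert ref.axis_kind is AxisKind.HEIGHT_CM

    def test_duplicate_axis_value_is_format_error(self):
        with pytest.raises(FormatError):
            load_growth_reference(
                _table("age_months,L,M,S\n0,1,3.3,0.12\n0,1,4.3,0.12\n"),
                Indicator.WFA, Sex.MALE)

    def test_nonpositive_s_is_validity_error(self):
        with pytest.raises(ValidityError):
            load_growth_reference(
                _table("age_months,L,M,S\n0,1,3.3,0\n1,1,4.3,0.12\n"),
                Indicator.WFA, Sex.MALE)

    def test_missing_column_is_format_error(self):
        with pytest.raises(FormatError):
            load_growth_reference(
                _table("age_months,L,M\n0,1,3.3\n1,1,4.3\n"),
                Indicator.WFA, Sex.MALE)

    def test_single_row_is_invalid(self):
        with pytest.raises(ValidityError):
            load_growth_reference(
                _table("age_months,L,M,S\n0,1,3.3,0.12\n"),
                Indicator.WFA, Sex.MALE)


class TestLmsZscore:
    def test_median_maps_to_zero(self):
        assert lms_zscore(16.0, -1.6, 16.0, 0.08) == pytest.approx(0.0)

    def test_unit_power_reduces_to_relative_deviation(self):
        # L=1: z = (x/M - 1)/S
        assert lms_zscore(12.0, 1.0, 10.0, 0.1) == pytest.approx(2.0)

    def test_skewed_reference_value(self):
        # frozen from an independent evaluation of ((x/M)^L - 1)/(L S)
        assert lms_zscore(14.0, -1.6, 16.0, 0.08) == pytest.approx(
            -1.861, abs=1e-3)

    @pytest.mark.parametrize("x,M,S", [(0.0, 10.0, 0.1), (-1.0, 10.0, 0.1),
                                       (10.0, 0.0, 0.1), (10.0, 10.0, -0.1)])
    def test_nonpositive_inputs_rejected(self, x, M, S):
        with pytest.raises(DomainError):
            lms_zscore(x, 1.0, M, S)

    @given(
        x=st.floats(0.5, 200.0),
        L=st.floats(-3.0, 3.0),
        M=st.floats(1.0, 100.0),
        S=st.floats(0.01, 0.5),
    )
    def test_round_trip_through_inverse(self, x, L, M, S):
        z = lms_zscore(x, L, M, S)
        if abs(L) > 1e-10 and 1.0 + L * S * z <= 0:
            return  # outside the invertible branch
        x2 = lms_inverse(z, L, M, S)
        assert lms_zscore(x2, L, M, S) == pytest.approx(z, abs=1e-9)

    @given(
        L=st.floats(-1e-6, 1e-6),
        M=st.floats(1.0, 100.0),
        S=st.floats(0.01, 0.3),
        # power-vs-log discrepancy ~ L*S*k^2/2, so keep |z| modest
        k=st.floats(-2.0, 2.0),
    )
    def test_log_limit_agrees_with_power_form(self, L, M, S, k):
        # whichever branch is taken, the result must sit within 1e-6 of the
        # exact log-form limit (the naive float power form cancels badly
        # here, which is exactly what the implementation must avoid)
        x = M * math.exp(S * k)
        z_log = math.log(x / M) / S
        assert lms_zscore(x, L, M, S) == pytest.approx(z_log, abs=1e-6)

    @given(
        L=st.floats(-2.0, 2.0),
        M=st.floats(1.0, 50.0),
        S=st.floats(0.02, 0.3),
        x1=st.floats(1.0, 100.0),
        x2=st.floats(1.0, 100.0),
    )
    def test_strictly_increasing_in_measurement(self, L, M, S, x1, x2):
        if x1 == x2:
            return
        lo, hi = sorted((x1, x2))
        assert lms_zscore(lo, L, M, S) < lms_zscore(hi, L, M, S)


class TestInterpolatedLms:
    @pytest.fixture()
    def ref(self):
        return GrowthReference(
            Indicator.WFA, Sex.MALE, AxisKind.AGE_MONTHS,
            axis=[0.0, 2.0, 4.0], L=[1.0, 0.5, 0.0],
            M=[10.0, 12.0, 13.0], S=[0.1, 0.12, 0.14])

    def test_exact_node_passthrough(self, ref):
        assert interpolated_lms(ref, 2.0) == (0.5, 12.0, 0.12)

    def test_linear_midpoint(self, ref):
        L, M, S = interpolated_lms(ref, 1.0)
        assert (L, M, S) == pytest.approx((0.75, 11.0, 0.11))

    @pytest.mark.parametrize("q", [-0.5, 4.1])
    def test_no_extrapolation(self, ref, q):
        with pytest.raises(OutOfRangeError):
            interpolated_lms(ref, q)

    def test_continuous_between_nodes(self, ref):
        qs = np.linspace(0.0, 4.0, 401)
        vals = np.array([interpolated_lms(ref, q) for q in qs])
        steps = np.abs(np.diff(vals, axis=0)).max()
        assert steps < 0.05  # dense sampling: no jumps beyond the local slope


class TestComputeBmi:
    @pytest.mark.parametrize("w,h,expected", [(10.0, 100.0, 10.0),
                                              (3.2, 50.0, 12.8)])
    def test_formula(self, w, h, expected):
        assert compute_bmi(w, h) == pytest.approx(expected)

    def test_nonpositive_rejected(self):
        with pytest.raises(DomainError):
            compute_bmi(0.0, 100.0)


class TestZscoreSet:
    def test_under_five_medians_map_to_zero(self, references):
        # age 30 months, weight and height at the synthetic medians
        rec = SubjectRecord(id="a", sex=Sex.MALE, age_months=30.0,
                            weight_kg=4 + 0.25 * 30, height_cm=50 + 0.5 * 30,
                            diagnosis_code="x")
        z = zscore_set(rec, references)
        assert z.wfa == pytest.approx(0.0, abs=1e-9)
        assert z.hfa == pytest.approx(0.0, abs=1e-9)
        assert z.wfh == pytest.approx(0.0, abs=1e-9)
        assert z.bmi is None

    def test_over_five_uses_bmi_only(self, references):
        rec = SubjectRecord(id="a", sex=Sex.FEMALE, age_months=72.0,
                            weight_kg=22.0, height_cm=86.0,
                            diagnosis_code="x")
        z = zscore_set(rec, references)
        assert z.wfa is None and z.hfa is None and z.wfh is None
        assert z.bmi is not None and math.isfinite(z.bmi)

    def test_closed_form_against_linear_fixture(self, references):
        # L=1, linear M: z = (x/M(age) - 1)/S exactly, even off-node
        age, S = 31.7, 0.11
        M = 4 + 0.25 * age
        x = M * 1.23
        rec = SubjectRecord(id="a", sex=Sex.MALE, age_months=age,
                            weight_kg=x, height_cm=50 + 0.5 * age,
                            diagnosis_code="x")
        z = zscore_set(rec, references)
        assert z.wfa == pytest.approx((x / M - 1) / S, abs=1e-9)

    def test_missing_reference_is_configuration_error(self):
        lib = ReferenceLibrary([synthetic_lms_table(
            Indicator.WFA, Sex.MALE, AxisKind.AGE_MONTHS,
            0.0, 216.0, 4.0, 0.25, 0.11)])
        rec = SubjectRecord(id="a", sex=Sex.MALE, age_months=30.0,
                            weight_kg=10.0, height_cm=65.0,
                            diagnosis_code="x")
        with pytest.raises(ConfigurationError):
            zscore_set(rec, lib)

    def test_implausible_values_flagged_not_censored(self, references):
        rec = SubjectRecord(id="a", sex=Sex.MALE, age_months=30.0,
                            weight_kg=30.0, height_cm=65.0,
                            diagnosis_code="x")
        z = zscore_set(rec, references)
        assert z.wfa > 5 and "wfa" in z.flagged


def test_days_to_months_mean_month():
    assert days_to_months(30.4375) == pytest.approx(1.0)
    assert days_to_months(365.25) == pytest.approx(12.0)
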