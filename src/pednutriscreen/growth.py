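"""LMS growth-reference engine: anthropometric z-scores for children.

Growth references parameterize the distribution of a measurement (weight,
height/length, BMI) at each value of an axis variable (age in months, or
length/height in cm) by three quantities: the Box-Cox power ``L``, the median
``M`` and the coefficient of variation ``S``.  A measurement ``x`` maps to a
z-score via the LMS transform

    z = ((x / M)**L - 1) / (L * S)        if L != 0
    z = ln(x / M) / S                     if L == 0

which is the computation behind the WHO child-growth standard charts.  This
module loads reference tables, interpolates L/M/S at arbitrary axis values,
and evaluates the full indicator set for a subject:

* weight-for-age (WFA), height/length-for-age (HFA) and weight-for-height
  (WFH) for children under five years;
* BMI-for-age for ages five to eighteen years.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    DomainError,
    FormatError,
    OutOfRangeError,
    ValidityError,
)

__all__ = [
    "Indicator",
    "Sex",
    "AxisKind",
    "MeasurementMode",
    "GrowthReference",
    "ReferenceLibrary",
    "ZScoreSet",
    "load_growth_reference",
    "lms_zscore",
    "lms_inverse",
    "interpolated_lms",
    "compute_bmi",
    "zscore_set",
    "days_to_months",
]

# Below this |L| the Box-Cox power form is numerically indistinguishable from
# its log-form limit; switch to avoid cancellation.
_L_EPS = 1e-10

# Age applicability (months): the under-five indicator set vs BMI-for-age.
UNDER_FIVE_MAX_AGE = 60.0
MAX_AGE_MONTHS = 216.0

# |z| beyond this is biologically implausible and flagged (not censored).
IMPLAUSIBLE_Z = 5.0

_DAYS_PER_MONTH = 30.4375


class Indicator(str, Enum):
    WFA = "wfa"
    HFA = "hfa"
    WFH = "wfh"
    BMI_FOR_AGE = "bmi"


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"


class AxisKind(str, Enum):
    AGE_MONTHS = "age_months"
    LENGTH_CM = "length_cm"
    HEIGHT_CM = "height_cm"


class MeasurementMode(str, Enum):
    RECUMBENT = "recumbent"
    STANDING = "standing"


def days_to_months(days: float) -> float:
    """Convert an age in days to fractional months (mean month length)."""
    return days / _DAYS_PER_MONTH


@dataclass(frozen=True)
class GrowthReference:
    """A sex- and indicator-specific table of (axis, L, M, S) rows.

    Rows must be strictly increasing in the axis variable, with positive
    medians and coefficients of variation; at least two rows are required so
    that interpolation has an interval to work with.
    """

    indicator: Indicator
    sex: Sex
    axis_kind: AxisKind
    axis: np.ndarray
    L: np.ndarray
    M: np.ndarray
    S: np.ndarray

    def __post_init__(self) -> None:
        for name in ("axis", "L", "M", "S"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
        n = len(self.axis)
        if n < 2:
            raise ValidityError("growth reference needs at least 2 rows")
        if any(len(getattr(self, name)) != n for name in ("L", "M", "S")):
            raise ValidityError("axis, L, M, S must have equal length")
        if not np.all(np.isfinite(self.axis)) or np.any(np.diff(self.axis) <= 0):
            raise FormatError("axis values must be finite and strictly increasing")
        if np.any(~np.isfinite(self.M)) or np.any(self.M <= 0):
            raise ValidityError("M must be finite and > 0 in every row")
        if np.any(~np.isfinite(self.S)) or np.any(self.S <= 0):
            raise ValidityError("S must be finite and > 0 in every row")
        if np.any(~np.isfinite(self.L)):
            raise ValidityError("L must be finite in every row")

    @property
    def axis_range(self) -> tuple[float, float]:
        return float(self.axis[0]), float(self.axis[-1])


_AXIS_COLUMN_ALIASES = {
    "axis", "age", "age_months", "month", "months", "agemos",
    "length", "length_cm", "height", "height_cm", "stature",
}


def load_growth_reference(
    source,
    indicator: Indicator,
    sex: Sex,
    axis_kind: AxisKind | None = None,
) -> GrowthReference:
    """Read a delimited (comma or tab) L/M/S table into a :class:`GrowthReference`.

    The file needs a header row with an axis column (``age_months``,
    ``length_cm``, ``height_cm`` or simply the first column) and columns named
    ``L``, ``M``, ``S`` (case-insensitive).
    """
    try:
        df = pd.read_csv(source, sep=None, engine="python")
    except (pd.errors.ParserError, pd.errors.EmptyDataError, UnicodeDecodeError) as exc:
        raise FormatError(f"cannot parse growth-reference table: {exc}") from exc

    cols = {c.strip().lower(): c for c in df.columns}
    missing = [k for k in ("l", "m", "s") if k not in cols]
    if missing:
        raise FormatError(f"growth-reference table missing column(s): {missing}")
    axis_col = None
    for alias in _AXIS_COLUMN_ALIASES:
        if alias in cols:
            axis_col = cols[alias]
            break
    if axis_col is None:
        # fall back to the first non-LMS column
        others = [c for c in df.columns if c.strip().lower() not in ("l", "m", "s")]
        if not others:
            raise FormatError("growth-reference table has no axis column")
        axis_col = others[0]

    if axis_kind is None:
        name = axis_col.strip().lower()
        if name in ("length", "length_cm"):
            axis_kind = AxisKind.LENGTH_CM
        elif name in ("height", "height_cm", "stature"):
            axis_kind = AxisKind.HEIGHT_CM
        else:
            axis_kind = AxisKind.AGE_MONTHS

    sub = df[[axis_col, cols["l"], cols["m"], cols["s"]]].apply(
        pd.to_numeric, errors="coerce"
    )
    if sub.isna().any().any():
        raise FormatError("non-numeric value in growth-reference table")
    sub = sub.sort_values(axis_col)
    axis = sub[axis_col].to_numpy(dtype=float)
    if np.any(np.diff(axis) <= 0):
        raise FormatError("duplicate axis values in growth-reference table")
    return GrowthReference(
        indicator=indicator,
        sex=sex,
        axis_kind=axis_kind,
        axis=axis,
        L=sub[cols["l"]].to_numpy(dtype=float),
        M=sub[cols["m"]].to_numpy(dtype=float),
        S=sub[cols["s"]].to_numpy(dtype=float),
    )


def lms_zscore(x: float, L: float, M: float, S: float) -> float:
    """Map a measurement ``x`` to a z-score through the LMS transform."""
    if not (x > 0 and M > 0 and S > 0):
        raise DomainError(f"lms_zscore requires x, M, S > 0 (got x={x}, M={M}, S={S})")
    if abs(L) > _L_EPS:
        # expm1 form of ((x/M)^L - 1)/(L S): no cancellation as L -> 0
        z = math.expm1(L * math.log(x / M)) / (L * S)
    else:
        z = math.log(x / M) / S
    if not math.isfinite(z):
        raise DomainError(f"non-finite z for x={x}, L={L}, M={M}, S={S}")
    return z


def lms_inverse(z: float, L: float, M: float, S: float) -> float:
    """Measurement at z-score ``z``: the inverse of :func:`lms_zscore`."""
    if not (M > 0 and S > 0):
        raise DomainError("lms_inverse requires M, S > 0")
    if abs(L) > _L_EPS:
        if 1.0 + L * S * z <= 0:
            raise DomainError(f"z={z} outside the invertible range for L={L}, S={S}")
        return M * math.exp(math.log1p(L * S * z) / L)
    return M * math.exp(S * z)


def interpolated_lms(ref: GrowthReference, axis_query: float) -> tuple[float, float, float]:
    """Linearly interpolate (L, M, S) at ``axis_query``; exact at table nodes.

    No extrapolation: queries outside the table range raise
    :class:`OutOfRangeError`.
    """
    lo, hi = ref.axis_range
    if not (lo <= axis_query <= hi):
        raise OutOfRangeError(
            f"{ref.indicator.value}/{ref.sex.value}: query {axis_query} outside "
            f"table range [{lo}, {hi}]"
        )
    L = float(np.interp(axis_query, ref.axis, ref.L))
    M = float(np.interp(axis_query, ref.axis, ref.M))
    S = float(np.interp(axis_query, ref.axis, ref.S))
    return L, M, S


def reference_zscore(ref: GrowthReference, axis_query: float, x: float) -> float:
    """z-score of measurement ``x`` at ``axis_query`` under reference ``ref``."""
    L, M, S = interpolated_lms(ref, axis_query)
    return lms_zscore(x, L, M, S)


def compute_bmi(weight_kg: float, height_cm: float) -> float:
    """Body-mass index, kg/m^2."""
    if weight_kg <= 0 or height_cm <= 0:
        raise DomainError("weight and height must be positive")
    h_m = height_cm / 100.0
    return weight_kg / (h_m * h_m)


class ReferenceLibrary:
    """A keyed collection of growth references covering both sexes.

    Weight-for-height tables may be stored per axis kind (length vs height);
    lookup prefers the table matching the subject's measurement mode and falls
    back to the other with no recumbent/standing adjustment.
    """

    def __init__(self, references: Iterable[GrowthReference] = ()) -> None:
        self._refs: dict[tuple[Indicator, Sex, AxisKind], GrowthReference] = {}
        for ref in references:
            self.add(ref)

    def add(self, ref: GrowthReference) -> None:
        self._refs[(ref.indicator, ref.sex, ref.axis_kind)] = ref

    def get(self, indicator: Indicator, sex: Sex,
            mode: MeasurementMode | None = None) -> GrowthReference:
        if indicator is Indicator.WFH:
            preferred = (AxisKind.LENGTH_CM if mode is MeasurementMode.RECUMBENT
                         else AxisKind.HEIGHT_CM)
            order = [preferred] + [
                k for k in (AxisKind.LENGTH_CM, AxisKind.HEIGHT_CM) if k != preferred
            ]
        else:
            order = [AxisKind.AGE_MONTHS]
        for axis_kind in order:
            ref = self._refs.get((indicator, sex, axis_kind))
            if ref is not None:
                return ref
        raise ConfigurationError(
            f"no growth reference for indicator={indicator.value}, sex={sex.value}"
        )

    def __len__(self) -> int:
        return len(self._refs)


@dataclass(frozen=True)
class ZScoreSet:
    """The subject's indicator z-scores; ``None`` marks "not applicable".

    WFA/HFA/WFH apply to ages up to five years, BMI-for-age from five years on
    (and, optionally, at any age for overweight flagging).  Implausible values
    (|z| > 5) are reported as-is and listed in ``flagged``.
    """

    wfa: float | None
    hfa: float | None
    wfh: float | None
    bmi: float | None
    flagged: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        flagged = frozenset(
            name for name in ("wfa", "hfa", "wfh", "bmi")
            if (z := getattr(self, name)) is not None and abs(z) > IMPLAUSIBLE_Z
        )
        object.__setattr__(self, "flagged", flagged)

    def applicable(self) -> dict[str, float]:
        return {
            name: z
            for name in ("wfa", "hfa", "wfh", "bmi")
            if (z := getattr(self, name)) is not None
        }


def zscore_set(record, references: ReferenceLibrary,
               bmi_always: bool = False) -> ZScoreSet:
    """Evaluate every age-applicable indicator z for a subject record.

    ``record`` needs ``sex``, ``age_months``, ``weight_kg``, ``height_cm`` and
    ``measurement_mode`` attributes (see :class:`~pednutriscreen.screening.SubjectRecord`).
    With ``bmi_always`` the BMI z is also computed for under-fives (used for
    overweight flagging); otherwise it follows the five-year age split.
    """
    age = float(record.age_months)
    sex = Sex(record.sex)
    mode = MeasurementMode(record.measurement_mode)
    if record.weight_kg <= 0 or record.height_cm <= 0:
        raise DomainError("weight and height must be positive")

    under_five = age <= UNDER_FIVE_MAX_AGE
    over_five = age >= UNDER_FIVE_MAX_AGE

    wfa = hfa = wfh = bmi = None
    if under_five:
        wfa = reference_zscore(
            references.get(Indicator.WFA, sex), age, record.weight_kg)
        hfa = reference_zscore(
            references.get(Indicator.HFA, sex), age, record.height_cm)
        wfh = reference_zscore(
            references.get(Indicator.WFH, sex, mode), record.height_cm,
            record.weight_kg)
    if over_five or bmi_always:
        bmi_value = compute_bmi(record.weight_kg, record.height_cm)
        bmi = reference_zscore(
            references.get(Indicator.BMI_FOR_AGE, sex), age, bmi_value)
    return ZScoreSet(wfa=wfa, hfa=hfa, wfh=wfh, bmi=bmi)
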