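"""Reference-standard nutrition-status classification (WHO z-score rules, ASPEN).

These classifiers provide the ground truth against which the screening score
is validated.  Under the WHO z-score standard:

* underweight (low weight):   WFA z < -2, or BMI-for-age z < -2 over five years
* growth retardation:         HFA z < -2
* stunting (low WFH):         WFH z < -2
* overweight:                 WFA z > 2 or BMI z > 1
* obesity:                    WFA z > 3 or BMI z > 2
* severe:                     any applicable z < -3 or > 3

A subject is "malnourished" when any of underweight, growth retardation,
stunting or overweight holds (the overweight arm can be excluded for a
deficit-only definition).  The ASPEN-style alternative is a single-time-point
z-score grading on the wasting indicator (WFH under five, BMI over five) with
configurable mild/moderate/severe cut-points.

Note the deliberate asymmetry with the screening score's bins: deficit flags
here use strict ``< -2``, while the score assigns a boundary z of exactly -2
to the more severe bin.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .errors import ConfigurationError, InputError
from .growth import ZScoreSet

__all__ = [
    "Standard",
    "AspenDegree",
    "AspenThresholds",
    "NutritionStatus",
    "classify_who",
    "classify_aspen",
]


class Standard(str, Enum):
    WHO = "who"
    ASPEN = "aspen"


class AspenDegree(str, Enum):
    NONE = "none"
    MILD = "mild"
    MODERATE = "moderate"
    SEVERE = "severe"


_DEGREE_ORDER = [AspenDegree.NONE, AspenDegree.MILD, AspenDegree.MODERATE,
                 AspenDegree.SEVERE]


@dataclass(frozen=True)
class NutritionStatus:
    """Outcome of a reference-standard classification."""

    underweight: bool = False
    growth_retardation: bool = False
    stunting: bool = False
    overweight: bool = False
    obesity: bool = False
    malnourished: bool = False
    severe: bool = False
    standard: Standard = Standard.WHO
    aspen_degree: AspenDegree = AspenDegree.NONE

    def __post_init__(self) -> None:
        if self.severe and not self.malnourished:
            raise ValueError("severe implies malnourished")


def classify_who(z: ZScoreSet, include_overweight: bool = True) -> NutritionStatus:
    """Classify nutrition status under the WHO z-score rules.

    ``include_overweight=False`` restricts "malnourished" to the deficit flags
    (undernutrition only).
    """
    if not z.applicable():
        raise InputError("no applicable z-score in ZScoreSet")

    weight_z = z.wfa if z.wfa is not None else z.bmi
    underweight = weight_z is not None and weight_z < -2
    growth_retardation = z.hfa is not None and z.hfa < -2
    stunting = z.wfh is not None and z.wfh < -2
    overweight = (z.wfa is not None and z.wfa > 2) or (z.bmi is not None and z.bmi > 1)
    obesity = (z.wfa is not None and z.wfa > 3) or (z.bmi is not None and z.bmi > 2)

    malnourished = underweight or growth_retardation or stunting
    if include_overweight:
        malnourished = malnourished or overweight
    severe = malnourished and any(
        v < -3 or v > 3 for v in z.applicable().values()
    )
    return NutritionStatus(
        underweight=underweight,
        growth_retardation=growth_retardation,
        stunting=stunting,
        overweight=overweight,
        obesity=obesity,
        malnourished=malnourished,
        severe=severe,
        standard=Standard.WHO,
    )


@dataclass(frozen=True)
class AspenThresholds:
    """Single-time-point z cut-points for the ASPEN-style grading.

    Defaults follow the pediatric consensus indicator bands: z <= -1 mild,
    z <= -2 moderate, z <= -3 severe, with "malnourished" meaning moderate or
    worse.
    """

    mild: float = -1.0
    moderate: float = -2.0
    severe: float = -3.0
    malnourished_at: AspenDegree = AspenDegree.MODERATE

    def __post_init__(self) -> None:
        if not (self.severe <= self.moderate <= self.mild):
            raise ConfigurationError(
                "ASPEN cut-points must satisfy severe <= moderate <= mild"
            )
        if self.malnourished_at is AspenDegree.NONE:
            raise ConfigurationError("malnourished_at must be a positive degree")


def classify_aspen(z: ZScoreSet,
                   thresholds: AspenThresholds | None = None) -> NutritionStatus:
    """Grade malnutrition from the wasting indicator z (WFH, else BMI-for-age)."""
    thresholds = thresholds or AspenThresholds()
    value = z.wfh if z.wfh is not None else z.bmi
    if value is None:
        raise InputError("ASPEN grading needs a WFH or BMI-for-age z-score")

    if value <= thresholds.severe:
        degree = AspenDegree.SEVERE
    elif value <= thresholds.moderate:
        degree = AspenDegree.MODERATE
    elif value <= thresholds.mild:
        degree = AspenDegree.MILD
    else:
        degree = AspenDegree.NONE

    malnourished = (_DEGREE_ORDER.index(degree)
                    >= _DEGREE_ORDER.index(thresholds.malnourished_at))
    return NutritionStatus(
        underweight=malnourished,
        malnourished=malnourished,
        severe=malnourished and degree is AspenDegree.SEVERE,
        standard=Standard.ASPEN,
        aspen_degree=degree,
    )
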