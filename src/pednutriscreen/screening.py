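"""The three-component pediatric malnutrition-risk score for children with CHD.

The score sums three elements and ranges 0-6:

* disease risk (0 or 1) — looked up from the primary congenital-heart-disease
  diagnosis in a registry; tier 1 holds the high-risk lesions (pulmonary
  atresia, severe pulmonary hypertension, anomalous pulmonary venous drainage,
  tetralogy of Fallot, ...);
* dietary intake (0, 1 or 2) — intake over the previous month: unchanged,
  reduced by up to half, or reduced by more than half;
* anthropometric indicator (0-3) — binned from the subject's z-score
  (weight-for-height under five years, BMI-for-age from five years), with an
  overlay raising the score to at least 1 for overweight and at least 2 for
  obese subjects.

A subject is "at risk" when the total reaches the threshold (default 2, the
validated cut-off).  Boundary z-values fall in gaps of the published strict
inequalities; by default they are assigned to the more severe bin (z = -2
scores 2, z = -3 scores 3), matching the WHO ``< -2`` deficit convention.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable

import pandas as pd

from . import criteria
from .errors import DomainError, FormatError, RegistryLookupError, ValidityError
from .growth import (
    MeasurementMode,
    ReferenceLibrary,
    Sex,
    UNDER_FIVE_MAX_AGE,
    ZScoreSet,
    zscore_set,
)

__all__ = [
    "DietaryIntake",
    "WeightStatus",
    "BethesdaClass",
    "WeightChangeCategory",
    "SubjectRecord",
    "DiagnosisEntry",
    "DiagnosisRegistry",
    "ScreeningResult",
    "score_disease_risk",
    "score_dietary_intake",
    "score_anthropometric",
    "screen",
    "weight_change_category",
    "DEFAULT_THRESHOLD",
]

DEFAULT_THRESHOLD = 2

MIN_AGE_MONTHS = 1.0
MAX_AGE_MONTHS = 216.0

WEIGHT_LOSS_FLAG_FRACTION = 0.05


class DietaryIntake(str, Enum):
    NORMAL = "normal"
    REDUCED_LE_50 = "reduced_le_50"
    REDUCED_GT_50 = "reduced_gt_50"


_DIET_SCORES = {
    DietaryIntake.NORMAL: 0,
    DietaryIntake.REDUCED_LE_50: 1,
    DietaryIntake.REDUCED_GT_50: 2,
}


class WeightStatus(str, Enum):
    NONE = "none"
    OVERWEIGHT = "overweight"
    OBESE = "obese"


class BethesdaClass(str, Enum):
    SIMPLE = "simple"
    MODERATE = "moderate"
    COMPLEX = "complex"


class WeightChangeCategory(str, Enum):
    GAINED = "gained"
    NO_GAIN_OR_LOST = "no_gain_or_lost"
    LOST_GT_5PCT = "lost_gt_5pct"


@dataclass(frozen=True)
class SubjectRecord:
    """One hospitalized child's demographics, anthropometry and diagnosis."""

    id: str
    sex: Sex
    age_months: float
    weight_kg: float
    height_cm: float
    diagnosis_code: str
    dietary_intake: DietaryIntake = DietaryIntake.NORMAL
    measurement_mode: MeasurementMode | None = None
    admission_weight_kg: float | None = None
    discharge_weight_kg: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sex", Sex(self.sex))
        object.__setattr__(self, "dietary_intake", DietaryIntake(self.dietary_intake))
        if self.measurement_mode is None:
            # instrument choice follows age: length (recumbent) under two years
            mode = (MeasurementMode.RECUMBENT if self.age_months < 24
                    else MeasurementMode.STANDING)
            object.__setattr__(self, "measurement_mode", mode)
        else:
            object.__setattr__(
                self, "measurement_mode", MeasurementMode(self.measurement_mode))
        if not (MIN_AGE_MONTHS <= self.age_months <= MAX_AGE_MONTHS):
            raise ValidityError(
                f"age {self.age_months} months outside [{MIN_AGE_MONTHS}, "
                f"{MAX_AGE_MONTHS}] (1 month to 18 years)"
            )
        if self.weight_kg <= 0 or self.height_cm <= 0:
            raise ValidityError("weight and height must be positive")
        for name in ("admission_weight_kg", "discharge_weight_kg"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValidityError(f"{name} must be positive when given")


@dataclass(frozen=True)
class DiagnosisEntry:
    """One congenital-heart-disease diagnosis and its screening attributes."""

    name: str
    icd10: str = ""
    risk_tier: int = 0
    cyanotic: bool = False
    bethesda: BethesdaClass = BethesdaClass.SIMPLE

    def __post_init__(self) -> None:
        if self.risk_tier not in (0, 1):
            raise ValidityError(f"risk_tier must be 0 or 1, got {self.risk_tier}")
        object.__setattr__(self, "bethesda", BethesdaClass(self.bethesda))


class DiagnosisRegistry:
    """Case-insensitive name -> :class:`DiagnosisEntry` lookup.

    The registry ships with the named lesions of the published rubric; the
    unenumerated "other" categories are user-extensible via a JSON or CSV
    registry file.
    """

    def __init__(self, entries: Iterable[DiagnosisEntry] = ()) -> None:
        self._entries: dict[str, DiagnosisEntry] = {}
        for entry in entries:
            self.add(entry)

    @staticmethod
    def _key(name: str) -> str:
        return " ".join(name.casefold().split())

    def add(self, entry: DiagnosisEntry) -> None:
        self._entries[self._key(entry.name)] = entry

    def entry(self, code: str) -> DiagnosisEntry:
        try:
            return self._entries[self._key(code)]
        except KeyError:
            raise RegistryLookupError(
                f"diagnosis {code!r} not in registry "
                f"({len(self._entries)} known entries)"
            ) from None

    def __contains__(self, code: str) -> bool:
        return self._key(code) in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def entries(self) -> list[DiagnosisEntry]:
        return list(self._entries.values())

    @classmethod
    def from_file(cls, path: str | Path) -> "DiagnosisRegistry":
        path = Path(path)
        if path.suffix.lower() == ".json":
            raw = json.loads(path.read_text())
            if not isinstance(raw, list):
                raise FormatError("registry JSON must be a list of entries")
            records = raw
        else:
            records = pd.read_csv(path).to_dict(orient="records")
        entries = []
        for rec in records:
            try:
                entries.append(DiagnosisEntry(
                    name=str(rec["name"]),
                    icd10=str(rec.get("icd10", "") or ""),
                    risk_tier=int(rec["risk_tier"]),
                    cyanotic=bool(rec.get("cyanotic", False)),
                    bethesda=BethesdaClass(rec.get("bethesda", "simple")),
                ))
            except KeyError as exc:
                raise FormatError(f"registry entry missing field {exc}") from exc
        return cls(entries)


@dataclass(frozen=True)
class ScreeningResult:
    """Subscores, total and classification for one subject."""

    disease_score: int
    diet_score: int
    anthro_score: int
    threshold: int = DEFAULT_THRESHOLD
    zscores: ZScoreSet | None = None
    anthro_z: float | None = None
    total: int = field(init=False)
    at_risk: bool = field(init=False)

    def __post_init__(self) -> None:
        if self.disease_score not in (0, 1):
            raise ValidityError("disease_score must be 0 or 1")
        if self.diet_score not in (0, 1, 2):
            raise ValidityError("diet_score must be 0, 1 or 2")
        if self.anthro_score not in (0, 1, 2, 3):
            raise ValidityError("anthro_score must be in 0..3")
        total = self.disease_score + self.diet_score + self.anthro_score
        object.__setattr__(self, "total", total)
        object.__setattr__(self, "at_risk", total >= self.threshold)


def score_disease_risk(diagnosis_code: str, registry: DiagnosisRegistry) -> int:
    """Disease-risk subscore: the registry tier (0 or 1) of the diagnosis."""
    return registry.entry(diagnosis_code).risk_tier


def score_dietary_intake(category: DietaryIntake | str) -> int:
    """Dietary-intake subscore: 0 normal, 1 reduced <=50%, 2 reduced >50%."""
    return _DIET_SCORES[DietaryIntake(category)]


def score_anthropometric(z: float,
                         weight_status: WeightStatus | str = WeightStatus.NONE,
                         boundary_to_severe: bool = True) -> int:
    """Anthropometric subscore from the indicator z plus overweight overlay.

    Base bins (``boundary_to_severe=True``, the default): z >= -1 scores 0,
    [-2, -1) scores 1, [-3, -2) scores 2, z <= -3 scores 3.  With
    ``boundary_to_severe=False`` the boundary values -1 and -2 drop to the
    milder bin.  Overweight forces at least 1, obesity at least 2; the final
    score is the maximum of base and overlay.
    """
    if not math.isfinite(z):
        raise DomainError(f"anthropometric z must be finite, got {z}")
    if boundary_to_severe:
        if z <= -3:
            base = 3
        elif z <= -2:
            base = 2
        elif z < -1:
            base = 1
        else:
            base = 0
    else:
        if z <= -3:
            base = 3
        elif z < -2:
            base = 2
        elif z < -1:
            base = 1
        else:
            base = 0
    overlay = {WeightStatus.NONE: 0, WeightStatus.OVERWEIGHT: 1,
               WeightStatus.OBESE: 2}[WeightStatus(weight_status)]
    return max(base, overlay)


def _weight_status(record: SubjectRecord, z: ZScoreSet) -> WeightStatus:
    status = criteria.classify_who(z)
    if status.obesity:
        return WeightStatus.OBESE
    if status.overweight:
        return WeightStatus.OVERWEIGHT
    return WeightStatus.NONE


def screen(record: SubjectRecord,
           registry: DiagnosisRegistry,
           references: ReferenceLibrary,
           threshold: int = DEFAULT_THRESHOLD,
           overweight_overlay: bool = True,
           boundary_to_severe: bool = True) -> ScreeningResult:
    """Compose the three subscores for one subject and classify at ``threshold``.

    The anthropometric indicator z is weight-for-height for children under
    five years and BMI-for-age from five years on.  ``overweight_overlay``
    controls whether WHO overweight/obesity raises the anthropometric
    subscore (the published rubric includes the overlay).
    """
    zset = zscore_set(record, references)
    anthro_z = zset.wfh if record.age_months < UNDER_FIVE_MAX_AGE else zset.bmi
    if anthro_z is None:  # age exactly at the split: either indicator works
        anthro_z = zset.bmi if zset.bmi is not None else zset.wfh
    status = (_weight_status(record, zset) if overweight_overlay
              else WeightStatus.NONE)
    return ScreeningResult(
        disease_score=score_disease_risk(record.diagnosis_code, registry),
        diet_score=score_dietary_intake(record.dietary_intake),
        anthro_score=score_anthropometric(anthro_z, status, boundary_to_severe),
        threshold=threshold,
        zscores=zset,
        anthro_z=anthro_z,
    )


def weight_change_category(
    admission_weight_kg: float, discharge_weight_kg: float
) -> tuple[float, WeightChangeCategory]:
    """Relative admission-to-discharge weight change and its category.

    Any positive change counts as "gained"; zero or a loss is "no gain or
    lost", except losses of more than 5% of admission weight, which are
    flagged as their own category.
    """
    if admission_weight_kg <= 0 or discharge_weight_kg <= 0:
        raise DomainError("weights must be positive")
    change = (discharge_weight_kg - admission_weight_kg) / admission_weight_kg
    if change > 0:
        category = WeightChangeCategory.GAINED
    elif change < -WEIGHT_LOSS_FLAG_FRACTION:
        category = WeightChangeCategory.LOST_GT_5PCT
    else:
        category = WeightChangeCategory.NO_GAIN_OR_LOST
    return change, category
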