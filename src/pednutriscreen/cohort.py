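"""Synthetic cohorts: marginal-constrained reconstruction and individual-level simulation.

The study cohort behind the published validation (1125 hospitalized children
with congenital heart disease, 272 WHO-malnourished) was never deposited, but
its printed marginals — per-score subject counts, the malnourished total, and
the per-cut-off sensitivity/specificity table — over-determine the joint
distribution of (screening score, WHO malnutrition status).  This module

* reconstructs that joint distribution by exhaustive integer search
  (:func:`reconstruct_joint_distribution`), asserting the solution is unique;
* expands it into a per-subject table for the validation pipeline
  (:func:`expand_to_records`);
* simulates fully individual-level cohorts (demographics, diagnosis, diet,
  anthropometry) by inverting the LMS transform from sampled z-scores
  (:func:`simulate_cohort`), so the whole pipeline is testable end to end
  without external data;
* builds closed-form synthetic LMS reference tables
  (:func:`synthetic_lms_table`, :func:`synthetic_reference_library`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .diagnostics import round_half_away
from .errors import ConfigurationError, ReconstructionError, ValidityError
from .growth import (
    AxisKind,
    GrowthReference,
    Indicator,
    MeasurementMode,
    ReferenceLibrary,
    Sex,
    UNDER_FIVE_MAX_AGE,
    interpolated_lms,
    lms_inverse,
)
from .screening import DiagnosisEntry, DiagnosisRegistry, DietaryIntake, SubjectRecord

__all__ = [
    "JointScoreDistribution",
    "SimulationConfig",
    "PRINTED_PER_SCORE_TOTALS",
    "PRINTED_TABLE3_ROWS",
    "COHORT_SIZE",
    "N_MALNOURISHED",
    "reconstruct_joint_distribution",
    "expand_to_records",
    "simulate_cohort",
    "synthetic_lms_table",
    "synthetic_reference_library",
    "default_diagnosis_registry",
]

MAX_SCORE = 6

# Printed marginals of the validation cohort: N, WHO-malnourished total,
# subjects per score 0..4 (no subject scored above 4), and the per-cut-off
# sensitivity/specificity table in percent.
COHORT_SIZE = 1125
N_MALNOURISHED = 272
PRINTED_PER_SCORE_TOTALS = (454, 320, 191, 128, 33)
PRINTED_TABLE3_ROWS: dict[float, tuple[float, float]] = {
    0.5: (98.2, 52.6),
    1.5: (91.2, 87.9),
    2.5: (47.4, 96.4),
    3.5: (10.7, 99.5),
    5.0: (0.0, 100.0),
}


@dataclass(frozen=True)
class JointScoreDistribution:
    """Counts of (malnourished, not malnourished) subjects at each score 0..6."""

    malnourished: tuple[int, ...]
    not_malnourished: tuple[int, ...]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        m = tuple(int(v) for v in self.malnourished)
        u = tuple(int(v) for v in self.not_malnourished)
        if len(m) != len(u):
            raise ValidityError("count vectors must have equal length")
        if len(m) > MAX_SCORE + 1:
            raise ValidityError(f"scores beyond {MAX_SCORE} are impossible")
        if any(v < 0 for v in m + u):
            raise ValidityError("counts must be non-negative")
        object.__setattr__(self, "malnourished", m)
        object.__setattr__(self, "not_malnourished", u)

    @property
    def n_scores(self) -> int:
        return len(self.malnourished)

    @property
    def n_total(self) -> int:
        return sum(self.malnourished) + sum(self.not_malnourished)

    @property
    def n_malnourished(self) -> int:
        return sum(self.malnourished)

    def per_score_totals(self) -> tuple[int, ...]:
        return tuple(m + u for m, u in
                     zip(self.malnourished, self.not_malnourished))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "score": range(self.n_scores),
            "malnourished": self.malnourished,
            "not_malnourished": self.not_malnourished,
        })


def _rounds_to(value_pct: float, printed: float) -> bool:
    return round_half_away(value_pct, 1) == printed


def _search_malnourished_vector(
    totals: Sequence[int],
    n_malnourished: int,
    table_rows: Mapping[float, tuple[float, float]],
) -> list[tuple[int, ...]]:
    """All malnourished-count vectors m (m[s] <= totals[s], sum = target)
    whose per-cut-off sensitivity and specificity reproduce every printed row
    after rounding to one decimal.

    Depth-first over scores high to low.  Once the tail m[s:] is fixed, the
    sensitivity at cut-off s - 0.5 and the specificity (which needs the tail
    non-malnourished counts) are determined, so each printed row prunes
    exactly — the enumeration stays exhaustive over the constraint set.
    """
    n_scores = len(totals)
    n_not = sum(totals) - n_malnourished
    rows = {float(t): v for t, v in table_rows.items()}

    def tail_ok(s: int, m_tail: list[int]) -> bool:
        # m_tail holds m[s..n_scores-1]; check every printed cut-off >= s - 0.5
        for t, (sens_p, spec_p) in rows.items():
            k = int(np.ceil(t))
            if k < s or k > n_scores:
                continue
            tp = sum(m_tail[k - s:])
            fp = sum(totals[k:]) - tp
            if not _rounds_to(100.0 * tp / n_malnourished, sens_p):
                return False
            if not _rounds_to(100.0 * (1.0 - fp / n_not), spec_p):
                return False
        return True

    solutions: list[tuple[int, ...]] = []

    def descend(s: int, m_tail: list[int], remaining: int) -> None:
        if s == 0:
            if remaining <= totals[0]:
                full = [remaining] + m_tail
                if tail_ok(0, full):
                    solutions.append(tuple(full))
            return
        lo = max(0, remaining - sum(totals[:s]))
        hi = min(totals[s], remaining)
        for m_s in range(lo, hi + 1):
            cand = [m_s] + m_tail
            if tail_ok(s, cand):
                descend(s - 1, cand, remaining - m_s)

    descend(n_scores - 1, [], n_malnourished)
    return solutions


def reconstruct_joint_distribution(
    cohort_size: int = COHORT_SIZE,
    n_malnourished: int = N_MALNOURISHED,
    per_score_totals: Sequence[int] = PRINTED_PER_SCORE_TOTALS,
    table3_rows: Mapping[float, tuple[float, float]] | None = None,
) -> JointScoreDistribution:
    """Reconstruct the score x malnutrition-status joint distribution.

    The printed per-score totals may disagree with the cohort size by one
    subject (they sum to 1126 against N = 1125); every single-score
    adjustment bridging the gap is tried, and the printed cut-off table must
    be reproduced exactly after rounding.  The solution — adjusted totals
    plus malnourished counts — must be unique, otherwise a
    :class:`ReconstructionError` reports the competing candidates.
    """
    if table3_rows is None:
        table3_rows = PRINTED_TABLE3_ROWS
    totals = [int(v) for v in per_score_totals]
    if any(v < 0 for v in totals) or n_malnourished < 0:
        raise ValidityError("counts must be non-negative")
    if n_malnourished > cohort_size:
        raise ReconstructionError(
            f"n_malnourished={n_malnourished} exceeds cohort size {cohort_size}"
        )

    gap = cohort_size - sum(totals)
    candidates: list[tuple[list[int], dict]] = []
    if gap == 0:
        candidates.append((totals, {}))
    elif abs(gap) == 1:
        for s in range(len(totals)):
            adj = list(totals)
            adj[s] += gap
            if adj[s] >= 0:
                candidates.append((adj, {
                    "adjusted_score": s,
                    "printed_total": totals[s],
                    "adjusted_total": adj[s],
                }))
    else:
        raise ReconstructionError(
            f"per-score totals sum to {sum(totals)}, off by {gap} from "
            f"N={cohort_size}; only a one-subject discrepancy is bridgeable"
        )

    solutions: list[tuple[list[int], dict, tuple[int, ...]]] = []
    for adj_totals, meta in candidates:
        for m in _search_malnourished_vector(adj_totals, n_malnourished,
                                             table3_rows):
            solutions.append((adj_totals, meta, m))

    if not solutions:
        raise ReconstructionError(
            "no malnourished-count vector reproduces the printed cut-off "
            f"table under totals {totals} (sum {sum(totals)}, N={cohort_size}, "
            f"malnourished {n_malnourished})"
        )
    if len(solutions) > 1:
        raise ReconstructionError(
            f"reconstruction is not unique; {len(solutions)} candidates: "
            + "; ".join(f"totals={t}, m={m}" for t, _, m in solutions[:5])
        )

    adj_totals, meta, m = solutions[0]
    u = tuple(t - mi for t, mi in zip(adj_totals, m))
    metadata = {
        "cohort_size": cohort_size,
        "n_malnourished": n_malnourished,
        "printed_per_score_totals": tuple(totals),
        **meta,
    }
    return JointScoreDistribution(
        malnourished=m, not_malnourished=u, metadata=metadata)


def expand_to_records(dist: JointScoreDistribution,
                      seed: int | None = 0) -> pd.DataFrame:
    """One row per subject of the joint distribution.

    Columns: ``id``, ``total_score``, ``who_malnourished``.  Row order is a
    deterministic shuffle under ``seed`` (``None`` keeps score order).
    """
    scores: list[int] = []
    status: list[bool] = []
    for s in range(dist.n_scores):
        scores += [s] * dist.malnourished[s]
        status += [True] * dist.malnourished[s]
        scores += [s] * dist.not_malnourished[s]
        status += [False] * dist.not_malnourished[s]
    df = pd.DataFrame({"total_score": scores, "who_malnourished": status})
    if seed is not None:
        rng = np.random.default_rng(seed)
        df = df.iloc[rng.permutation(len(df))].reset_index(drop=True)
    df.insert(0, "id", [f"S{i:04d}" for i in range(1, len(df) + 1)])
    return df


# --- individual-level simulation -------------------------------------------

@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the individual-level cohort simulator.

    Defaults emulate the validation cohort's printed composition: 51.1% boys,
    a young age distribution (median near 23 months), 16.8% tier-1 (high
    disease-risk) diagnoses (189/1125), dietary-intake reduction in roughly 2
    per 1125 subjects, and stratum-specific anthropometric z distributions —
    children with tier-1 lesions sit well below the reference median.
    """

    n_subjects: int = 1000
    p_male: float = 0.511
    # ages: lognormal in months, clipped to the eligible range
    age_log_mean: float = np.log(23.0)
    age_log_sd: float = 1.1
    tier1_prevalence: float = 0.168
    diet_probs: tuple[float, float, float] = (0.9982, 0.0009, 0.0009)
    z_mean_by_tier: tuple[float, float] = (-0.4, -1.8)
    z_sd_by_tier: tuple[float, float] = (1.1, 1.2)
    # height-for-age z is sampled independently around the reference median
    height_z_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.n_subjects < 0:
            raise ConfigurationError("n_subjects must be non-negative")
        for name in ("p_male", "tier1_prevalence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        if len(self.diet_probs) != 3 or any(p < 0 for p in self.diet_probs) \
                or abs(sum(self.diet_probs) - 1.0) > 1e-9:
            raise ConfigurationError(
                "diet_probs must be three non-negative numbers summing to 1")
        if any(sd < 0 for sd in self.z_sd_by_tier) or self.height_z_sd < 0:
            raise ConfigurationError("standard deviations must be >= 0")


def simulate_cohort(config: SimulationConfig,
                    registry: DiagnosisRegistry,
                    references: ReferenceLibrary,
                    seed: int | None = None) -> list[SubjectRecord]:
    """Draw a synthetic cohort of :class:`SubjectRecord` subjects.

    Anthropometry is generated by inversion: a height-for-age z gives the
    height, then the target indicator z (weight-for-height under five years,
    BMI-for-age above) is converted back to a weight through the inverse LMS
    transform, so the simulated records reproduce the sampled z exactly when
    rescreened.
    """
    rng = np.random.default_rng(seed)
    by_tier = {
        t: [e for e in registry.entries() if e.risk_tier == t] for t in (0, 1)
    }
    if not by_tier[0] or not by_tier[1]:
        raise ConfigurationError("registry must contain both risk tiers")

    diet_values = [DietaryIntake.NORMAL, DietaryIntake.REDUCED_LE_50,
                   DietaryIntake.REDUCED_GT_50]
    records: list[SubjectRecord] = []
    for i in range(config.n_subjects):
        sex = Sex.MALE if rng.random() < config.p_male else Sex.FEMALE
        age = float(np.clip(rng.lognormal(config.age_log_mean, config.age_log_sd),
                            1.0, 216.0))
        tier = 1 if rng.random() < config.tier1_prevalence else 0
        diagnosis = by_tier[tier][rng.integers(len(by_tier[tier]))]
        diet = diet_values[rng.choice(3, p=config.diet_probs)]
        mode = (MeasurementMode.RECUMBENT if age < 24
                else MeasurementMode.STANDING)

        hfa = references.get(Indicator.HFA, sex)
        hL, hM, hS = interpolated_lms(hfa, age)
        height = lms_inverse(float(rng.normal(0.0, config.height_z_sd)),
                             hL, hM, hS)
        z = float(rng.normal(config.z_mean_by_tier[tier],
                             config.z_sd_by_tier[tier]))
        if age < UNDER_FIVE_MAX_AGE:
            wfh = references.get(Indicator.WFH, sex, mode)
            wlo, whi = wfh.axis_range
            height = float(np.clip(height, wlo, whi))
            wL, wM, wS = interpolated_lms(wfh, height)
            weight = lms_inverse(z, wL, wM, wS)
        else:
            bmi_ref = references.get(Indicator.BMI_FOR_AGE, sex)
            bL, bM, bS = interpolated_lms(bmi_ref, age)
            bmi = lms_inverse(z, bL, bM, bS)
            weight = bmi * (height / 100.0) ** 2
        records.append(SubjectRecord(
            id=f"SIM{i:05d}",
            sex=sex,
            age_months=age,
            weight_kg=weight,
            height_cm=height,
            diagnosis_code=diagnosis.name,
            dietary_intake=diet,
            measurement_mode=mode,
        ))
    return records


# --- synthetic growth references -------------------------------------------

def synthetic_lms_table(indicator: Indicator,
                        sex: Sex,
                        axis_kind: AxisKind,
                        axis_start: float,
                        axis_stop: float,
                        M_intercept: float,
                        M_slope: float,
                        S_const: float,
                        L_const: float = 1.0,
                        step: float = 1.0) -> GrowthReference:
    """A linear-median synthetic reference: M(a) = intercept + slope * a.

    With the default L = 1 the z-score of measurement ``x`` at axis value
    ``a`` is exactly ``(x / M(a) - 1) / S`` — and because M is linear, linear
    interpolation between rows is exact at every query, giving a closed-form
    oracle for the whole lookup pipeline.
    """
    if S_const <= 0:
        raise ConfigurationError("S_const must be positive")
    if axis_stop <= axis_start:
        raise ConfigurationError("axis_stop must exceed axis_start")
    axis = np.arange(axis_start, axis_stop + step / 2, step, dtype=float)
    M = M_intercept + M_slope * axis
    if np.any(M <= 0):
        raise ConfigurationError("M must stay positive over the axis range")
    return GrowthReference(
        indicator=indicator, sex=sex, axis_kind=axis_kind, axis=axis,
        L=np.full_like(axis, L_const), M=M, S=np.full_like(axis, S_const),
    )


# Medians of the synthetic family: weight 4 + 0.25*age kg, height
# 50 + 0.5*age cm.  Weight-for-height follows by substitution
# (M = 0.5*len - 21), so the three under-five indicators are mutually
# consistent; BMI-for-age is tabulated from the same medians.
_SYN_WEIGHT = (4.0, 0.25)
_SYN_HEIGHT = (50.0, 0.5)
_SYN_S = {"weight": 0.11, "height": 0.04, "bmi": 0.10}


def synthetic_reference_library(step_months: float = 3.0) -> ReferenceLibrary:
    """The bundled synthetic reference set covering both sexes, ages 0-216."""
    lib = ReferenceLibrary()
    for sex in Sex:
        lib.add(synthetic_lms_table(
            Indicator.WFA, sex, AxisKind.AGE_MONTHS, 0.0, 216.0,
            _SYN_WEIGHT[0], _SYN_WEIGHT[1], _SYN_S["weight"],
            step=step_months))
        lib.add(synthetic_lms_table(
            Indicator.HFA, sex, AxisKind.AGE_MONTHS, 0.0, 216.0,
            _SYN_HEIGHT[0], _SYN_HEIGHT[1], _SYN_S["height"],
            step=step_months))
        # substitute age = (len - 50) / 0.5 into the weight median
        lib.add(synthetic_lms_table(
            Indicator.WFH, sex, AxisKind.HEIGHT_CM, 45.0, 170.0,
            -21.0, 0.5, _SYN_S["weight"], step=2.5))
        ages = np.arange(0.0, 216.0 + step_months / 2, step_months)
        h = _SYN_HEIGHT[0] + _SYN_HEIGHT[1] * ages
        w = _SYN_WEIGHT[0] + _SYN_WEIGHT[1] * ages
        bmi_m = w / (h / 100.0) ** 2
        lib.add(GrowthReference(
            indicator=Indicator.BMI_FOR_AGE, sex=sex,
            axis_kind=AxisKind.AGE_MONTHS, axis=ages,
            L=np.ones_like(ages), M=bmi_m,
            S=np.full_like(ages, _SYN_S["bmi"]),
        ))
    return lib


_DEFAULT_REGISTRY_ENTRIES = [
    # tier 0: left-to-right shunts and other lesions the rubric scores 0
    ("Patent ductus arteriosus", "Q25.0", 0, False, "simple"),
    ("Atrial septal defect", "Q21.1", 0, False, "simple"),
    ("Atrioventricular septal defect", "Q21.2", 0, False, "moderate"),
    ("Ventricular septal defect", "Q21.0", 0, False, "simple"),
    ("Pulmonary artery stenosis", "Q25.6", 0, False, "simple"),
    ("Aortic coarctation", "Q25.1", 0, False, "moderate"),
    # tier 1: high-risk lesions the rubric scores 1
    ("Pulmonary atresia", "Q25.5", 1, True, "complex"),
    ("Severe pulmonary hypertension", "I27.0", 1, False, "moderate"),
    ("Anomalous pulmonary venous drainage", "Q26.2", 1, True, "moderate"),
    ("Tetralogy of Fallot", "Q21.3", 1, True, "complex"),
    ("Transposition of the great arteries", "Q20.3", 1, True, "complex"),
]


def default_diagnosis_registry() -> DiagnosisRegistry:
    """Registry of the lesions named in the published rubric (user-extensible)."""
    return DiagnosisRegistry(
        DiagnosisEntry(name=n, icd10=c, risk_tier=t, cyanotic=cy, bethesda=b)
        for n, c, t, cy, b in _DEFAULT_REGISTRY_ENTRIES
    )
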