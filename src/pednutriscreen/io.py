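"""CSV/JSON input-output: subject batches, reference directories, bundled data.

Subject batch files are plain CSV with one row per child and lower_snake_case
columns::

    id, sex, age_months, weight_kg, height_cm, diagnosis_code,
    dietary_intake, measurement_mode, admission_weight_kg, discharge_weight_kg

Only the first six are required (``measurement_mode`` defaults by age).  A
``header_map`` option renames alternate headings on the way in.  Growth
references live one file per (indicator, sex) in a directory; filenames carry
the indicator and sex as underscore-separated tokens (e.g.
``synthetic_wfa_male.csv``).
"""

from __future__ import annotations

import importlib.resources
import math
from pathlib import Path
from typing import Mapping

import pandas as pd

from .errors import FormatError
from .growth import Indicator, ReferenceLibrary, Sex, load_growth_reference
from .screening import (
    DiagnosisRegistry,
    ScreeningResult,
    SubjectRecord,
    screen,
)

__all__ = [
    "REQUIRED_SUBJECT_COLUMNS",
    "read_subjects",
    "records_to_frame",
    "load_reference_dir",
    "bundled_reference_library",
    "bundled_registry_path",
    "bundled_registry",
    "screen_frame",
]

REQUIRED_SUBJECT_COLUMNS = (
    "id", "sex", "age_months", "weight_kg", "height_cm", "diagnosis_code",
)
OPTIONAL_SUBJECT_COLUMNS = (
    "dietary_intake", "measurement_mode",
    "admission_weight_kg", "discharge_weight_kg",
)


def _optional(row, name):
    v = row.get(name)
    if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
        return None
    return v


def read_subjects(source, header_map: Mapping[str, str] | None = None
                  ) -> list[SubjectRecord]:
    """Read a subject batch CSV into validated :class:`SubjectRecord` rows."""
    df = pd.read_csv(source)
    if header_map:
        df = df.rename(columns=dict(header_map))
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in REQUIRED_SUBJECT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"subject CSV missing column(s): {missing}")
    records = []
    for row in df.to_dict(orient="records"):
        records.append(SubjectRecord(
            id=str(row["id"]),
            sex=str(row["sex"]).strip().lower(),
            age_months=float(row["age_months"]),
            weight_kg=float(row["weight_kg"]),
            height_cm=float(row["height_cm"]),
            diagnosis_code=str(row["diagnosis_code"]),
            dietary_intake=str(_optional(row, "dietary_intake") or "normal"),
            measurement_mode=_optional(row, "measurement_mode"),
            admission_weight_kg=(None if (v := _optional(row, "admission_weight_kg")) is None
                                 else float(v)),
            discharge_weight_kg=(None if (v := _optional(row, "discharge_weight_kg")) is None
                                 else float(v)),
        ))
    return records


def records_to_frame(records) -> pd.DataFrame:
    """Subject records as a CSV-ready DataFrame (inverse of :func:`read_subjects`)."""
    rows = []
    for r in records:
        rows.append({
            "id": r.id,
            "sex": r.sex.value,
            "age_months": r.age_months,
            "weight_kg": r.weight_kg,
            "height_cm": r.height_cm,
            "diagnosis_code": r.diagnosis_code,
            "dietary_intake": r.dietary_intake.value,
            "measurement_mode": r.measurement_mode.value,
            "admission_weight_kg": r.admission_weight_kg,
            "discharge_weight_kg": r.discharge_weight_kg,
        })
    return pd.DataFrame(rows)


_INDICATOR_TOKENS = {i.value: i for i in Indicator}
_SEX_TOKENS = {s.value: s for s in Sex}


def load_reference_dir(path: str | Path) -> ReferenceLibrary:
    """Load every ``*.csv`` reference table in a directory.

    Indicator and sex are parsed from underscore-separated filename tokens
    (``wfa``/``hfa``/``wfh``/``bmi`` and ``male``/``female``).
    """
    path = Path(path)
    lib = ReferenceLibrary()
    for f in sorted(path.glob("*.csv")):
        tokens = f.stem.lower().split("_")
        ind = next((_INDICATOR_TOKENS[t] for t in tokens
                    if t in _INDICATOR_TOKENS), None)
        sex = next((_SEX_TOKENS[t] for t in tokens if t in _SEX_TOKENS), None)
        if ind is None or sex is None:
            raise FormatError(
                f"cannot parse indicator/sex from reference filename {f.name}")
        lib.add(load_growth_reference(f, ind, sex))
    if len(lib) == 0:
        raise FormatError(f"no reference CSVs found in {path}")
    return lib


def _data_dir() -> Path:
    return Path(importlib.resources.files("pednutriscreen") / "data")


def bundled_reference_library() -> ReferenceLibrary:
    """The packaged synthetic reference set (see ``data/lms/``)."""
    return load_reference_dir(_data_dir() / "lms")


def bundled_registry_path() -> Path:
    return _data_dir() / "diagnosis_registry.json"


def bundled_registry() -> DiagnosisRegistry:
    """The packaged diagnosis registry (named lesions of the rubric)."""
    return DiagnosisRegistry.from_file(bundled_registry_path())


def screen_frame(records, registry, references,
                 threshold: int = 2,
                 overweight_overlay: bool = True,
                 ) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Screen a batch; returns the annotated frame and per-row failures.

    Rows that fail (unknown diagnosis, out-of-range anthropometry, ...) keep
    their identifying columns, carry the failure text in ``error`` and do not
    abort the rest of the batch.
    """
    out_rows = []
    failures: list[tuple[str, str]] = []
    for r in records:
        base = {
            "id": r.id, "sex": r.sex.value, "age_months": r.age_months,
            "weight_kg": r.weight_kg, "height_cm": r.height_cm,
            "diagnosis_code": r.diagnosis_code,
            "dietary_intake": r.dietary_intake.value,
        }
        try:
            res: ScreeningResult = screen(
                r, registry, references, threshold=threshold,
                overweight_overlay=overweight_overlay)
        except Exception as exc:  # keep scoring the rest of the batch
            failures.append((r.id, str(exc)))
            out_rows.append({**base, "error": str(exc)})
            continue
        z = res.zscores
        out_rows.append({
            **base,
            "wfa_z": z.wfa, "hfa_z": z.hfa, "wfh_z": z.wfh, "bmi_z": z.bmi,
            "anthro_z": res.anthro_z,
            "disease_score": res.disease_score,
            "diet_score": res.diet_score,
            "anthro_score": res.anthro_score,
            "total_score": res.total,
            "at_risk": res.at_risk,
            "error": None,
        })
    columns = [
        "id", "sex", "age_months", "weight_kg", "height_cm", "diagnosis_code",
        "dietary_intake", "wfa_z", "hfa_z", "wfh_z", "bmi_z", "anthro_z",
        "disease_score", "diet_score", "anthro_score", "total_score",
        "at_risk", "error",
    ]
    frame = pd.DataFrame(out_rows, columns=columns if not out_rows else None)
    return frame, failures
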