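"""Cohort data model: disease codebook, patient records, and CSV/JSON I/O.

A cohort is a patient-level table combining demographics (age, sex,
socioeconomic-position score, smoking), periodontal metrics (teeth, deep
pockets, bleeding on probing, PISA) and 26 binary indicators for systemic
diseases recorded on a medical-history questionnaire.  Twenty of the 26
diseases additionally carry an organ-system group label adapted from the
ICD-11 chapter structure; the remaining six are ungrouped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "DiseaseCodebook",
    "PatientRecord",
    "Cohort",
    "CohortSchemaError",
    "load_codebook",
    "read_cohort",
    "write_cohort",
]

# Group labels (ICD-11-adapted organ systems)
CARDIOVASCULAR = "cardiovascular"
ENDOCRINE = "endocrine_nutritional_metabolic"
RESPIRATORY = "respiratory_tract"
DIGESTIVE = "digestive_system"
BLOOD = "blood"
NEOPLASMS = "neoplasms"

GROUP_LABELS = (CARDIOVASCULAR, ENDOCRINE, RESPIRATORY, DIGESTIVE, BLOOD, NEOPLASMS)

# (identifier, display label, group-or-None), in questionnaire table order.
_DISEASES: tuple[tuple[str, str, str | None], ...] = (
    ("angina_pectoris", "Angina pectoris", CARDIOVASCULAR),
    ("myocardial_infarction", "Myocardial infarction", CARDIOVASCULAR),
    ("heart_murmur_valve_defect", "Heart murmur or heart valve defect", CARDIOVASCULAR),
    ("artificial_valve_pacemaker_hip", "Artificial heart valve/pacemaker/hip", None),
    ("heart_vascular_surgery", "Heart or vascular surgery", CARDIOVASCULAR),
    ("cardiac_arrhythmia", "Cardiac arrhythmia", CARDIOVASCULAR),
    ("heart_weakness", "Heart weakness", CARDIOVASCULAR),
    ("hyperventilation", "Hyperventilation", None),
    ("hypertension", "Hypertension", CARDIOVASCULAR),
    ("cerebrovascular_disease", "Cerebrovascular disease", CARDIOVASCULAR),
    ("epilepsy", "Epilepsy", None),
    ("asthma", "Asthma", RESPIRATORY),
    ("lung_disease", "Lung disease", RESPIRATORY),
    ("allergic_rhinitis", "Allergic rhinitis", RESPIRATORY),
    ("allergy", "Allergy", None),
    ("diabetes_mellitus", "Diabetes mellitus", ENDOCRINE),
    ("hyperthyroidism", "Hyperthyroidism", ENDOCRINE),
    ("hypothyroidism", "Hypothyroidism", ENDOCRINE),
    ("liver_disease", "Liver disease", DIGESTIVE),
    ("chronic_kidney_disease", "Chronic kidney disease", None),
    ("chronic_gastrointestinal_disease", "Chronic gastrointestinal disease", DIGESTIVE),
    ("anemia", "Anemia", BLOOD),
    ("malignant_lymph_blood_disease", "Malignant lymph node or blood disease", NEOPLASMS),
    ("bleeding_diathesis", "Bleeding diathesis", BLOOD),
    ("radiation", "Radiation", NEOPLASMS),
    ("contagious_disease", "Contagious disease", None),
)

N_DISEASES = len(_DISEASES)

REQUIRED_COLUMNS = (
    "patient_id",
    "age",
    "sex",
    "sep",
    "smoking",
    "n_teeth",
    "n_pockets_ge6",
    "bop_pct",
    "pisa_mm2",
)


class CohortSchemaError(ValueError):
    """Raised when a cohort file does not match the expected column schema."""


@dataclass(frozen=True)
class DiseaseCodebook:
    """Ordered catalogue of the 26 systemic diseases and their group map.

    Attributes
    ----------
    diseases : tuple of str
        Stable snake_case identifiers, in fixed table order.  This order
        defines the layout of every disease-flag vector and the row order
        of incidence matrices downstream.
    labels : mapping id -> display name
    groups : mapping id -> group label
        Partial: covers the 20 diseases with an ICD-11-adapted organ-system
        group; the other 6 are absent from the map.
    """

    diseases: tuple[str, ...]
    labels: Mapping[str, str]
    groups: Mapping[str, str]

    def __post_init__(self) -> None:
        if len(self.diseases) != N_DISEASES:
            raise ValueError(f"codebook must contain {N_DISEASES} diseases")
        if len(set(self.diseases)) != len(self.diseases):
            raise ValueError("disease identifiers must be unique")

    def __len__(self) -> int:
        return len(self.diseases)

    def index(self, disease: str) -> int:
        return self.diseases.index(disease)

    def group_members(self, group: str) -> tuple[str, ...]:
        """Diseases belonging to an ICD-11-adapted group, in codebook order."""
        if group not in GROUP_LABELS:
            raise KeyError(f"unknown disease group: {group!r}")
        return tuple(d for d in self.diseases if self.groups.get(d) == group)

    @property
    def ungrouped(self) -> tuple[str, ...]:
        return tuple(d for d in self.diseases if d not in self.groups)

    def to_json(self, path) -> None:
        payload = {
            "diseases": [
                {"id": d, "label": self.labels[d], "group": self.groups.get(d)}
                for d in self.diseases
            ]
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "DiseaseCodebook":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        entries = payload["diseases"]
        return cls(
            diseases=tuple(e["id"] for e in entries),
            labels={e["id"]: e["label"] for e in entries},
            groups={e["id"]: e["group"] for e in entries if e.get("group")},
        )


def load_codebook() -> DiseaseCodebook:
    """Return the fixed 26-disease codebook with the organ-system group map."""
    return DiseaseCodebook(
        diseases=tuple(d for d, _, _ in _DISEASES),
        labels={d: label for d, label, _ in _DISEASES},
        groups={d: g for d, _, g in _DISEASES if g is not None},
    )


@dataclass
class PatientRecord:
    """One cohort row: demographics, periodontal metrics and disease flags.

    ``sep`` (socioeconomic position, normalized to [-1, 1]) may be missing
    (None); every other field is required.  ``disease_flags`` is a length-26
    0/1 vector aligned to the codebook order.
    """

    patient_id: str
    age: float
    sex: str  # {"female", "male"}
    sep: float | None
    smoking: bool
    n_teeth: int
    n_pockets_ge6: int
    bop_pct: float
    pisa_mm2: float
    disease_flags: np.ndarray = field(repr=False)

    def validate(self, codebook: DiseaseCodebook) -> None:
        if self.age < 18:
            raise ValueError(f"record {self.patient_id}: age {self.age} < 18")
        if self.sex not in ("female", "male"):
            raise ValueError(f"record {self.patient_id}: sex must be female/male")
        if self.sep is not None and not -1.0 <= self.sep <= 1.0:
            raise ValueError(f"record {self.patient_id}: sep outside [-1, 1]")
        if not 0 <= self.n_teeth <= 32:
            raise ValueError(f"record {self.patient_id}: n_teeth outside [0, 32]")
        if self.n_pockets_ge6 < 0 or self.bop_pct < 0 or self.bop_pct > 100:
            raise ValueError(f"record {self.patient_id}: invalid periodontal metric")
        if self.pisa_mm2 < 0:
            raise ValueError(f"record {self.patient_id}: negative PISA")
        flags = np.asarray(self.disease_flags)
        if flags.shape != (len(codebook),):
            raise ValueError(f"record {self.patient_id}: flag vector length mismatch")
        if not np.isin(flags, (0, 1)).all():
            raise ValueError(f"record {self.patient_id}: disease flags must be 0/1")

    @property
    def disease_count(self) -> int:
        return int(np.asarray(self.disease_flags).sum())


class Cohort:
    """A validated collection of patient records sharing one codebook.

    Internally the cohort is a pandas DataFrame (one row per patient,
    disease flags as 0/1 integer columns named by codebook id), which the
    analysis modules consume directly; `records()` yields PatientRecord
    views for row-wise access.
    """

    def __init__(self, frame: pd.DataFrame, codebook: DiseaseCodebook,
                 exclusions: dict[str, int] | None = None):
        if frame.empty:
            raise ValueError("cohort must contain at least one record")
        missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
        missing += [d for d in codebook.diseases if d not in frame.columns]
        if missing:
            raise CohortSchemaError(f"missing columns: {missing}")
        self.frame = frame.reset_index(drop=True)
        self.codebook = codebook
        #: rows dropped during reading, keyed by reason
        self.exclusions = dict(exclusions or {})

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def n(self) -> int:
        return len(self.frame)

    def flags_matrix(self) -> np.ndarray:
        """n x 26 int array of disease flags, columns in codebook order."""
        return self.frame[list(self.codebook.diseases)].to_numpy(dtype=np.int8)

    def disease_counts(self) -> np.ndarray:
        return self.flags_matrix().sum(axis=1)

    def subset(self, mask) -> "Cohort":
        sub = self.frame.loc[np.asarray(mask, dtype=bool)]
        return Cohort(sub, self.codebook)

    def comorbid(self, min_diseases: int = 1) -> "Cohort":
        """Sub-cohort of patients carrying at least ``min_diseases`` diseases."""
        return self.subset(self.disease_counts() >= min_diseases)

    def records(self) -> Iterator[PatientRecord]:
        flags = self.flags_matrix()
        for i, row in enumerate(self.frame.itertuples(index=False)):
            yield PatientRecord(
                patient_id=str(row.patient_id),
                age=float(row.age),
                sex=str(row.sex),
                sep=None if pd.isna(row.sep) else float(row.sep),
                smoking=bool(row.smoking),
                n_teeth=int(row.n_teeth),
                n_pockets_ge6=int(row.n_pockets_ge6),
                bop_pct=float(row.bop_pct),
                pisa_mm2=float(row.pisa_mm2),
                disease_flags=flags[i],
            )

    @classmethod
    def from_records(cls, records: Iterable[PatientRecord],
                     codebook: DiseaseCodebook) -> "Cohort":
        rows = []
        for r in records:
            r.validate(codebook)
            row = {
                "patient_id": r.patient_id,
                "age": r.age,
                "sex": r.sex,
                "sep": np.nan if r.sep is None else r.sep,
                "smoking": int(r.smoking),
                "n_teeth": r.n_teeth,
                "n_pockets_ge6": r.n_pockets_ge6,
                "bop_pct": r.bop_pct,
                "pisa_mm2": r.pisa_mm2,
            }
            row.update({d: int(f) for d, f in zip(codebook.diseases, r.disease_flags)})
            rows.append(row)
        if not rows:
            raise ValueError("cohort must contain at least one record")
        return cls(pd.DataFrame(rows), codebook)


def read_cohort(path, codebook: DiseaseCodebook | None = None) -> Cohort:
    """Read and validate a cohort CSV.

    Rows with age < 18 and rows with any missing disease flag are dropped and
    counted in ``Cohort.exclusions`` (keys ``under_age`` and
    ``incomplete_history``), mirroring the inclusion rules of an adult cohort
    with a mandatory medical-history questionnaire.  A missing required
    column raises :class:`CohortSchemaError`; a non-binary disease cell
    raises :class:`ValueError` naming the row and column.  SEP may be empty
    (missing).
    """
    codebook = codebook or load_codebook()
    frame = pd.read_csv(path, dtype={"patient_id": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    missing += [d for d in codebook.diseases if d not in frame.columns]
    if missing:
        raise CohortSchemaError(f"{path}: missing columns: {missing}")

    disease_cols = list(codebook.diseases)
    for col in disease_cols:
        bad = frame[col].notna() & ~frame[col].isin([0, 1, 0.0, 1.0, "0", "1"])
        if bad.any():
            row = int(frame.index[bad][0])
            raise ValueError(
                f"{path}: non-binary disease value {frame.at[row, col]!r} "
                f"in column {col!r}, row {row}"
            )

    required_nonmissing = [c for c in REQUIRED_COLUMNS if c != "sep"]
    incomplete = frame[disease_cols].isna().any(axis=1)
    incomplete |= frame[required_nonmissing].isna().any(axis=1)
    under_age = frame["age"].notna() & (frame["age"] < 18)

    exclusions = {
        "under_age": int(under_age.sum()),
        "incomplete_history": int((incomplete & ~under_age).sum()),
    }
    kept = frame.loc[~(under_age | incomplete)].copy()
    if kept.empty:
        raise ValueError(f"{path}: no valid records after exclusions")

    kept[disease_cols] = kept[disease_cols].astype(int)
    kept["smoking"] = kept["smoking"].astype(int)
    kept["n_teeth"] = kept["n_teeth"].astype(int)
    kept["n_pockets_ge6"] = kept["n_pockets_ge6"].astype(int)
    bad_sex = ~kept["sex"].isin(["female", "male"])
    if bad_sex.any():
        row = int(kept.index[bad_sex][0])
        raise ValueError(f"{path}: invalid sex value in row {row}")

    cohort = Cohort(kept, codebook, exclusions=exclusions)
    for rec in cohort.records():
        rec.validate(codebook)
    return cohort


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort to CSV (UTF-8, '.' decimal; missing SEP as empty cell).

    Round-trip safe: ``read_cohort(write_cohort(c))`` reproduces every field.
    """
    if len(cohort) == 0:  # Cohort construction forbids this; belt and braces
        raise ValueError("refusing to write an empty cohort")
    cols = list(REQUIRED_COLUMNS) + list(cohort.codebook.diseases)
    cohort.frame[cols].to_csv(path, index=False)
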