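"""In-memory model of a four-table EHR extract.

A :class:`Registry` bundles the patient, laboratory (serum creatinine),
diagnosis (ICD-10) and procedure (CPT) tables as pandas DataFrames together
with the extraction reference date ("as of" date).  Validation enumerates
every failing row rather than stopping at the first problem and never
mutates the input frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "PatientRecord",
    "LabResult",
    "CodedEvent",
    "Registry",
    "RowError",
    "RegistryValidationError",
    "PATIENT_COLUMNS",
    "LAB_COLUMNS",
    "DIAGNOSIS_COLUMNS",
    "PROCEDURE_COLUMNS",
]

PATIENT_COLUMNS = ["patient_id", "birth_date", "age_years", "sex", "race", "enrolled"]
LAB_COLUMNS = ["patient_id", "collection_date", "creatinine_mg_dl", "egfr"]
DIAGNOSIS_COLUMNS = ["patient_id", "event_date", "code"]
PROCEDURE_COLUMNS = ["patient_id", "event_date", "code"]

_SEXES = {"male", "female"}
_RACES = {"black", "white", "other"}


@dataclass(frozen=True)
class PatientRecord:
    """Demographics and enrollment status for one person.

    Either ``birth_date`` or ``age_years`` (age at the registry reference
    date) must be present; sex and race feed the MDRD equation.
    """

    patient_id: str
    sex: str
    race: str
    birth_date: Optional[date] = None
    age_years: Optional[float] = None
    enrolled: bool = True


@dataclass(frozen=True)
class LabResult:
    """One dated serum-creatinine measurement (mg/dL), optionally with eGFR."""

    patient_id: str
    collection_date: date
    creatinine_mg_dl: float
    egfr: Optional[float] = None


@dataclass(frozen=True)
class CodedEvent:
    """One dated ICD-10 diagnosis or CPT procedure."""

    patient_id: str
    event_date: date
    system: str  # "ICD10" or "CPT"
    code: str


@dataclass(frozen=True)
class RowError:
    table: str
    row: int  # 0-based positional index within the table
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.table}[row {self.row}]: {self.message}"


class RegistryValidationError(ValueError):
    """Raised when a registry fails validation; carries every failing row."""

    def __init__(self, errors: list[RowError]):
        self.errors = errors
        head = "\n".join(str(e) for e in errors[:20])
        more = "" if len(errors) <= 20 else f"\n... and {len(errors) - 20} more"
        super().__init__(f"{len(errors)} invalid row(s):\n{head}{more}")


def _empty(columns: list[str]) -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=object) for c in columns})


@dataclass
class Registry:
    """A four-table EHR extract as of ``reference_date``."""

    patients: pd.DataFrame
    labs: pd.DataFrame
    diagnoses: pd.DataFrame
    procedures: pd.DataFrame
    reference_date: date
    ground_truth: Optional[pd.DataFrame] = field(default=None, repr=False)

    # ------------------------------------------------------------------ build
    @classmethod
    def empty(cls, reference_date: date) -> "Registry":
        return cls(
            patients=_empty(PATIENT_COLUMNS),
            labs=_empty(LAB_COLUMNS),
            diagnoses=_empty(DIAGNOSIS_COLUMNS),
            procedures=_empty(PROCEDURE_COLUMNS),
            reference_date=reference_date,
        )

    @classmethod
    def from_records(
        cls,
        patients: list[PatientRecord],
        labs: list[LabResult],
        events: list[CodedEvent],
        reference_date: date,
    ) -> "Registry":
        pat = pd.DataFrame(
            [
                {
                    "patient_id": p.patient_id,
                    "birth_date": pd.Timestamp(p.birth_date) if p.birth_date else pd.NaT,
                    "age_years": np.nan if p.age_years is None else float(p.age_years),
                    "sex": p.sex,
                    "race": p.race,
                    "enrolled": bool(p.enrolled),
                }
                for p in patients
            ],
            columns=PATIENT_COLUMNS,
        )
        lab = pd.DataFrame(
            [
                {
                    "patient_id": l.patient_id,
                    "collection_date": pd.Timestamp(l.collection_date),
                    "creatinine_mg_dl": float(l.creatinine_mg_dl),
                    "egfr": np.nan if l.egfr is None else float(l.egfr),
                }
                for l in labs
            ],
            columns=LAB_COLUMNS,
        )
        dx = pd.DataFrame(
            [
                {"patient_id": e.patient_id, "event_date": pd.Timestamp(e.event_date), "code": e.code}
                for e in events
                if e.system == "ICD10"
            ],
            columns=DIAGNOSIS_COLUMNS,
        )
        px = pd.DataFrame(
            [
                {"patient_id": e.patient_id, "event_date": pd.Timestamp(e.event_date), "code": e.code}
                for e in events
                if e.system == "CPT"
            ],
            columns=PROCEDURE_COLUMNS,
        )
        return cls(pat, lab, dx, px, reference_date)

    # --------------------------------------------------------------- derived
    def events(self) -> pd.DataFrame:
        """Diagnoses and procedures in one frame with a ``system`` column."""
        dx = self.diagnoses.assign(system="ICD10")
        px = self.procedures.assign(system="CPT")
        cols = ["patient_id", "event_date", "system", "code"]
        if dx.empty and px.empty:
            return pd.DataFrame(columns=cols)
        return pd.concat([dx[cols] if not dx.empty else None,
                          px[cols] if not px.empty else None],
                         ignore_index=True).dropna(how="all")

    def enrolled_ids(self) -> set[str]:
        if self.patients.empty:
            return set()
        return set(self.patients.loc[self.patients["enrolled"].astype(bool), "patient_id"])

    # ------------------------------------------------------------ validation
    def validate(self, horizon_days: int = 365) -> list[RowError]:
        """Check invariants; return every failing row (input left untouched)."""
        errors: list[RowError] = []
        pat = self.patients
        ids = pat["patient_id"] if not pat.empty else pd.Series(dtype=object)
        dup = ids[ids.duplicated()]
        for i in dup.index:
            errors.append(RowError("patients", int(i), f"duplicate patient_id {ids[i]!r}"))
        known = set(ids)
        horizon = pd.Timestamp(self.reference_date) + pd.Timedelta(days=horizon_days)

        for i, row in pat.iterrows():
            if pd.isna(row.get("birth_date")) and pd.isna(row.get("age_years")):
                errors.append(RowError("patients", int(i), "needs birth_date or age_years"))
            if row["sex"] not in _SEXES:
                errors.append(RowError("patients", int(i), f"bad sex {row['sex']!r}"))
            if row["race"] not in _RACES:
                errors.append(RowError("patients", int(i), f"bad race {row['race']!r}"))

        def check_events(df: pd.DataFrame, table: str, date_col: str) -> None:
            for i, row in df.iterrows():
                if row["patient_id"] not in known:
                    errors.append(
                        RowError(table, int(i), f"unknown patient_id {row['patient_id']!r}")
                    )
                d = row[date_col]
                if pd.isna(d):
                    errors.append(RowError(table, int(i), f"missing {date_col}"))
                elif pd.Timestamp(d) > horizon:
                    errors.append(
                        RowError(table, int(i), f"{date_col} {d} after reference horizon")
                    )

        check_events(self.labs, "labs", "collection_date")
        check_events(self.diagnoses, "diagnoses", "event_date")
        check_events(self.procedures, "procedures", "event_date")

        for i, row in self.labs.iterrows():
            cr = row["creatinine_mg_dl"]
            if pd.isna(cr) or float(cr) <= 0:
                errors.append(RowError("labs", int(i), f"creatinine must be > 0, got {cr!r}"))
            eg = row.get("egfr")
            if eg is not None and not pd.isna(eg) and float(eg) <= 0:
                errors.append(RowError("labs", int(i), f"egfr must be > 0, got {eg!r}"))
        for table, df in (("diagnoses", self.diagnoses), ("procedures", self.procedures)):
            for i, row in df.iterrows():
                if not str(row["code"]).strip():
                    errors.append(RowError(table, int(i), "empty code"))
        return errors

    def require_valid(self, horizon_days: int = 365) -> "Registry":
        errors = self.validate(horizon_days=horizon_days)
        if errors:
            raise RegistryValidationError(errors)
        return self

    # --------------------------------------------------------------- equality
    def equals(self, other: "Registry") -> bool:
        """Field-wise equality on sorted tables (row order insensitive)."""
        if pd.Timestamp(self.reference_date).date() != pd.Timestamp(other.reference_date).date():
            return False

        def canon(df: pd.DataFrame, keys: list[str]) -> pd.DataFrame:
            out = df.copy()
            for c in out.columns:
                if "date" in c:
                    out[c] = pd.to_datetime(out[c])
            return out.sort_values(keys, kind="mergesort").reset_index(drop=True)

        pairs = [
            (self.patients, other.patients, ["patient_id"]),
            (self.labs, other.labs, ["patient_id", "collection_date", "creatinine_mg_dl"]),
            (self.diagnoses, other.diagnoses, ["patient_id", "event_date", "code"]),
            (self.procedures, other.procedures, ["patient_id", "event_date", "code"]),
        ]
        for a, b, keys in pairs:
            if len(a) != len(b):
                return False
            if len(a) == 0:
                continue
            ca, cb = canon(a, keys), canon(b, keys)
            if list(ca.columns) != list(cb.columns):
                return False
            for c in ca.columns:
                va, vb = ca[c], cb[c]
                if va.dtype.kind == "f" or vb.dtype.kind == "f":
                    if not np.allclose(
                        va.astype(float), vb.astype(float), rtol=1e-12, atol=0, equal_nan=True
                    ):
                        return False
                else:
                    if not va.fillna("").astype(str).equals(vb.fillna("").astype(str)):
                        return False
        return True
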