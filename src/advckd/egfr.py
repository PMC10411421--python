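"""MDRD eGFR computation and index / 90-day-prior value selection.

The 4-variable IDMS-traceable MDRD study equation is

    eGFR = 175 * Scr^-1.154 * age^-0.203 * 0.742(if female) * 1.212(if Black)

with serum creatinine (Scr) in mg/dL, age in years, and eGFR in
ml/min/1.73 m^2.  The leading coefficient is configurable (the older
non-IDMS re-expression used 186).  The race coefficient reflects the
historical equation used by the source laboratory convention; newer
race-free equations are deliberately out of scope here.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from typing import Optional, Union

import numpy as np
import pandas as pd

from .datamodel import Registry

__all__ = [
    "MDRD_COEFFICIENT",
    "CREATININE_EXPONENT",
    "AGE_EXPONENT",
    "FEMALE_FACTOR",
    "BLACK_FACTOR",
    "EgfrPair",
    "compute_egfr_mdrd",
    "invert_mdrd",
    "add_egfr",
    "select_egfr_pair",
    "select_egfr_pairs",
    "lookback_start",
]

MDRD_COEFFICIENT = 175.0
CREATININE_EXPONENT = -1.154
AGE_EXPONENT = -0.203
FEMALE_FACTOR = 0.742
BLACK_FACTOR = 1.212

ArrayLike = Union[float, np.ndarray, pd.Series]


@dataclass(frozen=True)
class EgfrPair:
    """A patient's index (latest) eGFR and the latest eGFR >=90 days earlier."""

    patient_id: str
    index_egfr: float
    index_date: date
    prior_egfr: Optional[float] = None
    prior_date: Optional[date] = None

    @property
    def gap_days(self) -> Optional[int]:
        if self.prior_date is None:
            return None
        return (pd.Timestamp(self.index_date) - pd.Timestamp(self.prior_date)).days


def _demographic_factor(sex, race_black) -> ArrayLike:
    female = np.asarray(pd.Series(sex).astype(str).str.lower() == "female")
    black = np.asarray(pd.Series(race_black).astype(bool))
    return np.where(female, FEMALE_FACTOR, 1.0) * np.where(black, BLACK_FACTOR, 1.0)


def compute_egfr_mdrd(
    creatinine_mg_dl: ArrayLike,
    age_years: ArrayLike,
    sex: Union[str, ArrayLike] = "male",
    race_black: Union[bool, ArrayLike] = False,
    *,
    coefficient: float = MDRD_COEFFICIENT,
) -> ArrayLike:
    """eGFR (ml/min/1.73 m^2) from creatinine, age, sex and race.

    Accepts scalars or aligned arrays.  Strictly decreasing in creatinine
    and in age; raises ``ValueError`` on non-positive creatinine or age.
    """
    cr = np.asarray(creatinine_mg_dl, dtype=float)
    age = np.asarray(age_years, dtype=float)
    if np.any(cr <= 0) or not np.all(np.isfinite(cr)):
        raise ValueError("creatinine must be positive and finite")
    if np.any(age <= 0) or not np.all(np.isfinite(age)):
        raise ValueError("age must be positive and finite")
    out = (
        coefficient
        * cr ** CREATININE_EXPONENT
        * age ** AGE_EXPONENT
        * _demographic_factor(sex, race_black)
    )
    if np.isscalar(creatinine_mg_dl) and np.isscalar(age_years):
        return float(np.asarray(out).reshape(-1)[0])
    return out


def invert_mdrd(
    target_egfr: ArrayLike,
    age_years: ArrayLike,
    sex: Union[str, ArrayLike] = "male",
    race_black: Union[bool, ArrayLike] = False,
    *,
    coefficient: float = MDRD_COEFFICIENT,
) -> ArrayLike:
    """Creatinine (mg/dL) that yields ``target_egfr`` under the MDRD equation."""
    g = np.asarray(target_egfr, dtype=float)
    age = np.asarray(age_years, dtype=float)
    if np.any(g <= 0) or not np.all(np.isfinite(g)):
        raise ValueError("target eGFR must be positive and finite")
    if np.any(age <= 0) or not np.all(np.isfinite(age)):
        raise ValueError("age must be positive and finite")
    base = coefficient * age ** AGE_EXPONENT * _demographic_factor(sex, race_black)
    out = (g / base) ** (1.0 / CREATININE_EXPONENT)
    if np.isscalar(target_egfr) and np.isscalar(age_years):
        return float(np.asarray(out).reshape(-1)[0])
    return out


def add_egfr(registry: Registry, *, coefficient: float = MDRD_COEFFICIENT) -> Registry:
    """Return a registry whose labs carry a computed ``egfr`` column.

    Age is taken at each lab's collection date when ``birth_date`` is known;
    otherwise ``age_years`` (age at the reference date) is shifted by the
    elapsed time between the lab and the reference date.
    """
    labs = registry.labs.copy()
    if labs.empty:
        return Registry(
            registry.patients, labs, registry.diagnoses, registry.procedures,
            registry.reference_date, registry.ground_truth,
        )
    pat = registry.patients.set_index("patient_id")
    merged = labs.join(pat[["birth_date", "age_years", "sex", "race"]], on="patient_id")
    dates = pd.to_datetime(merged["collection_date"])
    birth = pd.to_datetime(merged["birth_date"])
    age_from_birth = (dates - birth).dt.days / 365.25
    ref = pd.Timestamp(registry.reference_date)
    age_from_ref = merged["age_years"].astype(float) + (dates - ref).dt.days / 365.25
    age = age_from_birth.where(birth.notna(), age_from_ref)
    labs["egfr"] = compute_egfr_mdrd(
        merged["creatinine_mg_dl"].astype(float).to_numpy(),
        age.to_numpy(),
        merged["sex"],
        merged["race"].astype(str).str.lower() == "black",
        coefficient=coefficient,
    )
    return Registry(
        registry.patients, labs, registry.diagnoses, registry.procedures,
        registry.reference_date, registry.ground_truth,
    )


def lookback_start(reference_date: date, lookback_days: int = 365) -> pd.Timestamp:
    """First day of the closed lookback window ending on the reference date."""
    return pd.Timestamp(reference_date) - pd.Timedelta(days=lookback_days - 1)


def select_egfr_pairs(
    labs: pd.DataFrame,
    reference_date: date,
    *,
    lookback_days: int = 365,
    min_gap_days: int = 90,
) -> pd.DataFrame:
    """Index and >=90-day-prior eGFR per patient, for all patients at once.

    The index value is the eGFR with the latest collection date inside the
    lookback window (same-day ties resolved to the lowest eGFR); the prior
    value is the latest eGFR dated at least ``min_gap_days`` before the index
    date and still inside the window.  Patients with no in-window lab are
    absent from the result; a missing prior appears as NaN/NaT.

    Returns a frame indexed by patient_id with columns
    index_egfr, index_date, prior_egfr, prior_date.
    """
    if labs.empty:
        return pd.DataFrame(
            columns=["index_egfr", "index_date", "prior_egfr", "prior_date"]
        ).rename_axis("patient_id")
    df = labs.dropna(subset=["egfr"]).copy()
    df["collection_date"] = pd.to_datetime(df["collection_date"])
    ref = pd.Timestamp(reference_date)
    start = lookback_start(reference_date, lookback_days)
    df = df[(df["collection_date"] >= start) & (df["collection_date"] <= ref)]
    if df.empty:
        return pd.DataFrame(
            columns=["index_egfr", "index_date", "prior_egfr", "prior_date"]
        ).rename_axis("patient_id")
    # latest date first; within a day the LOWEST eGFR wins (conservative)
    df = df.sort_values(
        ["patient_id", "collection_date", "egfr"],
        ascending=[True, False, True],
        kind="mergesort",
    )
    idx = df.groupby("patient_id", sort=True).first()
    out = pd.DataFrame(
        {
            "index_egfr": idx["egfr"].astype(float),
            "index_date": idx["collection_date"],
        }
    )
    cutoff = out["index_date"] - pd.Timedelta(days=min_gap_days)
    pri = df.join(cutoff.rename("cutoff"), on="patient_id")
    pri = pri[pri["collection_date"] <= pri["cutoff"]]
    if pri.empty:
        out["prior_egfr"] = np.nan
        out["prior_date"] = pd.NaT
    else:
        first = pri.groupby("patient_id", sort=True).first()
        out["prior_egfr"] = first["egfr"].astype(float)
        out["prior_date"] = first["collection_date"]
    return out


def select_egfr_pair(
    labs: pd.DataFrame,
    reference_date: date,
    *,
    lookback_days: int = 365,
    min_gap_days: int = 90,
) -> Optional[EgfrPair]:
    """Single-patient convenience wrapper around :func:`select_egfr_pairs`."""
    pairs = select_egfr_pairs(
        labs, reference_date, lookback_days=lookback_days, min_gap_days=min_gap_days
    )
    if pairs.empty:
        return None
    if pairs.shape[0] != 1:
        raise ValueError("select_egfr_pair expects labs from a single patient")
    pid = pairs.index[0]
    row = pairs.iloc[0]
    has_prior = pd.notna(row["prior_egfr"])
    return EgfrPair(
        patient_id=str(pid),
        index_egfr=float(row["index_egfr"]),
        index_date=row["index_date"].date(),
        prior_egfr=float(row["prior_egfr"]) if has_prior else None,
        prior_date=row["prior_date"].date() if has_prior else None,
    )
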