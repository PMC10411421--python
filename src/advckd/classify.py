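"""Tiered risk classification of the advanced-CKD source cohort.

Each cohort member is placed in exactly one tier from two eGFR values
(index = latest, prior = latest at least 90 days earlier), the presence of
an advanced-CKD diagnosis code, and recent acute kidney injury (AKI) coding:

=====================  ==============  ==============  =========================
tier                   index eGFR      prior eGFR      additional criteria
=====================  ==============  ==============  =========================
high                   < 30            < 30            none
intermediate (sub 1)   < 30            30 <= x < 60    no AKI code in prior 90 d
excluded_aki           < 30            30 <= x < 60    AKI code in prior 90 d
intermediate (sub 2)   30 <= x < 60    < 30            advanced-CKD code present
low                    >= 30           >= 30           advanced-CKD code present
unclassified           anything else (including a missing prior value)
=====================  ==============  ==============  =========================

Combinations the scheme does not define (e.g. index < 30 with prior >= 60,
or a code-only member with no second eGFR) are deliberately left
``unclassified`` rather than forced into a tier.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date
from enum import Enum
from typing import Optional

import pandas as pd

from .codes import CodeSet, match_codes
from .cohort import CohortFlow
from .datamodel import Registry

__all__ = ["Tier", "PhenotypeAssignment", "classify", "assign_tiers", "apply_phenotype",
           "PHENOTYPES"]

PHENOTYPES = ("icd_only", "single_egfr", "two_egfr", "tiered")


class Tier(str, Enum):
    HIGH = "high"
    INTERMEDIATE = "intermediate"
    LOW = "low"
    EXCLUDED_AKI = "excluded_aki"
    UNCLASSIFIED = "unclassified"

    def __str__(self) -> str:  # pragma: no cover
        return self.value


@dataclass(frozen=True)
class PhenotypeAssignment:
    """A tier label plus the evidence that produced it."""

    patient_id: str
    tier: Tier
    subgroup: Optional[int]  # 1 or 2, intermediate only
    index_egfr: float
    prior_egfr: Optional[float]
    has_adv_code: bool
    aki_in_90d: bool


def classify(
    index_egfr: float,
    prior_egfr: Optional[float],
    has_adv_code: bool,
    aki_in_90d: bool,
    *,
    low_threshold: float = 30.0,
    high_threshold: float = 60.0,
    patient_id: str = "",
) -> PhenotypeAssignment:
    """Assign one patient's tier from the two eGFR values and code flags.

    ``index_egfr`` is required; a missing (None/NaN) ``prior_egfr`` yields
    ``unclassified``.  Pure function: thresholds compare full-precision
    values, nothing is rounded first.
    """
    if index_egfr is None or (isinstance(index_egfr, float) and math.isnan(index_egfr)):
        raise ValueError("index_egfr is required for classification")
    prior_missing = prior_egfr is None or (
        isinstance(prior_egfr, float) and math.isnan(prior_egfr)
    )

    tier, subgroup = Tier.UNCLASSIFIED, None
    if not prior_missing:
        lo, hi = low_threshold, high_threshold
        if index_egfr < lo and prior_egfr < lo:
            tier = Tier.HIGH
        elif index_egfr < lo and lo <= prior_egfr < hi:
            tier = Tier.EXCLUDED_AKI if aki_in_90d else Tier.INTERMEDIATE
            subgroup = None if aki_in_90d else 1
        elif lo <= index_egfr < hi and prior_egfr < lo and has_adv_code:
            tier, subgroup = Tier.INTERMEDIATE, 2
        elif index_egfr >= lo and prior_egfr >= lo and has_adv_code:
            tier = Tier.LOW
    return PhenotypeAssignment(
        patient_id=patient_id,
        tier=tier,
        subgroup=subgroup,
        index_egfr=float(index_egfr),
        prior_egfr=None if prior_missing else float(prior_egfr),
        has_adv_code=bool(has_adv_code),
        aki_in_90d=bool(aki_in_90d),
    )


def _aki_flags(
    registry: Registry,
    evidence: pd.DataFrame,
    aki_code_set: CodeSet,
    aki_window_days: int,
) -> pd.Series:
    """AKI code within ``aki_window_days`` before each patient's index date."""
    flags = pd.Series(False, index=evidence["patient_id"])
    dx = registry.diagnoses
    if dx.empty:
        return flags
    dx = dx.assign(system="ICD10")
    for _, row in evidence.iterrows():
        if pd.isna(row["index_date"]):
            continue
        idx = pd.Timestamp(row["index_date"])
        window = ((idx - pd.Timedelta(days=aki_window_days)).date(), idx.date())
        sub = dx[dx["patient_id"] == row["patient_id"]]
        if not sub.empty and row["patient_id"] in match_codes(sub, aki_code_set, window):
            flags.loc[row["patient_id"]] = True
    return flags


def assign_tiers(
    flow: CohortFlow,
    registry: Registry,
    aki_code_set: CodeSet,
    *,
    aki_window_days: int = 90,
    low_threshold: float = 30.0,
    high_threshold: float = 60.0,
) -> pd.DataFrame:
    """Classify every (non-excluded) source-cohort member.

    Returns one row per member: tier, subgroup, and the evidence columns.
    Members with no usable eGFR (code-arm only, no in-window lab) are
    ``unclassified``.
    """
    evidence = flow.evidence
    members = evidence[~evidence["excluded_dialysis"]].copy()
    aki = _aki_flags(registry, members, aki_code_set, aki_window_days)
    rows = []
    for _, row in members.iterrows():
        pid = row["patient_id"]
        if pd.isna(row["index_egfr"]):
            assignment = PhenotypeAssignment(
                patient_id=pid, tier=Tier.UNCLASSIFIED, subgroup=None,
                index_egfr=float("nan"), prior_egfr=None,
                has_adv_code=bool(row["code_arm"]), aki_in_90d=bool(aki.loc[pid]),
            )
        else:
            assignment = classify(
                row["index_egfr"],
                None if pd.isna(row["prior_egfr"]) else row["prior_egfr"],
                has_adv_code=bool(row["code_arm"]),
                aki_in_90d=bool(aki.loc[pid]),
                low_threshold=low_threshold,
                high_threshold=high_threshold,
                patient_id=pid,
            )
        rows.append(
            {
                "patient_id": pid,
                "tier": assignment.tier.value,
                "subgroup": assignment.subgroup,
                "index_egfr": assignment.index_egfr,
                "index_date": row["index_date"],
                "prior_egfr": assignment.prior_egfr,
                "prior_date": row["prior_date"],
                "has_adv_code": assignment.has_adv_code,
                "aki_in_90d": assignment.aki_in_90d,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id", "tier", "subgroup", "index_egfr", "index_date",
            "prior_egfr", "prior_date", "has_adv_code", "aki_in_90d",
        ],
    )


def apply_phenotype(
    pairs: pd.DataFrame,
    coded_ids: set[str],
    phenotype: str,
    *,
    low_threshold: float = 30.0,
    high_threshold: float = 60.0,
) -> pd.Series:
    """Evaluate one comparator phenotype over all patients with an index eGFR.

    ``pairs`` is the frame from :func:`advckd.egfr.select_egfr_pairs`;
    ``coded_ids`` the advanced-CKD-coded patients.  Returns a boolean Series
    (index = patient_id); for ``two_egfr``, patients missing a prior value
    are returned as ``pd.NA`` (not evaluable) rather than negative.
    """
    if phenotype not in PHENOTYPES:
        raise ValueError(f"unknown phenotype {phenotype!r}; expected one of {PHENOTYPES}")
    idx = pairs["index_egfr"].astype(float)
    pri = pairs["prior_egfr"].astype(float)
    if phenotype == "icd_only":
        return pd.Series(pairs.index.isin(coded_ids), index=pairs.index, dtype="boolean")
    if phenotype == "single_egfr":
        return (idx < low_threshold).astype("boolean")
    if phenotype == "two_egfr":
        out = ((idx < low_threshold) & (pri < high_threshold)).astype("boolean")
        out[pri.isna()] = pd.NA
        return out
    # tiered: positive = assigned high or intermediate on the comparator rule set
    out = pd.Series(False, index=pairs.index, dtype="boolean")
    for pid in pairs.index:
        a = classify(
            idx.loc[pid],
            None if pd.isna(pri.loc[pid]) else pri.loc[pid],
            has_adv_code=pid in coded_ids,
            aki_in_90d=False,
            low_threshold=low_threshold,
            high_threshold=high_threshold,
        )
        out.loc[pid] = a.tier in (Tier.HIGH, Tier.INTERMEDIATE)
    return out
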