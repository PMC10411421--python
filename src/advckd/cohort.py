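"""Source-cohort extraction: active users -> creatinine-tested -> advanced CKD.

The source cohort contains every active enrollee who, inside the 12-month
lookback, either (a) has an index eGFR at or below the advanced-CKD
threshold, or (b) carries an advanced-CKD diagnosis code (N18.4/N18.5) —
minus everyone flagged by dialysis/ESKD ICD-10 or CPT codes.  The eGFR arm
uses an inclusive comparison (<= 30) by default, mirroring the cohort
definition's wording, while the downstream risk tiers compare strictly
(< 30); a switch harmonizes the two if desired.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date

import pandas as pd

from .codes import CodeSet, match_codes
from .datamodel import Registry
from .egfr import lookback_start, select_egfr_pairs

__all__ = ["CohortFlow", "creatinine_tested_users", "exclude_dialysis", "build_source_cohort"]


@dataclass
class CohortFlow:
    """Attrition counts and memberships mirroring the cohort-selection flow."""

    n_active_users: int
    n_with_creatinine: int
    n_source_cohort: int
    n_excluded_dialysis: int
    active_ids: set = field(repr=False, default_factory=set)
    tested_ids: set = field(repr=False, default_factory=set)
    source_ids: set = field(repr=False, default_factory=set)
    excluded_ids: set = field(repr=False, default_factory=set)
    evidence: pd.DataFrame = field(repr=False, default=None)

    def counts(self) -> dict:
        return {
            "active_users": self.n_active_users,
            "with_creatinine_12mo": self.n_with_creatinine,
            "source_cohort": self.n_source_cohort,
            "excluded_dialysis": self.n_excluded_dialysis,
        }


def creatinine_tested_users(
    registry: Registry, *, lookback_days: int = 365
) -> set[str]:
    """Enrollees with >=1 creatinine lab in the lookback window."""
    enrolled = registry.enrolled_ids()
    labs = registry.labs
    if labs.empty:
        return set()
    dates = pd.to_datetime(labs["collection_date"])
    ref = pd.Timestamp(registry.reference_date)
    start = lookback_start(registry.reference_date, lookback_days)
    in_window = (dates >= start) & (dates <= ref)
    return set(labs.loc[in_window, "patient_id"]) & enrolled


def exclude_dialysis(
    candidates: set[str],
    registry: Registry,
    dialysis_code_set: CodeSet,
    window: tuple[date, date],
) -> tuple[set[str], set[str]]:
    """Split candidates into (kept, excluded-by-dialysis-codes)."""
    flagged = match_codes(registry.events(), dialysis_code_set, window)
    excluded = candidates & flagged
    return candidates - excluded, excluded


def build_source_cohort(
    registry: Registry,
    adv_ckd_code_set: CodeSet,
    dialysis_code_set: CodeSet,
    *,
    lookback_days: int = 365,
    min_gap_days: int = 90,
    egfr_threshold: float = 30.0,
    egfr_inclusive: bool = True,
) -> CohortFlow:
    """Build the advanced-CKD source cohort with per-patient evidence.

    Requires labs with a computed ``egfr`` column (see
    :func:`advckd.egfr.add_egfr`).  The returned flow's ``evidence`` frame
    (one row per source-cohort or excluded patient) records which arm
    qualified, the index/prior eGFR values and dates, and the exclusion flag.
    Patients qualifying only through codes, with no usable eGFR, are retained
    and flagged unclassifiable by eGFR (index columns left NaN).
    """
    active = registry.enrolled_ids()
    tested = creatinine_tested_users(registry, lookback_days=lookback_days)
    ref = registry.reference_date
    window = (lookback_start(ref, lookback_days).date(), pd.Timestamp(ref).date())

    pairs = select_egfr_pairs(
        registry.labs, ref, lookback_days=lookback_days, min_gap_days=min_gap_days
    )
    pairs = pairs[pairs.index.isin(tested)]
    if egfr_inclusive:
        egfr_arm = set(pairs.index[pairs["index_egfr"] <= egfr_threshold])
    else:
        egfr_arm = set(pairs.index[pairs["index_egfr"] < egfr_threshold])
    code_arm = match_codes(registry.diagnoses.assign(system="ICD10"), adv_ckd_code_set, window)
    code_arm &= active
    candidates = egfr_arm | code_arm
    kept, excluded = exclude_dialysis(candidates, registry, dialysis_code_set, window)

    rows = []
    for pid in sorted(candidates):
        has_pair = pid in pairs.index
        rows.append(
            {
                "patient_id": pid,
                "egfr_arm": pid in egfr_arm,
                "code_arm": pid in code_arm,
                "excluded_dialysis": pid in excluded,
                "index_egfr": float(pairs.at[pid, "index_egfr"]) if has_pair else float("nan"),
                "index_date": pairs.at[pid, "index_date"] if has_pair else pd.NaT,
                "prior_egfr": float(pairs.at[pid, "prior_egfr"]) if has_pair else float("nan"),
                "prior_date": pairs.at[pid, "prior_date"] if has_pair else pd.NaT,
            }
        )
    evidence = pd.DataFrame(
        rows,
        columns=[
            "patient_id", "egfr_arm", "code_arm", "excluded_dialysis",
            "index_egfr", "index_date", "prior_egfr", "prior_date",
        ],
    )
    return CohortFlow(
        n_active_users=len(active),
        n_with_creatinine=len(tested),
        n_source_cohort=len(kept),
        n_excluded_dialysis=len(excluded),
        active_ids=active,
        tested_ids=tested,
        source_ids=kept,
        excluded_ids=excluded,
        evidence=evidence,
    )
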