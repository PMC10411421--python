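"""Six-month prospective stability of classified cohorts.

For each phenotype group the report counts, over a follow-up horizon after
the extraction date:

* ``n_subsequent`` — patients with at least one eGFR dated after their index
  eGFR and within the horizon (denominator for the "current" row);
* ``n_any_ge30`` — patients with *any* such follow-up eGFR at or above
  30 ml/min/1.73 m^2, as a percent of the whole group;
* ``n_current_ge30`` — patients whose *latest* follow-up eGFR is >= 30,
  as a percent of those with a follow-up measurement;
* ``pct_remaining`` — 100 minus the current->=30 percent: the probability of
  still being in the advanced-CKD stage at the end of follow-up.

The two "≥30" rows intentionally use different denominators, so no ordering
between them is implied.
"""

from __future__ import annotations

from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .codes import CodeSet, match_codes
from .datamodel import Registry
from .egfr import lookback_start, select_egfr_pairs
from .metrics import round_half_up

__all__ = [
    "followup_stats",
    "gap_statistics",
    "pct_remaining_from_counts",
    "cumulative_high_intermediate",
]


def pct_remaining_from_counts(n_current_ge30: int, n_subsequent: int) -> float:
    """Percent remaining in advanced CKD, from the Table-style counts."""
    if n_subsequent <= 0:
        raise ValueError("no patients with follow-up measurements")
    return 100.0 - 100.0 * n_current_ge30 / n_subsequent


def followup_stats(
    groups: Mapping[str, set],
    registry: Registry,
    pairs: pd.DataFrame,
    *,
    horizon_days: int = 180,
    threshold: float = 30.0,
) -> pd.DataFrame:
    """Stability report, one row per group.

    ``groups`` maps a group label to its patient-id set; ``pairs`` supplies
    each patient's index date (:func:`advckd.egfr.select_egfr_pairs`).
    Groups with no members are omitted (with a console warning).  Percents
    are full precision; ``pct_*`` columns are NaN where undefined.
    """
    labs = registry.labs.dropna(subset=["egfr"]).copy()
    labs["collection_date"] = pd.to_datetime(labs["collection_date"])
    ref = pd.Timestamp(registry.reference_date)
    end = ref + pd.Timedelta(days=horizon_days)

    rows = []
    for name, members in groups.items():
        members = set(members)
        if not members:
            import warnings

            warnings.warn(f"group {name!r} is empty; omitted from stability report")
            continue
        n_group = len(members)
        n_subsequent = n_any = n_current = 0
        for pid in members:
            if pid not in pairs.index:
                continue
            idx_date = pd.Timestamp(pairs.at[pid, "index_date"])
            sub = labs[
                (labs["patient_id"] == pid)
                & (labs["collection_date"] > idx_date)
                & (labs["collection_date"] <= end)
            ]
            if sub.empty:
                continue
            n_subsequent += 1
            if (sub["egfr"] >= threshold).any():
                n_any += 1
            # latest follow-up value; same-day ties resolved to the lowest eGFR
            latest = (
                sub.sort_values(["collection_date", "egfr"], ascending=[True, False])
                .iloc[-1]
            )
            if latest["egfr"] >= threshold:
                n_current += 1
        rows.append(
            {
                "group": name,
                "n_group": n_group,
                "n_subsequent": n_subsequent,
                "pct_subsequent": 100.0 * n_subsequent / n_group,
                "n_any_ge30": n_any,
                "pct_any_ge30": 100.0 * n_any / n_group,
                "n_current_ge30": n_current,
                "pct_current_ge30": (
                    100.0 * n_current / n_subsequent if n_subsequent else np.nan
                ),
                "pct_remaining": (
                    100.0 - 100.0 * n_current / n_subsequent if n_subsequent else np.nan
                ),
            }
        )
    return pd.DataFrame(rows).set_index("group") if rows else pd.DataFrame()


def gap_statistics(groups: Mapping[str, set], pairs: pd.DataFrame) -> pd.DataFrame:
    """Mean and sample SD of index-minus-prior gap (days) per group.

    Patients without a prior value are skipped; SD is NaN for n < 2.
    """
    gaps_all = (
        pd.to_datetime(pairs["index_date"]) - pd.to_datetime(pairs["prior_date"])
    ).dt.days
    rows = []
    for name, members in groups.items():
        gaps = gaps_all[gaps_all.index.isin(set(members))].dropna()
        rows.append(
            {
                "group": name,
                "n_with_pair": int(gaps.shape[0]),
                "mean_gap_days": float(gaps.mean()) if len(gaps) else np.nan,
                "sd_gap_days": float(gaps.std(ddof=1)) if len(gaps) >= 2 else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("group")


def cumulative_high_intermediate(
    registry: Registry,
    adv_ckd_code_set: CodeSet,
    dialysis_code_set: CodeSet,
    aki_code_set: CodeSet,
    *,
    months: int = 6,
    snapshot_interval_days: int = 30,
    lookback_days: int = 365,
    min_gap_days: int = 90,
) -> tuple[set, int]:
    """Cumulative advanced-CKD membership over monthly re-extractions.

    Re-runs the cohort build and tier assignment at monthly snapshot dates
    after the baseline reference date and returns the union of patients ever
    classified high- or intermediate-risk, together with the fixed baseline
    creatinine-tested denominator.
    """
    from .cohort import build_source_cohort, creatinine_tested_users
    from .classify import Tier, assign_tiers

    denominator = len(creatinine_tested_users(registry, lookback_days=lookback_days))
    ever: set = set()
    for k in range(months + 1):
        snap_ref = (
            pd.Timestamp(registry.reference_date)
            + pd.Timedelta(days=k * snapshot_interval_days)
        ).date()
        snap = Registry(
            registry.patients, registry.labs, registry.diagnoses,
            registry.procedures, snap_ref, registry.ground_truth,
        )
        flow = build_source_cohort(
            snap, adv_ckd_code_set, dialysis_code_set,
            lookback_days=lookback_days, min_gap_days=min_gap_days,
        )
        tiers = assign_tiers(flow, snap, aki_code_set)
        hi = tiers.loc[
            tiers["tier"].isin([Tier.HIGH.value, Tier.INTERMEDIATE.value]), "patient_id"
        ]
        ever |= set(hi)
    return ever, denominator
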