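"""Seeded four-table synthetic EHR generator with known ground truth.

The generator emulates the statistical structure the advanced-CKD phenotype
relies on: a population of enrollees, a creatinine-tested subset, and a
mixture of ground-truth groups (high / intermediate / low risk, non-CKD,
dialysis).  Each patient gets a true eGFR trajectory — stage-defining index
and >=90-day-prior values, flat history before, linear drift after — from
which serum creatinine is derived by algebraic inversion of the MDRD
equation and perturbed with multiplicative lognormal noise.  Diagnosis and
procedure codes follow a simple coding model: code-defined groups (low risk,
intermediate subgroup 2) carry advanced-CKD codes, eGFR-defined groups carry
them with a configurable sensitivity, non-CKD patients with a small
false-positive rate; dialysis patients are flagged by dialysis codes unless
"miscoded" (the contamination a chart review would catch).

Everything is reproducible from the seed; ``truth_table`` exposes the
per-patient ground truth for scoring phenotypes against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import (
    DIAGNOSIS_COLUMNS,
    LAB_COLUMNS,
    PATIENT_COLUMNS,
    PROCEDURE_COLUMNS,
    Registry,
)
from .egfr import invert_mdrd

__all__ = ["GeneratorConfig", "generate_registry", "truth_table"]

GROUPS = ("high", "intermediate", "low", "non_ckd", "dialysis")
_DAYS_PER_MONTH = 30.4375


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic registry; defaults emulate a regional VA-scale
    system scaled down (advanced CKD ~1.5% of creatinine-tested users).

    Group weights are fractions of all enrollees; ``non_ckd`` takes the
    remainder.  Baseline eGFR means/SDs for the three risk tiers follow the
    demographic profile of a real advanced-CKD cohort (high 20.3+-6.6,
    intermediate 27.4+-5.6, low 42.1+-16.6 ml/min/1.73 m^2).
    """

    n_patients: int = 20_000
    reference_date: date = date(2021, 4, 1)
    lookback_days: int = 365
    horizon_days: int = 180
    seed: int = 0

    # mixture (fractions of all enrollees; non-CKD gets the remainder)
    w_high: float = 0.0069
    w_intermediate: float = 0.0036
    w_low: float = 0.0024
    w_dialysis: float = 0.0030

    frac_tested: float = 0.69  # creatinine-tested fraction of non-CKD enrollees
    prior_available_prob: float = 0.98  # advanced patients with a usable prior eGFR
    subgroup2_frac: float = 0.08  # intermediate patients with the rising pattern

    # baseline true eGFR (mean, sd); tier groups truncated to their defining range
    egfr_high: tuple[float, float] = (20.3, 6.6)
    egfr_intermediate: tuple[float, float] = (27.4, 5.6)
    egfr_intermediate_prior: tuple[float, float] = (45.0, 10.0)
    egfr_subgroup2_index: tuple[float, float] = (40.0, 8.0)
    egfr_subgroup2_prior: tuple[float, float] = (24.0, 4.0)
    egfr_low: tuple[float, float] = (42.1, 16.6)
    egfr_non_ckd: tuple[float, float] = (78.0, 18.0)
    egfr_dialysis: tuple[float, float] = (8.0, 3.0)

    # measurement model
    creatinine_noise_sd: float = 0.12  # lognormal sigma on creatinine (CV ~12%)
    extra_labs_rate: float = 1.0  # mean count of additional pre-index labs
    index_window_days_advanced: int = 45
    index_window_days_non_ckd: int = 364
    gap_days_range: tuple[int, int] = (95, 300)

    # follow-up measurement coverage and true monthly eGFR drift after index
    followup_prob: dict = field(
        default_factory=lambda: {
            "high": 0.59, "intermediate": 0.50, "low": 0.57,
            "non_ckd": 0.50, "dialysis": 0.60,
        }
    )
    extra_followup_rate: float = 0.8
    drift_per_month: dict = field(
        default_factory=lambda: {
            "high": -0.2, "intermediate": -0.2, "low": 0.0,
            "non_ckd": 0.0, "dialysis": -0.3,
        }
    )

    # AKI episodes (N17-coded creatinine dips shortly before the index eGFR)
    aki_rate: float = 0.03
    non_ckd_aki_rate: float = 0.01
    aki_dip_factor: float = 0.55

    # coding model
    coding_sensitivity: float = 0.55  # eGFR-defined groups (high, subgroup 1)
    coding_sensitivity_code_defined: float = 1.0  # code-defined groups (low, subgroup 2)
    coding_fp_rate: float = 0.0003  # advanced-CKD codes among non-CKD patients
    dialysis_miscoded_frac: float = 0.5  # dialysis patients lacking dialysis codes
    undotted_code_frac: float = 0.2  # ICD-10 codes recorded without the dot

    # demographics
    age_mean: float = 75.3
    age_sd: float = 11.1
    age_bounds: tuple[float, float] = (20.0, 105.0)
    male_frac: float = 0.958
    black_frac: float = 0.219
    white_frac: float = 0.678

    def weights(self) -> dict[str, float]:
        w = {
            "high": self.w_high,
            "intermediate": self.w_intermediate,
            "low": self.w_low,
            "dialysis": self.w_dialysis,
        }
        rest = 1.0 - sum(w.values())
        if rest < -1e-12:
            raise ValueError("group weights exceed 1")
        w["non_ckd"] = max(rest, 0.0)
        return w

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        self.weights()
        for name in ("frac_tested", "prior_available_prob", "subgroup2_frac",
                     "coding_sensitivity", "coding_sensitivity_code_defined",
                     "coding_fp_rate", "dialysis_miscoded_frac", "aki_rate",
                     "non_ckd_aki_rate", "undotted_code_frac", "male_frac",
                     "black_frac", "white_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("creatinine_noise_sd", "extra_labs_rate", "extra_followup_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for pair in ("egfr_high", "egfr_intermediate", "egfr_low", "egfr_non_ckd",
                     "egfr_dialysis", "egfr_intermediate_prior",
                     "egfr_subgroup2_index", "egfr_subgroup2_prior"):
            mean, sd = getattr(self, pair)
            if mean <= 0 or sd < 0:
                raise ValueError(f"{pair} needs positive mean and non-negative sd")
        if self.black_frac + self.white_frac > 1.0:
            raise ValueError("race fractions exceed 1")


def _tnorm(rng, mean, sd, lo, hi, size):
    if sd == 0:
        return np.full(size, float(np.clip(mean, lo, hi)))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _icd_dialect(code: str, rng, undotted_frac: float) -> str:
    return code.replace(".", "") if rng.random() < undotted_frac else code


def generate_registry(config: GeneratorConfig, seed: Optional[int] = None) -> Registry:
    """Build a synthetic registry (with ground truth attached) from the config.

    ``seed`` overrides ``config.seed``.  The output is fully deterministic
    given (config, seed); :func:`truth_table` returns the per-patient truth.
    """
    config.validate()
    if seed is not None:
        config = replace(config, seed=int(seed))
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    ref = pd.Timestamp(config.reference_date)
    weights = config.weights()

    group = rng.choice(GROUPS, size=n, p=[weights[g] for g in GROUPS])
    age = _tnorm(rng, config.age_mean, config.age_sd, *config.age_bounds, size=n)
    male = rng.random(n) < config.male_frac
    race_u = rng.random(n)
    race = np.where(
        race_u < config.black_frac,
        "black",
        np.where(race_u < config.black_frac + config.white_frac, "white", "other"),
    )
    birth_offset_days = np.round(age * 365.25).astype(int)

    # --- per-group true stage-defining values (vectorized draws) -----------
    idx_true = np.empty(n)
    pri_true = np.empty(n)
    sub2 = np.zeros(n, dtype=bool)
    for g, (im, isd), (pm, psd), bounds_i, bounds_p in (
        ("high", config.egfr_high, config.egfr_high, (5.0, 29.9), (5.0, 29.9)),
        ("low", config.egfr_low, config.egfr_low, (30.1, 120.0), (30.1, 120.0)),
        ("non_ckd", config.egfr_non_ckd, config.egfr_non_ckd, (33.0, 140.0), (33.0, 140.0)),
        ("dialysis", config.egfr_dialysis, config.egfr_dialysis, (3.0, 14.9), (3.0, 14.9)),
    ):
        m = group == g
        if m.any():
            idx_true[m] = _tnorm(rng, im, isd, *bounds_i, size=int(m.sum()))
            if g == "non_ckd":
                pri_true[m] = idx_true[m]  # stable kidney function
            else:
                pri_true[m] = _tnorm(rng, pm, psd, *bounds_p, size=int(m.sum()))
    m = group == "intermediate"
    if m.any():
        k = int(m.sum())
        is2 = rng.random(k) < config.subgroup2_frac
        i1 = _tnorm(rng, *config.egfr_intermediate, 8.0, 29.9, size=k)
        p1 = _tnorm(rng, *config.egfr_intermediate_prior, 30.1, 59.9, size=k)
        i2 = _tnorm(rng, *config.egfr_subgroup2_index, 30.1, 59.9, size=k)
        p2 = _tnorm(rng, *config.egfr_subgroup2_prior, 8.0, 29.9, size=k)
        idx_true[m] = np.where(is2, i2, i1)
        pri_true[m] = np.where(is2, p2, p1)
        sub2[m] = is2

    tested = np.ones(n, dtype=bool)
    m = group == "non_ckd"
    tested[m] = rng.random(int(m.sum())) < config.frac_tested

    lookback_start = ref - pd.Timedelta(days=config.lookback_days - 1)

    patients_rows: list[dict] = []
    lab_parts: list[tuple] = []  # (patient_idx, date, true_egfr)
    dx_rows: list[dict] = []
    px_rows: list[dict] = []
    truth_rows: list[dict] = []

    for i in range(n):
        pid = f"P{i:06d}"
        g = group[i]
        drift = config.drift_per_month[g]
        birth = (ref - pd.Timedelta(days=int(birth_offset_days[i]))).date()
        patients_rows.append(
            {
                "patient_id": pid,
                "birth_date": pd.Timestamp(birth),
                "age_years": np.nan,
                "sex": "male" if male[i] else "female",
                "race": race[i],
                "enrolled": True,
            }
        )

        index_date = prior_date = None
        has_prior = False
        aki = False
        if tested[i]:
            if g == "non_ckd":
                offset = int(rng.integers(0, config.index_window_days_non_ckd + 1))
            else:
                offset = int(rng.integers(0, config.index_window_days_advanced + 1))
            index_date = ref - pd.Timedelta(days=offset)
            lab_parts.append((i, index_date, idx_true[i]))

            if g != "non_ckd":
                has_prior = rng.random() < config.prior_available_prob
                if has_prior:
                    gap = int(rng.integers(config.gap_days_range[0],
                                           config.gap_days_range[1] + 1))
                    prior_date = index_date - pd.Timedelta(days=gap)
                    lab_parts.append((i, prior_date, pri_true[i]))
                    # older history: flat at the prior value, before the prior lab
                    n_extra = int(rng.poisson(config.extra_labs_rate))
                    span = (prior_date - lookback_start).days
                    for _ in range(min(n_extra, max(span, 0))):
                        d = prior_date - pd.Timedelta(days=int(rng.integers(1, span + 1)))
                        lab_parts.append((i, d, pri_true[i]))
            else:
                n_extra = int(rng.poisson(config.extra_labs_rate))
                span = (index_date - lookback_start).days
                for _ in range(min(n_extra, max(span, 0))):
                    d = index_date - pd.Timedelta(days=int(rng.integers(1, span + 1)))
                    lab_parts.append((i, d, idx_true[i]))

            # AKI episode: N17 code + transient dip inside the 90 days pre-index
            aki_p = (
                config.aki_rate
                if (g == "intermediate" and not sub2[i])
                else config.non_ckd_aki_rate if g == "non_ckd" else 0.0
            )
            if rng.random() < aki_p:
                aki = True
                dip_date = index_date - pd.Timedelta(days=int(rng.integers(1, 90)))
                if dip_date >= lookback_start:
                    lab_parts.append(
                        (i, dip_date, max(idx_true[i] * config.aki_dip_factor, 2.0))
                    )
                    dx_rows.append(
                        {
                            "patient_id": pid,
                            "event_date": dip_date,
                            "code": _icd_dialect("N17.9", rng, config.undotted_code_frac),
                        }
                    )

            # follow-up labs after the reference date
            if rng.random() < config.followup_prob[g]:
                n_fu = 1 + int(rng.poisson(config.extra_followup_rate))
                days = np.unique(rng.integers(1, config.horizon_days + 1, size=n_fu))
                for d_off in days:
                    d = ref + pd.Timedelta(days=int(d_off))
                    months = (d - index_date).days / _DAYS_PER_MONTH
                    lab_parts.append((i, d, max(idx_true[i] + drift * months, 2.0)))

        # ---- coding model -------------------------------------------------
        has_code = False
        if g in ("high",) or (g == "intermediate" and not sub2[i]):
            has_code = rng.random() < config.coding_sensitivity
        elif g == "low" or (g == "intermediate" and sub2[i]):
            has_code = rng.random() < config.coding_sensitivity_code_defined
        elif g == "dialysis":
            has_code = rng.random() < config.coding_sensitivity
        else:
            has_code = rng.random() < config.coding_fp_rate
        if has_code:
            code = "N18.5" if idx_true[i] < 15 else "N18.4"
            anchor = index_date if index_date is not None else ref
            d = anchor - pd.Timedelta(days=int(rng.integers(0, 300)))
            if d < lookback_start:
                d = lookback_start
            dx_rows.append(
                {
                    "patient_id": pid,
                    "event_date": d,
                    "code": _icd_dialect(code, rng, config.undotted_code_frac),
                }
            )

        miscoded = False
        dialysis_coded = False
        if g == "dialysis":
            miscoded = rng.random() < config.dialysis_miscoded_frac
            dialysis_coded = not miscoded
            if dialysis_coded and index_date is not None:
                d = index_date - pd.Timedelta(days=int(rng.integers(0, 200)))
                if d < lookback_start:
                    d = lookback_start
                dx_rows.append(
                    {
                        "patient_id": pid,
                        "event_date": d,
                        "code": _icd_dialect("Z99.2", rng, config.undotted_code_frac),
                    }
                )
                px_rows.append({"patient_id": pid, "event_date": d, "code": "90937"})

        truth_rows.append(
            {
                "patient_id": pid,
                "group": g,
                "true_tier": g if g in ("high", "intermediate", "low") else "none",
                "subgroup": (2 if sub2[i] else 1) if g == "intermediate" else np.nan,
                "tested": bool(tested[i]),
                "dialysis": g == "dialysis",
                "dialysis_coded": dialysis_coded,
                "miscoded_dialysis": miscoded,
                "aki_in_90d": aki,
                "has_adv_code": has_code,
                "true_index_egfr": idx_true[i] if tested[i] else np.nan,
                "true_prior_egfr": (
                    pri_true[i] if (tested[i] and (has_prior or g == "non_ckd")) else np.nan
                ),
                "index_date": index_date if index_date is not None else pd.NaT,
                "prior_date": prior_date if prior_date is not None else pd.NaT,
            }
        )

    # ---- creatinine from true eGFR, vectorized over all labs --------------
    if lab_parts:
        pat_idx = np.array([p[0] for p in lab_parts])
        dates = pd.DatetimeIndex([p[1] for p in lab_parts])
        true_g = np.array([p[2] for p in lab_parts])
        births = pd.DatetimeIndex(
            [patients_rows[j]["birth_date"] for j in pat_idx]
        )
        lab_age = (dates - births).days / 365.25
        scr_true = invert_mdrd(
            true_g,
            lab_age,
            np.where(male[pat_idx], "male", "female"),
            race[pat_idx] == "black",
        )
        noise = np.exp(config.creatinine_noise_sd * rng.standard_normal(len(lab_parts)))
        labs = pd.DataFrame(
            {
                "patient_id": [f"P{j:06d}" for j in pat_idx],
                "collection_date": dates,
                "creatinine_mg_dl": scr_true * noise,
                "egfr": np.nan,
            },
            columns=LAB_COLUMNS,
        )
    else:
        labs = pd.DataFrame(columns=LAB_COLUMNS)

    registry = Registry(
        patients=pd.DataFrame(patients_rows, columns=PATIENT_COLUMNS),
        labs=labs,
        diagnoses=pd.DataFrame(dx_rows, columns=DIAGNOSIS_COLUMNS),
        procedures=pd.DataFrame(px_rows, columns=PROCEDURE_COLUMNS),
        reference_date=config.reference_date,
        ground_truth=pd.DataFrame(truth_rows),
    )
    return registry


def truth_table(registry: Registry) -> pd.DataFrame:
    """Per-patient ground truth of a generated registry (tier, dialysis, AKI)."""
    if registry.ground_truth is None:
        raise ValueError("registry carries no ground truth (not produced by the generator)")
    return registry.ground_truth.copy()
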