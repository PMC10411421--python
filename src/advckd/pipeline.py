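"""End-to-end orchestration: registry -> cohort -> tiers -> reports.

``run_pipeline`` ties the stages together deterministically and returns (and
optionally writes) a report bundle: cohort-flow counts, the per-patient
assignment table, prevalence / diagnostic-accuracy / stability report tables,
and a machine-readable run manifest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .classify import PHENOTYPES, Tier, apply_phenotype, assign_tiers
from .codes import CodeSet, default_code_sets, load_code_sets, match_codes
from .cohort import build_source_cohort
from .datamodel import Registry
from .egfr import add_egfr, lookback_start, select_egfr_pairs
from .followup import followup_stats, gap_statistics
from .io import RegistryPaths, read_registry
from .metrics import accuracy_stats, confusion, prevalence

log = logging.getLogger("advckd")

__all__ = ["RunConfig", "run_pipeline", "resolve_code_sets"]


@dataclass
class RunConfig:
    """Everything a reproducible extraction run needs."""

    registry_dir: Optional[Path] = None
    reference_date: Optional[date] = None
    code_set_file: Optional[Path] = None
    phenotype: str = "tiered"
    egfr_low: float = 30.0
    egfr_high: float = 60.0
    min_gap_days: int = 90
    lookback_days: int = 365
    horizon_days: int = 180
    cohort_egfr_inclusive: bool = True  # cohort arm <=30; tiers always compare <30
    ci_method: str = "wilson"
    out_dir: Optional[Path] = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("egfr_low", "egfr_high", "min_gap_days", "lookback_days",
                     "horizon_days"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.lookback_days < self.min_gap_days:
            raise ValueError("lookback_days must be >= min_gap_days")
        if self.phenotype not in PHENOTYPES:
            raise ValueError(f"unknown phenotype {self.phenotype!r}")


def resolve_code_sets(code_set_file: Optional[Path]) -> dict[str, CodeSet]:
    sets = default_code_sets()
    if code_set_file is not None:
        path = Path(code_set_file)
        if not path.exists():
            raise FileNotFoundError(f"code-set file not found: {path}")
        sets.update(load_code_sets(path))
    for required in ("advanced_ckd", "aki", "dialysis"):
        if required not in sets:
            raise ValueError(f"code-set config must define {required!r}")
    return sets


def run_pipeline(
    config: RunConfig,
    registry: Optional[Registry] = None,
) -> dict:
    """Run extraction, classification, metrics and follow-up in one pass.

    Pass either an in-memory ``registry`` or ``config.registry_dir``.
    Returns a bundle dict with keys: flow, evidence, assignments, pairs,
    phenotype_labels, prevalence, accuracy, stability, gap_stats, manifest.
    When ``config.out_dir`` is set the tables are also written as CSV plus a
    ``manifest.json``.
    """
    if registry is None:
        if config.registry_dir is None:
            raise ValueError("either a registry or config.registry_dir is required")
        registry = read_registry(
            RegistryPaths.in_dir(config.registry_dir), config.reference_date
        )
    sets = resolve_code_sets(config.code_set_file)

    log.info("stage egfr: computing MDRD eGFR for %d labs", len(registry.labs))
    registry = add_egfr(registry)
    pairs = select_egfr_pairs(
        registry.labs, registry.reference_date,
        lookback_days=config.lookback_days, min_gap_days=config.min_gap_days,
    )

    flow = build_source_cohort(
        registry, sets["advanced_ckd"], sets["dialysis"],
        lookback_days=config.lookback_days, min_gap_days=config.min_gap_days,
        egfr_threshold=config.egfr_low, egfr_inclusive=config.cohort_egfr_inclusive,
    )
    log.info("stage cohort: %s", flow.counts())

    assignments = assign_tiers(
        flow, registry, sets["aki"],
        aki_window_days=config.min_gap_days,
        low_threshold=config.egfr_low, high_threshold=config.egfr_high,
    )

    # comparator phenotypes over everyone with an index eGFR
    ref = registry.reference_date
    window = (
        lookback_start(ref, config.lookback_days).date(),
        pd.Timestamp(ref).date(),
    )
    coded = match_codes(
        registry.diagnoses.assign(system="ICD10"), sets["advanced_ckd"], window
    )
    tested_pairs = pairs[pairs.index.isin(flow.tested_ids)]
    labels = pd.DataFrame(index=tested_pairs.index)
    for ph in PHENOTYPES:
        labels[ph] = apply_phenotype(
            tested_pairs, coded, ph,
            low_threshold=config.egfr_low, high_threshold=config.egfr_high,
        )

    # prevalence over the creatinine-tested denominator
    tiers = assignments.set_index("patient_id")["tier"]
    high_ids = set(tiers.index[tiers == Tier.HIGH.value])
    int_ids = set(tiers.index[tiers == Tier.INTERMEDIATE.value])
    low_ids = set(tiers.index[tiers == Tier.LOW.value])
    den = flow.n_with_creatinine
    prev_rows = []
    positives = {
        "icd_coded": coded & flow.tested_ids,
        "single_egfr_lt30": set(labels.index[labels["single_egfr"].fillna(False)]),
        "two_egfr": set(labels.index[labels["two_egfr"].fillna(False)]),
        "high_risk": high_ids,
        "high_intermediate_risk": high_ids | int_ids,
    }
    for name, ids in positives.items():
        est = prevalence(len(ids), den, ci_method=config.ci_method) if den else None
        prev_rows.append(
            {
                "definition": name,
                "n": len(ids),
                "denominator": den,
                "percent": est.percent if est else float("nan"),
                "ci_low": est.ci_low if est else float("nan"),
                "ci_high": est.ci_high if est else float("nan"),
                "display": est.display() if est else "",
            }
        )
    prevalence_table = pd.DataFrame(prev_rows)

    # diagnostic accuracy of ICD codes vs eGFR-based reference standards
    universe = set(tested_pairs.index)
    pred = coded & universe
    references = {
        "single_egfr_lt30": positives["single_egfr_lt30"],
        "two_egfr": positives["two_egfr"],
        "high_risk": high_ids & universe,
        "high_intermediate_risk": (high_ids | int_ids) & universe,
    }
    acc_rows = []
    for name, ref_pos in references.items():
        table = confusion(pred, ref_pos, universe)
        stats_ = accuracy_stats(table, ci_method=config.ci_method)
        row = {"reference": name, "tp": table.tp, "fp": table.fp,
               "fn": table.fn, "tn": table.tn}
        for metric, est in stats_.items():
            row[metric] = est.proportion if est else float("nan")
        acc_rows.append(row)
    accuracy_table = pd.DataFrame(acc_rows)

    # 6-month stability per phenotype group and per tier
    groups = {
        "source_cohort": flow.source_ids,
        "icd_coded": pred & flow.source_ids,
        "single_egfr_lt30": positives["single_egfr_lt30"] & flow.source_ids,
        "two_egfr": positives["two_egfr"] & flow.source_ids,
        "high": high_ids,
        "intermediate": int_ids,
        "low": low_ids,
    }
    groups = {k: v for k, v in groups.items() if v}
    stability = followup_stats(
        groups, registry, pairs,
        horizon_days=config.horizon_days, threshold=config.egfr_low,
    )
    gaps = gap_statistics(groups, pairs)

    manifest = {
        "advckd_version": __version__,
        "reference_date": str(pd.Timestamp(registry.reference_date).date()),
        "seed": config.seed,
        "phenotype": config.phenotype,
        "thresholds": {
            "egfr_low": config.egfr_low,
            "egfr_high": config.egfr_high,
            "min_gap_days": config.min_gap_days,
            "lookback_days": config.lookback_days,
            "horizon_days": config.horizon_days,
            "cohort_egfr_inclusive": config.cohort_egfr_inclusive,
        },
        "ci_method": config.ci_method,
        "flow": flow.counts(),
    }

    bundle = {
        "flow": flow,
        "evidence": flow.evidence,
        "assignments": assignments,
        "pairs": pairs,
        "phenotype_labels": labels,
        "prevalence": prevalence_table,
        "accuracy": accuracy_table,
        "stability": stability,
        "gap_stats": gaps,
        "manifest": manifest,
    }
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame([flow.counts()]).to_csv(out / "cohort_flow.csv", index=False)
        flow.evidence.to_csv(out / "cohort_evidence.csv", index=False)
        assignments.to_csv(out / "assignments.csv", index=False)
        labels.to_csv(out / "phenotype_labels.csv")
        prevalence_table.to_csv(out / "prevalence.csv", index=False)
        accuracy_table.to_csv(out / "accuracy.csv", index=False)
        stability.to_csv(out / "stability.csv")
        gaps.to_csv(out / "gap_stats.csv")
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    return bundle
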