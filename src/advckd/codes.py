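"""ICD-10 / CPT code sets and dated code matching.

ICD-10 codes are stored and compared dot-normalized ("N18.4" and "N184" are the
same code) and matched by *prefix*, so a category-level entry such as "N17"
matches every N17.x subcode.  CPT codes are five-character procedure codes and
are matched exactly; a range entry "90935-90999" in a config file expands to
every numeric code in the closed range.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from importlib import resources

import pandas as pd
import yaml

__all__ = [
    "CodeSet",
    "normalize_icd10",
    "match_codes",
    "load_code_sets",
    "default_code_sets",
]


def normalize_icd10(code: str) -> str:
    """Uppercase an ICD-10 code and strip the optional dot."""
    return code.strip().upper().replace(".", "")


def _expand_cpt(entry: str) -> list[str]:
    entry = entry.strip()
    if "-" in entry:
        lo, hi = entry.split("-", 1)
        return [str(c) for c in range(int(lo), int(hi) + 1)]
    return [entry]


@dataclass(frozen=True)
class CodeSet:
    """A named bundle of ICD-10 prefixes (dot-normalized) and exact CPT codes."""

    name: str
    icd10_codes: frozenset[str] = field(default_factory=frozenset)
    cpt_codes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "icd10_codes", frozenset(normalize_icd10(c) for c in self.icd10_codes)
        )
        object.__setattr__(
            self, "cpt_codes", frozenset(str(c).strip() for c in self.cpt_codes)
        )
        if not self.icd10_codes and not self.cpt_codes:
            raise ValueError(f"code set {self.name!r} is empty")

    def matches_icd10(self, code: str) -> bool:
        norm = normalize_icd10(code)
        return any(norm.startswith(prefix) for prefix in self.icd10_codes)

    def matches_cpt(self, code: str) -> bool:
        return str(code).strip() in self.cpt_codes

    def matches(self, system: str, code: str) -> bool:
        if system == "ICD10":
            return self.matches_icd10(code)
        if system == "CPT":
            return self.matches_cpt(code)
        raise ValueError(f"unknown coding system {system!r}")


def match_codes(
    events: pd.DataFrame,
    code_set: CodeSet,
    window: tuple[date, date],
) -> set[str]:
    """Patient ids with >=1 matching event inside the closed date window.

    ``events`` needs columns patient_id, event_date, system ("ICD10"/"CPT")
    and code.  Matching is prefix-based for ICD-10 (after dot normalization)
    and exact for CPT.
    """
    start, end = window
    if start > end:
        raise ValueError("window start must be <= end")
    if events.empty:
        return set()
    dates = pd.to_datetime(events["event_date"])
    in_window = (dates >= pd.Timestamp(start)) & (dates <= pd.Timestamp(end))
    sub = events.loc[in_window]
    if sub.empty:
        return set()
    hit = pd.Series(False, index=sub.index)
    icd = sub["system"] == "ICD10"
    if icd.any() and code_set.icd10_codes:
        norm = sub.loc[icd, "code"].map(normalize_icd10)
        hit.loc[icd] = norm.str.startswith(tuple(code_set.icd10_codes))
    cpt = sub["system"] == "CPT"
    if cpt.any() and code_set.cpt_codes:
        hit.loc[cpt] = sub.loc[cpt, "code"].astype(str).str.strip().isin(code_set.cpt_codes)
    return set(sub.loc[hit, "patient_id"])


def _sets_from_mapping(raw: dict) -> dict[str, CodeSet]:
    out: dict[str, CodeSet] = {}
    for name, spec in raw.items():
        icd = [str(c) for c in spec.get("icd10", [])]
        cpt = [c for entry in spec.get("cpt", []) for c in _expand_cpt(str(entry))]
        if len(set(icd)) != len(icd) or len(set(cpt)) != len(cpt):
            raise ValueError(f"duplicate codes in code set {name!r}")
        out[name] = CodeSet(name=name, icd10_codes=frozenset(icd), cpt_codes=frozenset(cpt))
    return out


def load_code_sets(path) -> dict[str, CodeSet]:
    """Load named code sets from a YAML file: name -> {icd10: [...], cpt: [...]}."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"code-set file {path} must map names to code lists")
    return _sets_from_mapping(raw)


def default_code_sets() -> dict[str, CodeSet]:
    """The packaged defaults: advanced_ckd (N18.4/N18.5), aki (N17), dialysis.

    The dialysis list is a configurable stand-in (see data/default_codesets.yaml);
    deployments should override it with their institution's dialysis/ESKD list.
    """
    ref = resources.files("advckd").joinpath("data/default_codesets.yaml")
    with ref.open() as fh:
        raw = yaml.safe_load(fh)
    return _sets_from_mapping(raw)
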