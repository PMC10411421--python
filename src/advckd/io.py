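"""Reading and writing the four-table delimited extract.

Files are plain comma- or tab-separated text with a header row; the delimiter
is auto-detected unless given. Column names can be remapped through a simple
key-value schema config (YAML: table -> {canonical_name: source_name}).
A sidecar ``registry.yaml`` written next to the tables records the reference
date so a written registry reads back identically.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from datetime import date
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd
import yaml

from .datamodel import (
    DIAGNOSIS_COLUMNS,
    LAB_COLUMNS,
    PATIENT_COLUMNS,
    PROCEDURE_COLUMNS,
    Registry,
    RegistryValidationError,
)

__all__ = ["RegistryPaths", "read_registry", "write_registry", "SchemaError"]

_TABLES = {
    "patients": PATIENT_COLUMNS,
    "labs": LAB_COLUMNS,
    "diagnoses": DIAGNOSIS_COLUMNS,
    "procedures": PROCEDURE_COLUMNS,
}
_DATE_COLUMNS = {"birth_date", "collection_date", "event_date"}
# columns a file may omit entirely (filled with defaults on read)
_OPTIONAL = {"patients": {"birth_date", "age_years", "enrolled"}, "labs": {"egfr"}}


class SchemaError(ValueError):
    """A required column is missing from an input table."""


@dataclass(frozen=True)
class RegistryPaths:
    patients: Path
    labs: Path
    diagnoses: Path
    procedures: Path

    @classmethod
    def in_dir(cls, directory, suffix: str = ".csv") -> "RegistryPaths":
        d = Path(directory)
        return cls(*(d / f"{t}{suffix}" for t in _TABLES))

    def items(self):
        return {
            "patients": self.patients,
            "labs": self.labs,
            "diagnoses": self.diagnoses,
            "procedures": self.procedures,
        }.items()

    @property
    def manifest(self) -> Path:
        return Path(self.patients).parent / "registry.yaml"


def _sniff_sep(path: Path) -> str:
    with open(path, newline="") as fh:
        sample = fh.readline()
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t;").delimiter
    except csv.Error:
        return ","


def _read_table(
    path: Path,
    table: str,
    sep: Optional[str],
    column_map: Optional[Mapping[str, str]],
) -> pd.DataFrame:
    if not Path(path).exists():
        raise FileNotFoundError(f"{table} table not found: {path}")
    use_sep = sep or _sniff_sep(Path(path))
    df = pd.read_csv(path, sep=use_sep, dtype=str, keep_default_na=False)
    if column_map:
        df = df.rename(columns={src: canon for canon, src in column_map.items()})
    want = _TABLES[table]
    optional = _OPTIONAL.get(table, set())
    missing = [c for c in want if c not in df.columns and c not in optional]
    if missing:
        raise SchemaError(f"{table} table {path} is missing column(s): {', '.join(missing)}")
    for c in want:
        if c not in df.columns:
            df[c] = ""
    df = df[want].copy()
    # typed conversion with row-level error reporting
    errors: list[str] = []
    for c in df.columns:
        raw = df[c].replace("", None)
        if c in _DATE_COLUMNS:
            parsed = pd.to_datetime(raw, errors="coerce", format="mixed")
            bad = raw.notna() & parsed.isna()
            for i in df.index[bad]:
                errors.append(f"{table} line {i + 2}: unparseable date {df.loc[i, c]!r} in {c}")
            df[c] = parsed
        elif c in ("creatinine_mg_dl", "egfr", "age_years"):
            parsed = pd.to_numeric(raw, errors="coerce")
            bad = raw.notna() & parsed.isna()
            for i in df.index[bad]:
                errors.append(f"{table} line {i + 2}: non-numeric {df.loc[i, c]!r} in {c}")
            df[c] = parsed.astype(float)
        elif c == "enrolled":
            df[c] = raw.map(
                lambda v: True if v is None else str(v).strip().lower() in ("true", "1", "yes")
            )
    if errors:
        raise SchemaError("; ".join(errors))
    return df


def read_registry(
    paths: RegistryPaths,
    reference_date: Optional[date] = None,
    *,
    sep: Optional[str] = None,
    column_maps: Optional[Mapping[str, Mapping[str, str]]] = None,
    validate: bool = True,
    horizon_days: int = 365,
) -> Registry:
    """Load a registry from four delimited files.

    ``reference_date`` may be omitted when a ``registry.yaml`` manifest sits
    next to the patient table (written by :func:`write_registry`).
    Raises :class:`SchemaError` for structural problems and
    :class:`RegistryValidationError` (listing every bad row) for invariant
    violations unless ``validate=False``.
    """
    if reference_date is None:
        manifest = paths.manifest
        if not manifest.exists():
            raise ValueError("reference_date not given and no registry.yaml manifest found")
        with open(manifest) as fh:
            meta = yaml.safe_load(fh)
        reference_date = pd.Timestamp(meta["reference_date"]).date()
        horizon_days = int(meta.get("horizon_days", horizon_days))
    column_maps = column_maps or {}
    frames = {
        table: _read_table(path, table, sep, column_maps.get(table))
        for table, path in paths.items()
    }
    reg = Registry(
        patients=frames["patients"],
        labs=frames["labs"],
        diagnoses=frames["diagnoses"],
        procedures=frames["procedures"],
        reference_date=reference_date,
    )
    if validate:
        errors = reg.validate(horizon_days=horizon_days)
        if errors:
            raise RegistryValidationError(errors)
    return reg


def write_registry(
    registry: Registry,
    paths: RegistryPaths,
    *,
    sep: str = ",",
    horizon_days: int = 365,
) -> None:
    """Write the four tables plus a ``registry.yaml`` manifest (lossless)."""
    for table, path in paths.items():
        df = getattr(registry, table).copy()
        for c in df.columns:
            if c in _DATE_COLUMNS:
                df[c] = pd.to_datetime(df[c]).dt.strftime("%Y-%m-%d")
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        df.to_csv(path, sep=sep, index=False)
    with open(paths.manifest, "w") as fh:
        yaml.safe_dump(
            {
                "reference_date": str(pd.Timestamp(registry.reference_date).date()),
                "horizon_days": horizon_days,
            },
            fh,
        )
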