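"""Tabular I/O: the canonical specimen CSV schema, reports, run config.

One CSV dialect only (RFC 4180, UTF-8, "." decimal).  Concentration
units are encoded in the column names (``n_g_kg`` ... ``fe_mg_kg``) so
macro- and micronutrient scales can never be silently confused.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd
import yaml

from .composition import MACRONUTRIENTS, NUTRIENTS, NutrientProfile
from .specimen import Specimen

__all__ = [
    "SPECIMEN_COLUMNS",
    "SchemaError",
    "RunConfig",
    "read_specimens",
    "specimens_to_frame",
    "write_specimens",
    "write_report",
]

SPECIMEN_COLUMNS: tuple[str, ...] = (
    "specimen_id",
    "clone",
    "soil_type",
    "location",
    "age_yr",
    "dbh_cm",
    "n_g_kg",
    "p_g_kg",
    "k_g_kg",
    "mg_g_kg",
    "ca_g_kg",
    "s_g_kg",
    "b_mg_kg",
    "cu_mg_kg",
    "zn_mg_kg",
    "mn_mg_kg",
    "fe_mg_kg",
)

_CONC_COLS = {
    p: f"{p.lower()}_{'g_kg' if p in MACRONUTRIENTS else 'mg_kg'}" for p in NUTRIENTS
}


class SchemaError(ValueError):
    """Schema violation with row/column-specific messages."""

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        super().__init__("schema violation:\n  " + "\n  ".join(self.problems))


@dataclass(frozen=True)
class RunConfig:
    """Pipeline settings, round-trippable through YAML/JSON."""

    kappa: float = 1000.0
    cutoff_cm: float = 4.3
    quantile_estimator: str = "linear"
    k_neighbors: int = 10
    factor_exact: tuple[str, ...] = ("clone",)
    factor_windows: Mapping[str, float] = field(default_factory=lambda: {"age_yr": 0.1})
    cv_runs: int = 10
    cv_holdout: float = 0.1
    seed: int = 0
    zero_replacement_multiplier: float = 0.65

    def __post_init__(self) -> None:
        if self.kappa <= 0 or self.cutoff_cm <= 0 or self.k_neighbors < 1:
            raise ValueError("config values out of range")
        if not 0 < self.cv_holdout < 1 or self.cv_runs < 1:
            raise ValueError("invalid cross-validation settings")
        if not 0 < self.zero_replacement_multiplier < 1:
            raise ValueError("zero-replacement multiplier must be in (0, 1)")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["factor_exact"] = list(self.factor_exact)
        d["factor_windows"] = dict(self.factor_windows)
        return d

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML is a JSON superset
        if not isinstance(data, dict):
            raise ValueError(f"config {path} is not a mapping")
        if "factor_exact" in data:
            data["factor_exact"] = tuple(data["factor_exact"])
        return cls(**data)


def read_specimens(path: str | Path, kappa: float = 1000.0) -> list[Specimen]:
    """Load specimens from the canonical CSV, collecting row-level errors.

    Raises :class:`SchemaError` naming every offending column and row
    (1-based data row numbers) instead of failing on the first problem.
    """
    df = pd.read_csv(path, dtype={"specimen_id": str, "clone": str,
                                  "soil_type": str, "location": str})
    problems: list[str] = []
    missing = [c for c in SPECIMEN_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError([f"missing columns: {missing}"])
    dup = df["specimen_id"][df["specimen_id"].duplicated()].unique()
    if len(dup):
        problems.append(f"duplicated specimen_id: {sorted(dup)}")
    specimens: list[Specimen] = []
    for i, row in df.iterrows():
        rowno = i + 1
        try:
            values = {}
            for part, col in _CONC_COLS.items():
                v = row[col]
                if pd.isna(v):
                    values[part] = None
                elif float(v) < 0:
                    raise ValueError(f"negative concentration in {col}: {v}")
                else:
                    values[part] = float(v)
            specimens.append(
                Specimen(
                    id=str(row["specimen_id"]),
                    profile=NutrientProfile(values),
                    clone=str(row["clone"]),
                    soil_type=str(row["soil_type"]),
                    location=str(row["location"]),
                    age_yr=float(row["age_yr"]),
                    dbh_cm=float(row["dbh_cm"]),
                    kappa=kappa,
                )
            )
        except (ValueError, KeyError) as exc:
            problems.append(f"row {rowno}: {exc}")
    if problems:
        raise SchemaError(problems)
    return specimens


def specimens_to_frame(specimens: Sequence[Specimen]) -> pd.DataFrame:
    rows = []
    for s in specimens:
        row: dict[str, Any] = {
            "specimen_id": s.id,
            "clone": s.clone,
            "soil_type": s.soil_type,
            "location": s.location,
            "age_yr": s.age_yr,
            "dbh_cm": s.dbh_cm,
        }
        for part, col in _CONC_COLS.items():
            row[col] = s.profile.concentration(part)
        rows.append(row)
    return pd.DataFrame(rows, columns=list(SPECIMEN_COLUMNS))


def write_specimens(specimens: Sequence[Specimen], path: str | Path) -> None:
    specimens_to_frame(specimens).to_csv(path, index=False)


def write_report(report: Any, path: str | Path, format: str | None = None) -> None:
    """Serialize a report deterministically (sorted JSON keys, fixed CSV
    column order) so identical runs produce byte-identical files."""
    path = Path(path)
    fmt = format or ("csv" if path.suffix.lower() == ".csv" else "json")
    try:
        if fmt == "json":
            path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
        elif fmt == "csv":
            df = report if isinstance(report, pd.DataFrame) else pd.DataFrame(report)
            df.to_csv(path, index=False)
        else:
            raise ValueError(f"unknown format {fmt!r}")
    except OSError as exc:
        raise OSError(f"cannot write report to {path}: {exc}") from exc
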