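"""Readers and writers for karyotype files, record CSVs and JSON reports.

Karyotype files are plain text, one race per line::

    # comment
    CHBU<TAB>1.18 2.5 3.6 4.12 7.15 8.16 9.14 10.17 11.13
    CHHN<TAB>1.3 2.8 4.12 5.7 6.15 9.14 10.11 13.16
    ancestral

Record tables are CSV with fixed schemas (below); all counts are absolute
integers internally — display conventions such as sperm ×10³ are applied
only when rendering reports.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .karyotype import Karyotype, KaryotypeError, parse_karyotype


class SchemaError(ValueError):
    """Raised when a record table does not match its schema."""


# column -> (dtype kind, must_be_nonnegative)
MALE_SCHEMA = {
    "male_id": ("str", False),
    "category": ("str", False),
    "parent_pair_id": ("str", False),
    "body_mass": ("float", True),
    "sperm_count": ("float", True),
    "testis_mass": ("float", True),
    "epididymis_mass": ("float", True),
    "sv_cg_mass": ("float", True),
    "preputial_mass": ("float", True),
    "age_days": ("float", True),
}

FEMALE_SCHEMA = {
    "female_id": ("str", False),
    "category": ("str", False),
    "parent_pair_id": ("str", False),
    "first_litter_size": ("float", True),
    "weeks_to_first_litter": ("float", True),
    "total_offspring": ("float", True),
    "scar_count": ("float", True),
}

BREEDING_SCHEMA = {
    "female_id": ("str", False),
    "category": ("str", False),
    "cycle": ("int", True),
    "eggs": ("int", True),
    "fertilized": ("int", True),
    "balanced": ("int", True),
    "trisomic": ("int", True),
    "monosomic": ("int", True),
    "litter_size": ("int", True),
    "scars": ("int", True),
}

TRIAL_SCHEMA = {
    "female_id": ("str", False),
    "female_race": ("str", False),
    "male_pair_id": ("str", False),
    "side_of_CHHN": ("str", False),
    "t_CHHN": ("float", True),
    "t_CHBU": ("float", True),
    "trial_duration": ("float", True),
    "delta_body_mass": ("float", False),
    "delta_age": ("float", False),
    "delta_male_time": ("float", False),
    "pre_epoch_s": ("float", True),
}

SCHEMAS = {
    "males": MALE_SCHEMA,
    "females": FEMALE_SCHEMA,
    "breeding": BREEDING_SCHEMA,
    "trials": TRIAL_SCHEMA,
}


def validate_records(df: pd.DataFrame, schema: str | dict) -> pd.DataFrame:
    """Coerce column types and check value ranges against a schema."""
    if isinstance(schema, str):
        schema = SCHEMAS[schema]
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise SchemaError(f"missing columns: {missing}")
    out = df.copy()
    for col, (kind, nonneg) in schema.items():
        try:
            if kind == "int":
                out[col] = out[col].astype("int64")
            elif kind == "float":
                out[col] = out[col].astype("float64")
            else:
                out[col] = out[col].astype("string").astype(object)
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"column {col!r}: cannot coerce to {kind}: {exc}") from exc
        if nonneg and kind != "str":
            vals = out[col].to_numpy()
            if np.nanmin(vals, initial=0) < 0:
                raise SchemaError(f"column {col!r}: negative values present")
    return out[list(schema)]


def read_records(path: str | Path, schema: str) -> pd.DataFrame:
    return validate_records(pd.read_csv(path), schema)


def write_records(df: pd.DataFrame, path: str | Path, schema: str) -> None:
    validate_records(df, schema).to_csv(path, index=False)


# -- karyotype files ---------------------------------------------------------


def read_karyotype_file(path: str | Path) -> list[Karyotype]:
    """One karyotype per non-comment line: ``NAME<TAB>fusion list``."""
    karyotypes: list[Karyotype] = []
    names: set[str] = set()
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        name, _, fusion_text = line.partition("\t")
        name = name.strip()
        if not name:
            raise KaryotypeError(f"{path}:{lineno}: missing race name")
        if name in names:
            raise KaryotypeError(f"{path}:{lineno}: duplicate race name {name!r}")
        try:
            karyotypes.append(parse_karyotype(fusion_text, name=name))
        except KaryotypeError as exc:
            raise KaryotypeError(f"{path}:{lineno}: {exc}") from exc
        names.add(name)
    return karyotypes


def write_karyotype_file(karyotypes: list[Karyotype], path: str | Path) -> None:
    lines = [f"{k.name}\t{k.format()}".rstrip() for k in karyotypes]
    Path(path).write_text("\n".join(lines) + "\n")


# -- analysis reports --------------------------------------------------------


@dataclass
class AnalysisReport:
    """Structured, JSON-serialisable analysis output.

    Re-running with identical inputs and seeds reproduces the report
    bit-for-bit (no timestamps are embedded).
    """

    metadata: dict = field(default_factory=dict)
    sections: dict = field(default_factory=dict)

    def add(self, name: str, payload) -> None:
        self.sections[name] = _jsonable(payload)

    def to_json(self, path: str | Path | None = None) -> str:
        doc = json.dumps(
            {"metadata": _jsonable(self.metadata), "sections": self.sections},
            indent=2,
            sort_keys=True,
        )
        if path is not None:
            Path(path).write_text(doc + "\n")
        return doc

    @classmethod
    def from_json(cls, path: str | Path) -> "AnalysisReport":
        doc = json.loads(Path(path).read_text())
        return cls(metadata=doc.get("metadata", {}), sections=doc.get("sections", {}))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="records"))
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, float) and (obj != obj):  # NaN -> null
        return None
    if obj is None or isinstance(obj, (str, int, float, bool)):
        return obj
    return str(obj)
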