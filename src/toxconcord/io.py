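"""Delimited-text I/O for the five input tables and the result tables.

All tables are UTF-8, comma-separated, RFC-4180 quoted, with a header
row. Column names can be remapped through a ``schema`` dict (file column
-> canonical column); a JSON sidecar written next to each output records
the map actually used. Writers sort rows by key so output is byte-stable
and diffable.
"""

from __future__ import annotations

import csv
import importlib.resources
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .records import (
    AE_COLUMNS,
    AERecord,
    DrugEntity,
    Modality,
    PKRecord,
    Species,
    TargetAnnotation,
    TargetRelation,
    validate_pt_soc_unique,
)

log = logging.getLogger(__name__)


class SchemaError(ValueError):
    """A required column is missing or the column map is invalid."""


def load_species_aliases(path: Optional[Path] = None) -> dict[str, str]:
    """Load the species alias table (shipped as editable package data)."""
    if path is None:
        ref = importlib.resources.files("toxconcord").joinpath("data/species_aliases.csv")
        text = ref.read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    aliases: dict[str, str] = {}
    for row in csv.DictReader(text.splitlines()):
        aliases[row["alias"].strip().lower()] = row["species"].strip().lower()
    return aliases


def normalize_species(value: str, aliases: Mapping[str, str]) -> Optional[Species]:
    """Map a free-text species string onto the six-value enum, else None."""
    key = str(value).strip().lower()
    if key in aliases:
        return Species(aliases[key])
    try:
        return Species(key)
    except ValueError:
        return None


@dataclass
class RowRejection:
    row_index: int
    reason: str
    row: dict


@dataclass
class AELoadResult:
    """Loaded AE records plus the per-row rejection report."""

    records: pd.DataFrame
    rejected: list[RowRejection] = field(default_factory=list)
    pt_to_soc: dict[str, str] = field(default_factory=dict)


def _remap(frame: pd.DataFrame, schema: Optional[Mapping[str, str]], required: Sequence[str]) -> pd.DataFrame:
    if schema:
        frame = frame.rename(columns=dict(schema))
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    return frame


_TRUTHY = {"true", "1", "yes", "y", "t"}


def _as_bool(v) -> bool:
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    if pd.isna(v):
        return False
    return str(v).strip().lower() in _TRUTHY


def load_ae_records(
    path: str | Path,
    schema: Optional[Mapping[str, str]] = None,
    aliases: Optional[Mapping[str, str]] = None,
) -> AELoadResult:
    """Read an AE table, normalizing species names via the alias table.

    Rows whose species cannot be mapped onto the six-species enum are
    returned in ``rejected`` (never silently dropped). The phase column is
    derived from species and need not be present in the file. A PT
    appearing under two SOCs is a load-time error.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    if raw.empty:
        log.warning("AE table %s is empty", path)
        return AELoadResult(records=pd.DataFrame(columns=AE_COLUMNS))
    required = ["drug_id", "species", "soc", "pt"]
    raw = _remap(raw, schema, required)
    if aliases is None:
        aliases = load_species_aliases()

    rows: list[tuple] = []
    rejected: list[RowRejection] = []
    for i, row in enumerate(raw.to_dict("records")):
        sp = normalize_species(row["species"], aliases)
        if sp is None:
            rejected.append(RowRejection(i, f"unmapped species {row['species']!r}", row))
            continue
        if not str(row["soc"]).strip() or not str(row["pt"]).strip():
            rejected.append(RowRejection(i, "empty soc or pt", row))
            continue
        phase = "clinical" if sp == Species.human else "preclinical"
        rows.append(
            (
                str(row["drug_id"]),
                sp.value,
                phase,
                str(row["soc"]),
                str(row["pt"]),
                _as_bool(row.get("post_marketing", False)),
                _as_bool(row.get("refuted", False)),
                str(row.get("source", "")),
            )
        )
    frame = pd.DataFrame(rows, columns=AE_COLUMNS)
    pt_to_soc = validate_pt_soc_unique(frame) if not frame.empty else {}
    if rejected:
        log.warning("%d row(s) rejected while loading %s", len(rejected), path)
    return AELoadResult(records=frame, rejected=rejected, pt_to_soc=pt_to_soc)


def load_drug_entities(path: str | Path, schema: Optional[Mapping[str, str]] = None) -> list[DrugEntity]:
    raw = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    raw = _remap(raw, schema, ["drug_id", "main_name"])
    out: list[DrugEntity] = []
    seen: set[str] = set()
    for row in raw.to_dict("records"):
        did = str(row["drug_id"])
        if did in seen:
            raise ValueError(f"duplicate drug_id {did!r} in {path}")
        seen.add(did)
        syns = {s.strip() for s in str(row.get("synonyms", "")).split(";") if s.strip()}
        out.append(
            DrugEntity(
                drug_id=did,
                main_name=str(row["main_name"]),
                synonyms=syns,
                cid=str(row["cid"]) if row.get("cid") else None,
                cas=str(row["cas"]) if row.get("cas") else None,
                smiles=str(row["smiles"]) if row.get("smiles") else None,
                modality=Modality(row.get("modality") or "unknown"),
            )
        )
    return out


def load_pk_records(path: str | Path, schema: Optional[Mapping[str, str]] = None) -> list[PKRecord]:
    raw = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    raw = _remap(raw, schema, ["drug_id", "species"])
    aliases = load_species_aliases()
    out: list[PKRecord] = []
    for row in raw.to_dict("records"):
        sp = normalize_species(row["species"], aliases)
        if sp is None:
            raise ValueError(f"unmapped species {row['species']!r} in PK table {path}")
        cmax = float(row["cmax"]) if row.get("cmax") else None
        auc = float(row["auc"]) if row.get("auc") else None
        out.append(PKRecord(drug_id=str(row["drug_id"]), species=sp, cmax=cmax, auc=auc))
    return out


def load_target_annotations(path: str | Path, schema: Optional[Mapping[str, str]] = None) -> list[TargetAnnotation]:
    raw = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    raw = _remap(raw, schema, ["drug_id", "target_symbol", "relation"])
    out = [
        TargetAnnotation(
            drug_id=str(r["drug_id"]),
            target_symbol=str(r["target_symbol"]),
            relation=TargetRelation(r["relation"]),
        )
        for r in raw.to_dict("records")
    ]
    return out


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read annotation sets in GMT format: id <tab> description <tab> members..."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        sets[parts[0]] = {m for m in parts[2:] if m}
    return sets


def write_gmt(sets: Mapping[str, set[str]], path: str | Path, descriptions: Optional[Mapping[str, str]] = None) -> None:
    lines = []
    for set_id in sorted(sets):
        desc = (descriptions or {}).get(set_id, "")
        lines.append("\t".join([set_id, desc, *sorted(sets[set_id])]))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_table(
    frame: pd.DataFrame,
    path: str | Path,
    sort_by: Optional[Sequence[str]] = None,
    column_map: Optional[Mapping[str, str]] = None,
) -> None:
    """Write a CSV with byte-stable (key-sorted) row order and a JSON sidecar.

    +inf serializes as the literal string ``Inf``; missing values as ``NA``.
    """
    out = frame.copy()
    if sort_by:
        out = out.sort_values(list(sort_by), kind="mergesort").reset_index(drop=True)
    for col in out.columns:
        if out[col].dtype.kind == "f":
            out[col] = out[col].map(_fmt_float)
    out.to_csv(path, index=False, na_rep="NA", encoding="utf-8", lineterminator="\n")
    sidecar = Path(str(path) + ".schema.json")
    sidecar.write_text(
        json.dumps(
            {"columns": list(frame.columns), "column_map": dict(column_map or {})},
            indent=2,
            sort_keys=True,
        )
        + "\n",
        encoding="utf-8",
    )


def _fmt_float(v):
    if pd.isna(v):
        return "NA"
    if np.isposinf(v):
        return "Inf"
    if np.isneginf(v):
        return "-Inf"
    return repr(float(v))


def parse_float(v) -> float:
    """Inverse of the writer's float convention (``Inf``/``NA`` aware)."""
    if v is None or v == "NA":
        return float("nan")
    if v == "Inf":
        return float("inf")
    if v == "-Inf":
        return float("-inf")
    return float(v)
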