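"""Reading and writing the pipeline's on-disk artifacts.

Formats:

* molecule libraries — ``.smi`` (one ``SMILES<whitespace>id`` per line)
  or SDF (V2000), parsed with RDKit;
* activity tables — CSV/TSV with a fixed header vocabulary emulating a
  ChEMBL activity export;
* family definitions — JSON with an explicit ``stage`` field and, for
  refined families, the parent filtered family;
* score matrices — CSV, rows = families, columns = compounds.

Records that fail to parse are reported, never silently dropped: the
readers return a parse report alongside the loaded objects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.rdBase import BlockLogs

from .models import ACTIVITY_TYPES, ActivityRecord, Family, Molecule, ProfileMatrix

ACTIVITY_COLUMNS = ("compound_id", "family_id", "activity_type", "relation", "value", "unit")
OPTIONAL_ACTIVITY_COLUMNS = ("target_name", "explicit_label")


@dataclass
class ParseReport:
    """Per-file account of records that could not be loaded."""

    source: str
    n_ok: int = 0
    failures: list[tuple[int, str]] = field(default_factory=list)  # (record index, reason)

    @property
    def n_failed(self) -> int:
        return len(self.failures)


def _canonical_smiles(mol: Chem.Mol) -> str:
    return Chem.MolToSmiles(mol)


def read_molecules(
    path: str | Path, format: str | None = None
) -> tuple[list[Molecule], ParseReport]:
    """Load a molecule library from a ``.smi`` or SDF file.

    Returns the parseable molecules (SMILES canonicalised) and a report
    listing every record that failed, with its line/record index.
    Raises if the file is missing or contains no parseable record.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "sdf" if path.suffix.lower() == "sdf" or path.suffix.lower() == ".sdf" else "smiles"
    if format not in ("smiles", "sdf"):
        raise ValueError(f"unknown molecule format {format!r}")

    molecules: list[Molecule] = []
    report = ParseReport(source=str(path))
    seen: set[str] = set()

    with BlockLogs():
        if format == "smiles":
            with open(path, encoding="utf-8") as fh:
                for lineno, line in enumerate(fh, start=1):
                    line = line.strip()
                    if not line or line.startswith("#"):
                        continue
                    parts = line.split(None, 1)
                    smiles = parts[0]
                    mol_id = parts[1].strip() if len(parts) > 1 else f"mol{lineno}"
                    mol = Chem.MolFromSmiles(smiles)
                    if mol is None:
                        report.failures.append((lineno, f"unparseable SMILES {smiles!r}"))
                        continue
                    if mol_id in seen:
                        report.failures.append((lineno, f"duplicate id {mol_id!r}"))
                        continue
                    seen.add(mol_id)
                    molecules.append(Molecule(id=mol_id, smiles=_canonical_smiles(mol)))
        else:
            supplier = Chem.SDMolSupplier(str(path))
            for idx, mol in enumerate(supplier):
                if mol is None:
                    report.failures.append((idx, "unparseable SDF record"))
                    continue
                mol_id = (
                    mol.GetProp("_Name").strip()
                    if mol.HasProp("_Name") and mol.GetProp("_Name").strip()
                    else f"mol{idx}"
                )
                if mol_id in seen:
                    report.failures.append((idx, f"duplicate id {mol_id!r}"))
                    continue
                seen.add(mol_id)
                name = mol.GetProp("name") if mol.HasProp("name") else None
                molecules.append(
                    Molecule(id=mol_id, smiles=_canonical_smiles(mol), name=name)
                )

    report.n_ok = len(molecules)
    if not molecules:
        raise ValueError(f"no parseable molecule records in {path}")
    return molecules, report


def write_molecules(molecules: list[Molecule], path: str | Path) -> None:
    """Write a ``.smi`` library, one ``SMILES id`` pair per line."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for m in molecules:
            fh.write(f"{m.smiles}\t{m.id}\n")


def read_activity_table(path: str | Path) -> tuple[list[ActivityRecord], ParseReport]:
    """Load a CSV/TSV bioactivity table into typed records.

    The delimiter is auto-detected (comma or tab).  Rows with an
    activity type outside the eight-category rule vocabulary, or with
    malformed fields, are excluded and listed in the report.  Unknown
    extra columns are ignored.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=None, engine="python", comment="#", dtype=str)
    missing = [c for c in ACTIVITY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"activity table {path} lacks required columns: {missing}")

    records: list[ActivityRecord] = []
    report = ParseReport(source=str(path))
    for idx, row in df.iterrows():
        atype = str(row["activity_type"]).strip()
        if atype not in ACTIVITY_TYPES:
            report.failures.append((int(idx), f"unknown activity_type {atype!r}"))
            continue
        try:
            value = float(row["value"])
        except (TypeError, ValueError):
            report.failures.append((int(idx), f"unparseable value {row['value']!r}"))
            continue
        label = None
        if "explicit_label" in df.columns and pd.notna(row.get("explicit_label")):
            label = str(row["explicit_label"]).strip() or None
        target = None
        if "target_name" in df.columns and pd.notna(row.get("target_name")):
            target = str(row["target_name"]).strip() or None
        try:
            records.append(
                ActivityRecord(
                    compound_id=str(row["compound_id"]).strip(),
                    family_id=str(row["family_id"]).strip(),
                    activity_type=atype,
                    relation=str(row["relation"]).strip(),
                    value=value,
                    unit=str(row["unit"]).strip(),
                    target_name=target,
                    explicit_label=label,
                )
            )
        except ValueError as exc:
            report.failures.append((int(idx), str(exc)))
    report.n_ok = len(records)
    return records, report


def write_activity_table(records: list[ActivityRecord], path: str | Path) -> None:
    """Write activity records as a CSV with the fixed header vocabulary."""
    df = pd.DataFrame(
        [
            {
                "compound_id": r.compound_id,
                "family_id": r.family_id,
                "target_name": r.target_name,
                "activity_type": r.activity_type,
                "relation": r.relation,
                "value": r.value,
                "unit": r.unit,
                "explicit_label": r.explicit_label,
            }
            for r in records
        ],
        columns=list(ACTIVITY_COLUMNS[:2]) + ["target_name", "activity_type", "relation", "value", "unit", "explicit_label"],
    )
    df.to_csv(path, index=False)


def write_families(
    families: list[Family], path: str | Path, meta: dict | None = None
) -> None:
    """Serialise families to JSON, preserving stage and parentage.

    Empty families violate the Family invariant and are rejected (the
    Family constructor already enforces this; the check here guards
    hand-built dictionaries passed through ``meta``-free code paths).
    """
    payload = {
        "meta": meta or {},
        "families": [
            {
                "family_id": f.family_id,
                "stage": f.stage,
                "target_name": f.target_name,
                "parent_id": f.parent_id,
                "members": sorted(f.member_ids),
            }
            for f in sorted(families, key=lambda f: f.family_id)
        ],
    }
    for f in families:
        if not f.member_ids:
            raise ValueError(f"refusing to write empty family {f.family_id!r}")
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_families(path: str | Path) -> list[Family]:
    """Load families from JSON written by :func:`write_families`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    if "families" not in payload:
        raise ValueError(f"{path} is not a family file (no 'families' key)")
    out = []
    for d in payload["families"]:
        out.append(
            Family(
                family_id=d["family_id"],
                stage=d["stage"],
                member_ids=frozenset(d["members"]),
                target_name=d.get("target_name"),
                parent_id=d.get("parent_id"),
            )
        )
    return out


def write_score_matrix(
    matrix: ProfileMatrix, path: str | Path, meta: dict | None = None
) -> None:
    """Write a PR-score matrix as CSV (rows = families, columns = compounds).

    Metadata is embedded as ``#``-prefixed comment lines before the header.
    """
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for key, val in (meta or {}).items():
            fh.write(f"# {key}={val}\n")
        df = pd.DataFrame(
            matrix.scores, index=matrix.family_ids, columns=matrix.compound_ids
        )
        df.index.name = "family_id"
        df.to_csv(fh, float_format="%.12g")


def read_score_matrix(path: str | Path) -> ProfileMatrix:
    """Load a PR-score matrix written by :func:`write_score_matrix`."""
    df = pd.read_csv(path, comment="#", index_col=0)
    return ProfileMatrix(
        family_ids=[str(i) for i in df.index],
        compound_ids=[str(c) for c in df.columns],
        scores=df.to_numpy(dtype=float),
    )


def family_lineage_check(families: list[Family]) -> None:
    """Validate refined-family parentage: parents exist and contain the children."""
    by_id = {f.family_id: f for f in families}
    for f in families:
        if f.stage != "refined":
            continue
        parent = by_id.get(f.parent_id)
        if parent is None:
            continue  # parent may legitimately live in another file
        if not f.member_ids <= parent.member_ids:
            raise ValueError(
                f"refined family {f.family_id!r} has members outside parent {f.parent_id!r}"
            )
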