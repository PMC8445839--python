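"""Molecule records and plain-text I/O.

A :class:`MoleculeRecord` carries one molecule's identity, SMILES, class
label (natural / synthetic / unknown), optional activity annotation with a
target id, and an optional natural-product-likeness (NPL) score.  Datasets
move between modules as plain lists of records; CSV with the column schema
``id,smiles[,source_class,activity,target_id,npl]`` is the on-disk form, and
bare SMILES files (one molecule per line) are accepted for convenience.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

SOURCE_CLASSES = ("natural", "synthetic", "unknown")
ACTIVITIES = ("active", "inactive", "unknown")

CSV_COLUMNS = ("id", "smiles", "source_class", "activity", "target_id", "npl")


@dataclass(frozen=True)
class MoleculeRecord:
    """One molecule with identity, structure and labels."""

    id: str
    smiles: str
    source_class: str = "unknown"
    activity: str = "unknown"
    target_id: str | None = None
    npl: float | None = None

    def __post_init__(self) -> None:
        if self.source_class not in SOURCE_CLASSES:
            raise ValueError(f"source_class must be one of {SOURCE_CLASSES}, "
                             f"got {self.source_class!r}")
        if self.activity not in ACTIVITIES:
            raise ValueError(f"activity must be one of {ACTIVITIES}, "
                             f"got {self.activity!r}")

    def with_npl(self, npl: float) -> "MoleculeRecord":
        return replace(self, npl=npl)

    def with_smiles(self, smiles: str) -> "MoleculeRecord":
        return replace(self, smiles=smiles)


def records_to_frame(records: Sequence[MoleculeRecord]) -> pd.DataFrame:
    """Tabulate records in the standard CSV column order."""
    return pd.DataFrame(
        [
            {
                "id": r.id,
                "smiles": r.smiles,
                "source_class": r.source_class,
                "activity": r.activity,
                "target_id": r.target_id,
                "npl": r.npl,
            }
            for r in records
        ],
        columns=list(CSV_COLUMNS),
    )


def frame_to_records(frame: pd.DataFrame) -> list[MoleculeRecord]:
    if "id" not in frame.columns or "smiles" not in frame.columns:
        raise ValueError("molecule table requires 'id' and 'smiles' columns")
    out: list[MoleculeRecord] = []
    for row in frame.itertuples(index=False):
        d = row._asdict()
        npl = d.get("npl")
        if npl is not None and (isinstance(npl, float) and math.isnan(npl)):
            npl = None
        target = d.get("target_id")
        if target is not None and (not isinstance(target, str) and pd.isna(target)):
            target = None
        out.append(
            MoleculeRecord(
                id=str(d["id"]),
                smiles=str(d["smiles"]),
                source_class=_norm_enum(d.get("source_class"), SOURCE_CLASSES),
                activity=_norm_enum(d.get("activity"), ACTIVITIES),
                target_id=str(target) if target is not None else None,
                npl=float(npl) if npl is not None else None,
            )
        )
    return out


def _norm_enum(value, allowed: tuple[str, ...]) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return "unknown"
    value = str(value).strip().lower()
    return value if value in allowed else "unknown"


def read_molecules(path: str | Path) -> list[MoleculeRecord]:
    """Read molecules from CSV (standard schema) or a bare SMILES file.

    A file whose first line contains a comma and the ``id``/``smiles``
    headers is treated as CSV; otherwise each non-empty line is one SMILES,
    with ids assigned positionally (``mol_0``, ``mol_1``, ...).
    """
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
    if "smiles" in first.lower() and "," in first:
        return frame_to_records(pd.read_csv(path, dtype={"id": str, "target_id": str}))
    records = []
    with open(path, "r", encoding="utf-8") as fh:
        for i, line in enumerate(fh):
            token = line.strip().split()
            if not token:
                continue
            smiles = token[0]
            mol_id = token[1] if len(token) > 1 else f"mol_{i}"
            records.append(MoleculeRecord(id=mol_id, smiles=smiles))
    return records


def write_molecules(records: Sequence[MoleculeRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def check_unique_ids(records: Iterable[MoleculeRecord]) -> None:
    seen: set[str] = set()
    for r in records:
        if r.id in seen:
            raise ValueError(f"duplicate molecule id {r.id!r} in dataset")
        seen.add(r.id)
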