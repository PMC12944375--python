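"""Compound tables, descriptor matrices and curation rules.

Data enter the workflow as two CSV files: a compound table (id, SMILES,
optional name/MW, LD50 in mg/kg and/or a binary toxicity class) and a
numeric descriptor matrix keyed by compound id (e.g. Mold2 columns
D001...D777).  Descriptor calculation itself is out of scope — descriptors
arrive precomputed.

The binary endpoint follows the EPA acute-oral-toxicity categories: a
compound is *low* toxicity iff its rat oral LD50 is strictly greater than
500 mg/kg (categories III/IV), otherwise *high* (categories I/II).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

DEFAULT_LD50_THRESHOLD = 500.0  # mg/kg; EPA category II/III boundary


class ToxClass(enum.Enum):
    """Binary acute-oral-toxicity class.

    Numeric encoding used in explanation outputs: low = 0, high = 1.
    """

    LOW = "low"
    HIGH = "high"

    @property
    def code(self) -> int:
        return 1 if self is ToxClass.HIGH else 0

    def __str__(self) -> str:  # CSV-friendly
        return self.value


class ValidationError(ValueError):
    """Raised when an input table or value violates the data contract."""


@dataclass
class CompoundRecord:
    """One chemical: identifiers, structure and toxicity endpoint."""

    id: str
    smiles: str
    name: str | None = None
    mw: float | None = None
    ld50: float | None = None
    tox_class: ToxClass | None = None

    def __post_init__(self) -> None:
        if self.ld50 is not None and not self.ld50 > 0:
            raise ValidationError(
                f"compound {self.id!r}: LD50 must be positive (got {self.ld50})"
            )
        if self.mw is not None and not self.mw > 0:
            raise ValidationError(
                f"compound {self.id!r}: MW must be positive (got {self.mw})"
            )


@dataclass
class DescriptorMatrix:
    """Compounds x numeric features, id-aligned.

    Thin wrapper around a float DataFrame indexed by compound id; rows with
    missing values are rejected at load time unless imputation is explicit.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        if self.df.index.has_duplicates:
            dups = self.df.index[self.df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate compound ids: {dups}")
        if self.df.shape[1] < 1:
            raise ValidationError("descriptor matrix needs at least one column")

    @property
    def row_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def column_names(self) -> list[str]:
        return list(self.df.columns)

    @property
    def values(self) -> np.ndarray:
        return self.df.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.df.shape

    def select_rows(self, ids: Sequence[str]) -> "DescriptorMatrix":
        missing = [i for i in ids if i not in self.df.index]
        if missing:
            raise ValidationError(f"unknown compound ids: {missing[:5]}")
        return DescriptorMatrix(self.df.loc[list(ids)])

    def select_columns(self, names: Sequence[str]) -> "DescriptorMatrix":
        missing = [c for c in names if c not in self.df.columns]
        if missing:
            raise ValidationError(f"unknown descriptor columns: {missing[:5]}")
        return DescriptorMatrix(self.df[list(names)])

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index_label="id")


@dataclass
class LabeledDataset:
    """Compound records plus their descriptor matrix."""

    records: list[CompoundRecord]
    descriptors: DescriptorMatrix

    def __post_init__(self) -> None:
        ids = {r.id for r in self.records}
        if len(ids) != len(self.records):
            raise ValidationError("duplicate compound ids in records")
        stray = set(self.descriptors.row_ids) - ids
        if stray:
            raise ValidationError(
                f"descriptor rows without a compound record: {sorted(stray)[:5]}"
            )

    def labels(self) -> dict[str, ToxClass]:
        out: dict[str, ToxClass] = {}
        for r in self.records:
            if r.tox_class is not None:
                out[r.id] = r.tox_class
        return out

    def record_by_id(self) -> dict[str, CompoundRecord]:
        return {r.id: r for r in self.records}


def assign_toxicity_class(
    ld50: float, threshold: float = DEFAULT_LD50_THRESHOLD
) -> ToxClass:
    """Classify a rat oral LD50 (mg/kg) as high or low toxicity.

    Low toxicity requires LD50 strictly greater than the threshold
    (default 500 mg/kg); a value exactly at the boundary is high.
    """
    if ld50 is None or not np.isfinite(ld50) or ld50 <= 0:
        raise ValidationError(f"LD50 must be a positive number (got {ld50})")
    if threshold <= 0:
        raise ValidationError(f"threshold must be positive (got {threshold})")
    return ToxClass.LOW if ld50 > threshold else ToxClass.HIGH


ACCEPTED = "accepted"
REJECTED_MULTIFRAGMENT = "rejected_multifragment"
REJECTED_UNPARSABLE = "rejected_unparsable"


def screen_structure(smiles: str) -> str:
    """Screen a SMILES for the single-fragment, parsable requirement.

    Mixtures and salts (dot-separated fragments) are rejected outright; no
    desalting is attempted.  Returns one of ``accepted``,
    ``rejected_multifragment``, ``rejected_unparsable``.
    """
    if not isinstance(smiles, str) or not smiles.strip():
        return REJECTED_UNPARSABLE
    if "." in smiles:
        return REJECTED_MULTIFRAGMENT
    mol = Chem.MolFromSmiles(smiles)
    return ACCEPTED if mol is not None else REJECTED_UNPARSABLE


_CLASS_ALIASES = {
    "low": ToxClass.LOW,
    "high": ToxClass.HIGH,
    "0": ToxClass.LOW,
    "1": ToxClass.HIGH,
}


def _parse_class(raw: object, where: str) -> ToxClass:
    key = str(raw).strip().lower()
    if key not in _CLASS_ALIASES:
        raise ValidationError(f"{where}: unrecognised toxicity class {raw!r}")
    return _CLASS_ALIASES[key]


def read_compound_table(
    path: str | Path,
    assign_classes: bool = False,
    threshold: float = DEFAULT_LD50_THRESHOLD,
) -> list[CompoundRecord]:
    """Read a compound CSV (columns: id, smiles, [name, mw, ld50, tox_class]).

    With ``assign_classes=True`` any record with an LD50 but no explicit
    class gets one from :func:`assign_toxicity_class`.
    """
    df = pd.read_csv(path, dtype={"id": str})
    for col in ("id", "smiles"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing mandatory column {col!r}")
    if df["id"].duplicated().any():
        dups = df.loc[df["id"].duplicated(), "id"].tolist()
        raise ValidationError(f"{path}: duplicate ids {dups[:5]}")

    records: list[CompoundRecord] = []
    for i, row in df.iterrows():
        ld50 = None
        if "ld50" in df.columns and pd.notna(row["ld50"]):
            ld50 = float(row["ld50"])
        tox = None
        if "tox_class" in df.columns and pd.notna(row["tox_class"]):
            tox = _parse_class(row["tox_class"], f"{path} row {i}")
        elif assign_classes and ld50 is not None:
            tox = assign_toxicity_class(ld50, threshold)
        records.append(
            CompoundRecord(
                id=str(row["id"]),
                smiles=str(row["smiles"]),
                name=(str(row["name"]) if "name" in df.columns and pd.notna(row.get("name")) else None),
                mw=(float(row["mw"]) if "mw" in df.columns and pd.notna(row.get("mw")) else None),
                ld50=ld50,
                tox_class=tox,
            )
        )
    return records


def read_descriptor_csv(
    path: str | Path, impute_mean: bool = False
) -> DescriptorMatrix:
    """Read an id-keyed numeric descriptor CSV.

    Missing or non-numeric cells are an error naming the offending
    row/column; with ``impute_mean=True`` missing cells are filled with the
    column mean instead.
    """
    df = pd.read_csv(path, dtype={"id": str})
    if "id" not in df.columns:
        raise ValidationError(f"{path}: missing mandatory column 'id'")
    df = df.set_index("id")
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicate ids {dups[:5]}")

    non_numeric = []
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            non_numeric.append((df.index[bad.argmax()], col))
        df[col] = coerced
    if non_numeric:
        rid, col = non_numeric[0]
        raise ValidationError(
            f"{path}: non-numeric descriptor cell at row {rid!r}, column {col!r}"
        )

    if df.isna().any().any():
        if impute_mean:
            df = df.fillna(df.mean())
        else:
            col = df.columns[df.isna().any().argmax()]
            rid = df.index[df[col].isna().argmax()]
            raise ValidationError(
                f"{path}: missing descriptor value at row {rid!r}, column {col!r}"
                " (pass impute_mean=True to mean-impute)"
            )
    return DescriptorMatrix(df.astype(float))


def read_batch_structures(path: str | Path) -> list[tuple[str, str]]:
    """Read batch prediction input: a SMILES list or an SDF (v2000).

    SMILES list: one structure per line, optionally ``smiles<TAB>id``.
    SDF: molecule name line (or a synthetic ``mol_<n>``) is the id.
    Returns ordered (id, smiles) pairs.
    """
    path = Path(path)
    if path.suffix.lower() == ".sdf":
        out = []
        supplier = Chem.SDMolSupplier(str(path), sanitize=True)
        for i, mol in enumerate(supplier):
            if mol is None:
                raise ValidationError(f"{path}: unparsable molecule at index {i}")
            name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
            out.append((name or f"mol_{i + 1}", Chem.MolToSmiles(mol)))
        return out

    out = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            smiles = parts[0].strip()
            ident = parts[1].strip() if len(parts) > 1 else f"mol_{i + 1}"
            out.append((ident, smiles))
    return out


def write_results(path: str | Path, records: Iterable[CompoundRecord]) -> None:
    """Write compound records back to CSV; read_compound_table round-trips."""
    rows = []
    for r in records:
        rows.append(
            {
                "id": r.id,
                "smiles": r.smiles,
                "name": r.name,
                "mw": r.mw,
                "ld50": r.ld50,
                "tox_class": str(r.tox_class) if r.tox_class is not None else None,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
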